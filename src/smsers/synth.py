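"""Synthetic spectrum generator.

Renders analytic band templates onto a wavenumber grid with additive white
noise, a slowly varying polynomial baseline and shot-to-shot intensity
variation, and simulates the three experiment designs analysed downstream:
sparse bi-analyte event sets, trap on/off switching series, and large
conformational-species sets.

Every stochastic operation takes an explicit seed (or an already-constructed
``numpy.random.Generator``); there is no hidden global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Spectrum, SpectrumSet, WavenumberAxis

__all__ = [
    "PeakBand",
    "SpeciesTemplate",
    "NoiseModel",
    "EventProcess",
    "render_spectrum",
    "template_peak_height",
    "amplitude_for_snr",
    "merge_templates",
    "scale_template",
    "simulate_biasers_set",
    "simulate_switching_series",
    "simulate_hiapp_set",
    "tyr_mixture_template",
    "TYR_PKA",
]

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PeakBand:
    """One analytic band: integrated area, centre and width.

    ``lineshape`` is ``"lorentzian"``, ``"gaussian"`` or ``"pseudo-voigt"``
    (the latter mixes the two with Lorentzian fraction ``eta``).
    """

    center: float
    fwhm: float
    area: float
    lineshape: str = "lorentzian"
    eta: float = 0.5

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center}: fwhm must be positive")
        if self.area < 0:
            raise ValueError(f"band at {self.center}: area must be non-negative")
        if self.lineshape not in ("lorentzian", "gaussian", "pseudo-voigt"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("pseudo-voigt eta must lie in [0, 1]")

    @classmethod
    def from_height(
        cls,
        center: float,
        fwhm: float,
        height: float,
        lineshape: str = "lorentzian",
        eta: float = 0.5,
    ) -> "PeakBand":
        """Construct a band from its peak height instead of its area."""
        gamma = fwhm / 2.0
        sigma = fwhm / _GAUSS_FWHM
        if lineshape == "lorentzian":
            area = height * math.pi * gamma
        elif lineshape == "gaussian":
            area = height * sigma * math.sqrt(2.0 * math.pi)
        else:
            # unit-area pseudo-voigt height = eta/(pi*gamma) + (1-eta)/(sigma*sqrt(2pi))
            unit_h = eta / (math.pi * gamma) + (1.0 - eta) / (sigma * math.sqrt(2.0 * math.pi))
            area = height / unit_h
        return cls(center, fwhm, area, lineshape, eta)

    @property
    def height(self) -> float:
        """Peak height at the band centre."""
        gamma = self.fwhm / 2.0
        sigma = self.fwhm / _GAUSS_FWHM
        if self.lineshape == "lorentzian":
            return self.area / (math.pi * gamma)
        if self.lineshape == "gaussian":
            return self.area / (sigma * math.sqrt(2.0 * math.pi))
        return self.area * (
            self.eta / (math.pi * gamma)
            + (1.0 - self.eta) / (sigma * math.sqrt(2.0 * math.pi))
        )

    def profile(self, nu: np.ndarray) -> np.ndarray:
        """Evaluate the band on grid *nu*."""
        gamma = self.fwhm / 2.0
        sigma = self.fwhm / _GAUSS_FWHM
        d = nu - self.center
        lor = (self.area / math.pi) * gamma / (d * d + gamma * gamma)
        if self.lineshape == "lorentzian":
            return lor
        gau = self.area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
            -0.5 * (d / sigma) ** 2
        )
        if self.lineshape == "gaussian":
            return gau
        return self.eta * lor + (1.0 - self.eta) * gau


@dataclass
class SpeciesTemplate:
    """Named set of bands describing one analyte/species."""

    name: str
    bands: list[PeakBand]
    provenance: str = ""

    def __post_init__(self):
        if not self.bands:
            # the empty template is permitted only via explicit construction
            # helpers (noise-only rendering uses template=None instead)
            pass

    def profile(self, nu: np.ndarray) -> np.ndarray:
        out = np.zeros_like(nu, dtype=float)
        for b in self.bands:
            out += b.profile(nu)
        return out


@dataclass
class NoiseModel:
    """Additive white Gaussian noise + polynomial baseline + amplitude jitter.

    ``baseline_coeffs`` are polynomial coefficients (highest order first,
    ``numpy.polyval`` convention) evaluated in the normalised coordinate
    ``x = (nu - mid) / (span/2)`` in [-1, 1], so magnitudes stay comparable
    across axes.  ``intensity_cv`` is the fractional shot-to-shot scale
    variation of the whole template.
    """

    additive_sd: float = 0.125
    baseline_coeffs: Sequence[float] = field(default_factory=lambda: (0.0,))
    intensity_cv: float = 0.0

    def __post_init__(self):
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")

    def baseline(self, nu: np.ndarray) -> np.ndarray:
        mid = 0.5 * (nu[0] + nu[-1])
        half = max(0.5 * (nu[-1] - nu[0]), 1.0)
        x = (nu - mid) / half
        return np.polyval(list(self.baseline_coeffs), x)


NOISELESS = NoiseModel(additive_sd=0.0, baseline_coeffs=(0.0,), intensity_cv=0.0)


@dataclass
class EventProcess:
    """Sparse stochastic occupancy of the probed volume.

    Each spectrum independently carries analyte signal with probability
    ``p_event``; the analyte is drawn from ``mix`` (template name -> weight).
    With probability ``dual_rule`` (conditional on an event) all mixture
    species co-occupy and their templates superpose.
    """

    p_event: float = 0.05
    mix: Mapping[str, float] = field(default_factory=dict)
    dual_rule: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p_event <= 1.0:
            raise ValueError("p_event must lie in [0, 1]")
        if not 0.0 <= self.dual_rule <= 1.0:
            raise ValueError("dual_rule must lie in [0, 1]")
        if self.mix:
            total = float(sum(self.mix.values()))
            if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(f"mixture weights must sum to 1, got {total}")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_template_on_axis(template: SpeciesTemplate, axis: WavenumberAxis) -> None:
    for b in template.bands:
        if not (axis.start <= b.center <= axis.stop):
            raise ValueError(
                f"template {template.name!r}: band center {b.center} cm-1 lies "
                f"outside axis span [{axis.start}, {axis.stop}]"
            )


def template_peak_height(template: SpeciesTemplate, axis: WavenumberAxis) -> float:
    """Maximum of the noise-free template profile on *axis*."""
    if not template.bands:
        return 0.0
    return float(np.max(template.profile(axis.values)))


def amplitude_for_snr(
    template: SpeciesTemplate, axis: WavenumberAxis, noise: NoiseModel, snr: float
) -> float:
    """Amplitude scale that puts the template's tallest point at snr x noise SD."""
    h = template_peak_height(template, axis)
    if h <= 0 or noise.additive_sd <= 0:
        return 1.0
    return snr * noise.additive_sd / h


def render_spectrum(
    template: SpeciesTemplate | None,
    axis: WavenumberAxis,
    noise: NoiseModel = NOISELESS,
    amplitude_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    meta: Mapping[str, object] | None = None,
) -> Spectrum:
    """Render one spectrum: bands x jittered amplitude + baseline + noise.

    ``template=None`` renders a signal-free spectrum (baseline + noise only,
    truth label "none").
    """
    rng = _rng(seed)
    nu = axis.values
    intensity = np.zeros_like(nu)
    label = "none"
    if template is not None and template.bands:
        _check_template_on_axis(template, axis)
        scale = amplitude_scale
        if noise.intensity_cv > 0:
            scale *= max(0.0, 1.0 + noise.intensity_cv * rng.standard_normal())
        intensity = template.profile(nu) * scale
        label = template.name
    intensity = intensity + noise.baseline(nu)
    if noise.additive_sd > 0:
        intensity = intensity + noise.additive_sd * rng.standard_normal(nu.size)
    full_meta: dict[str, object] = {"label_truth": label, "integration_s": 1.0}
    if meta:
        full_meta.update(meta)
    return Spectrum(axis, intensity, full_meta)


def merge_templates(name: str, templates: Sequence[SpeciesTemplate]) -> SpeciesTemplate:
    bands: list[PeakBand] = []
    for t in templates:
        bands.extend(t.bands)
    return SpeciesTemplate(name, bands, "superposition: " + "+".join(t.name for t in templates))


def scale_template(template: SpeciesTemplate, factor: float) -> SpeciesTemplate:
    bands = [
        PeakBand(b.center, b.fwhm, b.area * factor, b.lineshape, b.eta)
        for b in template.bands
    ]
    return SpeciesTemplate(template.name, bands, template.provenance)


def simulate_biasers_set(
    n: int,
    process: EventProcess,
    noise: NoiseModel,
    axis: WavenumberAxis,
    seed: int | np.random.Generator = 0,
    templates: Mapping[str, SpeciesTemplate] | None = None,
    amplitude_scale: float = 1.0,
) -> SpectrumSet:
    """Simulate a sparse bi-analyte measurement series of *n* spectra.

    Ground-truth labels are stored in each spectrum's ``label_truth``; dual
    occupancy is labelled ``dual_<A>_<B>`` with names in mixture order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if templates is None:
        from .templates import builtin_template

        templates = {name: builtin_template(name) for name in process.mix}
    missing = [name for name in process.mix if name not in templates]
    if missing:
        raise ValueError(f"templates missing for mixture species: {missing}")
    rng = _rng(seed)
    names = list(process.mix)
    weights = np.array([process.mix[k] for k in names], dtype=float)
    spectra = []
    for i in range(n):
        meta = {"session_id": "sim", "time_s": float(i)}
        occupied = rng.random() < process.p_event
        if not occupied:
            s = render_spectrum(None, axis, noise, seed=rng, meta=meta)
        elif len(names) >= 2 and rng.random() < process.dual_rule:
            merged = merge_templates("dual_" + "_".join(names), [templates[k] for k in names])
            s = render_spectrum(merged, axis, noise, amplitude_scale, seed=rng, meta=meta)
        else:
            pick = names[int(rng.choice(len(names), p=weights))]
            s = render_spectrum(templates[pick], axis, noise, amplitude_scale, seed=rng, meta=meta)
        spectra.append(s)
    return SpectrumSet(spectra, axis)


def simulate_switching_series(
    n_cycles: int,
    on_template: SpeciesTemplate,
    noise: NoiseModel,
    axis: WavenumberAxis,
    seed: int | np.random.Generator = 0,
    amplitude_scale: float = 1.0,
) -> SpectrumSet:
    """Simulate trap on/off switching: 2*n_cycles spectra alternating on/off.

    On-state spectra contain the analyte template (with shot-to-shot scale
    variation per ``noise.intensity_cv``); off-state spectra are baseline +
    noise only.  ``trap_state`` metadata is set accordingly.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = _rng(seed)
    spectra = []
    for cycle in range(n_cycles):
        for state in ("on", "off"):
            meta = {
                "trap_state": state,
                "session_id": "switching",
                "time_s": float(len(spectra)),
            }
            tmpl = on_template if state == "on" else None
            spectra.append(
                render_spectrum(tmpl, axis, noise, amplitude_scale, seed=rng, meta=meta)
            )
    return SpectrumSet(spectra, axis)


def simulate_hiapp_set(
    n: int,
    species_probs: Mapping[str, float],
    noise: NoiseModel,
    axis: WavenumberAxis,
    seed: int | np.random.Generator = 0,
    templates: Mapping[str, SpeciesTemplate] | None = None,
    amplitude_scale: float = 1.0,
) -> SpectrumSet:
    """Simulate a conformational-species set.

    ``species_probs`` maps template names (e.g. ``hIAPP_helix_coil``,
    ``hIAPP_typeI``, ``hIAPP_typeII``) to probabilities summing to <= 1;
    the remainder yields signal-free (below-threshold) spectra.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = float(sum(species_probs.values()))
    if total > 1.0 + 1e-9:
        raise ValueError(f"species probabilities sum to {total} > 1")
    if templates is None:
        from .templates import builtin_template

        templates = {name: builtin_template(name) for name in species_probs}
    rng = _rng(seed)
    names = list(species_probs)
    probs = np.array([species_probs[k] for k in names], dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(probs)])
    spectra = []
    for i in range(n):
        u = rng.random()
        meta = {"session_id": "sim", "time_s": float(i)}
        idx = int(np.searchsorted(edges, u, side="right")) - 1
        if u >= edges[-1] or idx >= len(names):
            s = render_spectrum(None, axis, noise, seed=rng, meta=meta)
        else:
            s = render_spectrum(templates[names[idx]], axis, noise, amplitude_scale, seed=rng, meta=meta)
        spectra.append(s)
    return SpectrumSet(spectra, axis)


#: Free tyrosine ionizable-group pKa values: carboxyl, alpha-amino, phenol OH.
TYR_PKA = {"carboxyl": 2.2, "amino": 9.2, "phenol": 10.5}


def tyr_mixture_template(pH: float, pka: Mapping[str, float] | None = None) -> SpeciesTemplate:
    """pH-dependent tyrosine template.

    A convex combination of the +1 (fully protonated) and -2 (fully
    deprotonated) limiting templates.  The mixing coefficient is the
    independent-site protonation coordinate: the net fractional charge q(pH)
    mapped linearly from the [-2, +1] range onto [0, 1].  Both v8a bands
    (1620 and 1602 cm-1) are present with protonation-dependent weights, so
    the apparent band centre shifts continuously from 1620 to 1602.
    """
    from .chemphys import IonizableGroup, net_charge
    from .templates import builtin_template

    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {pH}")
    pka = dict(pka or TYR_PKA)
    for name, value in pka.items():
        if not 0.0 < value < 14.0:
            raise ValueError(f"pKa for {name!r} must lie in (0, 14), got {value}")
    groups = [
        IonizableGroup("carboxyl", pka["carboxyl"], "acid"),
        IonizableGroup("amino", pka["amino"], "base"),
        IonizableGroup("phenol", pka["phenol"], "acid"),
    ]
    q = net_charge(groups, pH).fractional_charge  # in [-2, +1]
    lam = (q + 2.0) / 3.0  # 1 at full protonation, 0 at full deprotonation
    plus = scale_template(builtin_template("Tyr_plus1"), lam)
    minus = scale_template(builtin_template("Tyr_minus2"), 1.0 - lam)
    merged = merge_templates(f"Tyr_pH{pH:g}", [plus, minus])
    merged.provenance = (
        f"tyrosine at pH {pH:g}: {lam:.3f} x (+1 template) + {1 - lam:.3f} x (-2 template)"
    )
    return merged
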