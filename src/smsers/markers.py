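"""Structural marker analysis: amide-I second-derivative bands, the tyrosine
Fermi doublet, the ν8a charge-state marker, disulfide conformation markers,
and the conformational-species decision table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .core import Spectrum, SpectrumSet
from .events import BandHit, DetectionWindow, detect_band
from .preprocess import (
    AMIDE_I_REGION,
    DEFAULT_DERIV2,
    DEFAULT_QUIET_REGION,
    DEFAULT_SMOOTH,
    NoiseEstimate,
    SGParams,
    estimate_noise_sd,
    noise_sd_second_derivative,
    second_derivative_region,
)

__all__ = [
    "AmideBands",
    "DoubletRatio",
    "SpeciesCall",
    "HIAPP_CALLS",
    "ClassifierConfig",
    "amide_band_centers",
    "band_fwhm",
    "doublet_ratio",
    "v8a_position",
    "disulfide_marker",
    "classify_hiapp",
    "classify_hiapp_evidence",
    "species_census",
]

HIAPP_CALLS = (
    "predominant_helix_coil",
    "typeI_turn",
    "typeII_beta",
    "fibril_like",
    "unclassified",
)

#: Integration windows for the tyrosine Fermi doublet (cm⁻¹).
DOUBLET_WINDOW_830 = (822.0, 840.0)
DOUBLET_WINDOW_854 = (846.0, 864.0)

#: Detection windows for residue-specific markers.
V8A_WINDOW = DetectionWindow("v8a", 1595.0, 1630.0)
DISULFIDE_523 = DetectionWindow("ss_523", 515.0, 531.0)
DISULFIDE_490 = DetectionWindow("ss_490", 482.0, 498.0)
AMIDE_III_1226 = DetectionWindow("amideIII_1226", 1220.0, 1232.0)


@dataclass(frozen=True)
class AmideBands:
    """Band centres/widths found in the amide-I second derivative."""

    centers: tuple[float, ...]
    widths: tuple[float, ...]
    trace: np.ndarray
    trace_axis: np.ndarray

    def __post_init__(self):
        if list(self.centers) != sorted(self.centers):
            raise ValueError("amide band centers must be sorted ascending")


@dataclass(frozen=True)
class DoubletRatio:
    """Integrated Fermi-doublet areas and their ratio I830/I854."""

    i830: float
    i854: float
    ratio: float | None
    uncertainty: float | None = None


@dataclass(frozen=True)
class SpeciesCall:
    call: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.call not in HIAPP_CALLS:
            raise ValueError(f"unknown species call {self.call!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the species decision table (all config-exposed)."""

    center_tol: float = 4.0          # cm-1 around each nominal amide-I position
    amide3_tol: float = 6.0          # cm-1 around the 1226 amide III marker
    ratio_threshold: float = 1.2     # doublet ratio separating "≈1" from ">1"
    broad_fwhm_min: float = 21.0     # cm-1; direct-domain band FWHM marking "broad"
    amide_core: tuple[float, float] = (1642.0, 1690.0)  # amide-I proper


DEFAULT_CLASSIFIER = ClassifierConfig()


def _second_derivative_floor(
    spectrum: Spectrum,
    noise: NoiseEstimate | None,
    sg: SGParams,
    presmooth: SGParams | None,
) -> float:
    if noise is not None and noise.sd > 0:
        return noise_sd_second_derivative(noise.sd, spectrum.axis.step, sg, presmooth)
    return 0.0


def amide_band_centers(
    spectrum: Spectrum,
    sg_params: SGParams = DEFAULT_DERIV2,
    noise: NoiseEstimate | None = None,
    region: tuple[float, float] = AMIDE_I_REGION,
    presmooth: SGParams | None = DEFAULT_SMOOTH,
    k_sigma: float = 3.0,
    rel_height_min: float = 0.15,
) -> AmideBands:
    """Find amide-I band centres as maxima of -d²I/dν².

    Peaks must clear both ``k_sigma`` times the propagated second-derivative
    noise floor and ``rel_height_min`` of the strongest peak; centres are
    refined by parabolic interpolation, widths are half-prominence widths in
    cm⁻¹.
    """
    d2 = second_derivative_region(spectrum, region, sg_params, presmooth)
    trace = d2.intensity
    nu = d2.axis.values
    floor = _second_derivative_floor(spectrum, noise, sg_params, presmooth)
    gmax = float(np.max(trace)) if trace.size else 0.0
    if gmax <= 0:
        return AmideBands((), (), trace, nu)
    height = max(k_sigma * floor, rel_height_min * gmax)
    prominence = max(0.5 * k_sigma * floor, 0.5 * rel_height_min * gmax)
    idx, props = find_peaks(trace, height=height, prominence=prominence)
    if idx.size == 0:
        return AmideBands((), (), trace, nu)
    widths_pts = peak_widths(trace, idx, rel_height=0.5)[0]
    step = d2.axis.step
    centers = []
    widths = []
    for i, w in zip(idx, widths_pts):
        c = _refine(nu, trace, int(i))
        centers.append(c)
        widths.append(float(w * step))
    order = np.argsort(centers)
    return AmideBands(
        tuple(float(centers[i]) for i in order),
        tuple(float(widths[i]) for i in order),
        trace,
        nu,
    )


def _refine(nu: np.ndarray, y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= y.size - 1:
        return float(nu[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-300:
        return float(nu[i])
    delta = float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -1.0, 1.0))
    return float(nu[i] + delta * (nu[1] - nu[0]))


def _region_areas(
    spectrum: Spectrum,
    window_a: tuple[float, float],
    window_b: tuple[float, float],
    margin: float = 8.0,
) -> tuple[float, int, float, int]:
    """Areas of two sub-windows above one shared flank-anchored baseline."""
    from .events import flank_baseline

    lo = min(window_a[0], window_b[0])
    hi = max(window_a[1], window_b[1])
    nu_full = spectrum.axis.values
    y_full = spectrum.intensity
    out: list[tuple[float, int]] = []
    for win in (window_a, window_b):
        sl = spectrum.axis.window_slice(*win)
        nu = nu_full[sl]
        base = flank_baseline(nu_full, y_full, lo, hi, nu, margin)
        area = float(np.trapezoid(y_full[sl] - base, nu))
        out.append((area, int(nu.size)))
    (a1, n1), (a2, n2) = out
    return a1, n1, a2, n2


def doublet_ratio(
    spectrum: Spectrum,
    noise: NoiseEstimate | None = None,
    window_830: tuple[float, float] = DOUBLET_WINDOW_830,
    window_854: tuple[float, float] = DOUBLET_WINDOW_854,
) -> DoubletRatio:
    """Tyrosine Fermi-doublet area ratio I830/I854.

    Both bands are integrated above one linear baseline anchored on the
    flanking zones just outside the doublet region (so neither band lifts
    its own baseline); the ratio is undefined (None) when the 854 cm⁻¹ area
    is not positive.  When a noise estimate is supplied, a first-order
    propagated uncertainty is attached.
    """
    a830, n830, a854, n854 = _region_areas(spectrum, window_830, window_854)
    if a854 <= 0:
        return DoubletRatio(a830, a854, None, None)
    ratio = a830 / a854
    uncertainty = None
    if noise is not None and noise.sd > 0:
        step = spectrum.axis.step
        # area variance of a trapezoid sum of n iid points, baseline ignored
        var830 = (noise.sd * step) ** 2 * n830
        var854 = (noise.sd * step) ** 2 * n854
        uncertainty = float(
            abs(ratio) * np.sqrt(var830 / a830**2 + var854 / a854**2)
        )
    return DoubletRatio(a830, a854, float(ratio), uncertainty)


def v8a_position(
    spectrum: Spectrum,
    noise: NoiseEstimate | None = None,
    window: DetectionWindow = V8A_WINDOW,
    k_sigma: float = 3.0,
    quiet_region: tuple[float, float] = DEFAULT_QUIET_REGION,
) -> float | None:
    """Centre of the dominant tyrosine ring-stretch band in 1595-1630 cm⁻¹.

    Returns None when no band passes the k·σ rule (reported "absent").
    """
    if noise is None:
        noise = estimate_noise_sd(spectrum, quiet_region)
    hit = detect_band(spectrum, window, noise, k_sigma)
    return hit.center if hit.present else None


def disulfide_marker(
    spectrum: Spectrum,
    noise: NoiseEstimate | None = None,
    k_sigma: float = 3.0,
    quiet_region: tuple[float, float] = DEFAULT_QUIET_REGION,
) -> dict:
    """Disulfide conformation markers: 523 (g-g-t/t-g-g) vs 490 (strained).

    Returns a dict with ``state`` in {"ggt_tgg_523", "strained_490", "both",
    "absent"} plus the two hits.
    """
    if noise is None:
        noise = estimate_noise_sd(spectrum, quiet_region)
    h523 = detect_band(spectrum, DISULFIDE_523, noise, k_sigma)
    h490 = detect_band(spectrum, DISULFIDE_490, noise, k_sigma)
    if h523.present and h490.present:
        state = "both"
    elif h523.present:
        state = "ggt_tgg_523"
    elif h490.present:
        state = "strained_490"
    else:
        state = "absent"
    return {"state": state, "hit_523": h523, "hit_490": h490}


def band_fwhm(
    spectrum: Spectrum,
    center: float,
    half_span: float = 35.0,
    smooth: SGParams | None = DEFAULT_SMOOTH,
) -> float | None:
    """Direct-domain FWHM of the band at *center*, above a flank baseline.

    Measures half-maximum crossings of the smoothed, baseline-corrected
    intensity in ``center ± half_span``; returns None when the crossings are
    not bracketed (overlapping or truncated bands).
    """
    from .events import flank_baseline
    from .preprocess import sg_filter

    lo = max(spectrum.axis.start, center - half_span)
    hi = min(spectrum.axis.stop, center + half_span)
    work = sg_filter(spectrum, smooth) if smooth is not None else spectrum
    sl = spectrum.axis.window_slice(lo, hi)
    nu = spectrum.axis.values[sl]
    y = work.intensity[sl] - flank_baseline(
        spectrum.axis.values, work.intensity, lo, hi, nu
    )
    i0 = int(np.argmin(np.abs(nu - center)))
    peak = y[i0]
    if peak <= 0:
        return None
    half = 0.5 * peak
    left = right = None
    for i in range(i0, 0, -1):
        if y[i - 1] < half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = nu[i - 1] + frac * (nu[i] - nu[i - 1])
            break
    for i in range(i0, y.size - 1):
        if y[i + 1] < half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = nu[i] + frac * (nu[i + 1] - nu[i])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def classify_hiapp_evidence(
    amide: AmideBands,
    doublet: DoubletRatio,
    disulfide_state: str,
    amide3_present: bool,
    config: ClassifierConfig = DEFAULT_CLASSIFIER,
    direct_fwhm: float | None = None,
) -> str:
    """Species decision table on pre-computed evidence (deterministic, total).

    Branches are evaluated in a fixed order, making the table mutually
    exclusive and exhaustive by construction.  ``direct_fwhm`` is the
    direct-domain FWHM of the single amide-I band (when one exists); it
    carries the "broad" discrimination for the type-I branch.
    """
    lo, hi = config.amide_core
    centers = [c for c in amide.centers if lo <= c <= hi]
    tol = config.center_tol
    ratio = doublet.ratio

    def near(c: float, target: float) -> bool:
        return abs(c - target) <= tol

    if len(centers) == 1 and near(centers[0], 1656.0):
        return "predominant_helix_coil"
    if (
        len(centers) == 1
        and near(centers[0], 1668.0)
        and direct_fwhm is not None
        and direct_fwhm >= config.broad_fwhm_min
        and (ratio is None or ratio <= config.ratio_threshold)
    ):
        return "typeI_turn"
    if (
        len(centers) == 2
        and near(centers[0], 1655.0)
        and near(centers[1], 1674.0)
        and ratio is not None
        and ratio > config.ratio_threshold
    ):
        return "typeII_beta"
    if any(near(c, 1674.0) for c in centers) and (
        amide3_present or disulfide_state in ("strained_490", "both")
    ):
        return "fibril_like"
    return "unclassified"


def classify_hiapp(
    spectrum: Spectrum,
    noise: NoiseEstimate | None = None,
    config: ClassifierConfig = DEFAULT_CLASSIFIER,
    sg_params: SGParams = DEFAULT_DERIV2,
    k_sigma: float = 3.0,
    quiet_region: tuple[float, float] = DEFAULT_QUIET_REGION,
) -> SpeciesCall:
    """Classify one spectrum into the conformational-species catalogue."""
    if noise is None:
        noise = estimate_noise_sd(spectrum, quiet_region)
    amide = amide_band_centers(spectrum, sg_params, noise)
    doublet = doublet_ratio(spectrum, noise)
    ss = disulfide_marker(spectrum, noise, k_sigma)
    h1226 = detect_band(spectrum, AMIDE_III_1226, noise, k_sigma)
    lo, hi = config.amide_core
    core = [c for c in amide.centers if lo <= c <= hi]
    direct = band_fwhm(spectrum, core[0]) if len(core) == 1 else None
    call = classify_hiapp_evidence(
        amide, doublet, ss["state"], h1226.present, config, direct_fwhm=direct
    )
    return SpeciesCall(
        call,
        evidence={
            "amide_centers": list(amide.centers),
            "amide_widths": list(amide.widths),
            "direct_fwhm": direct,
            "doublet_ratio": doublet.ratio,
            "disulfide": ss["state"],
            "amide3_1226": h1226.present,
        },
    )


def species_census(
    sset: SpectrumSet,
    calls: Sequence[SpeciesCall | str] | None = None,
    **classify_kwargs,
) -> dict:
    """Counts/fractions per species call plus the normalized amide-I map.

    The map is the per-spectrum min-max-normalized -d²I/dν² over the amide-I
    region, one row per spectrum in acquisition order.
    """
    if len(sset) == 0:
        raise ValueError("species census needs a non-empty set")
    if calls is None:
        calls = [classify_hiapp(s, **classify_kwargs) for s in sset]
    if len(calls) != len(sset):
        raise ValueError(f"got {len(calls)} calls for {len(sset)} spectra")
    labels = [c.call if isinstance(c, SpeciesCall) else str(c) for c in calls]
    counts = {k: 0 for k in HIAPP_CALLS}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    n = len(labels)
    rows = []
    for s in sset:
        d2 = second_derivative_region(s)
        t = d2.intensity
        span = float(t.max() - t.min())
        rows.append((t - t.min()) / span if span > 0 else np.zeros_like(t))
    return {
        "n": n,
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()},
        "labels": labels,
        "map": np.vstack(rows),
    }
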