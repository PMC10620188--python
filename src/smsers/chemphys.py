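"""Acid-base, charge-state, frequency-scaling and optical-trapping calculations.

All are closed-form: independent-site protonation (Henderson-Hasselbalch),
strong-electrolyte titration by charge balance, least-squares vibrational
frequency scaling, and the Rayleigh-regime gradient force/potential with a
Boltzmann stability criterion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "K_B",
    "EPS0",
    "KW",
    "IonizableGroup",
    "ChargeState",
    "TrapProfile",
    "TrapResult",
    "hiapp_groups",
    "tyr_groups",
    "net_charge",
    "microstate_weights",
    "mix_strong_acid_base",
    "apply_freq_scaling",
    "fit_scaling_factor",
    "thermal_energy",
    "polarizability_cm",
    "SILVER_EPSILON",
    "trap_force_potential",
]

K_B = 1.380649e-23          # J/K
EPS0 = 8.8541878128e-12     # F/m
KW = 1e-14                  # water autoionization at 25 C
ROOM_T = 293.0              # K

#: Relative permittivity of silver (Johnson & Christy interpolation) and water.
SILVER_EPSILON = {
    532.0: complex(-11.7, 0.37),
    1064.0: complex(-58.9, 0.60),
}
WATER_EPSILON = 1.77


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable site.

    ``kind`` is "base" (+1 when protonated, 0 otherwise) or "acid" (0 when
    protonated, -1 otherwise).  ``blocked`` sites (amidated C-terminus,
    disulfide-bonded thiols) contribute no charge at any pH.
    """

    name: str
    pka: float
    kind: str
    blocked: bool = False

    def __post_init__(self):
        if self.kind not in ("acid", "base"):
            raise ValueError(f"group {self.name!r}: kind must be 'acid' or 'base'")
        if not self.blocked and not (0.0 < self.pka < 14.0):
            raise ValueError(
                f"group {self.name!r}: pKa must lie in (0, 14), got {self.pka}"
            )

    def protonated_fraction(self, pH: float) -> float:
        if self.blocked:
            return 1.0
        return 1.0 / (1.0 + 10.0 ** (pH - self.pka))

    def charge(self, protonated: bool) -> int:
        if self.blocked:
            return 0
        if self.kind == "base":
            return 1 if protonated else 0
        return 0 if protonated else -1


@dataclass(frozen=True)
class ChargeState:
    fractional_charge: float
    integer_charge: int
    site_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.fractional_charge - self.integer_charge) > 0.5 + 1e-9:
            raise ValueError("integer charge must be the rounded fractional charge")


def hiapp_groups(
    his_pka: float = 6.0,
    nterm_pka: float = 9.0,
    lys_pka: float = 10.5,
    arg_pka: float = 12.5,
) -> list[IonizableGroup]:
    """Ionizable groups of amylin: four basic sites; the amidated C-terminus
    and the two disulfide-bonded cysteines are blocked; no acidic side chains.
    """
    return [
        IonizableGroup("alpha_amino", nterm_pka, "base"),
        IonizableGroup("Lys1", lys_pka, "base"),
        IonizableGroup("Arg11", arg_pka, "base"),
        IonizableGroup("His18", his_pka, "base"),
        IonizableGroup("C_term_amide", 0.0, "acid", blocked=True),
        IonizableGroup("Cys2", 0.0, "acid", blocked=True),
        IonizableGroup("Cys7", 0.0, "acid", blocked=True),
    ]


def tyr_groups(
    carboxyl_pka: float = 2.2, amino_pka: float = 9.2, phenol_pka: float = 10.5
) -> list[IonizableGroup]:
    """Free tyrosine: carboxyl and phenol acids, alpha-amino base."""
    return [
        IonizableGroup("carboxyl", carboxyl_pka, "acid"),
        IonizableGroup("amino", amino_pka, "base"),
        IonizableGroup("phenol", phenol_pka, "acid"),
    ]


def net_charge(groups: Sequence[IonizableGroup], pH: float) -> ChargeState:
    """Independent-site net charge at *pH*.

    Each base contributes +f, each acid -(1-f), where f is the protonated
    fraction 1/(1+10^(pH-pKa)); blocked groups contribute 0.  The integer
    charge is the rounded sum.
    """
    if not groups:
        raise ValueError("need at least one ionizable group")
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {pH}")
    total = 0.0
    fractions: dict[str, float] = {}
    for g in groups:
        f = g.protonated_fraction(pH)
        fractions[g.name] = f
        if g.blocked:
            continue
        total += f if g.kind == "base" else -(1.0 - f)
    return ChargeState(total, int(round(total)), fractions)


def microstate_weights(groups: Sequence[IonizableGroup], pH: float) -> dict[int, float]:
    """Probability of each total integer charge under independent sites.

    Enumerates protonation microstates of the unblocked sites with Bernoulli
    weights and aggregates by total charge; weights sum to 1.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {pH}")
    active = [g for g in groups if not g.blocked]
    weights: dict[int, float] = {}
    if not active:
        return {0: 1.0}
    fracs = [g.protonated_fraction(pH) for g in active]
    for states in itertools.product((True, False), repeat=len(active)):
        w = 1.0
        q = 0
        for g, f, prot in zip(active, fracs, states):
            w *= f if prot else (1.0 - f)
            q += g.charge(prot)
        weights[q] = weights.get(q, 0.0) + w
    return dict(sorted(weights.items()))


def mix_strong_acid_base(
    v_acid_ul: float, pH_acid: float, v_base_ul: float, c_base: float
) -> float:
    """pH after ideal mixing of a strong-acid solution with strong base.

    Solves the charge balance [H+] + [Na+] = [OH-] + [A-] with water
    autoionization included; monotone increasing in added base volume.
    """
    if v_acid_ul <= 0:
        raise ValueError("acid volume must be positive")
    if v_base_ul < 0 or c_base < 0:
        raise ValueError("base volume and concentration must be non-negative")
    h0 = 10.0 ** (-pH_acid)
    acid_conc = h0 - KW / h0  # strong-acid anion concentration in the feed
    v_total = v_acid_ul + v_base_ul
    a = acid_conc * v_acid_ul / v_total
    b = c_base * v_base_ul / v_total
    d = a - b
    # numerically stable root of h^2 - d*h - Kw = 0 (avoids cancellation
    # when base is in excess and h ~ Kw/|d|)
    if d >= 0:
        h = 0.5 * (d + math.sqrt(d * d + 4.0 * KW))
    else:
        h = 2.0 * KW / (-d + math.sqrt(d * d + 4.0 * KW))
    return -math.log10(h)


def apply_freq_scaling(
    freqs: Sequence[float], factor: float = 0.9770, cutoff: float = 1000.0
) -> list[float]:
    """Scale computed wavenumbers above *cutoff* by *factor* (others unchanged)."""
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    out = []
    for nu in freqs:
        if nu <= 0:
            raise ValueError(f"wavenumbers must be positive, got {nu}")
        out.append(nu * factor if nu > cutoff else float(nu))
    return out


def fit_scaling_factor(calc: Sequence[float], obs: Sequence[float]) -> float:
    """Least-squares scaling factor through the origin.

    Minimizes sum((obs - f*calc)^2): f = sum(calc*obs) / sum(calc^2).
    """
    calc_arr = np.asarray(calc, dtype=float)
    obs_arr = np.asarray(obs, dtype=float)
    if calc_arr.size == 0 or calc_arr.size != obs_arr.size:
        raise ValueError("need equal-length, non-empty calc/obs frequency lists")
    if np.any(calc_arr <= 0):
        raise ValueError("computed wavenumbers must be positive")
    return float(np.sum(calc_arr * obs_arr) / np.sum(calc_arr**2))


def thermal_energy(T: float = ROOM_T) -> float:
    """k_B * T in joules."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return K_B * T


def polarizability_cm(
    radius_nm: float, eps_particle: complex, eps_medium: float = WATER_EPSILON
) -> complex:
    """Clausius-Mossotti dipole polarizability of a sphere (SI units, C·m²/V).

    alpha = 4*pi*eps0*eps_m*r^3*(eps_p - eps_m)/(eps_p + 2*eps_m).
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    if eps_medium <= 0:
        raise ValueError("medium permittivity must be positive")
    denom = eps_particle + 2.0 * eps_medium
    if abs(denom) < 1e-12:
        raise ValueError("singular Clausius-Mossotti denominator (eps_p + 2*eps_m = 0)")
    r = radius_nm * 1e-9
    return 4.0 * math.pi * EPS0 * eps_medium * r**3 * (eps_particle - eps_medium) / denom


@dataclass
class TrapProfile:
    """Relative field-intensity profile |E/E0|² along z.

    ``z_nm``: strictly increasing positions (nm); ``e2``: relative intensity
    (dimensionless, >= 0); ``e0_sq``: reference field intensity (V²/m²);
    ``alpha_re``: real part of the particle polarizability (C·m²/V).
    """

    z_nm: np.ndarray
    e2: np.ndarray
    e0_sq: float
    alpha_re: float

    def __post_init__(self):
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.e2 = np.asarray(self.e2, dtype=float)
        if self.z_nm.ndim != 1 or self.z_nm.size < 3:
            raise ValueError("trap profile needs at least 3 z points")
        if np.any(np.diff(self.z_nm) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if self.e2.shape != self.z_nm.shape:
            raise ValueError("e2 and z grids must have the same length")
        if np.any(self.e2 < 0):
            raise ValueError("relative field intensity must be >= 0")


@dataclass
class TrapResult:
    z_nm: np.ndarray
    force_pn: np.ndarray        # gradient force along z, pN
    potential_j: np.ndarray     # potential energy, J, zero at the far end
    well_depth_j: float
    stability_ratio: float
    stable: bool

    def as_dict(self) -> dict:
        return {
            "well_depth_j": self.well_depth_j,
            "stability_ratio": self.stability_ratio,
            "stable": self.stable,
            "max_force_pn": float(np.max(np.abs(self.force_pn))),
        }


#: Common optical-trapping stability criterion: well depth >= 10 k_B T.
STABILITY_THRESHOLD = 10.0


def trap_force_potential(profile: TrapProfile, T: float = ROOM_T) -> TrapResult:
    """Time-averaged Rayleigh gradient force and trapping potential.

    F(z) = (1/4) Re(alpha) E0² d|E/E0|²/dz and
    U(z) = -(1/4) Re(alpha) E0² (|E/E0|²(z) - |E/E0|²(z_far)), with U = 0 at
    the far end of the grid; the two satisfy F = -dU/dz identically.  The
    well depth is -min(U); the trap is "stable" when it exceeds
    ``STABILITY_THRESHOLD`` times k_B T.
    """
    z_m = profile.z_nm * 1e-9
    pref = 0.25 * profile.alpha_re * profile.e0_sq
    force = pref * np.gradient(profile.e2, z_m)          # N
    potential = -pref * (profile.e2 - profile.e2[-1])    # J
    well = float(max(0.0, -np.min(potential)))
    kbt = thermal_energy(T)
    ratio = well / kbt
    return TrapResult(
        z_nm=profile.z_nm,
        force_pn=force * 1e12,
        potential_j=potential,
        well_depth_j=well,
        stability_ratio=ratio,
        stable=ratio >= STABILITY_THRESHOLD,
    )
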