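"""Background subtraction, Savitzky-Golay smoothing/derivatives, noise estimation.

Defaults: smoothing window 11 points (22 cm⁻¹ at the 2 cm⁻¹ grid), polynomial
order 3; second-derivative window 15 points, order 3.  Band detection operates
on -d²I/dν² so band centres appear as maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .core import AxisError, Spectrum, WavenumberAxis

__all__ = [
    "SGParams",
    "NoiseEstimate",
    "DEFAULT_SMOOTH",
    "DEFAULT_DERIV2",
    "DEFAULT_QUIET_REGION",
    "AMIDE_I_REGION",
    "subtract_background",
    "sg_filter",
    "second_derivative_region",
    "estimate_noise_sd",
    "noise_sd_second_derivative",
]

#: Quiet region used for noise estimation (no bands above amide I).
DEFAULT_QUIET_REGION = (1750.0, 1800.0)

#: Amide I analysis region.
AMIDE_I_REGION = (1550.0, 1750.0)


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter parameters."""

    window_pts: int = 11
    polyorder: int = 3
    deriv_order: int = 0

    def __post_init__(self):
        if self.window_pts % 2 == 0:
            raise ValueError(f"window_pts must be odd, got {self.window_pts}")
        if self.window_pts <= self.polyorder:
            raise ValueError(
                f"window_pts ({self.window_pts}) must exceed polyorder ({self.polyorder})"
            )
        if self.deriv_order not in (0, 1, 2):
            raise ValueError("deriv_order must be 0, 1 or 2")
        if self.deriv_order > self.polyorder:
            raise ValueError("deriv_order must not exceed polyorder")


DEFAULT_SMOOTH = SGParams(11, 3, 0)
DEFAULT_DERIV2 = SGParams(15, 3, 2)


@dataclass(frozen=True)
class NoiseEstimate:
    """Standard deviation of the additive noise, from a quiet region."""

    sd: float
    quiet_region: tuple[float, float]
    n_points: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_points < 8:
            raise ValueError("noise estimate needs at least 8 points")


def subtract_background(spectrum: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise background subtraction; axes must match exactly."""
    if spectrum.axis != background.axis:
        raise AxisError("spectrum and background axes differ; resample first")
    return spectrum.copy_with(intensity=spectrum.intensity - background.intensity)


def sg_filter(spectrum: Spectrum, params: SGParams = DEFAULT_SMOOTH) -> Spectrum:
    """Savitzky-Golay filter; derivatives are with respect to ν (cm⁻¹)."""
    n = len(spectrum.axis)
    if params.window_pts > n:
        raise ValueError(
            f"window_pts ({params.window_pts}) exceeds spectrum length ({n})"
        )
    out = savgol_filter(
        spectrum.intensity,
        window_length=params.window_pts,
        polyorder=params.polyorder,
        deriv=params.deriv_order,
        delta=spectrum.axis.step,
    )
    return spectrum.copy_with(intensity=out)


def second_derivative_region(
    spectrum: Spectrum,
    region: tuple[float, float] = AMIDE_I_REGION,
    params: SGParams = DEFAULT_DERIV2,
    presmooth: SGParams | None = DEFAULT_SMOOTH,
) -> Spectrum:
    """-d²I/dν² restricted to *region* (band centres appear as maxima).

    The spectrum is optionally pre-smoothed (``presmooth``) before the
    second-derivative filter, mirroring the smooth-then-differentiate
    processing chain.  Pass ``presmooth=None`` to skip.
    """
    lo, hi = region
    sl = spectrum.axis.window_slice(lo, hi)  # validates the region
    work = spectrum
    if presmooth is not None:
        work = sg_filter(work, presmooth)
    d2 = savgol_filter(
        work.intensity,
        window_length=params.window_pts,
        polyorder=params.polyorder,
        deriv=2,
        delta=spectrum.axis.step,
    )
    sub_axis = WavenumberAxis(spectrum.axis.values[sl])
    return Spectrum(sub_axis, -d2[sl], dict(spectrum.meta))


def noise_sd_second_derivative(
    sigma: float,
    step: float,
    params: SGParams = DEFAULT_DERIV2,
    presmooth: SGParams | None = DEFAULT_SMOOTH,
) -> float:
    """Propagate white-noise SD through the (presmooth ∘ d²) filter chain.

    Returns the SD of the second-derivative trace produced by
    :func:`second_derivative_region` for input white noise of SD *sigma*.
    """
    k2 = savgol_coeffs(params.window_pts, params.polyorder, deriv=2, delta=step, use="conv")
    kernel = k2
    if presmooth is not None:
        k0 = savgol_coeffs(
            presmooth.window_pts, presmooth.polyorder, deriv=0, use="conv"
        )
        kernel = np.convolve(k2, k0)
    return float(sigma * np.sqrt(np.sum(kernel**2)))


def estimate_noise_sd(
    spectrum: Spectrum,
    quiet_region: tuple[float, float] = DEFAULT_QUIET_REGION,
    band_centers: list[float] | None = None,
) -> NoiseEstimate:
    """Noise SD as the residual scatter after a local linear detrend.

    *quiet_region* must contain at least 8 grid points and should be free of
    analyte bands; pass the active template's ``band_centers`` to get a
    warning if any falls inside the region.
    """
    lo, hi = quiet_region
    sl = spectrum.axis.window_slice(lo, hi)
    nu = spectrum.axis.values[sl]
    y = spectrum.intensity[sl]
    if nu.size < 8:
        raise ValueError(
            f"quiet region [{lo}, {hi}] contains only {nu.size} points (need >= 8)"
        )
    if band_centers:
        inside = [c for c in band_centers if lo <= c <= hi]
        if inside:
            warnings.warn(
                f"quiet region [{lo}, {hi}] overlaps declared bands at {inside}"
            )
    coeffs = np.polyfit(nu, y, 1)
    resid = y - np.polyval(coeffs, nu)
    ddof = min(2, nu.size - 1)
    sd = float(np.std(resid, ddof=ddof))
    return NoiseEstimate(sd=sd, quiet_region=(lo, hi), n_points=int(nu.size))
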