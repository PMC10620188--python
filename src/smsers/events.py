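"""Rare-event detection and bi-analyte classification.

The detection rule: a band is present in a window when the smoothed,
locally baseline-corrected maximum reaches ``k_sigma`` times the noise SD
*and* at least three consecutive points exceed half that threshold (a
multiplicity control against single-pixel noise).  Band centres are refined
by parabolic interpolation through the three points around the maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import AxisError, Spectrum, SpectrumSet
from .preprocess import (
    DEFAULT_QUIET_REGION,
    DEFAULT_SMOOTH,
    NoiseEstimate,
    SGParams,
    estimate_noise_sd,
    sg_filter,
)

__all__ = [
    "DetectionWindow",
    "BandHit",
    "EVENT_LABELS",
    "BIASERS_WINDOWS",
    "detect_band",
    "flank_baseline",
    "classify_biasers",
    "classify_spectrum",
    "event_summary",
    "switching_rsd",
]


@dataclass(frozen=True)
class DetectionWindow:
    """Named wavenumber window for band detection."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError(f"window {self.name!r}: lo must be below hi")


#: Bi-analyte detection windows: the 590-610 marker region and the
#: 1620-1660 region split between the 1630 and 1650 assignments.
BIASERS_WINDOWS = {
    "marker600": DetectionWindow("marker600", 590.0, 610.0),
    "mb1630": DetectionWindow("mb1630", 1620.0, 1640.0),
    "nba1650": DetectionWindow("nba1650", 1642.0, 1662.0),
}

EVENT_LABELS = ("none", "single_MB", "single_NBA", "dual_MB_NBA")


@dataclass(frozen=True)
class BandHit:
    """Outcome of band detection in one window."""

    window: DetectionWindow
    present: bool
    center: float
    height: float
    snr: float
    clipped: bool = False


def _parabolic_refine(nu: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points (i-1, i, i+1); falls back to nu[i]."""
    if i <= 0 or i >= y.size - 1:
        return float(nu[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return float(nu[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(nu[i] + delta * (nu[1] - nu[0]))


def _anchor(nu_full: np.ndarray, y_full: np.ndarray, lo: float, hi: float) -> tuple[float, float] | None:
    """Mean (x, y) over grid points in [lo, hi]; None when < 2 points."""
    i0 = int(np.searchsorted(nu_full, lo - 1e-9, side="left"))
    i1 = int(np.searchsorted(nu_full, hi + 1e-9, side="right"))
    if i1 - i0 < 2:
        return None
    return float(np.mean(nu_full[i0:i1])), float(np.mean(y_full[i0:i1]))


def flank_baseline(
    nu_full: np.ndarray,
    y_full: np.ndarray,
    lo: float,
    hi: float,
    nu_window: np.ndarray,
    margin: float = 8.0,
) -> np.ndarray:
    """Linear baseline through flanking zones just outside [lo, hi].

    Anchors on the mean of the points within *margin* cm⁻¹ on each side of
    the window, so a band filling the window does not lift its own baseline.
    Falls back to the window's own edge points where a flank is unavailable
    (window at the axis boundary).
    """
    step = nu_full[1] - nu_full[0]
    left = _anchor(nu_full, y_full, lo - margin, lo - 0.5 * step)
    right = _anchor(nu_full, y_full, hi + 0.5 * step, hi + margin)
    in_lo = int(np.searchsorted(nu_full, lo - 1e-9, side="left"))
    in_hi = int(np.searchsorted(nu_full, hi + 1e-9, side="right"))
    if left is None:
        left = (float(np.mean(nu_full[in_lo:in_lo + 2])), float(np.mean(y_full[in_lo:in_lo + 2])))
    if right is None:
        right = (float(np.mean(nu_full[in_hi - 2:in_hi])), float(np.mean(y_full[in_hi - 2:in_hi])))
    (x0, y0), (x1, y1) = left, right
    if x1 == x0:
        return np.full_like(nu_window, y0)
    slope = (y1 - y0) / (x1 - x0)
    return y0 + slope * (nu_window - x0)


def detect_band(
    spectrum: Spectrum,
    window: DetectionWindow,
    noise: NoiseEstimate,
    k_sigma: float = 3.0,
    smooth: SGParams | None = DEFAULT_SMOOTH,
) -> BandHit:
    """Detect a band in *window* against the k·σ rule.

    The spectrum is smoothed, a linear baseline through the window edges is
    removed, and the maximum is tested against ``k_sigma * noise.sd`` with a
    3-consecutive-points multiplicity control at half threshold.  With
    ``noise.sd == 0`` any non-negligible positive signal is reported present
    with infinite SNR.
    """
    sl = spectrum.axis.window_slice(window.lo, window.hi)
    work = sg_filter(spectrum, smooth) if smooth is not None else spectrum
    nu = spectrum.axis.values[sl]
    y = work.intensity[sl]
    if y.size < 5:
        raise AxisError(
            f"window {window.name!r} covers only {y.size} grid points (need >= 5)"
        )
    baseline = flank_baseline(
        spectrum.axis.values, work.intensity, window.lo, window.hi, nu
    )
    corrected = y - baseline
    i_max = int(np.argmax(corrected))
    height = float(corrected[i_max])

    if noise.sd <= 0.0:
        tol = 1e-9 * max(1.0, float(np.max(np.abs(spectrum.intensity))))
        present = height > tol
        snr = math.inf if present else 0.0
    else:
        snr = height / noise.sd
        threshold = k_sigma * noise.sd
        half = 0.5 * threshold
        above_half = corrected >= half
        run = _longest_run_through(above_half, i_max)
        present = (height >= threshold) and (run >= 3)

    center = _parabolic_refine(nu, corrected, i_max)
    clipped = False
    if center < window.lo or center > window.hi:
        warnings.warn(
            f"window {window.name!r}: refined centre {center:.2f} clipped into window"
        )
        center = float(np.clip(center, window.lo, window.hi))
        clipped = True
    return BandHit(window, bool(present), center, height, float(snr), clipped)


def _longest_run_through(mask: np.ndarray, i: int) -> int:
    """Length of the run of True values in *mask* containing index *i*."""
    if not mask[i]:
        return 0
    lo = i
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = i
    while hi < mask.size - 1 and mask[hi + 1]:
        hi += 1
    return hi - lo + 1


def classify_biasers(hits: Mapping[str, BandHit | bool]) -> str:
    """Bi-analyte event label from the three marker-window hits.

    Expects keys ``marker600``, ``mb1630``, ``nba1650``.  Rules: NBA shows
    1650 together with 600; MB shows 1630 without 600; simultaneous 1630 and
    1650 is a dual event; anything else is "none".
    """
    def _p(key: str) -> bool:
        h = hits[key]
        return h.present if isinstance(h, BandHit) else bool(h)

    m600, m1630, m1650 = _p("marker600"), _p("mb1630"), _p("nba1650")
    if m1630 and m1650:
        return "dual_MB_NBA"
    if m1650 and m600 and not m1630:
        return "single_NBA"
    if m1630 and not m600 and not m1650:
        return "single_MB"
    return "none"


def classify_spectrum(
    spectrum: Spectrum,
    noise: NoiseEstimate | None = None,
    windows: Mapping[str, DetectionWindow] = BIASERS_WINDOWS,
    k_sigma: float = 3.0,
    quiet_region: tuple[float, float] = DEFAULT_QUIET_REGION,
) -> tuple[str, dict[str, BandHit]]:
    """Detect all marker windows on one spectrum and classify the event."""
    if noise is None:
        noise = estimate_noise_sd(spectrum, quiet_region)
    hits = {
        name: detect_band(spectrum, win, noise, k_sigma)
        for name, win in windows.items()
    }
    return classify_biasers(hits), hits


def event_summary(sset: SpectrumSet, labels: Sequence[str]) -> dict:
    """Counts per label, detected fraction, and the label histogram."""
    if len(labels) != len(sset):
        raise ValueError(
            f"got {len(labels)} labels for {len(sset)} spectra"
        )
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    n = len(labels)
    detected = n - counts.get("none", 0)
    return {
        "n": n,
        "counts": counts,
        "detected": detected,
        "detected_fraction": detected / n,
        "histogram": {k: v for k, v in sorted(counts.items()) if k != "none"},
    }


@dataclass
class SwitchingResult:
    on_heights: list[float]
    off_heights: list[float]
    rsd_percent: float
    contrast: float
    off_violations: int = 0

    def as_dict(self) -> dict:
        return {
            "n_on": len(self.on_heights),
            "n_off": len(self.off_heights),
            "on_heights": self.on_heights,
            "rsd_percent": self.rsd_percent,
            "contrast": self.contrast,
            "off_violations": self.off_violations,
        }


def switching_rsd(
    series: SpectrumSet,
    analyte_window: DetectionWindow,
    noise: NoiseEstimate | None = None,
    k_sigma: float = 3.0,
    quiet_region: tuple[float, float] = DEFAULT_QUIET_REGION,
) -> SwitchingResult:
    """Reproducibility of on-state peak heights across a trap on/off series.

    ``rsd_percent`` = 100 * sd / mean of the baseline-corrected on-state peak
    heights in *analyte_window*.  Off-state spectra that themselves pass the
    k·σ rule are counted as protocol violations.
    """
    on_h: list[float] = []
    off_h: list[float] = []
    violations = 0
    for s in series:
        state = s.meta.get("trap_state")
        if state not in ("on", "off"):
            raise ValueError("series spectra need trap_state metadata 'on'/'off'")
        est = noise or estimate_noise_sd(s, quiet_region)
        hit = detect_band(s, analyte_window, est, k_sigma)
        if state == "on":
            on_h.append(hit.height)
        else:
            off_h.append(hit.height)
            if hit.present:
                violations += 1
    if len(on_h) < 2:
        raise ValueError("switching analysis needs at least 2 on-state spectra")
    mean_on = float(np.mean(on_h))
    sd_on = float(np.std(on_h, ddof=1))
    rsd = 100.0 * sd_on / mean_on if mean_on != 0 else math.inf
    mean_off = float(np.mean(np.abs(off_h))) if off_h else 0.0
    contrast = mean_on / mean_off if mean_off > 0 else math.inf
    return SwitchingResult(on_h, off_h, rsd, contrast, violations)
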