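"""Core spectral domain types and text-format readers/writers.

Conventions used throughout the package:

* Spectral axes are Raman shifts in cm⁻¹, strictly ascending on a uniform
  grid.  The default working grid is 400–1800 cm⁻¹ at 2 cm⁻¹ resolution.
* Intensities are arbitrary units (no absolute calibration is modelled).
* Text dialects: per-spectrum two-column delimited files, multi-spectrum
  matrix files (first column = wavenumber), and JSON for analysis reports.
  Metadata travels in ``# key: value`` comment headers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Sequence

import numpy as np

__all__ = [
    "AxisError",
    "ParseError",
    "WavenumberAxis",
    "Spectrum",
    "SpectrumSet",
    "make_axis",
    "default_axis",
    "resample",
    "read_spectrum",
    "write_spectrum",
    "read_spectrum_set",
    "write_spectrum_set",
    "read_report",
    "write_report",
]

#: Instrument-style default resolution (cm⁻¹).
DEFAULT_STEP = 2.0
DEFAULT_START = 400.0
DEFAULT_STOP = 1800.0

_REL_TOL = 1e-9


class AxisError(ValueError):
    """Raised for invalid or mismatched wavenumber axes."""


class ParseError(ValueError):
    """Raised for malformed spectral text files; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform, strictly ascending grid of Raman shifts (cm⁻¹)."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise AxisError("axis needs at least two wavenumber points")
        if not np.all(np.isfinite(vals)):
            raise AxisError("axis contains non-finite values")
        diffs = np.diff(vals)
        if np.any(diffs <= 0):
            raise AxisError("axis must be strictly ascending")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=1e-6, atol=1e-9 * max(step, 1.0)):
            raise AxisError("axis spacing is not uniform")
        object.__setattr__(self, "values", vals)

    @property
    def start(self) -> float:
        return float(self.values[0])

    @property
    def stop(self) -> float:
        return float(self.values[-1])

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=_REL_TOL, atol=1e-9
        )

    def __hash__(self):  # frozen dataclass with array field
        return hash((self.values.size, self.start, self.stop))

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to *wavenumber*."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window_slice(self, lo: float, hi: float) -> slice:
        """Slice selecting grid points with lo ≤ ν ≤ hi."""
        if lo >= hi:
            raise AxisError(f"window bounds inverted: lo={lo} >= hi={hi}")
        if lo < self.start - _REL_TOL or hi > self.stop + _REL_TOL:
            raise AxisError(
                f"window [{lo}, {hi}] outside axis span [{self.start}, {self.stop}]"
            )
        i0 = int(np.searchsorted(self.values, lo - 1e-9, side="left"))
        i1 = int(np.searchsorted(self.values, hi + 1e-9, side="right"))
        return slice(i0, i1)


def make_axis(
    start: float = DEFAULT_START,
    stop: float = DEFAULT_STOP,
    step: float = DEFAULT_STEP,
) -> WavenumberAxis:
    """Build a uniform axis from *start* to at most *stop* with spacing *step*.

    The grid always includes *start*; the last point is the largest value of
    ``start + k*step`` not exceeding *stop* (truncation rule).
    """
    if step <= 0:
        raise AxisError(f"step must be positive, got step={step}")
    if start >= stop:
        raise AxisError(f"start must be below stop, got start={start}, stop={stop}")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return WavenumberAxis(start + step * np.arange(n))


def default_axis() -> WavenumberAxis:
    return make_axis()


@dataclass
class Spectrum:
    """One intensity trace on a wavenumber axis, with acquisition metadata.

    Recognised metadata keys: ``trap_state`` ("on"/"off"), ``session_id``,
    ``time_s``, ``integration_s``, ``label_truth``.  Arbitrary extra keys
    are carried along unchanged.
    """

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        if arr.shape != (len(self.axis),):
            raise ValueError(
                f"intensity length {arr.size} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensity contains non-finite values")
        if "integration_s" in self.meta and float(self.meta["integration_s"]) <= 0:
            raise ValueError("integration_s must be positive")
        self.intensity = arr

    def copy_with(self, intensity: np.ndarray | None = None, **meta: Any) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(
            self.axis,
            self.intensity if intensity is None else intensity,
            new_meta,
        )


@dataclass
class SpectrumSet:
    """Ordered collection of spectra sharing one axis."""

    spectra: list[Spectrum]
    shared_axis: WavenumberAxis

    def __post_init__(self):
        if not self.spectra:
            raise ValueError("SpectrumSet must be non-empty")
        for i, s in enumerate(self.spectra):
            if s.axis != self.shared_axis:
                raise AxisError(f"spectrum {i} does not share the set axis")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("SpectrumSet must be non-empty")
        return cls(spectra, spectra[0].axis)

    def intensities(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_points) matrix."""
        return np.vstack([s.intensity for s in self.spectra])

    def labels(self, key: str = "label_truth", default: str = "none") -> list[str]:
        return [str(s.meta.get(key, default)) for s in self.spectra]


def resample(spectrum: Spectrum, axis: WavenumberAxis) -> Spectrum:
    """Linearly interpolate *spectrum* onto *axis* (no extrapolation)."""
    src = spectrum.axis
    if axis.start < src.start - _REL_TOL or axis.stop > src.stop + _REL_TOL:
        raise AxisError(
            f"target axis [{axis.start}, {axis.stop}] extends beyond source span "
            f"[{src.start}, {src.stop}]; extrapolation is not supported"
        )
    vals = np.interp(axis.values, src.values, spectrum.intensity)
    return Spectrum(axis, vals, dict(spectrum.meta))


# ---------------------------------------------------------------------------
# text i/o
# ---------------------------------------------------------------------------

_META_PREFIX = "# "


def _format_header(meta: dict[str, Any]) -> list[str]:
    return [f"{_META_PREFIX}{k}: {json.dumps(v)}" for k, v in meta.items()]


def _parse_header_line(line: str, lineno: int) -> tuple[str, Any]:
    body = line[len(_META_PREFIX):] if line.startswith(_META_PREFIX) else line[1:]
    if ":" not in body:
        raise ParseError(f"malformed header line {line!r}", lineno)
    key, _, raw = body.partition(":")
    raw = raw.strip()
    try:
        value = json.loads(raw)
    except json.JSONDecodeError:
        value = raw
    return key.strip(), value


def _sniff_delimiter(line: str) -> str:
    return "," if ("," in line and "\t" not in line) else "\t"


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = "\t") -> None:
    """Write one spectrum as two-column delimited text with a ``#`` header."""
    path = Path(path)
    lines = _format_header(spectrum.meta)
    for nu, inten in zip(spectrum.axis.values, spectrum.intensity):
        lines.append(f"{float(nu)!r}{delimiter}{float(inten)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column delimited text spectrum written by :func:`write_spectrum`.

    A descending wavenumber column is re-sorted ascending with a warning.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    nus: list[float] = []
    vals: list[float] = []
    delimiter = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            k, v = _parse_header_line(line, lineno)
            meta[k] = v
            continue
        if delimiter is None:
            delimiter = _sniff_delimiter(line)
        parts = line.split(delimiter)
        if len(parts) != 2:
            raise ParseError(f"expected 2 columns, got {len(parts)}", lineno)
        try:
            nus.append(float(parts[0]))
            vals.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"non-numeric row {line!r}", lineno) from exc
    if len(nus) < 2:
        raise ParseError(f"no spectral data found in {path}")
    nu_arr = np.array(nus)
    val_arr = np.array(vals)
    if np.all(np.diff(nu_arr) < 0):
        warnings.warn(f"{path}: descending wavenumber axis re-sorted ascending")
        nu_arr = nu_arr[::-1]
        val_arr = val_arr[::-1]
    try:
        axis = WavenumberAxis(nu_arr)
    except AxisError as exc:
        raise ParseError(f"invalid wavenumber axis: {exc}") from exc
    return Spectrum(axis, val_arr, meta)


def write_spectrum_set(sset: SpectrumSet, path: str | Path, delimiter: str = "\t") -> None:
    """Write a set as a matrix: first column ν, one column per spectrum.

    Per-spectrum metadata is stored as a JSON list in the header.
    """
    path = Path(path)
    lines = [f"{_META_PREFIX}n_spectra: {len(sset)}"]
    metas = [s.meta for s in sset]
    lines.append(f"{_META_PREFIX}spectrum_meta: {json.dumps(metas)}")
    mat = sset.intensities()
    for j, nu in enumerate(sset.shared_axis.values):
        row = delimiter.join(repr(float(x)) for x in mat[:, j])
        lines.append(f"{float(nu)!r}{delimiter}{row}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_set(path: str | Path) -> SpectrumSet:
    """Read a matrix file written by :func:`write_spectrum_set`."""
    path = Path(path)
    meta: dict[str, Any] = {}
    rows: list[list[float]] = []
    ncols = None
    delimiter = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            k, v = _parse_header_line(line, lineno)
            meta[k] = v
            continue
        if delimiter is None:
            delimiter = _sniff_delimiter(line)
        parts = line.split(delimiter)
        if ncols is None:
            ncols = len(parts)
            if ncols < 2:
                raise ParseError("matrix rows need at least 2 columns", lineno)
        elif len(parts) != ncols:
            raise ParseError(
                f"ragged matrix: expected {ncols} columns, got {len(parts)}", lineno
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"non-numeric row {line!r}", lineno) from exc
    if not rows:
        raise ParseError(f"no spectral data found in {path}")
    data = np.array(rows)
    nu_arr = data[:, 0]
    mat = data[:, 1:]
    if np.all(np.diff(nu_arr) < 0):
        warnings.warn(f"{path}: descending wavenumber axis re-sorted ascending")
        nu_arr = nu_arr[::-1]
        mat = mat[::-1, :]
    try:
        axis = WavenumberAxis(nu_arr)
    except AxisError as exc:
        raise ParseError(f"invalid wavenumber axis: {exc}") from exc
    metas = meta.get("spectrum_meta")
    n = mat.shape[1]
    if not isinstance(metas, list) or len(metas) != n:
        metas = [{} for _ in range(n)]
    spectra = [Spectrum(axis, mat[:, i], dict(metas[i])) for i in range(n)]
    return SpectrumSet(spectra, axis)


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Serialise an analysis report dict as pretty JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
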