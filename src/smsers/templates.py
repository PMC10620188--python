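"""Built-in species templates for the synthetic spectrum generator.

Band positions follow standard vibrational assignments for the two reporter
dyes (Nile Blue A, Methylene Blue), free tyrosine at its two limiting charge
states, and the amylin (hIAPP) conformational species and fibrils.  Widths,
lineshapes and relative amplitudes are generator choices (the raw data carry
no published noise model); all are configurable and round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .synth import PeakBand, SpeciesTemplate

__all__ = [
    "builtin_template",
    "builtin_template_names",
    "templates_to_yaml",
    "templates_from_yaml",
]


def _bands(spec_rows) -> list[PeakBand]:
    return [PeakBand.from_height(*row) for row in spec_rows]


def _build() -> dict[str, SpeciesTemplate]:
    # rows: (center, fwhm, height, lineshape)
    lib = {
        "NBA": SpeciesTemplate(
            name="NBA",
            bands=_bands([
                (600.0, 12.0, 0.8, "lorentzian"),
                (1650.0, 14.0, 1.0, "lorentzian"),
            ]),
            provenance="Nile Blue A: ring deformation ~600, ring stretching ~1650 cm-1",
        ),
        # Junction/switching experiments see the NBA ring stretch at ~1645.
        "NBA_junction": SpeciesTemplate(
            name="NBA_junction",
            bands=_bands([
                (600.0, 12.0, 0.8, "lorentzian"),
                (1645.0, 14.0, 1.0, "lorentzian"),
            ]),
            provenance="Nile Blue A at a plasmonic junction: ring stretching ~1645 cm-1",
        ),
        "MB": SpeciesTemplate(
            name="MB",
            bands=_bands([
                (1630.0, 14.0, 1.0, "lorentzian"),
            ]),
            provenance="Methylene Blue: C-C ring stretching ~1630 cm-1; no 600 cm-1 band",
        ),
        # Tyrosine, +1 charge state (acidic): v8a at 1620, Fermi doublet 1:1.
        "Tyr_plus1": SpeciesTemplate(
            name="Tyr_plus1",
            bands=_bands([
                (830.0, 12.0, 0.75, "gaussian"),
                (854.0, 12.0, 0.75, "gaussian"),
                (1620.0, 14.0, 1.0, "lorentzian"),
            ]),
            provenance="tyrosine +1 state: v8a 1620 cm-1, doublet area ratio I830/I854 = 1",
        ),
        # Tyrosine, -2 charge state (basic): v8a at 1602, doublet 2:1.
        "Tyr_minus2": SpeciesTemplate(
            name="Tyr_minus2",
            bands=_bands([
                (830.0, 12.0, 1.0, "gaussian"),
                (854.0, 12.0, 0.5, "gaussian"),
                (1602.0, 14.0, 1.0, "lorentzian"),
            ]),
            provenance="tyrosine -2 state: v8a 1602 cm-1, doublet area ratio I830/I854 = 2",
        ),
        # hIAPP predominant helix-coil monomer.
        "hIAPP_helix_coil": SpeciesTemplate(
            name="hIAPP_helix_coil",
            bands=_bands([
                (523.0, 12.0, 0.8, "lorentzian"),
                (830.0, 12.0, 0.7, "gaussian"),
                (850.0, 12.0, 0.7, "gaussian"),
                (1006.0, 10.0, 0.8, "lorentzian"),
                (1250.0, 16.0, 0.45, "lorentzian"),
                (1287.0, 16.0, 0.45, "lorentzian"),
                (1450.0, 14.0, 0.55, "lorentzian"),
                (1656.0, 16.0, 1.0, "lorentzian"),
            ]),
            provenance=(
                "hIAPP helix-coil monomer: amide I 1656, amide III 1250/1287, "
                "CH2 1450, Phe 1006, Cys-Cys g-g-t 523, Tyr doublet ~1:1"
            ),
        ),
        # Transient species type I: broad amide I at 1668 (turn), doublet ~1.
        "hIAPP_typeI": SpeciesTemplate(
            name="hIAPP_typeI",
            bands=_bands([
                (523.0, 12.0, 0.8, "lorentzian"),
                (830.0, 12.0, 0.9, "gaussian"),
                (854.0, 12.0, 0.9, "gaussian"),
                (1668.0, 28.0, 1.0, "lorentzian"),
            ]),
            provenance="hIAPP type I transient: broad amide I 1668 (turn), doublet ratio ~1, intact 523",
        ),
        # Transient species type II: amide I 1655 + 1674 (helix-coil + beta), doublet > 1.
        "hIAPP_typeII": SpeciesTemplate(
            name="hIAPP_typeII",
            bands=_bands([
                (523.0, 12.0, 0.8, "lorentzian"),
                (830.0, 12.0, 1.0, "gaussian"),
                (854.0, 12.0, 0.667, "gaussian"),
                (1655.0, 14.0, 0.9, "lorentzian"),
                (1674.0, 14.0, 0.9, "lorentzian"),
            ]),
            provenance="hIAPP type II transient: amide I 1655+1674, doublet ratio ~1.5, intact 523",
        ),
        # Mature fibril: amide I 1674, amide III 1226, strained disulfide 490.
        "hIAPP_fibril": SpeciesTemplate(
            name="hIAPP_fibril",
            bands=_bands([
                (490.0, 12.0, 0.8, "lorentzian"),
                (830.0, 12.0, 0.8, "gaussian"),
                (854.0, 12.0, 0.67, "gaussian"),
                (1226.0, 14.0, 0.8, "lorentzian"),
                (1674.0, 14.0, 1.0, "lorentzian"),
            ]),
            provenance="hIAPP fibril: beta-sheet amide I 1674, amide III 1226, strained disulfide 490",
        ),
    }
    return lib


_LIBRARY: dict[str, SpeciesTemplate] | None = None


def _library() -> dict[str, SpeciesTemplate]:
    global _LIBRARY
    if _LIBRARY is None:
        _LIBRARY = _build()
    return _LIBRARY


def builtin_template(name: str) -> SpeciesTemplate:
    """Return a copy of the named built-in template."""
    lib = _library()
    if name not in lib:
        raise KeyError(
            f"unknown template {name!r}; available: {sorted(lib)}"
        )
    t = lib[name]
    return SpeciesTemplate(t.name, list(t.bands), t.provenance)


def builtin_template_names() -> list[str]:
    return sorted(_library())


def templates_to_yaml(templates: list[SpeciesTemplate], path: str | Path) -> None:
    doc = {
        t.name: {
            "provenance": t.provenance,
            "bands": [asdict(b) for b in t.bands],
        }
        for t in templates
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def templates_from_yaml(path: str | Path) -> dict[str, SpeciesTemplate]:
    doc = yaml.safe_load(Path(path).read_text())
    out: dict[str, SpeciesTemplate] = {}
    for name, entry in doc.items():
        bands = [PeakBand(**b) for b in entry["bands"]]
        out[name] = SpeciesTemplate(name, bands, entry.get("provenance", ""))
    return out
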