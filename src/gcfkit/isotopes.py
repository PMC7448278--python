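"""Molecular-formula parsing, monoisotopic mass / adduct m/z, ppm error,
and stable-isotope label bookkeeping for precursor feeding experiments.

Feeding a heavy-isotope-labeled precursor (e.g. ring-[13C6]anthranilate or
indole-ring-pentadeuterated tryptophan) shifts the product's m/z by the
number of labeled atoms that survive the biosynthetic transformations.  A
:class:`LabelScenario` records, per labeled site class, how many atoms were
labeled and how many are retained in the product; :func:`label_shift`
returns both the nominal (integer Da) and the exact mass shift.  Comparing
the observed shift with the scenario's prediction tests a precursor
hypothesis — e.g. a tryptophan-D5 feed shifting the product by +4 rather
than +5 is the signature of ring cleavage to kynurenine, where the indole
C2 deuteron leaves with the formyl group.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "MONOISOTOPIC_MASS",
    "H_ATOM_MASS",
    "PROTON_MASS",
    "FormulaComposition",
    "MassResult",
    "LabelSite",
    "LabelScenario",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "label_shift",
    "load_scenario",
    "builtin_scenarios",
]

#: Monoisotopic atomic masses (Da) for light elements and the heavy
#: isotopes used in labeling studies.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    # heavy isotopes (keys use mass-number prefixes)
    "2H": 2.0141017781,
    "13C": 13.0033548,
    "15N": 15.0001088984,
    "18O": 17.9991604,
}

#: Light counterpart of each heavy isotope.
_LIGHT_OF = {"2H": "H", "13C": "C", "15N": "N", "18O": "O"}

H_ATOM_MASS = MONOISOTOPIC_MASS["H"]
#: H-atom mass minus the electron mass.
PROTON_MASS = 1.0072764666


class FormulaError(ValueError):
    """Malformed molecular formula; message carries the string offset."""


@dataclass(frozen=True)
class FormulaComposition:
    """Element (or heavy-isotope) symbol → count."""

    counts: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "FormulaComposition") -> "FormulaComposition":
        merged = self.as_dict()
        for sym, n in other.counts:
            merged[sym] = merged.get(sym, 0) + n
        return FormulaComposition(tuple(sorted(merged.items())))


_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)(\d*)\]|([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> FormulaComposition:
    """Parse a Hill-style formula, optionally with bracketed isotopes.

    ``"C17H15N3O3"`` → C:17, H:15, N:3, O:3; ``"[13C6]C1H7NO2"`` → 13C:6,
    C:1, H:7, N:1, O:2.  Unknown elements and stray characters raise
    :class:`FormulaError` with the offending offset.
    """
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise FormulaError(f"cannot parse formula at offset {pos}: {text!r}")
        if m.group(2):  # bracketed isotope, e.g. [13C6]
            sym = f"{m.group(1)}{m.group(2)}"
            n = int(m.group(3) or "1")
        else:
            sym = m.group(4)
            n = int(m.group(5) or "1")
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unknown element or isotope {sym!r} at offset {pos}"
            )
        if n < 0:
            raise FormulaError(f"negative count at offset {pos}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return FormulaComposition(tuple(sorted(counts.items())))


def monoisotopic_mass(comp: FormulaComposition | str) -> float:
    """Sum of count × monoisotopic atomic mass over the composition."""
    if isinstance(comp, str):
        comp = parse_formula(comp)
    total = 0.0
    for sym, n in comp.counts:
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"no monoisotopic mass for {sym!r}")
        total += n * MONOISOTOPIC_MASS[sym]
    return total


@dataclass(frozen=True)
class MassResult:
    """A computed neutral mass and adduct m/z, optionally with ppm error."""

    neutral_mass: float
    adduct_mz: float
    adduct_name: str
    ppm_vs_observed: float | None = None


def adduct_mz(
    neutral_mass: float,
    adduct: str = "[M+H]+",
    convention: str = "H-atom",
) -> float:
    """m/z of a protonated adduct.

    ``convention="H-atom"`` (default) adds the hydrogen-atom mass
    1.0078250319 Da; ``"proton"`` adds the electron-corrected proton mass
    1.0072764666 Da.  The H-atom convention is the default because it
    reproduces printed [M+H]+ values computed the common shorthand way.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if adduct != "[M+H]+":
        raise ValueError(f"unsupported adduct {adduct!r}")
    if convention == "H-atom":
        return neutral_mass + H_ATOM_MASS
    if convention == "proton":
        return neutral_mass + PROTON_MASS
    raise ValueError(f"unknown convention {convention!r}")


def ppm_error(observed: float, calculated: float) -> float:
    """Mass accuracy: ``(observed - calculated) / calculated * 1e6``."""
    if calculated <= 0:
        raise ValueError("calculated mass must be positive")
    return (observed - calculated) / calculated * 1e6


@dataclass(frozen=True)
class LabelSite:
    """One class of labeled atoms in a precursor.

    ``n_labeled`` atoms of ``element`` carry the heavy ``isotope``;
    ``n_retained`` of them survive into the product.
    """

    element: str
    isotope: str
    n_labeled: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.isotope not in _LIGHT_OF:
            raise ValueError(f"unknown heavy isotope {self.isotope!r}")
        if _LIGHT_OF[self.isotope] != self.element:
            raise ValueError(
                f"isotope {self.isotope} is not a heavy form of {self.element}"
            )
        if not 0 <= self.n_labeled:
            raise ValueError("n_labeled must be >= 0")
        if not 0 <= self.n_retained <= self.n_labeled:
            raise ValueError(
                f"n_retained ({self.n_retained}) must lie in "
                f"[0, n_labeled={self.n_labeled}]"
            )


@dataclass(frozen=True)
class LabelScenario:
    """A labeled-precursor feeding experiment with its atom-retention map."""

    precursor_name: str
    labels: tuple[LabelSite, ...]
    retention_note: str = ""

    @property
    def n_labeled(self) -> int:
        return sum(s.n_labeled for s in self.labels)

    @property
    def n_retained(self) -> int:
        return sum(s.n_retained for s in self.labels)


def label_shift(scenario: LabelScenario) -> tuple[int, float]:
    """Predicted product mass shift of a feeding experiment.

    Returns ``(nominal_shift, exact_shift)``: the nominal shift is the
    count of retained heavy atoms (integer Da); the exact shift sums each
    retained atom's heavy-minus-light mass difference.
    """
    nominal = 0
    exact = 0.0
    for site in scenario.labels:
        nominal += site.n_retained
        exact += site.n_retained * (
            MONOISOTOPIC_MASS[site.isotope] - MONOISOTOPIC_MASS[site.element]
        )
    return nominal, exact


def _scenario_from_dict(doc: dict) -> LabelScenario:
    return LabelScenario(
        precursor_name=doc["precursor_name"],
        labels=tuple(
            LabelSite(
                element=s["element"],
                isotope=s["isotope"],
                n_labeled=int(s["n_labeled"]),
                n_retained=int(s["n_retained"]),
            )
            for s in doc["labels"]
        ),
        retention_note=doc.get("retention_note", ""),
    )


def load_scenario(source: str | Path) -> LabelScenario:
    """Load a feeding scenario from a JSON file or a built-in name.

    Built-ins: ``"anthranilate_13c6"`` (six ring carbons, all retained) and
    ``"trp_d5"`` (five ring deuteriums, four retained after ring cleavage
    to kynurenine and loss of the formyl deuteron).
    """
    p = Path(source)
    if p.exists():
        doc = json.loads(p.read_text())
    else:
        ref = resources.files("gcfkit").joinpath(f"data/{source}.json")
        if not ref.is_file():
            raise FileNotFoundError(
                f"{source!r} is neither a file nor a built-in scenario"
            )
        doc = json.loads(ref.read_text())
    return _scenario_from_dict(doc)


def builtin_scenarios() -> dict[str, LabelScenario]:
    """All shipped feeding scenarios, keyed by name."""
    out = {}
    for ref in resources.files("gcfkit").joinpath("data").iterdir():
        if ref.name.endswith(".json"):
            out[ref.name[: -len(".json")]] = _scenario_from_dict(
                json.loads(ref.read_text())
            )
    return out
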