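"""Formula-level molecular properties and rule-based drug-likeness.

Average and monoisotopic masses and elemental composition are computed
from a Hill-notation molecular formula using the standard atomic-weight
and isotope tables bundled with RDKit.  Drug-likeness is rule-based
over *supplied* property tables: Lipinski's Rule of Five (MW <= 500,
HBD <= 5, HBA <= 10, logP <= 5) and a six-axis bioavailability radar
with configurable ideal ranges.  Structure-derived descriptors (TPSA,
HBD/HBA, logP, FSP3, rotatable counts) are inputs, never computed from
connectivity here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from rdkit import Chem

__all__ = [
    "MolecularFormula",
    "PropertyTable",
    "RadarRanges",
    "parse_formula",
    "average_mass",
    "monoisotopic_mass",
    "composition",
    "lipinski_violations",
    "radar_verdict",
]

_PT = Chem.GetPeriodicTable()

# Hill order: C first, then H, then the rest alphabetically.
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _atomic_weight(symbol: str) -> float:
    return _PT.GetAtomicWeight(symbol)


def _monoisotopic(symbol: str) -> float:
    return _PT.GetMostCommonIsotopeMass(symbol)


def _known(symbol: str) -> bool:
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


@dataclass(frozen=True)
class MolecularFormula:
    """Element-to-count mapping with a canonical Hill-order string."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if not _known(el):
                raise ValueError(f"unknown element symbol {el!r}")
            if not isinstance(n, int) or n < 1:
                raise ValueError(f"element count must be a positive integer: {el}={n}")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def hill_string(self) -> str:
        elements = dict(self.counts)
        ordered: list[str] = []
        if "C" in elements:
            ordered.append("C")
            if "H" in elements:
                ordered.append("H")
            ordered.extend(sorted(e for e in elements if e not in ("C", "H")))
        else:
            ordered.extend(sorted(elements))
        return "".join(
            f"{el}{elements[el] if elements[el] > 1 else ''}" for el in ordered
        )

    def __str__(self) -> str:
        return self.hill_string


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular formula string like ``C28H35N7O6``.

    Implicit count 1 is allowed (``H2O``); zero or negative counts and
    unknown element symbols are errors.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"unparseable formula fragment at {text[pos:]!r}")
        pos = match.end()
        el, digits = match.groups()
        n = int(digits) if digits else 1
        if n < 1:
            raise ValueError(f"element count must be >= 1: {el}{digits}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise ValueError(f"unparseable formula fragment at {text[pos:]!r}")
    return MolecularFormula(counts)


def average_mass(formula: MolecularFormula | str) -> float:
    """Average molar mass in g/mol from standard atomic weights."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(n * _atomic_weight(el) for el, n in formula.counts.items())


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic (exact) mass in Da from most-abundant-isotope masses."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(n * _monoisotopic(el) for el, n in formula.counts.items())


def composition(formula: MolecularFormula | str) -> dict[str, float]:
    """Mass-percent of each element, full precision (round for display)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = average_mass(formula)
    return {
        el: 100.0 * n * _atomic_weight(el) / total for el, n in formula.counts.items()
    }


@dataclass(frozen=True)
class PropertyTable:
    """Supplied physicochemical properties for one molecule.

    All values come from an external property calculation or a printed
    table; optional fields may be None and the rules that need them are
    then skipped.
    """

    molecule_id: str
    molar_mass: float               # g/mol
    hbd_count: int
    hba_count: int
    tpsa: float | None = None       # Angstrom^2
    fsp3: float | None = None       # fraction of sp3 carbons
    rotatable_count: int | None = None
    logp: float | None = None
    logs: float | None = None

    def __post_init__(self) -> None:
        if self.hbd_count < 0 or self.hba_count < 0:
            raise ValueError("H-bond donor/acceptor counts must be nonnegative")
        if self.rotatable_count is not None and self.rotatable_count < 0:
            raise ValueError("rotatable count must be nonnegative")
        if self.fsp3 is not None and not (0.0 <= self.fsp3 <= 1.0):
            raise ValueError(f"FSP3 must be in [0, 1], got {self.fsp3}")


def lipinski_violations(props: PropertyTable) -> list[str]:
    """Names of violated Rule-of-Five criteria (empty list = compliant).

    The logP rule is skipped when logP was not supplied.
    """
    violations = []
    if props.molar_mass > 500:
        violations.append("MW>500")
    if props.hbd_count > 5:
        violations.append("HBD>5")
    if props.hba_count > 10:
        violations.append("HBA>10")
    if props.logp is not None and props.logp > 5:
        violations.append("logP>5")
    return violations


# SwissADME bioavailability-radar ideal ranges, per axis (low, high).
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "size": (150.0, 500.0),          # molar mass, g/mol
    "polarity": (20.0, 130.0),       # TPSA, Angstrom^2
    "lipophilicity": (-0.7, 5.0),    # logP (XLOGP3 scale)
    "insolubility": (-6.0, 0.0),     # logS (ESOL scale)
    "insaturation": (0.25, 1.0),     # FSP3
    "flexibility": (0.0, 9.0),       # rotatable count
}


@dataclass(frozen=True)
class RadarRanges:
    """Ideal (low, high) band per bioavailability-radar axis."""

    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        for axis, (low, high) in self.ranges.items():
            if not low < high:
                raise ValueError(f"axis {axis!r}: require low < high, got ({low}, {high})")
        object.__setattr__(self, "ranges", dict(self.ranges))


def _axis_value(props: PropertyTable, axis: str) -> float | None:
    return {
        "size": props.molar_mass,
        "polarity": props.tpsa,
        "lipophilicity": props.logp,
        "insolubility": props.logs,
        "insaturation": props.fsp3,
        "flexibility": props.rotatable_count,
    }.get(axis)


def radar_verdict(
    props: PropertyTable, ranges: RadarRanges | None = None
) -> dict[str, object]:
    """Per-axis in/out verdict against the bioavailability-radar bands.

    Returns ``{"axes": {axis: "in"|"out"|"unknown"}, "offending": [...],
    "all_in": bool}``; axes with no supplied value are "unknown", not
    failed, and ``all_in`` considers known axes only.
    """
    ranges = ranges or RadarRanges()
    axes: dict[str, str] = {}
    offending: list[str] = []
    for axis, (low, high) in ranges.ranges.items():
        value = _axis_value(props, axis)
        if value is None:
            axes[axis] = "unknown"
        elif low <= value <= high:
            axes[axis] = "in"
        else:
            axes[axis] = "out"
            offending.append(axis)
    return {"axes": axes, "offending": offending, "all_in": not offending}
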