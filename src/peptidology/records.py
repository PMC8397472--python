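"""Charge-state triad records: domain types, readers/writers, validation.

The pipeline's sole input pathway is a *triad* per molecule: three
independently converged self-consistent-field results for the neutral
(N electrons), radical cation (N-1) and radical anion (N+1) at fixed
geometry, carrying total ground-state energies, orbital-energy spectra
and, optionally, per-atom partial charges for each state.  Everything
downstream (vertical I/A, Koopmans-compliance descriptors, global and
condensed reactivity indices) is arithmetic on these records.

Energies are held internally in eV; hartree is accepted on input and
converted with the CODATA factor.  Open-shell records carry a single
merged (alpha) orbital list; the radical anion's highest occupied
orbital is its SOMO.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from rdkit import Chem

__all__ = [
    "HARTREE_TO_EV",
    "EnergyUnit",
    "ChargeState",
    "ElectronicStateRecord",
    "MoleculeTriad",
    "TriadSchemaError",
    "TriadValidationError",
    "read_triads",
    "write_triads",
    "read_triads_csv",
    "write_triads_csv",
    "validate_triad",
    "frontier_energies",
]

#: CODATA 2018 conversion factor.
HARTREE_TO_EV = 27.211386245988

_PERIODIC_TABLE = Chem.GetPeriodicTable()


class EnergyUnit(str, Enum):
    """Unit of energies in an input stream. Internal storage is always eV."""

    EV = "eV"
    HARTREE = "hartree"


class ChargeState(str, Enum):
    """Which member of the N / N-1 / N+1 triad a record describes."""

    NEUTRAL = "neutral"
    CATION = "cation"
    ANION = "anion"


class TriadSchemaError(ValueError):
    """Raised when an input stream does not conform to the triad schema."""


class TriadValidationError(ValueError):
    """Raised when a structurally well-formed triad violates an invariant."""


def _is_known_element(symbol: str) -> bool:
    try:
        return _PERIODIC_TABLE.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


@dataclass(frozen=True)
class ElectronicStateRecord:
    """One charge state's energies, orbital spectrum and optional charges.

    Parameters
    ----------
    charge_state
        Member of the triad this record describes.
    total_energy
        Ground-state total energy in eV.
    spin_multiplicity
        2S+1; the neutral is a singlet, both radical ions doublets.
    orbital_energies_occupied
        Occupied orbital energies in eV.  Stored descending (frontier
        first); any input order is accepted and re-sorted.
    orbital_energies_virtual
        Virtual orbital energies in eV, stored ascending.
    atomic_charges
        Optional per-atom partial charges in units of e, in atom-label
        order.  Their population-analysis provenance is metadata, not
        interpreted here.
    """

    charge_state: ChargeState
    total_energy: float
    spin_multiplicity: int
    orbital_energies_occupied: tuple[float, ...]
    orbital_energies_virtual: tuple[float, ...] = ()
    atomic_charges: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.orbital_energies_occupied:
            raise TriadValidationError(
                f"{self.charge_state.value}: occupied orbital list is empty"
            )
        object.__setattr__(
            self,
            "orbital_energies_occupied",
            tuple(sorted(self.orbital_energies_occupied, reverse=True)),
        )
        object.__setattr__(
            self,
            "orbital_energies_virtual",
            tuple(sorted(self.orbital_energies_virtual)),
        )
        if self.atomic_charges is not None:
            object.__setattr__(self, "atomic_charges", tuple(self.atomic_charges))


@dataclass(frozen=True)
class MoleculeTriad:
    """Neutral / cation / anion records for one molecule plus atom labels."""

    molecule_id: str
    atom_labels: tuple[tuple[str, int], ...]
    neutral: ElectronicStateRecord
    cation: ElectronicStateRecord
    anion: ElectronicStateRecord

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def state(self, which: ChargeState) -> ElectronicStateRecord:
        return {
            ChargeState.NEUTRAL: self.neutral,
            ChargeState.CATION: self.cation,
            ChargeState.ANION: self.anion,
        }[which]

    @property
    def has_charges(self) -> bool:
        return all(
            s.atomic_charges is not None for s in (self.neutral, self.cation, self.anion)
        )


def validate_triad(triad: MoleculeTriad) -> list[str]:
    """Check every triad invariant; return human-readable issues.

    An empty list means the triad is fully valid.  Issues are returned,
    never raised, so callers can report all problems at once.
    """
    issues: list[str] = []
    n = triad.n_atoms

    indices = [idx for _, idx in triad.atom_labels]
    if indices != list(range(1, n + 1)):
        issues.append("atom_labels: indices must be 1..n contiguous")
    for symbol, idx in triad.atom_labels:
        if not _is_known_element(symbol):
            issues.append(f"atom_labels: unknown element symbol {symbol!r} at index {idx}")

    if triad.neutral.spin_multiplicity != 1:
        issues.append(
            "neutral.spin_multiplicity: neutral state must be a singlet (multiplicity 1), "
            f"got {triad.neutral.spin_multiplicity}"
        )
    for name, rec in (("cation", triad.cation), ("anion", triad.anion)):
        if rec.spin_multiplicity != 2:
            issues.append(
                f"{name}.spin_multiplicity: radical ions must be in the doublet spin "
                f"state (multiplicity 2), got {rec.spin_multiplicity}"
            )

    states = {"neutral": triad.neutral, "cation": triad.cation, "anion": triad.anion}
    with_charges = {k for k, s in states.items() if s.atomic_charges is not None}
    if with_charges and with_charges != set(states):
        missing = sorted(set(states) - with_charges)
        issues.append(
            "atomic_charges: present for "
            f"{sorted(with_charges)} but missing for {missing}; charges must cover all "
            "three states or none"
        )
    for name, rec in states.items():
        if rec.atomic_charges is not None and len(rec.atomic_charges) != n:
            issues.append(
                f"{name}.atomic_charges: length {len(rec.atomic_charges)} does not match "
                f"atom count {n}"
            )
    return issues


def frontier_energies(
    state: ElectronicStateRecord, require_virtual: bool = True
) -> tuple[float, float | None]:
    """Return (HOMO, LUMO) of a record in eV.

    The HOMO is the maximum of the occupied list and the LUMO the
    minimum of the virtual list, so the result is invariant to input
    ordering.  With ``require_virtual=False`` a record without virtual
    orbitals yields ``(homo, None)``.
    """
    homo = max(state.orbital_energies_occupied)
    if not state.orbital_energies_virtual:
        if require_virtual:
            raise TriadValidationError(
                f"{state.charge_state.value}: virtual orbital list is empty, LUMO undefined"
            )
        return homo, None
    return homo, min(state.orbital_energies_virtual)


# ---------------------------------------------------------------------------
# JSON reader / writer (the documented triad schema)
# ---------------------------------------------------------------------------

_STATE_KEYS = ("neutral", "cation", "anion")


def _convert(value: float, unit: EnergyUnit) -> float:
    return value * HARTREE_TO_EV if unit is EnergyUnit.HARTREE else value


def _record_from_dict(
    mol_id: str, key: str, payload: dict, unit: EnergyUnit
) -> ElectronicStateRecord:
    try:
        total = payload["total_energy"]
        mult = payload["multiplicity"]
        occ = payload["occupied"]
    except KeyError as exc:
        raise TriadSchemaError(
            f"molecule {mol_id!r}, state {key!r}: missing field {exc.args[0]!r}"
        ) from None
    return ElectronicStateRecord(
        charge_state=ChargeState(key),
        total_energy=_convert(total, unit),
        spin_multiplicity=int(mult),
        orbital_energies_occupied=tuple(_convert(e, unit) for e in occ),
        orbital_energies_virtual=tuple(_convert(e, unit) for e in payload.get("virtual", ())),
        atomic_charges=(
            tuple(payload["charges"]) if payload.get("charges") is not None else None
        ),
    )


def _triad_from_dict(obj: dict, default_unit: EnergyUnit | None = None) -> MoleculeTriad:
    mol_id = obj.get("molecule_id")
    if not mol_id:
        raise TriadSchemaError("triad record lacks 'molecule_id'")
    unit = EnergyUnit(obj.get("unit", default_unit or EnergyUnit.EV))
    atoms = obj.get("atoms", [])
    labels = tuple((a["element"], int(a["index"])) for a in atoms)
    states = obj.get("states", {})
    missing = [k for k in _STATE_KEYS if k not in states]
    if missing:
        raise TriadSchemaError(
            f"molecule {mol_id!r}: missing charge state(s) {', '.join(missing)}"
        )
    records = {k: _record_from_dict(mol_id, k, states[k], unit) for k in _STATE_KEYS}
    triad = MoleculeTriad(
        molecule_id=mol_id,
        atom_labels=labels,
        neutral=records["neutral"],
        cation=records["cation"],
        anion=records["anion"],
    )
    issues = validate_triad(triad)
    if issues:
        raise TriadValidationError(
            f"molecule {mol_id!r}: " + "; ".join(issues)
        )
    return triad


def read_triads(
    source, unit: EnergyUnit | str | None = None
) -> list[MoleculeTriad]:
    """Read a JSON triad stream into validated :class:`MoleculeTriad` objects.

    ``source`` may be a path, an open text handle, a JSON string, or an
    already-parsed list/dict.  Each record may carry its own ``unit``
    field; ``unit`` here supplies the default for records without one.
    Triads are returned sorted by ``molecule_id``.
    """
    default_unit = EnergyUnit(unit) if unit is not None else None
    if isinstance(source, (list, dict)):
        data = source
    elif hasattr(source, "read"):
        data = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith(("[", "{")):
            data = json.loads(text)
        else:
            with open(text, encoding="utf-8") as fh:
                data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    triads = [_triad_from_dict(obj, default_unit) for obj in data]
    return sorted(triads, key=lambda t: t.molecule_id)


def _record_to_dict(rec: ElectronicStateRecord) -> dict:
    payload = {
        "total_energy": rec.total_energy,
        "multiplicity": rec.spin_multiplicity,
        "occupied": list(rec.orbital_energies_occupied),
        "virtual": list(rec.orbital_energies_virtual),
    }
    if rec.atomic_charges is not None:
        payload["charges"] = list(rec.atomic_charges)
    return payload


def triad_to_dict(triad: MoleculeTriad) -> dict:
    return {
        "molecule_id": triad.molecule_id,
        "unit": "eV",
        "atoms": [{"element": e, "index": i} for e, i in triad.atom_labels],
        "states": {
            "neutral": _record_to_dict(triad.neutral),
            "cation": _record_to_dict(triad.cation),
            "anion": _record_to_dict(triad.anion),
        },
    }


def write_triads(triads: Iterable[MoleculeTriad], target) -> None:
    """Write triads as JSON (eV) such that read_triads round-trips exactly."""
    payload = [triad_to_dict(t) for t in triads]
    if hasattr(target, "write"):
        json.dump(payload, target, indent=1)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# CSV dialect: one row per scalar with columns molecule_id, state, kind, index, value
# ---------------------------------------------------------------------------

_CSV_HEADER = ["molecule_id", "state", "kind", "index", "value"]


def write_triads_csv(triads: Iterable[MoleculeTriad], target) -> None:
    """Long-format CSV dialect of the triad schema (always eV).

    ``kind`` is one of total_energy, multiplicity, occupied, virtual,
    charge, atom_element; atom elements carry the symbol in ``value``.
    """

    def _emit(writer):
        for t in triads:
            for el, idx in t.atom_labels:
                writer.writerow([t.molecule_id, "", "atom_element", idx, el])
            for key in _STATE_KEYS:
                rec = t.state(ChargeState(key))
                writer.writerow(
                    [t.molecule_id, key, "total_energy", 0, repr(float(rec.total_energy))]
                )
                writer.writerow([t.molecule_id, key, "multiplicity", 0, rec.spin_multiplicity])
                for i, e in enumerate(rec.orbital_energies_occupied, 1):
                    writer.writerow([t.molecule_id, key, "occupied", i, repr(float(e))])
                for i, e in enumerate(rec.orbital_energies_virtual, 1):
                    writer.writerow([t.molecule_id, key, "virtual", i, repr(float(e))])
                if rec.atomic_charges is not None:
                    for i, q in enumerate(rec.atomic_charges, 1):
                        writer.writerow([t.molecule_id, key, "charge", i, repr(float(q))])

    if hasattr(target, "write"):
        w = csv.writer(target)
        w.writerow(_CSV_HEADER)
        _emit(w)
    else:
        with open(target, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_HEADER)
            _emit(w)


def read_triads_csv(source, unit: EnergyUnit | str = EnergyUnit.EV) -> list[MoleculeTriad]:
    """Read the long-format CSV dialect back into triads."""
    unit = EnergyUnit(unit)
    if hasattr(source, "read"):
        rows = list(csv.DictReader(source))
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))

    by_mol: dict[str, dict] = {}
    for row in rows:
        mol = by_mol.setdefault(
            row["molecule_id"],
            {"atoms": {}, "states": {k: {"occupied": {}, "virtual": {}, "charges": {}} for k in _STATE_KEYS}},
        )
        kind = row["kind"]
        if kind == "atom_element":
            mol["atoms"][int(row["index"])] = row["value"]
            continue
        state = row["state"]
        if state not in mol["states"]:
            raise TriadSchemaError(
                f"molecule {row['molecule_id']!r}: unknown state {state!r}"
            )
        st = mol["states"][state]
        if kind == "total_energy":
            st["total_energy"] = float(row["value"])
        elif kind == "multiplicity":
            st["multiplicity"] = int(row["value"])
        elif kind in ("occupied", "virtual"):
            st[kind][int(row["index"])] = float(row["value"])
        elif kind == "charge":
            st["charges"][int(row["index"])] = float(row["value"])
        else:
            raise TriadSchemaError(f"unknown row kind {kind!r}")

    triads = []
    for mol_id, mol in by_mol.items():
        states = {}
        for key in _STATE_KEYS:
            st = mol["states"][key]
            if "total_energy" not in st:
                raise TriadSchemaError(
                    f"molecule {mol_id!r}: missing charge state(s) {key}"
                )
            states[key] = {
                "total_energy": st["total_energy"],
                "multiplicity": st.get("multiplicity", 1),
                "occupied": [st["occupied"][i] for i in sorted(st["occupied"])],
                "virtual": [st["virtual"][i] for i in sorted(st["virtual"])],
                "charges": (
                    [st["charges"][i] for i in sorted(st["charges"])]
                    if st["charges"]
                    else None
                ),
            }
        obj = {
            "molecule_id": mol_id,
            "unit": unit.value,
            "atoms": [
                {"element": mol["atoms"][i], "index": i} for i in sorted(mol["atoms"])
            ],
            "states": states,
        }
        triads.append(_triad_from_dict(obj))
    return sorted(triads, key=lambda t: t.molecule_id)
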