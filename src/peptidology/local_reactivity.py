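"""Condensed (per-atom) reactivity descriptors.

The Fukui functions measure how the electron density responds to a
change in electron count; condensed to atoms through partial charges
q_k of the N, N-1 and N+1 electron states they read

    f+_k = q_k(N)   - q_k(N+1)   (nucleophilic-attack susceptibility)
    f-_k = q_k(N-1) - q_k(N)     (electrophilic-attack susceptibility)

Each vector sums to 1 when exactly one electron is transferred.  The
condensed dual descriptor df_k = f+_k - f-_k separates the two site
types unambiguously: positive values mark sites prone to nucleophilic
attack (electrophilic sites), negative values the converse.  The global
electrophilicity omega and nucleophilicity N are apportioned to atoms
via the matching Fukui function,

    omega_k = omega * f+_k        N_k = N * f-_k,

so the condensed columns sum back to the global indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .global_reactivity import GlobalDescriptors
from .records import MoleculeTriad

__all__ = [
    "CondensedSiteTable",
    "RankMode",
    "condensed_fukui",
    "condensed_dual",
    "condensed_philicity",
    "rank_sites",
    "condensed_sites",
    "local_table",
]


class RankMode(str, Enum):
    ELECTROPHILIC = "electrophilic"    # descending omega_k
    NUCLEOPHILIC = "nucleophilic"      # descending N_k
    DUAL_POSITIVE = "dual_positive"    # descending df
    DUAL_NEGATIVE = "dual_negative"    # ascending df


@dataclass(frozen=True)
class CondensedSiteTable:
    """Per-atom condensed descriptors for one molecule.

    Arrays are aligned with ``atom_labels``; H atoms are included here
    and filtered only at presentation time.
    """

    molecule_id: str
    atom_labels: tuple[tuple[str, int], ...]
    f_plus: np.ndarray
    f_minus: np.ndarray
    delta_f: np.ndarray
    omega_k: np.ndarray
    N_k: np.ndarray

    def __len__(self) -> int:
        return len(self.atom_labels)


def _charges(triad: MoleculeTriad) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    states = {"neutral": triad.neutral, "cation": triad.cation, "anion": triad.anion}
    for name, rec in states.items():
        if rec.atomic_charges is None:
            raise ValueError(
                f"molecule {triad.molecule_id!r}: atomic charges missing for {name} state"
            )
        if len(rec.atomic_charges) != triad.n_atoms:
            raise ValueError(
                f"molecule {triad.molecule_id!r}: {name} charge vector length "
                f"{len(rec.atomic_charges)} != atom count {triad.n_atoms}"
            )
    return (
        np.asarray(triad.neutral.atomic_charges, dtype=float),
        np.asarray(triad.cation.atomic_charges, dtype=float),
        np.asarray(triad.anion.atomic_charges, dtype=float),
    )


def condensed_fukui(triad: MoleculeTriad) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom (f+, f-) from the three charge-state population vectors."""
    q_n, q_cat, q_an = _charges(triad)
    f_plus = q_n - q_an
    f_minus = q_cat - q_n
    return f_plus, f_minus


def condensed_dual(f_plus: Sequence[float], f_minus: Sequence[float]) -> np.ndarray:
    """Condensed dual descriptor df_k = f+_k - f-_k."""
    f_plus = np.asarray(f_plus, dtype=float)
    f_minus = np.asarray(f_minus, dtype=float)
    if f_plus.shape != f_minus.shape:
        raise ValueError(
            f"Fukui vectors differ in length: {f_plus.shape} vs {f_minus.shape}"
        )
    return f_plus - f_minus


def condensed_philicity(
    f_plus: Sequence[float],
    f_minus: Sequence[float],
    omega: float,
    nucleophilicity_N: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Condensed electrophilicity omega_k = omega f+_k and nucleophilicity N_k = N f-_k."""
    if omega < 0:
        raise ValueError(f"global electrophilicity must be nonnegative, got {omega}")
    f_plus = np.asarray(f_plus, dtype=float)
    f_minus = np.asarray(f_minus, dtype=float)
    if f_plus.shape != f_minus.shape:
        raise ValueError(
            f"Fukui vectors differ in length: {f_plus.shape} vs {f_minus.shape}"
        )
    return omega * f_plus, nucleophilicity_N * f_minus


def rank_sites(
    table: CondensedSiteTable, mode: RankMode | str, top_n: int | None = None
) -> list[tuple[str, int]]:
    """Atom labels ordered by reactivity in the requested sense.

    Sorting is by omega_k (electrophilic), N_k (nucleophilic) or the
    dual descriptor (descending for dual_positive, ascending for
    dual_negative); ties break by atom index ascending.
    """
    if len(table) == 0:
        raise ValueError("cannot rank an empty site table")
    mode = RankMode(mode)
    key, descending = {
        RankMode.ELECTROPHILIC: (table.omega_k, True),
        RankMode.NUCLEOPHILIC: (table.N_k, True),
        RankMode.DUAL_POSITIVE: (table.delta_f, True),
        RankMode.DUAL_NEGATIVE: (table.delta_f, False),
    }[mode]
    indices = np.array([idx for _, idx in table.atom_labels])
    primary = -key if descending else key
    order = np.lexsort((indices, primary))
    ranked = [table.atom_labels[i] for i in order]
    return ranked[:top_n] if top_n is not None else ranked


def local_table(
    triad: MoleculeTriad,
    glob: GlobalDescriptors,
    show_hydrogens: bool = False,
    round_digits: bool = True,
    flag_quantile: float = 0.9,
) -> pd.DataFrame:
    """Per-atom condensed descriptor report.

    Hydrogens are computed but hidden unless ``show_hydrogens``; the
    ``top_*`` columns flag atoms in the top decile of each descriptor
    (quantile taken over the displayed rows).
    """
    sites = condensed_sites(triad, glob)
    df = pd.DataFrame(
        {
            "element": [e for e, _ in sites.atom_labels],
            "index": [i for _, i in sites.atom_labels],
            "f_plus": sites.f_plus,
            "f_minus": sites.f_minus,
            "delta_f": sites.delta_f,
            "omega_k": sites.omega_k,
            "N_k": sites.N_k,
        }
    )
    if not show_hydrogens:
        df = df[df["element"] != "H"].reset_index(drop=True)
    for col in ("omega_k", "N_k", "delta_f"):
        cutoff = df[col].quantile(flag_quantile)
        df[f"top_{col}"] = df[col] >= cutoff
    if round_digits:
        for col in ("f_plus", "f_minus", "delta_f", "omega_k", "N_k"):
            df[col] = df[col].round(4)
    return df


def condensed_sites(triad: MoleculeTriad, glob: GlobalDescriptors) -> CondensedSiteTable:
    """Full condensed-descriptor bundle (all atoms, full precision)."""
    f_plus, f_minus = condensed_fukui(triad)
    delta_f = condensed_dual(f_plus, f_minus)
    omega_k, N_k = condensed_philicity(
        f_plus, f_minus, glob.omega, glob.nucleophilicity_N
    )
    return CondensedSiteTable(
        molecule_id=triad.molecule_id,
        atom_labels=triad.atom_labels,
        f_plus=f_plus,
        f_minus=f_minus,
        delta_f=delta_f,
        omega_k=omega_k,
        N_k=N_k,
    )
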