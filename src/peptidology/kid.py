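"""Koopmans-in-DFT (KID) compliance descriptors from charge-state triads.

In the generalized Kohn-Sham picture, a functional behaves
"Koopmans-like" when the frontier orbital energies reproduce the
vertical charge-transfer energetics: eps_HOMO ~ -I and eps_LUMO ~ -A,
with I and A obtained by the Delta-SCF route as total-energy
differences between the N, N-1 and N+1 electron systems at fixed
geometry.  The KID descriptors quantify the residuals:

    J_I   = |eps_H + E(N-1) - E(N)|
    J_A   = |eps_L + E(N)   - E(N+1)|
    J_HL  = sqrt(J_I^2 + J_A^2)
    dSL   = |eps_SOMO(anion) - eps_L(neutral)|

J_A is only meaningful if the radical anion's SOMO resembles the
neutral's LUMO, which dSL checks directly.  Values near zero certify
the model chemistry for the descriptor arithmetic downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .records import MoleculeTriad, frontier_energies

__all__ = [
    "KIDReport",
    "vertical_ionization_energy",
    "vertical_electron_affinity",
    "kid_report",
    "kid_table",
    "DEFAULT_JHL_MAX",
    "DEFAULT_DSL_MAX",
]

# Compliance flags: configurable defaults chosen so that deviations an
# order of magnitude below typical orbital energies count as compliant.
DEFAULT_JHL_MAX = 0.1
DEFAULT_DSL_MAX = 0.2

#: Table column order used by kid_table and the CLI reports.
KID_COLUMNS = ["HOMO", "LUMO", "SOMO", "H-L gap", "J_I", "J_A", "J_HL", "dSL"]


def vertical_ionization_energy(triad: MoleculeTriad) -> float:
    """Vertical ionization energy I = E(N-1) - E(N), in eV (Delta-SCF)."""
    return triad.cation.total_energy - triad.neutral.total_energy


def vertical_electron_affinity(triad: MoleculeTriad) -> float:
    """Vertical electron affinity A = E(N) - E(N+1), in eV (Delta-SCF).

    A negative value (anion above the neutral) is returned unchanged.
    """
    return triad.neutral.total_energy - triad.anion.total_energy


@dataclass(frozen=True)
class KIDReport:
    """Frontier energies and KID compliance descriptors for one molecule (eV)."""

    molecule_id: str
    homo: float
    lumo: float
    somo: float
    gap: float
    J_I: float
    J_A: float
    J_HL: float
    delta_SL: float

    def is_compliant(
        self, jhl_max: float = DEFAULT_JHL_MAX, dsl_max: float = DEFAULT_DSL_MAX
    ) -> bool:
        return self.J_HL <= jhl_max and self.delta_SL <= dsl_max


def kid_report(triad: MoleculeTriad) -> KIDReport:
    """Compute the four KID descriptors for one triad.

    The anion's SOMO is its highest occupied (alpha) orbital.  All
    descriptors are absolute deviations, hence nonnegative, and
    J_HL is their Euclidean combination.
    """
    eps_H, eps_L = frontier_energies(triad.neutral)
    somo, _ = frontier_energies(triad.anion, require_virtual=False)
    I = vertical_ionization_energy(triad)
    A = vertical_electron_affinity(triad)
    J_I = abs(eps_H + I)
    J_A = abs(eps_L + A)
    return KIDReport(
        molecule_id=triad.molecule_id,
        homo=eps_H,
        lumo=eps_L,
        somo=somo,
        gap=eps_L - eps_H,
        J_I=J_I,
        J_A=J_A,
        J_HL=math.hypot(J_I, J_A),
        delta_SL=abs(somo - eps_L),
    )


def kid_table(
    triads: Iterable[MoleculeTriad], round_digits: bool = True
) -> pd.DataFrame:
    """One row per molecule with the KID report columns, sorted by id.

    With ``round_digits`` (the default) orbital energies and the gap are
    rounded to 4 decimals and the J/dSL descriptors to 3, the precision
    used in printed reports; pass ``False`` for full precision.
    """
    rows = []
    for triad in sorted(triads, key=lambda t: t.molecule_id):
        r = kid_report(triad)
        rows.append(
            {
                "Molecule": r.molecule_id,
                "HOMO": r.homo,
                "LUMO": r.lumo,
                "SOMO": r.somo,
                "H-L gap": r.gap,
                "J_I": r.J_I,
                "J_A": r.J_A,
                "J_HL": r.J_HL,
                "dSL": r.delta_SL,
            }
        )
    df = pd.DataFrame(rows, columns=["Molecule"] + KID_COLUMNS)
    if round_digits and not df.empty:
        for col in ("HOMO", "LUMO", "SOMO", "H-L gap"):
            df[col] = df[col].round(4)
        for col in ("J_I", "J_A", "J_HL", "dSL"):
            df[col] = df[col].round(3)
    return df
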