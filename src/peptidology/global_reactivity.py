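"""Global conceptual-DFT reactivity descriptors.

All descriptors derive from the vertical ionization energy I and
electron affinity A, or — in a Koopmans-compliant functional — from the
frontier orbital energies via I ~ -eps_H, A ~ -eps_L:

    chi    = (I + A)/2        ~ -(eps_H + eps_L)/2     electronegativity
    mu     = -chi                                       chemical potential
    eta    = I - A            ~  eps_L - eps_H          global hardness (gap)
    S      = 1/eta                                      global softness
    omega  = chi^2 / (2 eta)                            electrophilicity
    omega- = (3I + A)^2 / (16 eta)                      electrodonating power
    omega+ = (I + 3A)^2 / (16 eta)                      electroaccepting power
    dOmega = omega+ + omega-                            net electrophilicity
    N      = eps_H - eps_H(TCE)                         nucleophilicity

The electrodonating/electroaccepting pair satisfies the algebraic
identity omega- - omega+ = chi, asserted on every computed bundle.
The nucleophilicity index N references the HOMO of tetracyanoethylene
(TCE) computed at the same model chemistry; the packaged default is
the MN12SX/Def2TZVP/H2O value.

The electrophilicity scale classifies organic molecules as strong
(omega > 1.5 eV), moderate (0.8-1.5 eV) or marginal (omega < 0.8 eV)
electrophiles; boundary points fall in the moderate class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .records import MoleculeTriad, frontier_energies

__all__ = [
    "TCE_HOMO_DEFAULT",
    "ElectrophileClass",
    "GlobalDescriptors",
    "global_descriptors",
    "global_descriptors_from_IA",
    "classify_electrophile",
    "global_table",
]

#: HOMO energy of tetracyanoethylene at the reference model chemistry (eV).
TCE_HOMO_DEFAULT = -8.7925

#: Electrophilicity scale boundaries (eV); closed on the moderate side.
CLASS_BOUNDARIES = (0.8, 1.5)

GLOBAL_COLUMNS = ["chi", "eta", "omega", "S", "N", "omega-", "omega+", "dOmega+-"]

_IDENTITY_TOL = 1e-9


class ElectrophileClass(str, Enum):
    STRONG = "strong"
    MODERATE = "moderate"
    MARGINAL = "marginal"


class DegenerateGapError(ValueError):
    """Raised when eta <= 0 (LUMO at or below HOMO / A >= I)."""


@dataclass(frozen=True)
class GlobalDescriptors:
    """The global CDFT descriptor bundle for one molecule (energies in eV)."""

    chi: float
    mu: float
    eta: float
    softness_S: float
    omega: float
    omega_minus: float
    omega_plus: float
    net_electrophilicity: float
    nucleophilicity_N: float
    electrophile_class: ElectrophileClass
    mode: str  # "orbital" or "delta_scf"

    def __post_init__(self) -> None:
        # Internal-consistency identities of the closed-form definitions.
        assert abs((self.omega_minus - self.omega_plus) - self.chi) < _IDENTITY_TOL
        assert (
            abs(self.net_electrophilicity - (self.omega_plus + self.omega_minus))
            < _IDENTITY_TOL
        )
        assert abs(self.softness_S * self.eta - 1.0) < _IDENTITY_TOL
        assert abs(self.omega - self.chi**2 / (2.0 * self.eta)) < _IDENTITY_TOL


def classify_electrophile(
    omega: float, boundaries: tuple[float, float] = CLASS_BOUNDARIES
) -> ElectrophileClass:
    """Place an electrophilicity index on the strong/moderate/marginal scale."""
    if omega < 0:
        raise ValueError(f"electrophilicity must be nonnegative, got {omega}")
    low, high = boundaries
    if omega > high:
        return ElectrophileClass.STRONG
    if omega < low:
        return ElectrophileClass.MARGINAL
    return ElectrophileClass.MODERATE


def _bundle_from_IA(
    I: float, A: float, eps_H: float, tce_homo: float, mode: str
) -> GlobalDescriptors:
    eta = I - A
    if eta <= 0:
        raise DegenerateGapError(
            f"hardness must be positive (I > A / LUMO above HOMO); got eta = {eta}"
        )
    chi = (I + A) / 2.0
    omega = chi**2 / (2.0 * eta)
    omega_minus = (3.0 * I + A) ** 2 / (16.0 * eta)
    omega_plus = (I + 3.0 * A) ** 2 / (16.0 * eta)
    return GlobalDescriptors(
        chi=chi,
        mu=-chi,
        eta=eta,
        softness_S=1.0 / eta,
        omega=omega,
        omega_minus=omega_minus,
        omega_plus=omega_plus,
        net_electrophilicity=omega_plus + omega_minus,
        nucleophilicity_N=eps_H - tce_homo,
        electrophile_class=classify_electrophile(omega),
        mode=mode,
    )


def global_descriptors(
    eps_H: float, eps_L: float, tce_homo: float = TCE_HOMO_DEFAULT
) -> GlobalDescriptors:
    """Descriptor bundle in the frontier-orbital (Koopmans) approximation.

    Substitutes I = -eps_H and A = -eps_L into the Delta-SCF forms, so
    chi = -(eps_H + eps_L)/2 and eta = eps_L - eps_H.
    """
    if eps_L <= eps_H:
        raise DegenerateGapError(
            f"LUMO ({eps_L}) must lie above HOMO ({eps_H})"
        )
    return _bundle_from_IA(-eps_H, -eps_L, eps_H, tce_homo, mode="orbital")


def global_descriptors_from_IA(
    I: float, A: float, tce_homo: float = TCE_HOMO_DEFAULT, eps_H: float | None = None
) -> GlobalDescriptors:
    """Descriptor bundle from Delta-SCF vertical I and A.

    The nucleophilicity index is orbital-based by definition, so it
    still needs eps_H; when not given, -I is used in its place (the
    Koopmans estimate of the HOMO energy).
    """
    if I <= A:
        raise DegenerateGapError(f"require I > A, got I = {I}, A = {A}")
    if eps_H is None:
        eps_H = -I
    return _bundle_from_IA(I, A, eps_H, tce_homo, mode="delta_scf")


def global_table(
    triads: Iterable[MoleculeTriad],
    tce_homo: float = TCE_HOMO_DEFAULT,
    round_digits: bool = True,
) -> pd.DataFrame:
    """One row per molecule with the global descriptor columns (4 dp)."""
    rows = []
    for triad in sorted(triads, key=lambda t: t.molecule_id):
        eps_H, eps_L = frontier_energies(triad.neutral)
        g = global_descriptors(eps_H, eps_L, tce_homo)
        rows.append(
            {
                "Molecule": triad.molecule_id,
                "chi": g.chi,
                "eta": g.eta,
                "omega": g.omega,
                "S": g.softness_S,
                "N": g.nucleophilicity_N,
                "omega-": g.omega_minus,
                "omega+": g.omega_plus,
                "dOmega+-": g.net_electrophilicity,
                "class": g.electrophile_class.value,
            }
        )
    df = pd.DataFrame(rows, columns=["Molecule"] + GLOBAL_COLUMNS + ["class"])
    if round_digits and not df.empty:
        df[GLOBAL_COLUMNS] = df[GLOBAL_COLUMNS].round(4)
    return df
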