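"""Seeded synthetic triads with known ground truth, plus printed fixtures.

Real triads come from three converged SCF calculations; this module
constructs them backwards from the answers so every pipeline stage can
be tested without a quantum-chemistry run.  A :class:`TriadSpec` fixes
the frontier energies, the imposed Koopmans deviations (delta_I,
delta_A), the SOMO offset from the LUMO, and the target Fukui vectors;
:func:`generate_triad` then builds total energies and charge-state
populations such that the downstream descriptors recover exactly those
quantities.  Total energies are anchored at a large negative constant
so that the I/A subtractions exercise realistic cancellation.

The generator emulates only what the descriptor arithmetic consumes:
it makes no attempt at physically realistic orbital spectra, geometries
or population analyses.

:func:`fixture_pashinintides` returns triads and property tables for
the two Rosaceae cyclopeptides Pashinintide A and B, transcribed from
the published MN12SX/Def2TZVP/H2O characterization, and
:func:`reference_site_table` exposes their published condensed
electrophilicity/nucleophilicity columns for rank-order work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .druglike import PropertyTable
from .local_reactivity import CondensedSiteTable
from .records import ChargeState, ElectronicStateRecord, MoleculeTriad

__all__ = [
    "TriadSpec",
    "generate_triad",
    "generate_cohort",
    "fixture_pashinintides",
    "reference_site_table",
]

#: Arbitrary anchor for E(N); only energy differences are meaningful.
ENERGY_ANCHOR_EV = -75000.0

_FILLER_OCC_SPACING = 1.5   # eV between synthetic occupied levels below the HOMO
_FILLER_VIRT_SPACING = 1.0  # eV between synthetic virtual levels above the LUMO
_N_FILLER = 3


@dataclass(frozen=True)
class TriadSpec:
    """Ground-truth recipe for one synthetic molecule triad."""

    molecule_id: str
    n_atoms: int
    eps_H: float
    eps_L: float
    delta_I: float = 0.0
    delta_A: float = 0.0
    somo_offset: float = 0.0          # SOMO - LUMO, usually <= 0
    f_plus_target: tuple[float, ...] | None = None
    f_minus_target: tuple[float, ...] | None = None
    element_palette: tuple[str, ...] = ("C", "N", "O")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if not self.eps_L > self.eps_H:
            raise ValueError(
                f"require eps_L > eps_H, got {self.eps_L} <= {self.eps_H}"
            )
        if not self.eps_L + self.somo_offset > self.eps_H:
            raise ValueError("SOMO (eps_L + somo_offset) must lie above the HOMO")
        for name in ("f_plus_target", "f_minus_target"):
            vec = getattr(self, name)
            if vec is None:
                continue
            vec = tuple(float(x) for x in vec)
            object.__setattr__(self, name, vec)
            if len(vec) != self.n_atoms:
                raise ValueError(f"{name} length {len(vec)} != n_atoms {self.n_atoms}")
            if any(x < 0 for x in vec):
                raise ValueError(f"{name} must be nonnegative")
            if abs(sum(vec) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1, got {sum(vec)}")


def _atom_labels(spec: TriadSpec, rng: np.random.Generator) -> tuple[tuple[str, int], ...]:
    elements = rng.choice(spec.element_palette, size=spec.n_atoms)
    return tuple((str(el), i) for i, el in enumerate(elements, 1))


def generate_triad(spec: TriadSpec) -> MoleculeTriad:
    """Build a triad whose descriptors equal the spec's imposed values.

    Construction guarantees (to float rounding): vertical I =
    -eps_H + delta_I and A = -eps_L - delta_A, hence J_I = |delta_I|
    and J_A = |delta_A|; anion SOMO = eps_L + somo_offset; and, when
    Fukui targets are given, condensed f+/f- recover them.  The same
    seed always yields the same triad.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _atom_labels(spec, rng)

    occ = tuple(
        spec.eps_H - k * _FILLER_OCC_SPACING for k in range(_N_FILLER, -1, -1)
    )
    virt = tuple(
        spec.eps_L + k * _FILLER_VIRT_SPACING for k in range(_N_FILLER + 1)
    )
    somo = spec.eps_L + spec.somo_offset

    e_neutral = ENERGY_ANCHOR_EV
    e_cation = e_neutral + (-spec.eps_H + spec.delta_I)
    e_anion = e_neutral - (-spec.eps_L - spec.delta_A)

    if spec.f_plus_target is not None and spec.f_minus_target is not None:
        q_n = rng.normal(scale=0.1, size=spec.n_atoms)
        q_n -= q_n.mean()  # neutral molecule: charges sum to zero
        q_cat = q_n + np.asarray(spec.f_minus_target)
        q_an = q_n - np.asarray(spec.f_plus_target)
        charges = {
            "neutral": tuple(float(q) for q in q_n),
            "cation": tuple(float(q) for q in q_cat),
            "anion": tuple(float(q) for q in q_an),
        }
    else:
        charges = {"neutral": None, "cation": None, "anion": None}

    neutral = ElectronicStateRecord(
        charge_state=ChargeState.NEUTRAL,
        total_energy=e_neutral,
        spin_multiplicity=1,
        orbital_energies_occupied=occ,
        orbital_energies_virtual=virt,
        atomic_charges=charges["neutral"],
    )
    cation = ElectronicStateRecord(
        charge_state=ChargeState.CATION,
        total_energy=e_cation,
        spin_multiplicity=2,
        orbital_energies_occupied=occ[:-1],  # electron removed from the HOMO
        orbital_energies_virtual=(spec.eps_H,) + virt,
        atomic_charges=charges["cation"],
    )
    anion = ElectronicStateRecord(
        charge_state=ChargeState.ANION,
        total_energy=e_anion,
        spin_multiplicity=2,
        orbital_energies_occupied=occ + (somo,),  # SOMO is the anion's alpha-HOMO
        orbital_energies_virtual=tuple(
            somo + (k + 1) * _FILLER_VIRT_SPACING for k in range(_N_FILLER)
        ),
        atomic_charges=charges["anion"],
    )
    return MoleculeTriad(
        molecule_id=spec.molecule_id,
        atom_labels=labels,
        neutral=neutral,
        cation=cation,
        anion=anion,
    )


def generate_cohort(
    n_molecules: int,
    seed: int = 0,
    eps_H_range: tuple[float, float] = (-7.0, -5.0),
    gap_range: tuple[float, float] = (4.0, 5.0),
    deviation_max: float = 0.1,
    n_atoms_range: tuple[int, int] = (8, 24),
) -> tuple[list[MoleculeTriad], list[TriadSpec]]:
    """Reproducible cohort of synthetic triads plus its ground-truth manifest.

    Frontier energies, Koopmans deviations and Fukui targets are drawn
    from the given ranges with an integer-seeded generator, so the same
    arguments always produce byte-identical triads and manifest.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    specs: list[TriadSpec] = []
    for i in range(n_molecules):
        eps_H = rng.uniform(*eps_H_range)
        gap = rng.uniform(*gap_range)
        n_atoms = int(rng.integers(n_atoms_range[0], n_atoms_range[1] + 1))
        f_plus = rng.dirichlet(np.ones(n_atoms))
        f_minus = rng.dirichlet(np.ones(n_atoms))
        specs.append(
            TriadSpec(
                molecule_id=f"synthetic-{i:04d}",
                n_atoms=n_atoms,
                eps_H=eps_H,
                eps_L=eps_H + gap,
                delta_I=rng.uniform(0.0, deviation_max),
                delta_A=rng.uniform(0.0, deviation_max),
                somo_offset=rng.uniform(-0.2, 0.0),
                f_plus_target=tuple(f_plus),
                f_minus_target=tuple(f_minus),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return [generate_triad(s) for s in specs], specs


# ---------------------------------------------------------------------------
# Pashinintide A / B fixtures (published characterization, synthetic triads)
# ---------------------------------------------------------------------------

# Frontier/SOMO energies (eV) and Koopmans deviations of the published
# MN12SX/Def2TZVP/H2O KID validation table.
_PASHININTIDE_KID = {
    "Pashinintide A": dict(eps_H=-5.5424, eps_L=-0.9796, somo=-1.1113,
                           delta_I=0.018, delta_A=0.054),
    "Pashinintide B": dict(eps_H=-5.6589, eps_L=-1.2210, somo=-1.3641,
                           delta_I=0.028, delta_A=0.070),
}

# Published condensed electrophilicity omega_k and nucleophilicity N_k
# (eV) over the non-hydrogen atoms; hydrogens are not reported.
_SITE_TABLE_A: tuple[tuple[str, int, float, float], ...] = (
    ("O", 1, 0.0247, 0.0307), ("O", 2, 0.0132, 0.0127), ("O", 3, 0.0210, 0.0028),
    ("O", 4, 0.1613, 0.0031), ("O", 5, 0.0129, 0.0204), ("O", 6, 0.0257, 0.0050),
    ("N", 7, 0.0097, 0.0045), ("N", 8, 0.0576, 0.0002), ("N", 9, 0.0052, 0.0039),
    ("N", 10, 0.0016, 0.0129), ("N", 11, 0.0103, 0.0020), ("N", 12, 0.0146, 0.0034),
    ("N", 13, 0.0018, 0.2820), ("C", 14, 0.0035, 0.0058), ("C", 15, 0.0029, 0.0056),
    ("C", 16, 0.0028, 0.0099), ("C", 17, 0.0035, 0.0071), ("C", 18, 0.0191, 0.0007),
    ("C", 19, 0.0101, 0.0007), ("C", 20, 0.0123, 0.0004), ("C", 21, 0.0233, 0.0007),
    ("C", 22, 0.0312, 0.0083), ("C", 23, 0.0059, 0.0337), ("C", 24, 0.0091, 0.0046),
    ("C", 25, 0.0076, 0.0624), ("C", 26, 0.0094, 0.0013), ("C", 27, 0.1956, 0.0006),
    ("C", 28, 0.0046, 0.0012), ("C", 29, 0.0003, 0.3993), ("C", 30, 0.0416, 0.0022),
    ("C", 31, 0.0061, 0.0052), ("C", 32, 0.0081, 0.0128), ("C", 33, 0.0009, 0.0893),
    ("C", 34, 0.0180, 0.0019), ("C", 35, 0.0033, 0.3996), ("C", 36, 0.0042, 0.0016),
    ("C", 37, 0.0016, 0.1249), ("C", 38, 0.0027, 0.2805), ("C", 39, 0.0028, 0.2514),
    ("C", 40, 0.0026, 0.1608), ("C", 41, 0.0019, 0.2900),
)

_SITE_TABLE_B: tuple[tuple[str, int, float, float], ...] = (
    ("O", 1, 0.1768, 0.0238), ("O", 2, 0.0181, 0.0091), ("O", 3, 0.0034, 0.0003),
    ("O", 4, 0.0030, 0.0032), ("O", 5, 0.1346, 0.0291), ("O", 6, 0.0012, 0.0430),
    ("O", 7, 0.0013, 0.0006), ("O", 8, 0.0150, 0.0037), ("O", 9, 0.0016, 0.0011),
    ("N", 10, 0.0072, 0.0009), ("N", 11, 0.0539, 0.0162), ("N", 12, 0.0020, 0.0009),
    ("N", 13, 0.0057, 0.2153), ("N", 14, 0.0003, 0.0003), ("N", 15, 0.0589, 0.0121),
    ("N", 16, 0.0009, 0.0008), ("N", 17, 0.0059, 0.0018), ("C", 18, 0.0050, 0.0014),
    ("C", 19, 0.0196, 0.0014), ("C", 20, 0.0038, 0.0011), ("C", 21, 0.0006, 0.0003),
    ("C", 22, 0.0344, 0.0361), ("C", 23, 0.0009, 0.0003), ("C", 24, 0.1587, 0.0090),
    ("C", 25, 0.0176, 0.0647), ("C", 26, 0.0068, 0.0012), ("C", 27, 0.0072, 0.3991),
    ("C", 28, 0.0041, 0.0016), ("C", 29, 0.0005, 0.0001), ("C", 30, 0.0130, 0.0098),
    ("C", 31, 0.0082, 0.1020), ("C", 32, 0.0043, 0.0008), ("C", 33, 0.0037, 0.0010),
    ("C", 34, 0.0005, 0.0002), ("C", 35, 0.0053, 0.1143), ("C", 36, 0.0180, 0.3832),
    ("C", 37, 0.1253, 0.0105), ("C", 38, 0.0026, 0.0026), ("C", 39, 0.0004, 0.0002),
    ("C", 40, 0.0128, 0.2814), ("C", 41, 0.0024, 0.0502), ("C", 42, 0.0096, 0.2328),
    ("C", 43, 0.0006, 0.0001), ("C", 44, 0.0074, 0.1523), ("C", 45, 0.0114, 0.2742),
    ("C", 46, 0.0173, 0.0022), ("C", 47, 0.0006, 0.0003), ("C", 48, 0.0106, 0.0017),
    ("C", 49, 0.0026, 0.0009), ("C", 50, 0.0009, 0.0003), ("C", 51, 0.0010, 0.0223),
)

_SITE_TABLES = {"Pashinintide A": _SITE_TABLE_A, "Pashinintide B": _SITE_TABLE_B}

# Non-hydrogen rows above, completed to the published formulas
# (C28H35N7O6 with 76 atoms; C34H50N8O9 with 101 atoms).
_N_HYDROGENS = {"Pashinintide A": 35, "Pashinintide B": 50}

_PASHININTIDE_PROPS = {
    "Pashinintide A": dict(molar_mass=565.631, hbd_count=5, hba_count=6,
                           tpsa=172.81, fsp3=0.50, rotatable_count=2),
    "Pashinintide B": dict(molar_mass=714.821, hbd_count=8, hba_count=9,
                           tpsa=238.09, fsp3=0.56, rotatable_count=9),
}


def _fixture_spec(name: str) -> TriadSpec:
    kid = _PASHININTIDE_KID[name]
    heavy = _SITE_TABLES[name]
    n_h = _N_HYDROGENS[name]
    n_atoms = len(heavy) + n_h
    # Fukui targets from the published condensed columns, renormalized
    # to unit sum with zero weight on the (unreported) hydrogens; this
    # preserves the published site rankings exactly.
    omega_k = np.array([row[2] for row in heavy])
    n_k = np.array([row[3] for row in heavy])
    f_plus = np.concatenate([omega_k / omega_k.sum(), np.zeros(n_h)])
    f_minus = np.concatenate([n_k / n_k.sum(), np.zeros(n_h)])
    return TriadSpec(
        molecule_id=name,
        n_atoms=n_atoms,
        eps_H=kid["eps_H"],
        eps_L=kid["eps_L"],
        delta_I=kid["delta_I"],
        delta_A=kid["delta_A"],
        somo_offset=kid["somo"] - kid["eps_L"],
        f_plus_target=tuple(f_plus),
        f_minus_target=tuple(f_minus),
        seed=20210301,
    )


def _fixture_labels(name: str) -> tuple[tuple[str, int], ...]:
    heavy = _SITE_TABLES[name]
    n_h = _N_HYDROGENS[name]
    labels = [(el, idx) for el, idx, _, _ in heavy]
    start = len(labels) + 1
    labels += [("H", i) for i in range(start, start + n_h)]
    return tuple(labels)


def fixture_pashinintides() -> tuple[list[MoleculeTriad], list[PropertyTable]]:
    """Triads and property tables for Pashinintide A and B.

    The triads are synthetic reconstructions: frontier/SOMO energies
    and imposed Koopmans deviations equal the published values, atom
    labels follow the published numbering, and the charge-state
    populations are built from the published condensed descriptor
    columns so that site rankings reproduce.
    """
    triads = []
    props = []
    for name in ("Pashinintide A", "Pashinintide B"):
        triad = generate_triad(_fixture_spec(name))
        # Replace palette-drawn labels with the published atom numbering.
        triad = MoleculeTriad(
            molecule_id=triad.molecule_id,
            atom_labels=_fixture_labels(name),
            neutral=triad.neutral,
            cation=triad.cation,
            anion=triad.anion,
        )
        triads.append(triad)
        props.append(PropertyTable(molecule_id=name, **_PASHININTIDE_PROPS[name]))
    return triads, props


def reference_site_table(molecule_id: str) -> CondensedSiteTable:
    """Published condensed omega_k / N_k columns as a site table.

    The Fukui columns are the published philicities renormalized to
    unit sum (hydrogens unreported, hence absent); use this table for
    rank-order analysis, not for absolute dual-descriptor values.
    """
    heavy = _SITE_TABLES[molecule_id]
    labels = tuple((el, idx) for el, idx, _, _ in heavy)
    omega_k = np.array([row[2] for row in heavy])
    n_k = np.array([row[3] for row in heavy])
    f_plus = omega_k / omega_k.sum()
    f_minus = n_k / n_k.sum()
    return CondensedSiteTable(
        molecule_id=molecule_id,
        atom_labels=labels,
        f_plus=f_plus,
        f_minus=f_minus,
        delta_f=f_plus - f_minus,
        omega_k=omega_k,
        N_k=n_k,
    )
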