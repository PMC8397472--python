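# Methods

## Scope and data model

The package operates strictly downstream of quantum chemistry. Its
unit of input is the *molecule triad*: three independently converged
SCF results — neutral (N electrons, singlet), radical cation (N−1,
doublet) and radical anion (N+1, doublet) — at the neutral geometry,
each carrying a total ground-state energy, an orbital-energy spectrum,
and optionally one partial charge per atom. Geometry, SCF history and
basis metadata are deliberately out of the data model; the triad
schema (JSON, plus a long-format CSV dialect) is the interface, so any
electronic-structure code can feed the pipeline.

Energies are stored internally in eV. Hartree input is converted with
the CODATA factor 1 Eh = 27.211386245988 eV; the conversion is exact
to a ulp under round-trip. Open-shell records carry a single merged
(α) orbital list — only the anion's highest occupied orbital (its
SOMO) is consumed downstream, so β spectra would be dead weight.

## KID validation

Vertical I and A come from the ΔSCF route: I = E(N−1) − E(N),
A = E(N) − E(N+1); negative affinities are returned unchanged. The
compliance residuals are J_I = |ε_H + I|, J_A = |ε_L + A|,
J_HL = √(J_I² + J_A²), and ΔSL = |ε_SOMO(anion) − ε_L(neutral)|. All
four are magnitudes; ΔSL in particular is reported as an absolute
difference because it gauges the accuracy of the J_A approximation,
not a direction. J_HL obeys the Euclidean triangle bounds
max(J_I, J_A) ≤ J_HL ≤ J_I + J_A, asserted as a property test.

No universal compliance threshold exists; the report flags a molecule
compliant at J_HL ≤ 0.1 eV and ΔSL ≤ 0.2 eV, both configurable. The
defaults sit an order of magnitude below typical frontier energies and
comfortably above the values observed for validated functionals.

## Global descriptors

Conventions, fixed package-wide:

- hardness η = I − A (no ½ factor); `global_descriptors_from_IA`
  accepts the ½-convention nowhere — reports always use the gap form.
- softness S = 1/η (not 1/(2η)).
- ω = χ²/(2η); ω⁻ = (3I+A)²/(16η); ω⁺ = (I+3A)²/(16η); Δω± = ω⁺+ω⁻.
- nucleophilicity N = ε_H − ε_H(TCE), with the tetracyanoethylene
  reference HOMO defaulting to −8.7925 eV (the value at the
  MN12SX/Def2TZVP/H2O model chemistry); it is a required,
  overridable configuration value since N is only meaningful when
  both HOMOs come from the same model chemistry.

Every computed bundle self-checks the algebraic identities
ω⁻ − ω⁺ = χ, Δω± = ω⁻ + ω⁺, S·η = 1 and ω = χ²/(2η) at 1e-9. Both an
orbital mode (I = −ε_H, A = −ε_L) and a ΔSCF mode are provided; they
agree exactly in the Koopmans limit, which is itself a test.

The electrophilicity scale (strong > 1.5 eV, 0.8–1.5 moderate,
< 0.8 marginal) leaves its boundary points unassigned in the strict
inequalities as usually quoted; this implementation closes the
moderate interval ([0.8, 1.5]), the minimal-surprise choice, and the
boundaries are configurable.

## Condensed local descriptors

The condensed scheme is the charge-difference ("response of the
molecular fragment") form over whatever population analysis produced
the input charges; the provenance (Hirshfeld, Mulliken, NPA, …) is
metadata the package does not interpret. Sum rules — Σf⁺ = Σf⁻ = 1,
ΣΔf = 0, Σω_k = ω, ΣN_k = N whenever each ionization transfers one
electron — are asserted on every synthetic cohort. Site rankings sort
descending by the relevant column with ties broken by atom index
ascending, making rankings deterministic. Hydrogens are computed but
hidden in reports by default (a flag reveals them), matching common
reporting practice for peptide-sized molecules.

A caveat for the published reference columns bundled as fixtures: the
printed condensed dual-descriptor column of the source tables is not
numerically consistent with the printed ω_k/N_k columns (back-dividing
ω_k/ω and N_k/N yields a different Δf than printed — evidently a
different population set or normalization upstream). The bundled
columns are therefore used for rank-order work only, never for
absolute Δf value checks. Similarly, the source's prose ranking of
nucleophilic sites for Pashinintide B omits one atom (C(42)) that its
own printed column places fifth; tests assert the prose order as a
relative order within the full ranking, the strongest claim the
printed data supports.

## Formula-level properties and drug-likeness

Average masses use IUPAC standard atomic weights and monoisotopic
masses the most-abundant-isotope table, both via RDKit's periodic
table; these reproduce the published reference masses to the printed
precision (3 dp average, 6 dp exact — the isotope-table edition behind
the source's 9-dp prints is unknowable, so agreement is asserted at
6 dp). Composition percentages are full precision internally and sum
to 100 within rounding.

Lipinski verdicts check MW ≤ 500, HBD ≤ 5, HBA ≤ 10, logP ≤ 5, with
the logP rule skipped (not failed) when logP is absent. Radar axes
default to the published SwissADME ideal bands — size MW 150–500
g/mol, polarity TPSA 20–130 Å², lipophilicity logP −0.7–5.0,
insolubility logS −6–0, insaturation FSP3 0.25–1.0, flexibility 0–9
rotatables — and are fully configurable; a rotatable-*atom* count is
mapped onto the flexibility axis as-is since no atoms↔bonds conversion
is derivable. Axes with missing values report "unknown" rather than
failing. All structure-derived descriptors are inputs: nothing is
perceived from SMILES or connectivity.

## Synthetic generator

The generator is the pipeline's test harness: a `TriadSpec` fixes the
frontier energies, the imposed Koopmans deviations (δ_I, δ_A), the
SOMO−LUMO offset, and target Fukui vectors; the triad is built
backwards so that the descriptors recover exactly those quantities.
Total energies are anchored at −75 000 eV so the I/A subtractions
exercise realistic floating-point cancellation (recovery is asserted
at 1e-10, the residual such cancellation leaves in double precision).
Filler orbital levels (three below the HOMO at 1.5 eV spacing, three
above the LUMO at 1.0 eV) ensure frontier extraction is tested against
non-frontier levels. Neutral charges are drawn from a seeded
zero-mean normal (σ = 0.1 e, a typical partial-charge scale) and the
ion charges offset by the target Fukui vectors, so each ionization
transfers exactly one electron. Cohort draws default to ε_H ∈ [−7, −5]
eV, gaps ∈ [4, 5] eV, deviations ∈ [0, 0.1] eV and 8–24 atoms —
peptide-like frontier ranges bracketing the reference molecules. All
randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical cohorts and manifests on any platform.

What the generator does *not* emulate: physically consistent orbital
spectra versus total energies, geometry relaxation, β-spin structure,
or realistic population analyses. Passing tests therefore demonstrate
the descriptor arithmetic, sum rules and parameter recovery — not that
any particular functional is Koopmans-compliant for real molecules.

The two Pashinintide fixtures are labelled synthetic reconstructions:
frontier/SOMO energies and imposed deviations equal the published
values, atom labelling follows the published numbering
(O, N, C blocks, then hydrogens), and Fukui targets are the published
condensed columns renormalized to unit sum with zero weight on the
unreported hydrogens — preserving published site ranks exactly while
keeping the sum rules intact.

## Numerical and reporting choices

- Report rounding mirrors the source tables: 4 dp for energies and
  global descriptors, 3 dp for KID deviations; JSON output keeps full
  precision and rounding is presentation-only.
- Published-cell tests compare at one unit of the printed precision
  where the printed inputs make exact agreement impossible: e.g.
  χ(Pashinintide B) computed from the printed 4-dp energies is exactly
  3.43995 (a half-ulp boundary), and ω⁻/Δω± of the same row land one
  print-ulp from the published cells, which were rounded upstream from
  unrounded orbital energies.
- Degenerate gaps (ε_L ≤ ε_H or A ≥ I) raise rather than produce
  infinities; negative electrophilicities are rejected at the
  classification boundary.
- Pipeline stages are pure: inputs are frozen dataclasses, and a
  before/after equality test guards against mutation. Missing optional
  inputs (no charges) skip the local stage with a warning instead of
  aborting, since local tables only exist where populations were
  computed.

## Problem sizes

The reference computations are desk-scale (two molecules, closed-form
arithmetic; milliseconds). Property-based acceptance runs a
1 000-molecule synthetic cohort plus 200 random frontier pairs, chosen
to exercise the sum rules and identities broadly while keeping the
default suite in the low seconds.
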