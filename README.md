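# peptidology

Conceptual-DFT reactivity profiling for (cyclo)peptides — a
"computational peptidology" pipeline that turns charge-state *triads*
(the N, N−1 and N+1 electron self-consistent-field results for one
molecule at fixed geometry) into:

- **Koopmans-in-DFT (KID) validation** — are the frontier orbital
  energies of the chosen functional trustworthy proxies for the
  vertical ionization energy I and electron affinity A?
- **Global reactivity descriptors** — electronegativity χ, hardness η,
  softness S, electrophilicity ω, electrodonating/electroaccepting
  powers ω⁻/ω⁺, net electrophilicity Δω±, nucleophilicity N.
- **Condensed local descriptors** — per-atom Fukui functions f⁺/f⁻,
  dual descriptor Δf, condensed philicities ω_k / N_k, and reactive-site
  rankings.
- **Rule-based drug-likeness** — formula masses and composition,
  Lipinski Rule-of-Five verdicts, and six-axis bioavailability-radar
  checks over supplied property tables.

It is aimed at computational chemists who already have the quantum
chemistry done (the package performs **no** electronic-structure
computation) and want the descriptor arithmetic, validation and
reporting to be reproducible, tested and scriptable. A deterministic
synthetic-triad generator with known ground truth makes the whole
pipeline testable without a single SCF run.

## The model

With ε_H, ε_L the neutral's HOMO/LUMO energies and E(N), E(N−1),
E(N+1) the triad total energies (all in eV):

```
I = E(N−1) − E(N)            A = E(N) − E(N+1)          (ΔSCF, vertical)

J_I  = |ε_H + I|             J_A  = |ε_L + A|           (KID residuals)
J_HL = sqrt(J_I² + J_A²)     ΔSL  = |ε_SOMO(anion) − ε_L|

χ = −(ε_H + ε_L)/2           η = ε_L − ε_H              S = 1/η
ω = χ²/(2η)                  ω⁻ = (3ε_H + ε_L)²/(16η)   ω⁺ = (ε_H + 3ε_L)²/(16η)
Δω± = ω⁺ + ω⁻               N = ε_H − ε_H(TCE)
```

Near-zero J and ΔSL certify "Koopmans-like" behaviour of the
functional, justifying the orbital route to the descriptors. The
electrophilicity scale reads: strong ω > 1.5 eV, moderate 0.8–1.5 eV,
marginal ω < 0.8 eV. Condensed to atoms via charge-state populations
q_k: f⁺_k = q_k(N) − q_k(N+1), f⁻_k = q_k(N−1) − q_k(N),
Δf_k = f⁺_k − f⁻_k, ω_k = ω·f⁺_k, N_k = N·f⁻_k.

## Worked example

The two Rosaceae cyclopeptides Pashinintide A and B ship as fixtures
(triads reconstructed from their published MN12SX/Def2TZVP/H2O
characterization):

```python
>>> import peptidology as p
>>> triads, props = p.fixture_pashinintides()
>>> print(p.kid_table(triads).to_string(index=False))
      Molecule    HOMO    LUMO    SOMO  H-L gap   J_I   J_A  J_HL   dSL
Pashinintide A -5.5424 -0.9796 -1.1113   4.5628 0.018 0.054 0.057 0.132
Pashinintide B -5.6589 -1.2210 -1.3641   4.4379 0.028 0.070 0.075 0.143
```

Every deviation is well under 0.1 eV: the functional is
Koopmans-compliant for these molecules, so the orbital-based global
descriptors are meaningful:

```python
>>> print(p.global_table(triads).to_string(index=False))
      Molecule   chi    eta  omega      S      N  omega-  omega+  dOmega+-    class
Pashinintide A 3.261 4.5628 1.1653 0.2192 3.2501  4.2463  0.9853    5.2316 moderate
Pashinintide B 3.440 4.4379 1.3332 0.2253 3.1336  4.6638  1.2238    5.8876 moderate
```

Both peptides are moderate electrophiles (0.8 ≤ ω ≤ 1.5 eV) of very
similar overall reactivity. Site rankings from the published condensed
columns identify where they react:

```python
>>> ref = p.reference_site_table("Pashinintide B")
>>> p.rank_sites(ref, "electrophilic", top_n=4)
[('O', 1), ('C', 24), ('O', 5), ('C', 37)]
```

and the drug-likeness rules flag exactly the liabilities expected of a
cyclic peptide — size and polarity, nothing else:

```python
>>> p.lipinski_violations(props[0])
['MW>500']
>>> p.radar_verdict(props[0])["offending"]
['size', 'polarity']
```

## Command line

```sh
cpt simulate --n 10 --seed 42 --out cohort.json --manifest truth.json
cpt kid      --input cohort.json --out kid.csv
cpt global   --input cohort.json --tce-homo -8.7925 --out global.csv
cpt local    --input cohort.json --out local.csv
cpt physchem --formula C28H35N7O6
cpt druglike --properties props.csv --out verdicts.csv
cpt run      --input cohort.json --out-dir reports/
```

Input is the triad JSON schema (see `peptidology.records`); a
long-format CSV dialect is also supported.

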