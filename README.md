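# torlam

Torsional-group-partitioned **local approximate models (LAMs)** of a
flexible molecule's intramolecular energy, dependent conformational
degrees of freedom and atomic point charges.

## The problem

Crystal structure prediction (CSP) global searches perform on the order of
10⁵–10⁶ lattice-energy minimizations. The intramolecular part of the
lattice energy — the strain ΔU^intra a conformation pays relative to the
isolated-molecule (*in vacuo*) minimum — must therefore be evaluated from a
cheap surrogate rather than from quantum chemistry at every step. The
standard surrogate is a database of LAMs: at reference values of the
flexible torsions θ, a constrained isolated-molecule minimization is
performed over all remaining geometry (the *dependent* degrees of freedom
β: bond lengths, bond angles, non-flexible torsions), and the energy,
geometry and charges are Taylor-expanded around the nearest reference:

    ΔU^intra(θ) ≈ (U_ref − U^vac) + bᵀd + ½ dᵀH d,      d = θ − θ_ref (wrapped)
    β(θ)        ≈ β_ref + K d,       q(θ) ≈ q_ref + A d

Second order in energy, first order in β and q. The catch: a uniform grid
over *l* torsions needs ∏ᵢ Nᵢ reference minimizations — exponential in *l*
and hopeless beyond six or seven flexible torsions.

**Torsional-group partitioning** fixes this for molecules whose torsions
are geometrically separated (e.g. *para*/*meta* substituents on an
aromatic ring). The torsions are split into N_G disjoint groups θ_g assumed
to contribute *additively* to the deviations from the in vacuo values:

    ΔU^intra(θ) = Σ_g ΔU_g(θ_g),    β(θ) = β^vac + Σ_g Δβ_g(θ_g),   …

Each group keeps its own reference set, fitted with all other groups held
at their in vacuo torsions, so the database costs Σ_g N_g,ref + 1
minimizations instead of ∏ N_ref + 1 — e.g. 43 instead of 217 for a
three-torsion molecule on six-point grids (an ~80 % reduction), and a
tractable 8 796 instead of millions for an eight-torsion molecule with
adaptively refined groups.

This package implements the full machinery — reference-grid dialects,
per-group LAM fitting, nearest-reference lookup with periodic wrapping,
the additivity evaluation rule, in vacuo rebasing, adaptive refinement
with the Δ\* = 5 / Δ\*\* = 20 kJ mol⁻¹ thresholds, oracle-call accounting,
and an accuracy-assessment protocol — exercisable against a built-in
closed-form synthetic conformational model that stands in for the QM
oracle (any object implementing the oracle contract can replace it).

## Worked example

```sh
torlam fixture paraben-like --out mp.yaml   # 3 torsions, groups {1} and {2,3}
torlam count mp.yaml
```

```
per-group reference counts: [6, 36]
partitioned scheme total:   43
full scheme total:          217
reduction:                  80.2%
```

Six reference points per torsion (60° spacing, first point at 30°): the
partitioned database needs 6 + 6×6 + 1 = 43 oracle minimizations, the
non-partitioned one 6³ + 1 = 217.

```sh
torlam build mp.yaml --out mp.h5 --seed 1
torlam evaluate --db mp.h5 --theta 104,235,310
```

```json
{
  "theta_deg": [104.0, 235.0, 310.0],
  "delta_U_kj_mol": 63.59,
  "per_group": [
    {"group_id": 0, "theta_ref_deg": [90.0],         "delta_U_kj_mol": 12.83},
    {"group_id": 1, "theta_ref_deg": [210.0, 330.0], "delta_U_kj_mol": 50.75}
  ]
}
```

Group 1's torsion (104°) expands around its nearest reference at 90°,
group 2's pair (235°, 310°) around (210°, 330°); the energy rise is the
sum of the two group contributions. `torlam assess` then runs the
accuracy protocol — uniform sampling, discarding conformations whose
oracle energy rise exceeds the 20 kJ mol⁻¹ crystallographic-relevance
cutoff, and LAM-vs-oracle error statistics on the rest:

```sh
torlam assess mp.yaml --db mp.h5 -n 500 --seed 1 --out report.json
```

```
n_sampled                 500
n_retained                38
aad_energy_kj_mol         2.254
aad_bond_length_angstrom  0.00016
aad_bond_angle_deg        0.042
aad_charge_e              0.00029
max_abs_energy_error_kj_mol  8.12
```

The same operations are available as a library (`torlam.evaluate`,
`torlam.build_partitioned_database`, `torlam.adaptive_refine`,
`torlam.assess`, …); see `docs/methods.md` for the model and the numerical
conventions.

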