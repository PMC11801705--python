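# Methods

## Model and procedure

The conformational state of a flexible molecule is split into *l*
independent flexible torsions θ (degrees, canonical domain [0, 360)) and
*M* dependent degrees of freedom β (bond lengths in Å, bond angles and
non-flexible torsions in degrees) that relax to their optimal values at
fixed θ. A conformational *oracle* answers constrained-minimization
queries: given θ, it returns the reduced (β-relaxed) energy U(θ) in
kJ mol⁻¹, the relaxed β, the atomic point charges q (e), and the
derivative blocks of all three with respect to θ. In production this
oracle is an isolated-molecule QM minimization; here it is any object
implementing the `ConformationalModel` contract. Derivatives are those of
the *reduced* energy, i.e. implicit-function corrections from the relaxed
β are the oracle's responsibility. Oracles lacking derivatives can be
wrapped in `FiniteDifferenceModel` (wrap-aware central differences,
default step 1°, small against the 60–120° grid spacings in use).

A **local approximate model (LAM)** at reference point θ_ref stores the
oracle solution there and evaluates, with d = θ − θ_ref wrapped into
(−180°, 180°]:

* energy rise: ΔU = (U_ref − U^vac) + bᵀd + ½ dᵀH d (second order),
* geometry: Δβ = (β_ref − β^vac) + K d (first order),
* charges: Δq = (q_ref − q^vac) + A d (first order),

all relative to the in vacuo record (θ^vac, β^vac, q^vac, U^vac), the
unconstrained minimum located by seeded multi-start BFGS over θ.

With **torsional-group partitioning**, the torsions are split into N_G
disjoint groups assumed additive: group g's references are fitted with
every other group pinned at its in vacuo torsions, and a query θ is
evaluated by expanding each group around its nearest reference (wrapped
Euclidean metric, ties to the lowest record index) and summing the
per-group deviations onto the in vacuo values. A single group containing
all torsions degenerates exactly to the non-partitioned scheme. Building
a partitioned database costs Σ_g N_g,ref + 1 oracle minimizations (one
per reference plus the in vacuo point), versus ∏ N + 1 without
partitioning; the `CallLedger` accounts every minimization by purpose.
The ledger counts one entry per *minimization problem* solved, matching
how database-generation cost is conventionally reported; the inner
iterations of the multi-start in vacuo search are not separate entries.

If an evaluation or oracle call finds a conformation below the current
U^vac, the database is flagged and `rebase_vacuo` re-minimizes from that
point, replaces the in vacuo record and refits every reference (Σ N + 1
further minimizations). Evaluation itself stays pure; the rebase is an
explicit, logged operation.

## Grids and adaptive refinement

Two uniform-grid dialects are supported per torsion: *bounded*
`[lower, increment, upper]` with inclusive endpoints, and *wraparound*
(increment dividing 360, plus an offset). A bounded grid covering
[offset, 360 − increment + offset] generates the same point set as the
wraparound grid with the same increment. Group grids are Cartesian
products in lexicographic order.

Adaptive refinement of a group draws candidates from a seeded scrambled
Sobol' sequence over the group's domain (the grid's bounded box, or the
full circle), with other groups at vacuo. Candidates whose oracle energy
rise exceeds the crystallographic-relevance cutoff Δ\*\* (default
20 kJ mol⁻¹) are skipped; where the surrogate misses the oracle by more
than the tolerance Δ\* (default 5 kJ mol⁻¹), the already-computed oracle
solution is adopted as a new reference, so probing and fitting share one
minimization. Convergence is a full sweep (default 64 candidates) that
adds no reference; exhausting the candidate budget first flags the group
non-converged rather than raising. Δ\* is interpreted as a
surrogate-error tolerance and Δ\*\* as the relevance cutoff; refinement
never removes points, and the dense-scan validation error inside the
relevant region is checked externally via `validation_max_error`.

## The synthetic conformational model

The built-in oracle emulates the structure the method assumes, with
closed-form constrained minima:

* **Torsional energy**: per-torsion cosine series A(1 + cos(mθ − φ))
  (amplitudes drawn from 4–12 kJ mol⁻¹ by default, matching typical
  rotational barriers; multiplicities 1–3) and/or quadratic bowls; plus
  pairwise couplings a·cos(θᵢ − θⱼ + φ). Couplings within a group model
  sterically interacting neighbours; couplings across groups are scaled
  by a dimensionless ε, so ε = 0 makes the surface exactly additive over
  groups — the regime the partitioning assumes. Benchmark fixtures use
  ε = 0.05 with cross-amplitudes of 0.5–2 kJ mol⁻¹, i.e. weak residual
  coupling across a *para*-separated ring.
* **Dependent DoFs**: harmonically bound to torsion-dependent sinusoidal
  equilibria (lengths ~1.3–1.6 Å ± 5 mÅ, angles ~105–125° ± 1.5°,
  non-flexible torsions ± 6°). At the constrained minimum the harmonic
  strain vanishes, so the reduced energy, its derivatives, β and the
  Jacobians are all analytic; the stiffness constants fix how sharply
  geometry would relax but do not enter the reduced surface.
* **Charges**: net-neutral base values ± 0.5 e with sinusoidal
  modulations of ±0.01 e whose per-torsion columns sum to zero (shared
  phase per torsion), conserving total charge exactly — as ESP-fitted
  charge sets do. Charge provenance (ESP fitting) is not modelled.
* The `quadratic=True` variant uses single quadratic bowls in the
  canonical angle coordinate and *affine* β/q maps, for which the LAM
  orders are exact: it provides the closed-form regime where partitioned
  evaluation must reproduce the oracle to machine precision.

What the synthetic model does **not** emulate: Cartesian geometry,
element types, real QM energetics, charge anisotropy, and the specific
anharmonicities of real torsional profiles. Passing tests therefore
demonstrate the correctness of the LAM/partitioning machinery and its
error structure (exact where the theory says exact, degrading
monotonically with coupling), not the accuracy of any particular real
molecule's surrogate.

## Numerical conventions

* Angles are degrees everywhere; derivative blocks are per degree;
  internal trigonometry converts as needed. Energies are absolute in the
  synthetic model; all reported quantities are differences against U^vac.
* Taylor deviations and the nearest-reference metric use per-dimension
  wrapping into (−180°, 180°]; ties break to the lowest record index.
* Each evaluation uses the single nearest reference (no smoothing or
  weighted averaging across references).
* The quadratic-bowl term is quadratic in the canonical angle coordinate,
  with its discontinuity at the 0/360 seam; full-circle reference grids
  keep every query on the same side of the seam as its nearest reference,
  which is what makes the exactness tests exact.
* In vacuo search: 16 Sobol'-seeded BFGS starts by default; a result is
  accepted on optimizer success or a gradient norm below 10⁻⁵. Rebase
  candidates must undercut U^vac by more than 10⁻⁹ kJ mol⁻¹ to take
  effect; duplicate references are rejected within a 10⁻⁶ ° wrap
  tolerance.
* Accuracy protocol: n uniform samples over [0, 360)^l (default 2000),
  relevance cutoff 20 kJ mol⁻¹, average absolute deviations per property
  category (dependent-torsion errors wrapped), maximum energy error, and
  parity R² (squared Pearson correlation of surrogate vs oracle energy
  rises; exact agreement scores 1 even for degenerate scatters). The
  "torsion" error category covers the dependent (non-flexible) torsions —
  the independent ones are inputs, fixed per sample.
* Problem sizes in the test suite and acceptance script (6-point circular
  grids, 100–200-sample error statistics, 1°-step validation scans on
  one-torsion groups, candidate budgets of a few hundred) were chosen so
  every check runs in seconds against the closed-form oracle while still
  exercising each code path at the sizes the worked benchmark layouts
  prescribe.

## Serialization and interfaces

Databases round-trip losslessly through a single HDF5 file (float64
arrays, JSON-encoded provenance: grid specs, adaptive history, seeds,
ledger). Loading checks the format version and, optionally, an expected
molecule specification, and flags stale (pre-rebase) databases. Batch
evaluation reads plain TSV (header = torsion names, one conformation per
row); reports export as JSON/TSV and the parity scatter as CSV. Every
CLI command that writes output also writes a JSON run manifest (command,
inputs, seeds, package version, timestamp).

## Known limitations

* The additivity assumption is structural: for surfaces with genuine
  cross-group coupling the surrogate error grows with the coupling
  strength, and no amount of per-group refinement removes it. The
  accuracy harness makes this visible rather than hiding it.
* Single-nearest-reference evaluation is piecewise-defined and therefore
  discontinuous at reference-cell boundaries; smoothed multi-reference
  variants are out of scope.
* The adaptive algorithm is a quasi-random accept/reject scheme run per
  group; it guarantees the tolerance only where candidates have probed,
  so very narrow error spikes can in principle be missed at small
  budgets.
* Lattice (intermolecular) energy, crystal-structure search and
  refinement, and real QM backends are out of scope.
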