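# Methods

## The model

stemfold predicts RNA secondary structure — including pseudoknots — by
selecting a subset of candidate stems that minimizes a binary quadratic
model (BQM/QUBO). The approach deliberately trades thermodynamic detail
for a form that maps directly onto quadratic optimizers (including
quantum annealers): the objective jointly maximizes the number of
consecutive base pairs and the average stem length, with a tunable
discount for crossing (pseudoknotted) stems and a hard exclusion of
stems that would make a base pair twice.

### Candidate stems

A stem is a run of `k` consecutive base pairs `(i+t, j−t)`, `t = 0..k−1`,
drawn from the allowed set {A-U, G-C, G-U}. The candidate set for a
sequence is *exhaustive*: every sub-stem of a longer helix is its own
candidate, because the optimizer must be free to shorten a helix to
resolve conflicts. Enumeration scans the pair matrix along
anti-diagonals in O(n² · max run length). Two constraints filter
candidates:

- `min_stem` (default 3): helices shorter than three pairs are not
  considered stable.
- `min_loop` (default 3): the innermost pair must enclose at least
  `j − i + 1 − 2k ≥ min_loop` unpaired bases, the tightest turn the
  backbone permits. A preset with `min_stem = 4` reproduces the
  small/exact-enumeration regime; `min_stem = 3, min_loop = 2` the
  large-set regime. `min_loop` for the small regime is not pinned by any
  external source, so it is an explicit parameter everywhere.

Candidates are ordered by `(i, j, k)` ascending; this fixes the binary
variable indexing and makes every downstream result reproducible.

### The Hamiltonian

Each candidate stem gets one binary variable `q_i` (1 = selected). With
`k_i` the stem lengths and `μ = max_i k_i`:

    H = Σ_i [ c_L (k_i − μ)² − c_B k_i² ] q_i
        − 2 c_B Σ_{a<b} k_a k_b δ_ab q_a q_b
        + P Σ_{a<b : overlap} q_a q_b

- The `c_B` terms are the expansion of `−c_B (Σ_selected k_i)²` using
  `q_i² = q_i`; the explicit factor 2 on the off-diagonal is what makes
  two selected length-3 stems score `(3+3)² = 36` and one length-6 stem
  `6² = 36`. Default `c_B = 1.0`.
- The `c_L` term penalizes stems shorter than the longest candidate,
  expressing the cost of interrupting π-stacking; default `c_L = 10.0`.
  `μ` is always recomputed from the candidate set.
- `δ_ab = c_P` when stems a and b cross (`i_a < i_b < j_a < j_b`) and 1
  otherwise. `c_P ∈ [0, 1]` (default 0.5) discounts but does not forbid
  pseudoknots; `c_P = 1` makes crossing invisible to the model. Values
  below 0 — which actively penalize crossing — are permitted only behind
  an explicit override flag, since the natural range is [0, 1].
- `P` is a finite stand-in for the infinite penalty on two stems sharing
  a base: `P = c_B (Σ_all k_i)² + c_L N μ² + 1`. The first term bounds
  any configuration's attractive part, the second its length part, so
  every overlap-containing configuration is strictly costlier than every
  overlap-free one while all coefficients stay finite for samplers.
  Overlap is decided on base-index sets, which also excludes base
  triplets.

Energies are reported as `H` (lower is better); user-facing output also
reports `score = −H`.

`objective_direct` recomputes the same objective from the defining sums
on an explicit stem list, bypassing the coefficient assembly; tests
verify `evaluate_energy ∘ build_bqm ≡ objective_direct` over all `2^N`
configurations of small instances.

## Solvers

- **Exact enumeration** (`solve_exact`): global minimum over all `2^N`
  configurations, refusing instances above 25 variables (the practical
  serial ceiling; the method itself scales to ~45 variables only on
  massively parallel hardware). The default depth-first search prunes
  branches already containing an overlap-penalized pair — sound because
  such branches cannot beat the always-available empty configuration —
  and is verified against a plain full scan. Ties break toward the
  lexicographically smallest bit vector (the search order makes this
  free); degenerate minima are otherwise arbitrary.
- **Simulated annealing** (`solve_sa`): single Metropolis chain, move
  set = add / remove / swap a stem (equal probability; inapplicable
  moves count as rejected steps), geometric cooling. Default schedule
  T: 10 → 1/30 over 2·10⁴ steps: the start temperature is set
  comparable to the typical move cost `c_B k² ≈ 9–16` at default
  weights, so the early phase genuinely randomizes — a colder start
  strands the chain in the first local minimum it meets.
- **Replica exchange** (`solve_remc`): the same chains at a fixed
  ladder of inverse temperatures β, spaced geometrically (the spacing
  rule is a design choice; only the range is externally fixed).
  Defaults: 64 replicas, β from 1 to 30, 10⁶ steps per replica,
  exchange attempts every 10³ steps, initial states of up to 5 random
  stems. Neighboring replicas swap *states* (not temperatures) with
  probability `min(1, exp((β_a − β_b)(E_a − E_b)))`, alternating
  even/odd pairs; state- and temperature-swapping are statistically
  equivalent but produce different traces for a fixed seed. The result
  is the best state seen by any replica. Replicas are advanced
  sequentially; because they are independent between exchange points, a
  process-parallel backend would give identical results for the same
  per-replica seeds.

On desk-scale instances (≲ 15 stems) both stochastic solvers recover
the exact minimum in ≥ 95% of seeded runs; this is the regime where the
objective's fitness can be assessed independently of sampling error.

**Exchange acceptance.** The canonical tuning target for replica
exchange is ~20% acceptance. At desk scale the default ladder cannot
show this: with energy gaps of order `c_B k² ≈ 10`, β = 1 is already
cold, every replica collapses onto the same minimum, `E_a ≈ E_b`, and
acceptance saturates near 1. The acceptance-band test therefore uses a
sparse wide ladder (6 replicas, β from 10⁻³ to 30) on a ~270-stem
random instance, where the hot end is genuinely disordered and measured
acceptance falls at 0.35–0.47 — inside the sane 5–60% band. Production
ladders should be tuned to the instance's energy scale the same way.

`sampler_adapter` defines the contract for plugging in an external
QUBO sampler (e.g. an annealer service): it takes the linear/quadratic
maps, returns bit vectors with energies, and every reported energy is
recomputed and checked before being trusted — a sampler that mis-scores
its own samples is rejected rather than silently believed.

## Scoring predictions

Predicted and reference structures are compared as base-pair sets with
exact index matching (no ±1 slip): `C` pairs in both, `M` reference
pairs missed, `I` predicted pairs not in the reference;
sensitivity `σ_SN = C/(C+M)`, specificity `σ_SP = C/(C+I)`.
When a denominator is empty: both sets empty → 1.0 (the empty
prediction of an unpaired reference is exactly right), otherwise 0.0.
Note `σ_SN` is recall of the reference pairs; the naming follows the
field's usage for structure comparison.

## Synthetic fixtures

The generators exist so every stage is testable without external data:

- `random_sequence(length, gc_fraction, seed)` — i.i.d. bases, G/C with
  the given probability.
- `planted_hairpin(stem_len, loop_len, seed)` — G/C arm, all-A loop
  (A cannot pair with G or C, so the loop is inert), reverse-complement
  arm.
- `planted_pseudoknot(len_a, len_b, seed)` — H-type layout
  `armA·sp·armB·sp·armA'·sp·armB'` with G/C arm A, A/U arm B and
  3-base spacers, whose two planted stems cross.

Planted generators rejection-sample their random draws until the
enumerated candidate set contains *only* the planted stems and their
sub-stems, making the planted structure the unique optimum — recovery
tests are then sharp (σ_SN = σ_SP = 1.0 expected exactly), not
probabilistic. This is also what the fixtures do **not** emulate: real
sequences carry competing near-optimal helices, non-canonical pairs,
and length scales where the exact solver is unavailable, so perfect
recovery on fixtures validates the machinery (enumeration, Hamiltonian,
solver, decoding, scoring), not the biological fidelity of the scoring
function.

## Numerical and degenerate-input choices

- Exact-solver tie-break: lexicographically smallest configuration.
- Metropolis acceptance guards `exp` overflow (arguments beyond ±700).
- Sequences with no candidate stems yield the unpaired structure rather
  than an error; the empty configuration always has energy 0.
- CT output is classic 6-column, 1-based; read enforces reciprocity and
  reports the offending line. Dot-bracket uses at most four layers
  `()[]{}<>` assigned by greedy coloring of the pair-crossing graph in
  `(p, q)` order (deterministic); structures needing a fifth layer are
  rejected.
- All internal coordinates are 0-based.

## Problem sizes used in the test suite

Unit and acceptance tests run on sequences of 9–100 bases (9–270
candidate stems), with exact enumeration limited to ≤ 15 variables where
a full 2^N scan is used as the oracle, and scaled-down stochastic
settings (8 replicas × 10⁴ steps; SA 10⁴ steps). These sizes exercise
every code path while keeping the whole suite under a minute.

## Known limitations

- The scoring function ignores stacking energies, loop entropies and
  hydrogen-bond counts; it can prefer configurations with more/longer
  stems than the native structure.
- Non-canonical pairs and base triplets are excluded by construction.
- The pseudoknot test uses outer stem coordinates only, even for
  sub-stems; no per-pair crossing refinement.
- The exact solver is serial; instances beyond ~25 stems must use the
  stochastic solvers, whose minima are then not certified.
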