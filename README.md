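# stemfold

RNA secondary structure prediction — pseudoknots included — by casting
stem selection as a binary quadratic model (BQM/QUBO) and minimizing it
with exact enumeration, simulated annealing, or replica-exchange Monte
Carlo.

Predicting which bases of an RNA molecule pair with which is central to
understanding its stability and function, but the search space with
pseudoknots is exponential: a sequence with *N* candidate stems admits
2^N stem combinations. stemfold is for researchers who want a folding
objective in a form that any quadratic optimizer — classical or quantum
annealer — can minimize directly, plus a reference implementation of
the classical solvers and the evaluation metrics.

## The model

Every candidate stem (a run of *k* ≥ `min_stem` consecutive A-U / G-C /
G-U pairs with an enclosed loop of ≥ `min_loop` bases, sub-stems
included) maps to one binary variable *qᵢ*. With *μ* the longest
candidate's length, the energy of a selection is

    H = Σᵢ [ c_L (kᵢ − μ)² − c_B kᵢ² ] qᵢ
        − 2 c_B Σ_{a<b} k_a k_b δ_ab q_a q_b
        + P Σ_{a<b : overlap} q_a q_b

where δ_ab = c_P ∈ [0, 1] if stems *a* and *b* cross (a pseudoknot,
i_a < i_b < j_a < j_b) and 1 otherwise, and *P* is a finite penalty
large enough that no overlapping selection can ever win. The c_B part
is exactly −c_B (Σ selected kᵢ)², rewarding many pairs; the c_L part
penalizes short stems. Defaults: c_B = 1, c_L = 10, c_P = 0.5.
Predictions are scored against references by base-pair sensitivity
σ_SN = C/(C+M) and specificity σ_SP = C/(C+I).

See `docs/methods.md` for derivations, solver details and design
choices.

## Worked example

Fold a 23-base sequence containing an H-type pseudoknot:

```sh
$ cat pk.fasta
>pk
GCCCAAAUUAAACGGGCAACUAA
$ stemfold fold pk.fasta --out-format dotbracket
INFO record pk: 4 candidate stems, search space 2^4 = 16
INFO record pk: solver=exact-prune energy=-27.0000 score=27.0000 pairs=7
>pk
GCCCAAAUUAAACGGGCAACUAA
((((...[[[...))))...]]]
```

Four candidate stems were found; exact enumeration over the 16
configurations selects two of them: a 4-pair helix `((((...))))` and a
3-pair helix `[[[...]]]` whose brackets interleave with it — a
pseudoknot, kept because its reward (discounted by c_P = 0.5) still
lowers the energy. The energy −27 decomposes as −16 − 9 (the two stems'
−c_B k² terms) − 2·4·3·0.5 (their discounted cross term); the reported
score is −H = 27. `--out-format json` additionally emits the candidate
stem table, the binary configuration `[0, 1, 0, 1]`, and the full
parameter provenance; `--out-format ct` writes a standard connectivity
table.

Score a prediction against a reference (CT or dot-bracket):

```sh
$ stemfold compare predicted.ct reference.ct
name    C   M   I   sensitivity  specificity
pk      7   0   0   1.0000       1.0000
mean                1.0000       1.0000
```

For larger instances switch solvers, e.g.
`--solver remc --replicas 64 --steps 100000 --seed 1` (replica
exchange) or `--solver sa` (annealing); identical seeds give
byte-identical output. The library API (`stemfold.enumerate_stems`,
`build_bqm`, `solve_exact`, `solve_remc`, …) exposes every step, and
`stemfold.solvers.sampler_adapter` plugs in any external QUBO sampler
while verifying the energies it reports.

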