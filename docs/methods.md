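# Methods

## Model

The hybridization free energy of a perfect-match DNA duplex is modelled as
a linear combination of stacking contributions: ΔG°(s) = Σ n_j(s)·x_j,
where n_j counts the overlapping k-windows of the first strand that fall in
motif class j and x_j is the class weight in kcal/mol. The doublet variant
(k=2) is the classical nearest-neighbour model with 10 classes; the triplet
variant (k=3) widens the context to 32 classes. Assumptions:

- **Perfect matches only.** Both strands are exact reverse complements and
  every base is paired. Mismatches, bulges, loops and dangling ends are out
  of the model's domain; `build_fit_problem` rejects any non-perfect-match
  record by id.
- **No initiation/symmetry/salt/temperature terms.** Training data spanning
  mixed temperatures and sodium concentrations is pooled; the weights
  therefore represent condition-averaged stacking contributions. This is a
  deliberate trade: it generalises across non-standard conditions at the
  cost of systematic error at any single condition, and explains why the
  fitted ranking of doublet weights can deviate from condition-controlled
  literature sets (e.g. an inflated CC/GG weight absent an initiation
  penalty).
- **Single-strand counting.** Windows are counted on the first strand only;
  the complementary strand contributes the same physical stacks, and
  counting both would simply halve every weight (strand symmetry of the
  classes is property-tested).

### Class canonicalisation

A class is the set {w, revcomp(w)}. Its label is `TOP/BOTTOM` with TOP the
lexicographically smaller member and BOTTOM the base-wise complement of TOP
(antiparallel orientation), so `GAC/CTG` = 5'-GAC-3' over 3'-CTG-5'.
Enumeration sorts by TOP, giving a stable column order; the test suite
checks the enumeration against a brute-force partition of all 4^k k-mers
and against the published label sets.

## Estimation

Weights solve min ‖F·X − R‖² via `numpy.linalg.lstsq` (SVD-based). The
contract on rank-deficient designs — random 67% training subsets need not
cover all 32 classes — is the **minimum-norm** solution: classes with no
occurrences in the training set receive weight exactly 0 and are reported
in `NNResults.uncovered`; predictions involving such classes should be
treated with caution. Rank, singular values, residual norm and train RMSE
are always reported. Standard errors use the OLS formula with the
pseudo-inverse of the normal matrix and the residual variance
σ² = RSS/(N − rank); they are NaN for uncovered classes, whose zero weight
is a convention rather than an estimate. An independent pseudo-inverse
normal-equations oracle cross-checks the solver in the tests.

A bundled reference parameter set (`duplexnn/data/reference_*.tsv`), a
published least-squares fit to a 340-duplex perfect-match compilation, is
the default ground truth of the synthetic generator and the fixture for
arithmetic examples. Its `reported_count` column is informational only:
published per-class tallies are ambiguous about the counting unit, so
`coverage_report` computes both conventions (total window occurrences and
number of duplexes containing the class) and nothing treats the bundled
counts as authoritative.

## Evaluation protocol

`repeated_evaluation` repeats, for i = 0 … iterations−1: draw a uniform
random train/test partition, fit on the training part, record Pearson r and
RMSE between estimated and experimental ΔG° on the test part. Choices:

- **Train size** = floor(0.67·N + 0.5) (half-up). This reproduces the
  published 228/340 and 132/197 designs exactly.
- **Per-iteration metrics** are computed over the whole test set; a
  per-data-point correlation is undefined.
- **Degenerate iterations**: if the test responses (or predictions) have
  zero variance, r is recorded as NaN with the RMSE kept; summaries of r
  use the finite entries.
- **Best parameter set** across iterations: highest test r, ties broken by
  lowest test RMSE, then lowest iteration index.
- **RNG**: iteration i uses `SeedSequence((master_seed, i))`, so iterations
  are independent streams and each is individually reproducible; same-seed
  reruns are bit-identical (tested), and different master seeds give
  statistically indistinguishable metric distributions (KS check in the
  suite).
- **Seven-number summaries** (min, q1, median, mean, q3, max, stddev) use
  type-7 linear-interpolation quantiles and the sample standard deviation
  (ddof = 1).

## Structure metrics

Duplex structures are dot-parenthesis strings matched across the
concatenation struct1+struct2 (nested matching; pseudoknots rejected with
the offending position). SSSI is the percentage of string positions at
which two annotations agree, normalised by the summed strand lengths —
equivalently 100·(1 − Hamming/(L1+L2)), which the tests verify against an
independent Hamming oracle. Character-level scoring automatically grants
partial credit when only one end of a base pair is placed correctly, so no
separate pair-level half-credit scheme is needed. SENS/PPV/F compare exact
(i, j) pair sets. Degenerate cases: no experimental and no predicted pairs
→ all three are 1 (vacuously perfect); empty prediction against real pairs
→ all three are 0. Indexing is 0-based internally; serialized reports are
1-based.

## Synthetic data

`generate_dataset` emulates experimental perfect-match compilations:
lengths uniform on 4–30 nt, bases uniform or per-base Bernoulli at a target
GC rate (a spread around the target, not a point mass, matching how real
compilations distribute), second strand the exact reverse complement, fully
paired structures, and ΔG° = model value under known truth weights +
N(0, σ²). Defaults: n = 340, the bundled reference triplet weights as
truth, σ = 0.5 kcal/mol (a typical optical-melting error scale), labelled
37 °C / 1 M Na⁺. What it does **not** emulate: imperfect matches, the
length/GC biases of literature compilations (real sets over-represent 8-
and 9-mers), condition-dependent energies, or model misspecification —
synthetic data are generated *by* the fitted functional form, so synthetic
r ≈ 1 says the estimator is correct, not that the linear model describes
real duplexes. Real-compilation accuracy (r ≈ 0.92 triplets vs ≈ 0.85
doublets) can only be measured against the experimental benchmark file,
which users must supply (`data/additional_file_1.csv`).

## Numerical choices and degenerate inputs

- lstsq `rcond=None` (machine-precision cutoff); exact interpolation is
  asserted at 1e-9 on noise-free data.
- Temperature filters match within ±0.01 °C; sodium filters are exact.
- Missing numeric fields parse to None (never 0); ΔG° and temperature are
  required per record.
- Sequence lengths outside 4–30 nt warn but do not error, since the model
  itself has no length limit.
- The recovery calibration bound (mean |error| < 0.2 kcal/mol at σ = 0.5,
  n = 500) was fixed by a pilot run during development and then frozen.

## Problem sizes

The shipped test suite and the acceptance script use synthetic sets of
100–1000 duplexes and 20–1000 split iterations — sizes chosen so the whole
pipeline (generation, 32-parameter fits, repeated splits) exercises every
code path while a full run stays in the tens of seconds. The protocol
itself is routinely run at 10,000 iterations via
`duplexnn evaluate --iterations 10000`.

## Known limitations

- No mismatch/loop/dangling-end energetics and no explicit temperature or
  salt dependence: predictions for a specific condition inherit the
  training pool's mixture.
- Uncovered-class weights are 0 by convention; predictions for sequences
  containing such motifs are biased toward less stable values.
- The exclusion-list mechanism for curated benchmark files takes ids from
  the user; no curated id list ships with the package.
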