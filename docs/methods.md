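# Methods

## Problem and model

The task is binary classification of proteins into antioxidant (class 1)
and non-antioxidant (class 0) from sequence alone. The model operates on
composition features and deliberately ignores position, homology and
structure: it is a fast screening baseline, not a homology-transfer
annotator.

### Composition encoding

A sequence of length L over the 20 standard amino acids is encoded as a
420-vector: 20 amino-acid frequencies (count / L, summing to 1) followed
by 400 overlapping dipeptide frequencies (count of each ordered pair over
the L − 1 windows, divided by L − 1, summing to 1 for L ≥ 2). Dipeptide
names read N→C: "FP" is F immediately followed by P. Columns are ordered
alphabetically, dipeptides row-major (AA, AC, ..., YY); every feature is
accessed by name, so the order is a convention, not a contract. Sequences
with ambiguity codes (B, X, Z), translated selenocysteine/pyrrolysine
(U, O), gaps or stops cannot be encoded and are rejected at validation
with per-record reason codes. Length-1 sequences have no dipeptide
windows and are an error rather than silently zero-filled.

### Feature selection (CFS + best-first)

Features are first discretized per-column by recursive entropy
minimization with the Fayyad–Irani MDL stopping criterion: a binary cut
is accepted when its information gain exceeds
(log2(N−1) + log2(3^k − 2) − [k·E(S) − k1·E(S1) − k2·E(S2)]) / N.
A feature that accepts no cut collapses to one bin and carries zero
class information at that sample size — this acts as built-in relevance
screening. Correlations between discretized variables are symmetrical
uncertainties SU(x, y) = 2·I(x; y)/(H(x) + H(y)) ∈ [0, 1], defined as 0
when either entropy is 0.

A subset S of k features is scored by the CFS merit
k·r̄cf / sqrt(k + k(k−1)·r̄ff), with r̄cf the mean feature–class SU and
r̄ff the mean pairwise feature–feature SU. Subsets are searched
best-first: starting from the empty set, the open subset with the
highest merit is expanded by every single-feature addition; when an
expansion fails to improve the best merit seen, the search backtracks to
the next-best unexpanded subset; it stops after `max_stale = 5`
consecutive non-improving expansions (the conventional default for this
search). Determinism: ties in merit prefer the smaller subset, then the
lexicographically earlier name tuple. On small problems (≤ 12 features)
the search provably matches exhaustive enumeration in our tests; on 420
features it is a heuristic, as it is everywhere this method is used.

Two properties of the merit are worth knowing. First, a literature
ambiguity: the search is sometimes described as maximizing "accuracy";
the filter actually maximizes merit, and this implementation is
merit-driven throughout. Second, the merit is not monotone under
duplication in general — duplicating a strong feature alongside a weak
one can *raise* merit because the mean relevance grows faster than the
redundancy penalty; only the pure pair case (duplicate vs singleton)
collapses exactly. The tests assert the exact pair identity rather than
a false general inequality.

Cross-validated selection (`crossval_select`) runs best-first CFS inside
each training fold of a seeded stratified k-fold and reports per-fold
subsets, a frequency-ranked consensus (features chosen in ≥ half the
folds), and the full-data selection. How per-fold subsets should be
merged into a single list is genuinely underdetermined; exposing all
three views rather than guessing is a deliberate choice.

### Naïve Bayes classifier

Features are assumed independent given the class. Scoring uses the log
posterior-odds s(x) = log P(1)/P(0) + Σ log pᵢ(xᵢ|1)/pᵢ(xᵢ|0); the call
is antioxidant iff s(x) ≥ θ (ties positive). Estimation choices:

* **Priors** — Laplace-smoothed class frequencies (n_c + 1)/(N + 2);
  avoids log(0) for tiny classes, negligible at realistic n.
* **Densities** — per-feature Gaussians by default (sample mean,
  unbiased sample variance). Composition features are zero-heavy, so
  variances are floored at max(1e-9, (0.01 × feature range)²); a feature
  constant within a class then contributes a finite, bounded log-ratio
  instead of ±∞. A discretized multinomial family (MDL bins with
  Laplace-smoothed per-class bin probabilities) is available via
  `density="multinomial"` for sensitivity analysis, because the Gaussian
  choice — standard as it is for numeric attributes — is an assumption,
  not a law.
* **No scaling** — features already live on [0, 1].
* **Threshold** — θ = 0 is the plain maximum-posterior decision and the
  default. `tune_theta` picks θ from midpoints between consecutive
  distinct scores (plus all-positive/all-negative sentinels) maximizing
  accuracy or Youden's J, ties toward the smallest θ. Every report
  records the θ it used.

### Evaluation

Sn, Sp and Acc come from exact integer confusion counts. ROC curves
sweep the threshold over distinct held-out scores (tied scores form one
step, i.e. diagonal segments); auROC is the trapezoidal area and equals
the pairwise rank statistic with half-credit for ties — the test suite
asserts this equality against a brute-force pair count.

The jackknife refits the model n times, scoring each held-out sample
once, and pools the n predictions into a single confusion matrix (the
"average" Sn/Sp of a jackknife report is interpreted as this pooled
matrix — one prediction per sample makes per-fold averaging vacuous).
Stratified k-fold shuffles within class with a seeded generator and
deals round-robin with a counter that continues across classes, so
per-class fold sizes differ by at most one and k = n reduces exactly to
the jackknife. Cross-validated reports default to a single global θ
(matching the convention of reporting one operating point per model);
per-fold θ tuning is available via `theta="tune"`.

## Synthetic study conditions

The generator draws sequences residue-by-residue from a per-class
residue distribution; dipeptide enrichment is injected as a first-order
Markov tilt (multiply the transition probability of the enriched pair,
renormalize its row), since i.i.d. residue draws cannot express
pair-specific signal. Defaults, chosen once:

* n = 200 per class, lengths uniform on 50–300 — small enough that the
  full pipeline (including leave-one-out) runs in seconds, large enough
  for stable composition estimates.
* Negative class: SwissProt-like background residue frequencies.
* Positive class: C ×4, G ×2, and dipeptides LK, AP, SV ×5.

The multipliers were calibrated at design time so that each injected
feature carries comparable class information (SU with the class roughly
0.2–0.5 at n = 400). This matters because the CFS merit prunes weak
features in the presence of a dominant one: with a naive "double
everything" design, G alone dominates (SU ≈ 0.5 vs ≈ 0.1 for the rest)
and the merit-optimal subset is the singleton {G} — correct behavior of
the selector, but a study condition under which "recovery of the
injected features" is not a meaningful probe. Equal detectability
requires a larger fold-change on a rare residue (C, 1.4% background)
than on a common one (G, 7%); a 4-fold cysteine enrichment is also the
biologically faithful choice, since thiol chemistry makes genuine
antioxidant families cysteine-rich. Enriched dipeptides use common
residues: a rare pair such as FW occurs far less than once per typical
sequence and is statistically invisible at these lengths.

What the synthetic conditions do **not** emulate: real length
distributions and length–composition coupling, phylogenetic redundancy
(real benchmarks need identity-based deduplication, here out of scope),
domain structure, and any higher-order sequence signal. Passing the
synthetic suite therefore demonstrates correctness of the machinery and
sensible behavior under known signal/no-signal conditions — not
real-data performance.

## Benchmark replication

The shipped constant `features.BENCHMARK_OPTIMAL_FEATURES` carries the
optimized composition subset reported for the 254 antioxidant / 1567
non-antioxidant benchmark, verbatim in its printed order. The source
text states 44 features but prints 43 names; the constant keeps the
printed list as-is and `len()` reports 43. The `replicate` CLI command
(and the corresponding acceptance test) encodes that protocol: encode,
jackknife with all 420 features and with the optimized subset, at both
θ = 0 and tuned θ (the original operating point's θ policy is not
documented, so both are reported), plus the independent all-positive
test. The benchmark FASTA files are journal supplementary material and
are not redistributed here; the replication layer runs when they are
placed under `data/benchmark/` and reports their absence otherwise.

## Numerical and degenerate-input choices

* Merit comparisons use an absolute epsilon of 1e-12; SU is clamped to
  [0, 1] against rounding.
* Empty feature subsets have merit 0 by convention; all-constant data
  selects the empty subset.
* Fitting requires ≥ 2 samples per class (variance undefined below).
* Confusion rates whose denominator class is absent are `None`
  (explicitly undefined), never silent NaN; ROC requires both classes.
* The jackknife requires n ≥ 3 and ≥ 2 samples per class so every
  training fold retains both classes.
* Generator sampling uses inverse-CDF draws on cumulative rows with the
  last entry pinned to 1.0, making output byte-deterministic per seed.

## Problem sizes

Default test and acceptance runs use n = 400 (biased conditions),
n = 200 (null control), 20 selection replicates, and leave-one-out
throughout — sizes chosen so the complete suite runs in well under a
minute of compute per layer while keeping composition estimates and
rank statistics stable.

## Known limitations

* Composition features discard positional and structural information by
  construction; two permuted sequences are indistinguishable.
* CFS with best-first search is a heuristic on 420 features; it carries
  no optimality guarantee beyond the small-problem regime where the
  tests verify it.
* The Gaussian density is a convenience for bounded, zero-inflated
  frequencies; the multinomial variant exists precisely to check how
  much that assumption matters on a given dataset.
* Identity-based redundancy reduction (e.g. clustering to ≤ 60%
  sequence identity, as done for the original benchmark with external
  tools) is documented but not reimplemented; users must deduplicate
  their own datasets or accept optimistic cross-validation.
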