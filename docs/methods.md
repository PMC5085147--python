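# Methods

## Model

A fixed-length DNA segment of L bp is represented by Z = L − 1 real
features.  Training sequences are split by label into a positive
(origin) and a negative (non-origin) subset; for every dinucleotide
start position j = 1..L−1 and every dinucleotide i (AA..TT in
lexicographic order), the occurrence frequency Q(2mer_i | j) is the
fraction of sequences in the subset whose pair (N_j, N_{j+1}) equals
2mer_i.  The denominator is the number of *sequences* in the subset —
each sequence contributes exactly one dinucleotide token per position,
so each column of the frequency table is a categorical distribution
over the 16 dinucleotides.  The propensity matrix is the element-wise
difference P = Q⁺ − Q⁻ (16 × 299 for L = 300); its columns sum to zero
and its entries lie in [−1, 1].  Encoding a sequence is a pure lookup:
φ_u = P(rank(N_u N_{u+1}), u).  Positions are 1-based at every public
interface.

No smoothing is applied to the frequencies by default; zero frequencies
are kept raw.  A pseudocount knob (`DPSPEncoder(pseudocount=...)`,
additive smoothing (c + α)/(n + 16α)) exists for small-sample
exploration and is off everywhere the package's own results are
computed.  The machinery is parameterised by the tuple size k (rows
4^k, columns L − k + 1); k = 2 is the canonical and the only
acceptance-tested configuration.

The decision stage is a random forest over the encoded vectors.  No
hyperparameters for it are prescribed by the method itself, so the
package fixes standard, stable defaults: 500 fully grown trees, Gini
impurity, √Z features per split, and a mandatory explicit seed (no
silent global randomness).  The continuous score of a query is the vote
fraction — the proportion of trees whose leaf vote is the positive
class, computed explicitly over the fitted trees so scores are exact
multiples of 1/n_trees.  A sample is called positive iff its score ≥
the decision threshold (default 0.5).  Whether the original method's
ROC was built from vote fractions is unrecorded; vote fractions are
adopted here.

## Metrics

Confusion bookkeeping uses the miscount convention: N⁺/N⁻ samples of
each class investigated, N⁻⁺ positives missed, N⁺⁻ negatives falsely
called positive.  Then

    Sn  = 1 − N⁻⁺/N⁺
    Sp  = 1 − N⁺⁻/N⁻
    Acc = 1 − (N⁻⁺ + N⁺⁻)/(N⁺ + N⁻)
    MCC = [1 − (N⁻⁺/N⁺ + N⁺⁻/N⁻)] / √[(1 + (N⁺⁻−N⁻⁺)/N⁺)(1 + (N⁻⁺−N⁺⁻)/N⁻)]

which is algebraically identical to the classical TP/TN/FP/FN forms
(property-tested to 1e−12 over random counts).  The source literature
for this formulation contains a prose typo that defines the symbol N⁺⁻
twice; the convention above (N⁻⁺ = missed positives, N⁺⁻ = false
positives) is the one consistent with Sn = 1 − N⁻⁺/N⁺ and is used
throughout without further comment.  MCC is undefined when TP + FP = 0
or TN + FN = 0; the package returns `None` in that case rather than
raising, and clamps the value to [−1, 1] against floating-point
overshoot at the exact bounds.  MCC is held on [−1, 1] internally; the
CLI prints Sn/Sp/Acc/MCC ×100 because the field habitually reports them
on a percent-like scale.  AUC is the trapezoidal area under the ROC
staircase with tied scores grouped into one threshold step, which makes
it equal to the Mann–Whitney concordance probability with ties counted
half (cross-checked against a brute-force pairwise oracle).

## Cross-validation and the leakage policy

Jackknife (leave-one-out) removes each sample in turn and scores it
with a forest trained on the rest; K-fold uses a stratified partition
and reduces exactly to the jackknife at K = n (same per-fold seeds by
construction).  Per-fold forest seeds are derived deterministically
from (master seed, fold index) via `numpy.random.SeedSequence`, so an
entire cross-validation is reproducible from one integer.

Because the propensity matrix is estimated from labelled data, the
protocol must say whether the held-out sample may influence it.  This
is the single most consequential under-specification in the method's
source description, so it is a mandatory, user-visible switch:

* **fold-safe** — matrix and forest both re-estimated per fold from the
  training portion only.  Methodologically clean; the default.
* **global** — one matrix from the full dataset, only the forest
  re-fitted per fold.  This treats the matrix as a fixed object of the
  benchmark, which is how the published 16 × 299 matrix is presented;
  it is the policy under which published benchmark scores are
  reproduced.

The bias of the global policy is not hypothetical.  On the packaged
*null* preset (no class difference whatsoever, 100 + 100 × 300 bp) the
fold-safe jackknife accuracy is statistically indistinguishable from
chance (≈ 0.45–0.48; the mild pessimism is the usual leave-one-out
artifact of balanced classes), while the global policy reports ≈ 0.96:
each held-out sample contributes 1/100 of its class's frequency at
every one of 299 positions of the matrix it is then encoded with, and
the forest reads that signature.  The acceptance suite asserts the
fold-safe value and records the global gap without asserting it.

## Synthetic data

The generator states a world, with the defaults frozen once:

* Negatives are i.i.d. uniform over ACGT (background configurable as a
  base-composition vector).
* Positives are drawn from the same background; then, inside each bias
  window, the dinucleotide starting at each position is overwritten by
  the window's code with probability δ, in one left-to-right pass.
  Windows are half-open runs [start, end) of 1-based dinucleotide start
  positions; a later overwrite may partially mask an earlier one on the
  shared base.  This plants exactly the per-position propensity
  differences the encoder measures — the design goal is a sharp test
  target, not biological realism (no AT-richness of real origins, no
  species motifs, no between-position dependence beyond the overwrites).

Frozen presets: `null` (δ = 0, 100 + 100 × 300 bp, seed 11); `weak`
(δ = 0.2, seed 13) and `strong` (δ = 0.6, seed 17), both with 50-position
AA and TT windows at positions 50–99 and 150–199, chosen to mimic the
kind of localized AA/TT profile divergence seen between real origin and
non-origin segments; `paper-shaped` (405 + 406 × 300 bp, δ = 0.3,
seed 19) reproducing the canonical benchmark geometry at a moderate
effect size.  δ values: 0.6 makes the two classes cleanly separable end
to end (the ≥ 0.95 fold-safe jackknife check), 0.2 sits in the
informative middle of the ROC range, 0.3 for the paper-shaped world is
a single moderate choice between the two.  A green synthetic test
establishes that the pipeline recovers planted positional dinucleotide
bias at the stated effect sizes and stays at chance under the null — it
does not establish real-origin accuracy, which requires the original
benchmark data (see below).

## Numerical and degenerate-input choices

* Frequencies are exact multiples of 1/n by construction; column
  stochasticity is asserted at 1e−9.
* Sequences with characters outside ACGT are rejected, never skipped —
  ambiguity codes have no defined frequency contribution and silent
  skipping would corrupt per-position denominators.  Lowercase input is
  uppercased (soft-masking discarded).
* Classes sharing an identical sequence are rejected as contamination
  when a benchmark is assembled.
* Sn/Sp require at least one sample in the respective class (error
  otherwise); MCC degeneracy returns `None` (see above).
* Vote-fraction ties at the threshold resolve positive (score ≥ t).
* K-fold requires 2 ≤ K ≤ n; stratification additionally requires K not
  to exceed the minority class size (error propagated from the
  splitter).

## Known limitations

* The published jackknife scores of the original 405/406 benchmark can
  only be checked with that supplementary dataset present (under
  `data/SD1/`); without it the two reproduction checks in
  `tests/test_acceptance.py` fail by design rather than skip.  Exact
  reproduction is impossible in any case — the original report omits
  the forest hyperparameters and the fold-level propensity protocol —
  so the check uses a ±2 percentage-point band under the global policy.
* Only the unit-of-analysis classification is provided: no genome-scale
  scanning/windowing, no physicochemical PseKNC variants, no multi-label
  metrics, no ensemble fusion, no probability calibration.
* k ≠ 2 propensities are structurally supported but not validated
  beyond unit level.
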