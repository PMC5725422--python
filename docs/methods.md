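# Methods

## The model

`diliforest` implements the Decision Forest (DF): a consensus ensemble of a
small number of deep binary classification trees.  Each tree is a CART-style
Gini tree grown on **all** training compounds; heterogeneity between member
trees comes not from bagging or feature subsampling (as in Random Forests)
but from *descriptor disjointness* — after each tree is grown and pruned, the
descriptors it used are removed from the candidate pool before the next tree
is grown.  The ensemble probability for a compound is the unweighted mean of
the member trees' leaf probabilities, where a leaf probability is the raw
positive-class fraction of the training compounds reaching that leaf (no
Laplace smoothing, so consensus values are averages of small-integer
fractions).

Tree growth: at each node every remaining candidate descriptor is scanned
over all midpoints between consecutive distinct sorted values; the split
maximizing the weighted Gini impurity decrease is taken.  Growth stops when
a node holds fewer than `min_samples_split` compounds (default 10), is pure,
or no split has positive gain.  Ties between equal-gain splits go to the
smallest column index, then the smallest threshold, so a fit is fully
deterministic given its input.

Pruning ("up to `prune_levels` levels", default 2) is a bottom-up pass: any
subtree whose root lies within `prune_levels` of its deepest frontier is
collapsed to a leaf when doing so does not increase the training
misclassification count.  This removes splits that re-partition compounds
without changing any majority vote — the typical signature of a noise split.
The original DF software's exact pruning rule is not documented publicly;
this reduced-error-on-training interpretation is this package's own reading,
and `prune_levels=0` disables it.

### Multi-class with rejection

The 3-class model trains one binary DF per class (one-vs-rest).  A compound
is assigned the class whose sub-forest reports the largest probability
("winner takes all").  When two or more probabilities are *equally* the
largest the compound is reported as `unknown` rather than forced into a
class.  Because consensus probabilities are averages of small-integer
fractions, exact ties genuinely occur (~1% of null predictions in our
simulations); equality is assessed after rounding to 12 decimals
(`tie_tol` makes the band configurable).  The binary model has no rejection
output.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 5 | member trees per (sub-)forest; fewer are kept if the descriptor pool runs out first |
| `min_samples_split` | 10 | smallest node that may be split |
| `prune_levels` | 2 | frontier depth eligible for collapse |
| decision threshold | 0.5 | binary rule: positive iff p ≥ 0.5 (boundary inclusive) |
| `unique_fraction` | 0.632 | strategy-A bootstrap stop rule |
| `k`, `iterations` | 5, 1000 | cross-validation geometry and repeats (2000 conventional for strategy B) |

## Validation protocol

* **Repeated k-fold cross-validation** — per iteration the dataset is
  randomly partitioned into k folds (plain uniform partition; `--stratified`
  is available but off by default), each fold held out once, and the pooled
  held-out predictions scored once.  Iterations are repeated with
  independent seeds.
* **Bootstrap strategy A** — draw with replacement until
  `ceil(unique_fraction · n)` *unique* compounds are in the boot.  The
  out-of-boot test set therefore has a constant size, while the boot size
  varies; its mean follows the coupon-collector expectation
  `n · (H_n − H_{n−u})`, ≈ 452 draws for n = 451 and ≈ 722 for n = 721 at
  the 63.2% stop rule.
* **Bootstrap strategy B** — the classical bootstrap: exactly n draws with
  replacement; the never-drawn fraction fluctuates around 1/e ≈ 36.8%.
  Training honors multiplicity: a compound drawn twice carries double
  weight in every Gini count.
* **Permutation tests (y-scrambling)** — per iteration the labels are
  uniformly shuffled (multiset conserved, descriptors untouched) and one
  k-fold cross-validation is run on the permuted table, estimating the
  chance-correlation baseline of the whole pipeline.

Per-iteration randomness derives from the master seed through
`numpy.random.SeedSequence(master_seed, spawn_key=(iteration, attempt))`,
so runs are bit-reproducible and any iteration can be replayed alone.
Degenerate resamples (a training fold or boot missing a class, an empty
test set, or a fit in which no descriptor can split) are re-drawn with the
`attempt` counter incremented and the re-draw count logged; the aggregate
count is reported on the result object.

Metrics with zero denominators (e.g. sensitivity when a permuted test fold
has no positives) are reported as explicit `None` and excluded from
summaries with a count — never coerced to 0.  Summaries report the mean,
the sample SD (ddof = 1) and a fixed-grid histogram per metric.

## Confidence and descriptor importance

Prediction confidence is `|p − 0.5| / 0.5` with p the (maximum) class
probability: 0 at maximal uncertainty, 1 at the extremes, symmetric under
p ↦ 1−p.  Pooled validation predictions are binned into ten even bins
([0, 0.1), …, [0.9, 1.0]) and re-scored per bin; on informative data the
high-confidence bins score better, which is the behaviour that justifies
reporting confidence alongside a call.

Descriptor importance is usage frequency: across every forest fitted during
a validation run, a descriptor is counted once per model whose trees use it
(one fitted forest = one model; each one-vs-rest sub-forest counts
separately in 3-class mode, giving k models per cross-validation iteration
in binary mode and 3k in ternary mode).  Descriptors the split search keeps
choosing under resampling are the informative ones; ranking is by
descending count with lexicographic tie-breaks.

## Synthetic data

Real descriptor matrices for the DILIrank compounds come from a closed
descriptor generator and are not redistributable, so the test bed is
synthetic.  Informative columns are Gaussian with a per-class mean shift of
`effect_size` standard deviations (class j has mean `j · effect_size`);
noise columns are label-independent; constant columns can be planted to
exercise the preprocessing filter; a Student-t(3) option provides heavy
tails.  Column roles are recorded in the returned object and in a sidecar
JSON, so importance-recovery tests check against planted truth.

Presets fix the study composition: 268 no-DILI + 183 most-DILI (n = 451)
for the binary problem and 268/270/183 no/less/most (n = 721) for the
ternary one, with all-noise descriptors.  The presets use 100 noise
columns: null calibration is insensitive to the column count, and 100
columns keep the descriptor-disjoint forest supplied with candidates for
its full five trees.  The balanced ternary null used for the
random-recall calibration has 150 compounds per class and 60 noise
columns.

What the generator does *not* emulate: the strong inter-descriptor
correlation structure of real 2-D structural descriptors, discrete/count
descriptors, and class overlap patterns of real chemistry.  Passing the
calibration suite therefore demonstrates that the machinery is correct and
unbiased under the null — not that any particular accuracy is attainable
on real descriptor data.

## Calibration results recomputed by `scripts/acceptance.py`

All quantities are computed from scratch at run time: mean strategy-A boot
sizes at n = 451 and 721 over 1000 seeded runs; the 2-class permutation
null (mean MCC, balanced accuracy, accuracy) over 100 iterations on the
binary preset; and the balanced 3-class null per-class recall over 100
iterations.  The permutation runs use 100 iterations rather than the
full-study 1000 — the standard error of those means at 100 iterations is
an order of magnitude below the width of any band of interest.

## Numerical choices and edge cases

* Split gains below 1e-12 are treated as zero (guards float noise).
* Routing convention: value ≤ threshold goes left; a sample exactly at a
  threshold follows the boundary-inclusive left branch.
* Ingestion rejects any non-numeric or missing cell with coordinates
  (descriptor exports are dense; imputation would mask upstream errors).
* Constant-descriptor removal is computed on the full dataset before any
  split, matching standard practice for this protocol; deriving the filter
  inside each training fold is possible by preprocessing per-subset but is
  not the default.
* If the descriptor pool runs out before `n_trees` trees, the forest keeps
  the trees it has (warning logged); if the *first* tree cannot split at
  all, fitting raises, and the resampling engines treat that as a
  degenerate resample to re-draw.

## Known limitations

* The pruning interpretation is one of several consistent with "pruned up
  to 2 levels"; cost-complexity pruning would give different trees.
* Exact-tie rejection depends on the 12-decimal rounding band; platforms
  with different floating-point summation could in principle flip a
  borderline tie (not observed under numpy's pairwise summation).
* The frequency-counting denominator ("one model" = one fitted forest) is
  configurable in spirit but fixed in code; alternative conventions
  (counting re-fits, counting trees) rescale counts without changing ranks.
* 2-class problems have no applicability-domain guard: every compound gets
  a call, however far from the training distribution.
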