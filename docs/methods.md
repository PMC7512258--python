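# Methods

## The statistic and its conventions

SampEn(m, r) is the negative log of the conditional probability that two
sequences similar for `m` points remain similar at the next point, with
self-matches excluded.  Several details are fixed here once, for all
backends:

* **Template count.**  Both the length-`m` and the length-`m+1` counts run
  over template starts `i = 1 … N−m` (not `N−m+1`), so the one-element
  extension always exists.  This is the convention of standard SampEn
  implementations.
* **Inequality.**  Similarity is non-strict (`≤ r`) in every coordinate and
  every backend.  Mixing strict and non-strict comparisons across backends
  would break exact agreement on boundary pairs.
* **Pair counting.**  Each unordered pair is counted once.  The reported
  probabilities `a_norm = A/(N−m)²` and `b_norm = B/(N−m)²` follow the
  pair-count normalisation; since SampEn is `ln(B/A)`, any constant
  normalisation cancels and the entropy is computed directly from the
  integer counts — hence bit-identical values whenever counts agree.
* **Degenerate inputs.**  `A = 0` yields an infinite entropy with flag
  `a_zero`; `B = 0` (which implies `A = 0`) yields flag `a_zero,b_zero`.
  Degenerate entropy is reported, never raised.
* **Tolerance.**  The library requires an explicit mode: `absolute`, or
  `sd_fraction` (scaled by the sample SD with the `N−1` denominator).  The
  CLI defaults to `sd_fraction`, the HRV convention behind "r = 0.2".
  A constant series has zero SD, so `sd_fraction` is rejected for it.

## Backends

**Brute force** enumerates all pairs `i < j`, comparing coordinates
`k = 0 … m−1` in increasing order and stopping at the first failure; a
match costs exactly one extra comparison for the `m+1` extension.  It is
the oracle all other backends are tested against.

**Incremental kd-tree.**  Templates are processed in series order; each is
range-searched against the tree of previously inserted templates, then
inserted.  Search-before-insert halves the work relative to
build-then-query and makes self-matches structurally impossible.  Nodes at
level `lv` discriminate on coordinate `lv mod m`; ties descend right (any
deterministic rule works because a range search visits both children
whenever the query interval covers the node value).  The tree is
array-backed (payload/left/right integer arrays), traversal is iterative
with an explicit stack, and there is no rebalancing: monotone inputs
degenerate the tree to a list, accepted and covered by tests.

**Bucket-assisted.**  The integrated series `X_i = x_i + … + x_{i+m−1}`
compresses each template to one number; similar templates satisfy
`|X_i − X_j| ≤ m·r`.  Templates are hashed into buckets of width
`r/rsplit` (after shifting so `min X = 1`), so partners of a template can
only sit in its own bucket or the `m·rsplit` buckets below/above; scanning
pairs one-sidedly (own bucket + lower neighbours) counts each pair once.
Bucket members are sorted once by the template's first element, so the
first-coordinate test becomes a contiguous window — binary search for
cross-bucket probes, an early-exit scan within a bucket — and only the
remaining `m−1` coordinates are verified element-wise.  Larger `rsplit`
prunes a larger fraction of neighbour buckets at slightly higher
bookkeeping cost; 5 is the default, with the sensitivity to the choice
known to be mild.  Only occupied buckets are materialised (sorted unique
bucket ids plus group offsets), so extreme `r/rsplit` combinations cannot
exhaust memory.

**Lightweight.**  The raw series is sorted once (stable).  For sorted rank
`i`, candidates are the ranks `j > i` with `ordx_j − ordx_i ≤ r` — a
contiguous block found by binary search; the lower side is omitted because
those pairs were enumerated when the smaller rank was the probe.  Rank
pairs map back to original positions, both endpoints must be valid template
starts (`≤ N−m`), and only coordinates `1 … m−1` plus the extension remain
to verify.  All `N` values are sorted and filtered at pair time; this is
the only reading that uses every element as template *content* while never
indexing past the series end during the `m+1` check.

## Exactness in floating point

The equality of counts across backends is an exact-arithmetic theorem; two
guards make it hold in IEEE doubles as well:

1. **One comparison expression.**  Brute force evaluates
   `fl(x_i − x_j) ≤ r`.  A windowed candidate test written as
   `x_j ≤ fl(x_i + r)` can disagree with that by one ULP (addition and
   subtraction round differently), which shows up precisely at saturation
   boundaries (`r = max − min`).  Every backend therefore uses the identical
   subtraction-and-compare form, including inside binary searches, and kd
   pruning relies only on the monotonicity of floating-point subtraction
   (prune the left child only when `fl(q − c) > r`, which proves failure
   for every smaller value).
2. **Guard bucket.**  The `±m·rsplit` bucket bound is proved for exact
   sums.  The integrated values are computed with one identical per-window
   summation for every template (no rolling updates), and the neighbour
   span is extended by one extra bucket below, immunising against a sum
   landing within one ULP of a bucket boundary.  The guard only adds
   candidates that fail verification; counts are unaffected.

## Instrumentation

`element_comparisons` counts every explicit scalar check
`|x_p − x_q| ≤ r`: the full short-circuiting loops in brute force and
kd-tree verification, the within-bucket early-exit scans, the per-candidate
window checks, the residual-coordinate verifications, and the `m+1`
extension checks.  Binary-search steps are not tallied — they locate a
window without evaluating the tolerance predicate per candidate, and their
`O(log n)` total is negligible.  Where a candidate's first coordinate is
already guaranteed by the sorted window (bucket cross-probes, lightweight
blocks), verification starts at the second coordinate; the counter reflects
comparisons actually executed.  The kd-tree additionally reports
`nodes_visited`.  Wall-clock timings in the benchmark harness are
informational only; comparison counts are the portable efficiency measure.

## Automatic backend selection

`select_algorithm(n, m)`: lightweight for `m = 1` at any length and for
series up to 3000 samples; bucket-assisted (rsplit 5) beyond.  This is a
deliberately simple transcription of empirical crossovers measured on RR
data; the true crossover depends on hardware, `r`, and signal variability,
so the threshold is a configurable argument and any backend can be forced
explicitly.

## Synthetic data

The generators are statistical surrogates whose contract is the first two
moments plus seedability — not physiological realism (no respiratory
modulation, circadian drift, or IPFM-style beat generation).  Presets
emulate the mean/SD profiles of the standard healthy (nsr2: 809 ± 204 ms)
and congestive-heart-failure (chf2: 681 ± 369 ms) Holter populations and
their ectopic-filtered variants (nsr2f: 807 ± 156, chf2f: 667 ± 45).  The
base process is a stationary AR(1) with lag-one correlation 0.7 — strong
short-range autocorrelation being the feature of RR series most relevant
to match counting.  Unfiltered presets multiply a small fraction of
intervals (nsr2: 1% × 1.5, chf2: 3% × 1.7) to mimic ectopic outliers; the
base mean is divided by `1 + rate·(scale − 1)` so the marginal mean
including ectopics hits the target, while the injected outliers add a few
percent of variance on top of the base SD, as real unfiltered recordings
do.  Passing tests on these surrogates demonstrates algorithmic
correctness and pruning behaviour on realistically autocorrelated,
duplicate-containing, outlier-contaminated inputs — not clinical validity
of any entropy value.

The ectopic *filter* in `signal_io` (remove values deviating from their
centered 11-point running median by more than 20% of that median) is this
package's own pragmatic rule: the practice of removing ectopics is
standard, the specific detector is not clinically validated, and on
high-variability surrogates it also trims genuine tails.

## Problem sizes in the shipped checks

The test-suite grid covers 216 series (N up to 5000, five signal shapes,
m = 1–3, both tolerance conventions, rsplit ∈ {1, 2, 5, 15}) for exact
four-way agreement; the i.i.d. Gaussian closed-form check uses
N = 100,000, where the estimate must land within ±0.05 of
`−ln erf(r/2σ) ≈ 2.185`; pruning efficacy is asserted at N = 5000
(bucket and lightweight under half of brute force's comparisons — in
practice they achieve ~7% and ~11%).  These sizes make the full suite run
in well under a minute while exercising every code path; the algorithms
themselves have no size-specific logic.

## Known limitations

* Maximum-norm similarity only; the kd-tree and bucket prunings are not
  valid for other norms.
* One `m` per run (no all-m-at-once counting).
* The kd-tree backend is consistently the slowest of the three accelerated
  backends and is retained as a comparison point and structural
  cross-check.
* `element_comparisons` excludes binary-search work by design; it is a
  pruning measure, not a total-operation count.
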