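# Methods

## Model and assumptions

The pipeline connects three data modalities over one shared gene universe:

1. **Expression** — a non-negative gene × sample intensity matrix with
   tumor/normal labels, either from a sample sheet or parsed from
   TCGA-style barcodes (fourth dash-delimited field 01–09 = tumor,
   10–19 = normal, anything else unknown).
2. **Somatic mutations** — (gene, sample) events over a tumor cohort,
   reduced to per-gene counts of *distinct* mutated samples. No
   variant-level filtering or mutation-significance modeling: a gene's
   evidence is simply how many patients carry at least one mutation in it.
3. **Drug instances** — full permutations of the universe, one per
   treatment experiment, position 1 = most up-regulated under treatment.
   Ties inside a profile are disallowed at the type level; upstream
   converters must break them deterministically.

The analysis assumes the mutation cohort and the expression cohort describe
the same disease (they need not be the same patients), and that a drug's
transcriptional response is adequately summarized by rank order — magnitudes
are deliberately discarded, which is what makes the KS statistic comparable
across platforms and instances.

## Statistics

**Standardization** uses the sample standard deviation (n−1). Zero-variance
genes cannot be standardized and are dropped with a report; this choice is
recorded in the run manifest.

**logFC** is computed on the *raw* matrix as
log2((mean_T + c)/(mean_N + c)) with pseudocount c = 1 by default. Dividing
group means of z-scores instead would be undefined whenever the denominator
mean is ≤ 0, which happens for roughly half of all genes; the raw-scale
ratio preserves the intended quantity (relative tumor/normal abundance) and
is always defined. The pseudocount only matters for genes expressed near
zero; with intensity scales around 2^8 its effect is negligible.

**Differential test**: a two-sided Welch t-test per gene on the raw
intensities. The t statistic is exactly invariant under per-gene affine
rescaling, so it gives identical p-values on raw values and on z-scores —
whether upstream normalization happened is immaterial. A log2(g + c)
variant is available through the pluggable `stat_fn` interface for strongly
heavy-tailed data; both variants are calibrated under the generator's null
(Kolmogorov distance from uniform ≈ 0.02 at 1000 genes). Moderated
(empirical-Bayes) tests are out of scope; the Welch test is the built-in
default and the interface accepts any row-wise test. Rows where both groups
have zero variance get p = 1 when the group means agree and p = 0 otherwise.
No multiple-testing correction is applied: the DE rule is the raw-threshold
pair (|logFC| ≥ 1, p ≤ 0.02), both comparisons inclusive. The logFC
threshold dominates error control — under the null the chance that a noise
gene reaches |logFC| ≥ 1 at the default noise level is vanishing, which is
why the rule's empirical FDR is near zero even without correction.

**Frequency threshold**: ⌊fraction × n_samples⌋ clamped to ≥ 1. Floor
semantics reproduce the canonical worked example (373 × 3% → 11); the clamp
keeps tiny cohorts from admitting every gene. Kernel status ignores DE
status: frequently mutated genes whose expression does not change are still
kernel genes, and conversely the signature uses *all* kernel genes' logFC
signs, DE or not.

**Signature ordering**: kernel genes sorted by decreasing logFC; ties break
lexicographically by symbol so outputs are order-independent. Genes with
logFC exactly 0 are excluded from both lists and reported — a zero-effect
gene should anchor neither tail. A one-sided signature (all kernel logFC of
one sign) is allowed with a warning but cannot be scored; scoring requires
at least one matched gene per side and fails naming the empty side.

**Enrichment score**: a = max_p (p/m − V(p)/n), b = max_p (V(p)/n − (p−1)/m),
ES = a or −b by the larger, 0 on an exact tie. The tie convention is the
symmetric choice; ties have measure zero for real rank data but occur on
small grids (e.g. m = 1, n = 2). Useful exact identities, verified
exhaustively against a term-by-term evaluation for every position subset of
every n ≤ 12:

* positions [1..m] → ES = 1 − m/n; positions [n−m+1..n] → ES = −(n−m+1)/n;
* profile reversal maps a → b − 1/n and b → a + 1/n, hence
  ES(reversed) = −ES − sign/n *whenever one maximum dominates by more than
  2/n*. Near-symmetric position sets (|a − b| ≤ 2/n; the set {1, n} is its
  own reversal) do not flip sign, so anti-symmetry checks are restricted to
  the dominated regime, with the 1/m − 1/n tolerance valid for m ≤ n/4 —
  always the case for signatures small relative to the universe.

**Therapeutic score**: TS = (1/k) Σ_j (ES_up,j − ES_down,j) over a drug's k
instances, in [−2, 2]. Negative = signature-reversing candidate, positive =
mimicking aggravator. The classic rule that zeroes an instance when ES_up
and ES_down share a sign is *off* by default (the plain mean is the
method's definition) and available via `cmap_zeroing` for comparison.
Signature genes absent from a profile's universe are dropped per instance
with a warning (m shrinks); only a fully unmatched side is an error, and
drugs with no matching instance are reported rather than silently dropped.

**Drug–drug connectivity**: a query drug's instances are collapsed by mean
position; the top_n smallest-mean genes form the query's up list and the
top_n largest its down list (default top_n = 250, ties by symbol with a
warning). The reference drug's TS against that query is reported raw and
divided by 2 onto [−1, 1] for display; the normalization is recorded in the
result. Mean-rank aggregation is the simplest deterministic reduction of a
multi-instance profile; alternatives (median, rank-product) would change
little for the hard-window synthetic data but are not implemented.

**Benchmarking**: drug names match case-insensitively after whitespace
trimming; no synonym resolution is attempted, and unmatched drugs go to an
exclusions report. Ranking is by |TS| descending (strong connections of
either sign first), ties lexicographic. precision@x = known hits / x.
Partitioning is by strict TS sign; TS = 0 drugs go to a separate bucket.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical skeleton* the method relies on:

* log-normal expression (Gaussian on log2 scale, baseline mean 8, sd 1 —
  typical microarray intensity scales) with an additive tumor-only log2
  shift ±δ on planted genes. Because the shift is additive on the log
  scale, the ratio of group arithmetic means converges to 2^δ and the
  planted logFC is recovered unbiasedly (skew factors cancel between
  groups).
* Bernoulli mutation matrices: planted frequent genes at per-sample rate
  0.5, background 0.005 over a 100-sample cohort — planted genes clear the
  3% threshold with probability 1 − ~1e-27 while a background gene crosses
  it ~1.4% of the time, so the kernel set is the planted set plus a small
  random background fringe, as in real cohorts where the 3% rule is a
  filter, not an oracle. At a 373-sample cohort (threshold 11) the
  background tail drops to ~3e-6 and recovery is exact.
* drug libraries of full-universe permutations. Reversal/mimic drugs place
  signature genes uniformly inside hard extreme windows of size ⌈s·n⌉
  (default s = 0.05), which pins their attainable ES into a narrow,
  analytically checkable band (|TS| ≈ 2 − O(s)); null drugs are uniform
  permutations with TS centered at 0.
* a benchmark marking exactly round(known_fraction · n_drugs) drugs known,
  planted drugs first — deterministic counts so saturation cases are exact.

Default study conditions (used by the test suite and the acceptance script):
1000 genes, 20 tumor vs 10 normal expression samples, δ = 2, noise sd 0.5,
25 + 25 planted DE genes, 100-sample mutation cohort, 20 planted frequent
genes, 100 drugs × 2 instances (5 reversal + 5 mimic at s = 0.05 among 90
nulls), benchmark = the 10 planted drugs. These sizes keep a full ten-seed
recovery study in seconds while leaving all the detection margins
non-trivial.

Not modeled: cell-line heterogeneity, dose/time covariates, batch effects,
library-size artifacts, correlated genes, name synonymy. Passing tests
therefore demonstrate that the *machinery* recovers planted structure under
the stated noise model — not that the thresholds are optimal for any real
cohort, where correlation structure and annotation mismatch dominate.

## Numerical and design choices

* All generators derive their RNG from `(seed, named substream)` so stages
  are reproducible in isolation; every pipeline output is written with
  fixed float formatting and the manifest checksums every file — two runs
  from one config are byte-identical (the config echo differs only in the
  output path it records).
* The enrichment-score implementation asserts its bounds (|ES| ≤ 1,
  |TS| ≤ 2) on every call; violations are logic errors, not data errors.
* Sample-type codes outside 01–19 are "unknown" and dropped (configurable
  to fail instead); malformed barcodes always fail loudly naming the
  barcode.
* Duplicate (gene, sample) mutation events collapse to one; records naming
  samples outside the declared cohort fail naming the sample.
* The gene-set overlap graph carries an optional hypergeometric tail test
  (requires an explicit universe size); it is a generic overlap test, not a
  reimplementation of any annotation service's enrichment procedure.

## Known limitations

* The Welch default assumes approximately location-shifted groups; grossly
  heteroskedastic heavy-tailed data should use the log-scale variant or a
  custom `stat_fn`.
* ES p-values (permutation nulls) are not computed; ranking is by score
  magnitude only, as in the underlying method.
* Drug-name matching is exact (case-insensitive); real benchmarks need a
  synonym layer upstream.
* The weighted (GSEA-style) running-sum statistic is intentionally not
  implemented; the statistic here is the unweighted KS form.
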