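# Methods

Statistical definitions, parameter defaults, and numerical choices for the
`estrores` package. All empirical statements below (calibration fractions,
recalls, p-value behavior) are the quantities computed by the test suite
and `scripts/acceptance.py`; none are asserted beyond what those runs
check.

## 1. Array preprocessing

Spot tables are GenePix-style TSVs with `F635 Median`, `B635 Median`,
`F532 Median`, `B532 Median`, `Flags`, `ID` and `Name` columns. A spot is
missing when its flag is ≤ 0 or either background-subtracted net intensity
is non-positive.

Normalization is intensity-dependent LOWESS on the MA scale:
`M = log2(net635/net532)`, `A = 0.5·log2(net635·net532)`; the fitted trend
`f(A)` (statsmodels `lowess`, tricube weights, 3 robustness iterations,
span = 0.3 by default) is subtracted from `M`. At least 10 non-missing
spots are required per array. The span default follows common two-color
practice (a broad smoother that removes the dye-intensity trend without
chasing local structure); the synthetic spot generator plants a linear
trend `0.15·(A − 10.5)` which this smoother removes (verified in the tests
against per-intensity-decile medians and a reduced-span refit).

The gene × sample matrix keeps a gene when it has at most `max_missing = 6`
missing values across the 10 arrays (4 control, 3 E2, 3 E2+ICI). Probes
are kept separate; no missing-value imputation is performed.

## 2. SAM (Significance Analysis of Microarrays)

Per gene, `d = r / (s + s0)`:

- two-class (E2 vs control): `r` is the mean difference and
  `s = sqrt((1/n1 + 1/n2) · SS_pooled / (n1 + n2 − 2))`;
- multiclass (K classes): `r = sqrt((Σn_k / Πn_k) · Σ n_k (x̄_k − x̄)²)`
  and `s = sqrt(Σ SS_k · (1/Σ(n_k − 1)) · Σ 1/n_k)`; for K = 2 this reduces
  exactly to the absolute two-class statistic.

Missing values are ignored per gene; a gene needs ≥ 2 finite values per
class or its statistic is NaN and its q-value NaN.

`s0` minimizes the coefficient of variation, across ~100 quantile windows
of `s`, of the median absolute deviation of `d` (scaled by 0.64); the
candidate grid is the percentiles of `s` at 0, 5, …, 100.

The null is calibrated by permuting class labels. When the number of
distinct label arrangements is within the permutation budget (e.g. 20 for
a 3+3 two-class design) every arrangement is enumerated once; otherwise
`n_perm` uniform label shuffles are drawn. This deviates from the original
balanced-permutation prescription: exhaustive enumeration subsumes it, and
uniform shuffles are the standard approximation when enumeration is
infeasible. `n_perm = 100` by default (minimum 25).

For each threshold δ on a 60-point grid from 0 to `max|d_(i) − d̄_i|`
(observed order statistics vs their permutation means): `cutup` is the
smallest observed `d_(i)` with `d_(i) − d̄_i ≥ δ`, `cutlow` the largest
with `d̄_i − d_(i) ≥ δ` (two-class only; the multiclass statistic is
one-sided). `called` counts genes beyond the cuts; `median_false` is
`π0 ×` the median across permutations of null statistics beyond the cuts,
with `π0 = min(1, #{d within the permutation IQR} / (0.5·G))`; the FDR is
`min(1, median_false / called)`. A gene's q-value is the minimum FDR over
the δ at which it is called, monotonized so q never increases with
statistic extremity. `select_significant(q)` uses a strict `q < threshold`
(threshold 0 selects nothing; a threshold of 1 keeps every gene with a
finite statistic).

Defaults `q < 0.08` for both the 3-class prefilter and the 2-class E2 vs
control test match the study design this pipeline reproduces.

## 3. Anti-estrogen rescue classification

For a 2-class candidate with class means `c` (control), `e` (E2), `i`
(E2+ICI) and `Δ = e − c`:

- direction consistency: up-candidates need `e > c` and `e > i`,
  down-candidates the reverse;
- effect size: `|Δ| ≥ log2(min_fold)`, `min_fold = 2`;
- rescue: "normalized" when `|i − c| ≤ τ·|Δ|` with `τ = 0.25`, otherwise
  "partial".

`τ` is a package choice (the source analysis describes normalization
qualitatively): 0.25 means ICI removes at least three quarters of the E2
effect before a gene is called fully normalized.

## 4. Homology mapping and overlap statistics

Mapping is a many-to-one dictionary lookup; the mapping rate is
`#mapped / #input` and distinct human ids are returned. For the overlap of
a query set `a` with a reference set `b` inside a universe of size `N`:

- `percent_overlap = k / |a|`;
- `p_hypergeometric = P(X ≥ k)`, `X ~ Hypergeom(N, |b|, |a|)`;
- `p_binomial = P(X ≥ k)`, `X ~ Binomial(|a|, |b|/N)` — the independent-
  draws approximation, reported alongside for comparison with analyses
  that used it.

Venn partitions for 2–4 labelled sets report exclusive region counts.
Fisher category enrichment is the same upper hypergeometric tail per
category, Benjamini–Hochberg adjusted across categories.

## 5. Motif scanning and enrichment

IUPAC patterns are compiled to regexes inside a lookahead
(`(?=(...))`) so overlapping matches are all found. The ERE consensus
`GGTCANNNTGACC` is its own reverse complement, so palindromic patterns are
scanned on the forward strand only and reported once per position with
strand "+"; non-palindromic patterns are scanned on both strands and both
matches are reported even at coinciding positions.

Gene regulatory regions are the gene body plus `flank` bases on each side
(default 20 kb, clipped at chromosome ends; labelled 5p/3p by strand).
Motif enrichment counts hits whose start lies in the merged regions and
compares to `X ~ Binomial(n_hits, merged_width / genome_size)` (upper
tail). It is an error to test with zero hits genome-wide.

## 6. Binding-site enrichment

A site counts for a gene when it overlaps `[start − window, end + window)`
(default `window` = 100 kb; intervals are half-open, no clipping, so the
assignment is translation-equivariant). The observed statistic for a
target gene set is the per-gene sum of nearby sites (a site near two
targets counts twice), or, with `merge_windows`, the number of distinct
sites in the union of target windows. The null redraws `|targets|` genes
uniformly without replacement from the background loci `n_rand` times
(default 1000) and

`p_empirical = (1 + #{null ≥ observed}) / (n_rand + 1)`.

The reported `expected` is the null mean; `per_gene_rate` is
`observed / |targets|` truncated (not rounded) to two decimals, matching
the convention of the bookkeeping this pipeline reproduces (210/336 →
0.62). A binomial tail is also reported with
`X ~ Binomial(n = #sites, p = expected / #sites)`, chosen so that `E[X]`
equals the randomization-null mean.

## 7. Synthetic data

The generators are pure functions of their parameters and a seed
(numpy `default_rng`); derived seeds stay below 2³¹.

What is emulated:

- three-class log-ratio matrix: null genes `N(0, σ = 0.5)`; planted genes
  shift the E2 mean by ±log2(f), f log-uniform on [2, 128]; the E2+ICI
  mean is `control + r·(E2 − control)` with r = 0.1 ("normalized") or 0.6
  ("partial");
- spot tables realizing the matrix with `A ~ U(7, 14)`, a plantable linear
  dye bias, and flagged-missing spots;
- a random genome (i.i.d. bases at a chosen GC fraction) with
  non-overlapping slot-packed gene loci, uniformly planted motif instances
  plus optional extra instances in designated flanks, all positions
  recorded;
- binding sites uniform except for an `enrich_factor`× density inside the
  windows of designated target genes;
- a many-to-one homology map at a configurable mapping rate, and cell-line
  lists that include each responsive homolog with probability
  `1 − (1 − overlap_fraction)^(1/L)` so the union hits `overlap_fraction`
  of them in expectation.

What is not emulated: microarray physics beyond the planted intensity
trend (no spatial artifacts, print-tip effects or saturation), realistic
genome composition (no repeats, isochores or real promoter structure),
biological correlation between genes, and any real homology or regulatory
annotation.

The default synthetic genome is 2 × 1 Mb, which cannot support the
full-scale 100 kb site window (it would cover most of a chromosome), so
the synthetic pipeline defaults scale down to a 10 kb window and 2 kb
flanks. File-mode runs keep the 100 kb / 20 kb defaults.

## 8. Numerical choices and limitations

- All tail probabilities come from scipy (`hypergeom.sf`, `binom.sf`);
  LOWESS from statsmodels; BH from statsmodels `multipletests`.
- NaN statistics are excluded from FDR machinery and never counted as
  null calls; permutation statistics that are NaN under a permuted
  labelling do not contribute.
- Empirical p-values use the add-one estimator and therefore cannot be
  smaller than `1/(n_rand + 1)`.
- `truncate2` truncates toward zero; it is used only where a printed
  two-decimal rate is defined that way.
- The q-values are permutation-based estimates, not guarantees: with 100
  shuffles the FDR estimate for very small q is resolution-limited, and
  π0 estimated from the permutation IQR can reach 1 on signal-rich data,
  making q conservative.
- The rescue classifier uses class means only; it does not test the
  E2-vs-E2+ICI contrast for significance.
- The binomial site-enrichment tail treats sites as independent; the
  randomization p-value is the primary statistic.
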