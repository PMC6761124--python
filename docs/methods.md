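# Methods

This note documents the statistical machinery implemented in scdrift: the
models and their assumptions, the parameters that matter, the synthetic
data the test suite runs on, and the numerical choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Cell-to-cell methylation heterogeneity

### Model

Single-cell bisulfite data give, per cell, a sparse set of CpG positions
with methylated/unmethylated read counts. Within a genomic region the data
form a cells × sites matrix of binary states with missingness (an entry is
the binarised methylated-read fraction; threshold 0.5, half rounds up —
single-cell CpG calls are near-binary, so the rule rarely matters but must
be deterministic).

For a pair of cells sharing `k` covered sites, three statistics are
computed on those sites only:

* `D` — normalised Hamming distance, the fraction of the `k` sites where
  the states disagree;
* `S` — joint Shannon entropy (bits) of the empirical distribution of the
  ordered pattern (x_cell1, x_cell2) ∈ {00, 01, 10, 11} over the `k`
  sites, with 0·log2(0) := 0;
* `w = k` — the pair's weight.

Pairs with `k < 4` (`min_shared_sites`) are discarded. The region score is
the product of the two coverage-weighted means, `H = D̄_w × S̄_w ∈ [0, 2]`.

Why a product: `D` alone is maximised by a bimodal population (two clones
with opposite patterns), while `S` alone is maximised by any unstructured
variation. Their product is high only for *disorder* — cells disagreeing
with each other in patterns that are themselves complex — which is the
signature of stochastic drift rather than substructure. `H = 0` whenever
all shared patterns are identical.

### Normalisation and contrasts

`H` is intrinsically mean-dependent (entropy vanishes at methylation 0 or
1 and peaks at intermediate levels), so raw scores are not comparable
between regions of different methylation. `normalise_heterogeneity` sorts
regions by coverage-weighted mean methylation (each cell's within-region
mean weighted by its covered-site count — equivalently the grand mean of
non-missing entries), excludes regions with mean methylation < 0.05 or
> 0.9 (where `H` is pinned near zero and the rolling trend is
uninformative), and subtracts a centred rolling median of `H` (window
1000 observations).

Age contrasts: with matched young/old region scores, `d = H_norm(old) −
H_norm(young)` is standardised by a sliding-window Z-score (window 100)
over regions ordered by the mean of the two normalised scores — a local
standardisation that asks whether a region's change is unusual *among
regions of comparable heterogeneity*, absorbing any global young/old
offset. A zero-variance window (all differences equal, including to
floating-point jitter) yields z = 0.

Coverage filters precede all of this: regions are kept only if, in both
age groups, they have ≥ 20 CpGs, ≥ 2 mean covered CpGs per cell and ≥ 100
qualifying pairs, and the two ages differ by ≤ 10 mean CpGs per cell and
≤ 200 pairs (coverage imbalance would otherwise masquerade as a
heterogeneity change). All bounds are inclusive on the passing side and
configurable (`scdrift.config`).

### Numerical choices

* Rolling statistics use centred windows whose half-width shrinks
  symmetrically at the array ends but not below a floor (50 for the
  heterogeneity trend), then truncate at the bounds; edge records are kept
  rather than discarded.
* The sliding Z-window of "100 observations" is implemented as half-width
  50 (≤ 101 observations including the centre record).
* Pairwise pattern counts are computed for all pairs at once via four
  matrix products (observed-methylated and observed-unmethylated indicator
  matrices against their transposes), which makes scoring thousands of
  35-cell regions cheap; the result is exactly the pair-enumeration value
  (cross-checked against a literal brute-force implementation in the test
  suite).

### Known limitation: plug-in entropy bias under heavy missingness

`S` is the plug-in entropy estimator, which is what the hand-worked score
values assume. Plug-in entropy is biased downward by roughly
`(m−1)/(2k ln 2)` bits for `m` occupied patterns and `k` shared sites. In
regions of ~30 CpGs, 50% random missingness leaves `k ≈ 7.5` shared sites
per pair, depressing `S̄` by ≈ 0.2 bits and hence `H` by up to ~0.13 for
highly heterogeneous regions (the effect is measured, not just predicted,
by the missing-data comparison in the test suite). Consequences: `H` is
*rank*-robust to missingness (the dose-response ordering survives), but
absolute `H` values from datasets with very different coverage should not
be compared directly — this is one reason the pipeline equalises coverage
by down-sampling before scoring, and contrasts ages only within matched,
coverage-filtered regions. A bias-corrected estimator (e.g. Miller–Madow)
would shrink the effect but change the score's defined values on small
complete matrices, so it was not adopted.

## 2. Quality control and down-sampling

RNA cells pass with ≥ 1000 detected genes, ≥ 1e5 reads mapped to nuclear
genes and < 10% mitochondrial reads; methylome cells with ≥ 1e6 paired-end
alignments and ≥ 5e5 covered CpGs. "Less than" fails, so a cell exactly at
a threshold passes.

Depth equalisation treats each counted read at a CpG as one unit and draws
exactly `n` units per cell without replacement (a multivariate
hypergeometric draw across site/state categories), then selects a fixed
number of cells per individual at random. Read-level records are not
retained after alignment, so call-count units are the finest available
down-sampling currency; without-replacement sampling leaves the expected
per-site methylated fraction unchanged. Both the unit choice and the
counts (default 1e6 units, 35 cells) are configurable.

## 3. Transcriptional variability

Expression is `count × 1e6 / mapped_total` (RPM); `mapped_total` is reads
mapped to the transcriptome and may exceed the in-matrix column sum.

Distance to the median (DM): genes with mean RPM ≥ 10 are ordered by mean;
`dm = log2(CV²) − rolling_mean(log2(CV²), window 100)`. The rolling-trend
form (rather than a parametric mean–CV² regression) makes no assumption
about the noise model; the log scale stabilises the heavy right tail of
CV². Constant genes have no defined log-CV² and are dropped with a
warning. DM is invariant to global depth rescaling because RPM is.

Cohort correlation: all within-individual pairwise Spearman correlations
over a chosen gene set (the top-N genes by DM; ties broken
lexicographically for determinism), plus the mean pairwise correlation of
random cohorts (default 10 cells, 1000 iterations, seeded). Cohorts are
read from the precomputed pairwise matrix, so the iteration count is
nearly free.

Similarity to young: the reference is the per-gene mean of log2(RPM + 1)
over young cells (+1 is the field-standard pseudocount; the log base
cancels in rank correlations). Genes expressed in < 5 cells are excluded.
Old cells are ranked by Spearman correlation with the reference; per-gene
Spearman correlation between expression and the per-cell similarity score
yields the top-200 correlated/anticorrelated gene lists.

Expression frequency: fraction of cells in a group with a non-zero count;
young−old drops > 15% are flagged.

## 4. Epigenetic clock

Single cells are pseudobulked by summing methylation calls per site. The
site panel is fixed by three sequential coverage filters: (1) sites
covered in ≥ 70% of training samples; (2) sites covered ≥ 5× in *every*
target pseudobulk; (3) training samples lacking 100% coverage of the
surviving panel are removed. Methylation fractions (training and targets
alike) are binned to the nearest multiple of 0.2 — half-way values round
up, implemented with a small epsilon because exact halves such as 0.3/0.2
are not binary-representable — so the model input carries no read-depth
information. The regression is an elastic net selected by 10-fold
cross-validation over an automatic penalty path and an l1-ratio grid
{0.1, 0.5, 0.9, 1.0}, seed-controlled; the penalised family and fold count
are the standard choice for methylation clocks and are exposed as
arguments.

Cell-composition uncertainty: each of 100 permutations drops
`round(drop_frac × n_cells)` cells (half rounds up, minimum one; 5% of 35
cells → 2), re-aggregates the remainder and predicts age; permutations
leaving any panel site below 4× coverage are discarded, so fewer than 100
predictions may be retained, and full failure raises rather than silently
returning nothing.

## 5. Integration of the two layers

Per-cell coupling: for each cell, Pearson correlation between promoter
methylation (coverage-weighted mean over promoter CpGs; cells with < 3
covered promoter CpGs contribute a missing value) and log-scale expression
across its doubly measured genes; cells with fewer than `min_genes`
(default 10) such genes are reported but unscored.

Cross-layer heterogeneity: the per-gene change in mean DM between ages is
normalised with the same sliding-window Z-score used for methylation
(window 100, ordered by the mean of the two DM values); promoters are
stratified at methylation-heterogeneity change > 0.3, and the high stratum
is contrasted against the rest with a Mann–Whitney–Wilcoxon test
(one-sided by default — the hypothesis is directional). For pooled sizes
≤ 12 the p-value comes from in-package exhaustive enumeration over all
group assignments with mid-ranks (exact even under ties); larger samples
use the tie-corrected normal approximation. How old cells are split into
"more/less similar to young" groups is not canonical; the split sizes are
config-exposed.

## 6. Synthetic data: what it does and does not emulate

`simulate_region` — template/stochastic mixture: a shared per-site binary
template drawn at the region's mean methylation; each cell×site entry
copies the template or, with probability `het_level`, resamples
independently at the same mean; entries then go missing completely at
random. This makes `het_level` map monotonically onto expected pairwise
disagreement *while the expected mean methylation is exactly `mean_meth`
for every het level* — the orthogonality the normalisation step assumes,
and the reason a beta-binomial (which entangles mean and dispersion) was
not used. Defaults (35 cells, 30 CpGs, mean 0.5) match the post-QC,
down-sampled cohort geometry the heterogeneity analysis is designed for.

`simulate_cohorts` assembles matched young/old cohorts from per-class
region specs (e.g. a repeat-element-like class gaining methylation and
losing heterogeneity with age, a polycomb-mark-like class gaining
heterogeneity), laid out on one synthetic chromosome and emitted as
standard call/BED structures. Young/old default ages are 6 and 115 weeks,
typical of young-adult vs aged mouse cohorts.

`simulate_expression` — negative-binomial counts (var = μ + φμ²) thinned
by gene-wise Bernoulli detection with probability logistic in log μ;
per-cell mapped totals are column sums plus a fixed offset representing
reads outside the gene set. Dispersion defaults of 0.1 (young-like) and
0.4 (old-like, a 4× inflation) are used in the contrast simulations.

`simulate_clock_data` — pseudo-bulk methylation fractions at `n_sites`
sites of which `n_causal` drift linearly with age (±0.01/week by default,
baselines drawn so trajectories stay inside [0, 1]); observation through
binomial sampling at fixed depth (default 20×). Acceptance-scale recovery
uses 140 training + 40 held-out samples, 500 sites, 50 causal — a
deliberately reduced stand-in for real multi-tissue training corpora,
sized so the full fit runs in seconds.

Not emulated: genomic CpG clustering and linkage between neighbouring
regions, bisulfite conversion errors, non-MCAR (coverage-correlated)
missingness, cell subpopulations, batch effects, and library-size
heterogeneity beyond the fixed mapped-read offset. Passing tests therefore
demonstrate the correctness and statistical behaviour of the machinery
under the stated models, not performance on any real dataset; in
particular MCAR is the *favourable* missingness regime, and real
coverage-biased missingness can only be harder.

All generators are pure functions of their spec: substream seeds are
derived with a process-independent hash (crc32), so the same seed gives
bit-identical output across sessions.

## 7. Degenerate inputs and tie rules (summary)

* Binarisation tie at the threshold → methylated (round half up).
* No qualifying pair in a region → `H` undefined, record skipped (not 0).
* All-missing region → mean methylation undefined, record skipped.
* Zero-variance Z-window → z = 0; spread below 1e-12 (relative) counts as
  zero.
* Top-N gene ties at the cutoff → lexicographically smaller gene id.
* Duplicate coverage-file lines for one position → counts summed.
* Constant clock site → elastic-net coefficient exactly 0.
* Rank ties in the exact rank-sum enumeration → mid-ranks.
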