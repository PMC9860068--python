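# Methods

This note documents the models and procedures implemented in `hicdyn`, the
assumptions behind them, the defaults that matter, and what the synthetic
benchmark does and does not establish.

## Scope and data model

All analyses operate on binned, symmetric, intra-chromosomal contact
matrices (`ContactMatrix`) with a uniform bins table per chromosome
(0-based, half-open coordinates). Trans contacts, read-level processing and
multi-resolution binary formats are out of scope; I/O is plain text (COO
pixels + bins TSV, bedGraph/BED/BEDPE, counts TSV), gzip-transparent.
Analyses default to one resolution per layer: 500 kb for compartments and
reproducibility, 100 kb for loop-anchor stratification, 40 kb for insulation
and TADs, 10 kb for loop calling. Autosome-style single-chromosome matrices
are the unit of computation; multi-chromosome studies pass lists and the
distance-stratified statistics pool pixels across chromosomes.

## Normalization

**ICE balancing.** Contact counts confound structure with per-bin visibility
(mappability, GC, fragment density). Iterative correction finds weights
*w* with balanced values *w_i w_j K_ij* whose unmasked marginals are equal;
weights are scaled so those marginals average 1. Convergence is declared
when the maximum relative marginal deviation is below `tol` (default 1e-5,
`max_iter` 200); non-convergence flags the result rather than raising, so
pipelines can proceed and inspect. Bins with zero coverage, or coverage more
than `mad_filter` (default 3) median absolute deviations below the median
marginal, are masked before correction. The filter presumes realistic
coverage dispersion; on data with near-uniform coverage a 3-MAD cut can bite
into genuine insulation dips (this drove the generator's bin-bias design
below).

**Observed/expected.** Each diagonal of the balanced matrix is divided by
its mean over unmasked pixels, making the per-diagonal mean exactly 1;
zero-mean diagonals stay zero. The Pearson correlation transform of the O/E
matrix (zero-variance rows masked, unit diagonal) is the input to
compartment calling.

## Contact decay and reproducibility

`contact_probability` stratifies contacts by single-bin diagonals (distance
0 excluded) and normalizes to unit mass up to `max_s` (default 100 Mb). Raw
counts are the default (a flag switches to balanced values); the choice only
rescales strata jointly, and raw counts keep the Poisson interpretation of
the per-stratum totals. `fit_decay_exponent` regresses log per-pixel mean on
log distance; because the generative decay is (d+1)^α while the regressor is
d, fits should use strata a few bins away from the diagonal. Condition
comparisons at selected distances use two-sided Welch t tests across
replicates with BH adjustment per distance — pairs of replicates give a
legitimate, if weak, t test; the p-values are reported as evidence summaries,
not gatekeepers.

The SCC follows the HiCRep recipe: both matrices are smoothed with a
(2h+1)² mean filter (h = 1 at 500 kb by default; the original
train/test selection of h is not implemented), each distance stratum
contributes its Pearson correlation with weight N_k·√(var r̃_x · var r̃_y)
(r̃ = ranks), and the SCC is the weighted mean. The smoother uses an exact
integral image so tied counts stay tied after smoothing; the rank-variance
weights are sensitive to ties, and this keeps the statistic reproducible to
float precision against a direct re-implementation. Sample maps are compared
by 1 − SCC, embedded with classical (Torgerson) MDS (double-centering +
top-k eigenvectors; requesting more dimensions than positive eigenvalues
returns fewer with a warning) and clustered with average linkage (robust for
small n).

## Compartments

PC1 is the leading eigenvector of the correlation-transformed map,
restricted to unmasked bins, scaled to unit norm × √eigenvalue. The
eigenvector sign is arbitrary, so each chromosome is oriented against a
covariate — gene density per bin by default (GC fraction works equally) —
such that the correlation is positive; A is then pc1 > 0. Per-bin switch
labels collapse consecutive repeats of the A/B sequence across time points
("B,B,A,A" → "B-to-A"); any masked time point invalidates the bin. Saddle
matrices rank bins by PC1 into deciles per chromosome (ties broken by bin
index) and average O/E over off-diagonal pixel pairs per decile pair; with
deciles ascending in PC1 the (0,0) corner is the strongest-B block.
Compartment-strength contrasts between saddles assume a stable A/B
composition: because O/E renormalizes every diagonal, a shift in the A/B bin
share moves the saddle corners even at fixed interaction preferences. The
generator therefore holds composition fixed over time (below); on real data
the same caveat applies to any saddle log-ratio.

## TADs

The insulation score slides a (window/binsize)² square across the diagonal
(window default 200 kb = 5 bins at 40 kb): for each bin with a complete
window the mean balanced contact between the upstream and downstream flanks
is taken (masked pixels ignored; at least half the window must be present),
then log2-normalized by the chromosome's geometric mean of window means, so
valid scores average zero by construction. Boundaries are local minima of
the track; because the square smears each dip over roughly 2·window, only
the deepest minimum within `delta_window` (default 120 kb) is kept.
Boundary strength is the mean of the maximal scores within `delta_window`
on each side minus the minimum; calls below `min_strength` (default 0.1)
are dropped. Boundary positions are the midpoint of the minimum bin.

Boundary-set intersections use one-to-one nearest matching within ±window
(default ±40 kb), so fractions are asymmetric (relative to each set's size)
and no boundary double-matches. TADs are the intervals between consecutive
boundaries (no hierarchy). Aggregate pileups rescale each TAD window (with
`flank_fraction` flanks) onto a common odd-sized grid by area-weighted
interpolation — a row-stochastic overlap matrix applied on both sides, which
preserves means exactly and handles missing pixels by weight renormalization.

## Point interactions (loops)

The caller is a deliberately simplified, single-resolution variant of the
donut-filter approach. For every candidate pixel more than w bins off the
diagonal, four neighborhood expecteds are computed (donut, lower-left,
horizontal, vertical; geometry parameters p = 2, w = 5 by default), each as
the neighborhood's observed/expected ratio applied to the pixel's own
distance expectation. Significance is a Poisson upper tail of the raw count
against the largest of the four expecteds converted to the raw scale through
the balancing weights. Multiplicity is handled by BH within distance bands
of 20 diagonals — a simpler, desk-scale replacement for lambda-chunking.
Pixels need q ≤ fdr (default 0.1) and observed/expected ≥ `enrichment_min`
(default 1.75) on *every* filter; significant pixels within `merge_radius`
(default 20 kb) merge into one call reporting the strongest pixel. A genuine
focal peak spans several significant pixels, while the ~q share of false
pixels BH admits are singletons, so single-pixel clusters are kept only
under stricter evidence (q ≤ fdr/10 and enrichment ≥ 2 on all filters) —
the same pruning idea as the original GPU implementation. Anchors are
reported as the full bin interval of the centroid pixel; anchor sets across
samples are unified by single-linkage clustering along the chromosome for
UpSet-style membership counts, and loops are stratified A-A/A-B/B-B by the
compartment state of the bin containing each anchor midpoint (recomputed at
100 kb by default rather than interpolated from 500 kb).

## Expression and enrichment

FPKM = count·10⁹/(exonic length · library size). PCA is by SVD of the
column-centered sample × gene matrix; Horn's parallel analysis retains the
leading components whose eigenvalues exceed the 95th percentile (default) of
same-rank eigenvalues from 100 independent column-wise permutations.

The DEG caller is intentionally minimal and explicitly not a DESeq2
replacement (externally computed DEG tables are first-class input). Counts
are normalized with median-of-ratios size factors — plain total-count
scaling is biased by composition when differential genes are asymmetric,
which inflates calls in the opposite direction. Log2 fold changes use
pseudocount 1 on group means of normalized counts. Significance is a
moderated t on log2(normalized + 1): per-gene pooled variances are shrunk
toward the gene-wide median with `prior_df` = 4 pseudo-degrees of freedom,
which restores power at 2–3 replicates per group (a plain Welch test,
available via `prior_df=0`, has essentially no power at n = 2–3 after BH).
Directions require adjusted p < 0.05 and |log2FC| > 1.

Enrichment follows the observed/expected convention: for a hit set over a
category partition of the gene universe, expected = |hits| × category share
of the background (gene-density mode), or the analogous share of a feature
union set (feature mode); reported as log2(observed/expected) with a
Yates-continuity-corrected chi-square per category (2×2 of hit membership
in/out of category, BH across categories). Zero observed yields −inf log2
(depletion beyond measurement); expected 0 with observed > 0 is flagged and
carries no ratio. Gene positions are strand-aware TSSs; the background
defaults to all annotated genes (an expressed-only background is the
caller's choice by passing a filtered universe). Ontology lookups are
replaced by generic hypergeometric gene-set enrichment with Bonferroni
correction against user-supplied sets.

## Synthetic data generator

The generator emulates a 4-time-point, 2-replicate differentiation study on
one 100-Mb chromosome (200 bins at 500 kb, 2,500 at 40 kb, 1,000 at 100 kb,
and a 20-Mb deep window at 10 kb — sizes chosen to exercise every stage in
minutes on one CPU). The expected matrix is a product of factors:

- **decay** (d+1)^α with α shallowing across time points (−1.05 → −0.95 by
  default): the plaid strengths alone cannot raise the long-range contact
  share (homotypic short-range mass grows faster than long-range mass), and
  a decay trend is how "near" contacts spreading outward actually manifests;
- **plaid**: alternating A/B segments (mean 3 Mb); pair factor s_A for A-A
  (1.6 → 1.45), s_B for B-B (1.5 → 1.8, the strengthening-B trend) and
  1/√(s_A s_B) for heterotypic pairs. A quarter of the genome (by bp) is
  dynamic: segments are selected in A/B pairs matched by size rank, sharing
  their switch times, so both switch directions carry similar bp and the
  A/B composition stays stable at every time point — otherwise composition
  drift confounds every compartment-strength contrast (see Compartments);
  20% of dynamic segments get a double switch (e.g. A-to-B-to-A);
- **TADs**: boundaries every ~1 Mb with 20% turnover (lost or gained at a
  random time point); same-domain pairs are boosted ×2. Compartment segment
  edges are additionally recorded as boundaries whenever the flanking states
  differ — the heterotypic depletion makes them genuine insulation minima,
  and leaving them out of the truth would misscore correct calls as false
  positives;
- **loops**: Gaussian peaks (σ = 0.75 bins, 8× center enrichment) inside the
  deep window; counts grow across time points (25 → 55) and maximum anchor
  distance grows with time. Half the loops are "regulatory": anchored at the
  TSS bin of a planted upregulated gene with both anchors in late-A
  chromatin. The deep window itself is auto-placed over the 20-Mb region
  with the most balanced A/B composition that also contains B-to-A
  chromatin, so the anchor-stratification and anchor↔DEG analyses have
  something to measure at any seed;
- **bin biases**: mean-one lognormal per-bin visibility factors (σ = 0.25),
  identical across samples — the feature ICE exists to remove. Without them
  coverage is so uniform that the 3-MAD filter masks the genuine coverage
  dips flanking TAD boundaries.

Counts are Poisson per replicate on the upper triangle, mirrored. Expression
counts are negative binomial (dispersion 0.05) around lognormal baselines;
genes in B-to-A (A-to-B) segments are up- (down-) shifted by 2³ from their
segment's switch time onward, plus 40 compartment-independent DEGs in stable
bins so that not every differential gene coincides with a switch. Gene
density itself is compartment-dependent (Poisson mean 4 per A bin vs 1.5
per B bin), which is what makes gene density a usable PC1 orientation
covariate. All randomness derives from a master seed through fixed-purpose
substreams (structure / genes / loops / per-sample matrices / expression),
so adding samples does not shift existing ones and regeneration is
bit-identical; the truth object serializes to JSON.

**What passing on this benchmark does not show.** The generator has no
trans contacts, no unmappable regions or copy-number variation, no
fragment-level biases (its biases are exactly the multiplicative kind ICE
models), Gaussian-shaped loops on an independent-Poisson background rather
than polymer contacts, and NB expression with gene-independent dispersion.
Recovery rates here are upper bounds on real-data performance; parameter
choices that the study itself left unreported (insulation window, boundary
strength threshold, loop-caller settings) are validated only in this
synthetic regime.

## Numerical choices and degenerate inputs

Ties in PC1 ranking break by bin index; an orientation covariate with zero
correlation falls back to making the first non-zero loading positive.
Zero-variance rows mask their bin in the correlation transform; all-zero
matrices are errors for balancing, empty matrices for decay curves, empty
TAD/loop sets for their summaries. BH is statsmodels' `fdr_bh` throughout.
Insulation windows tolerate up to half their pixels missing. The chi-square
continuity term floors at zero. Boundary/anchor windowed matching is greedy
nearest-first and one-to-one. Saddle log-ratios require strictly positive
cells and raise otherwise.

## Orchestration

`pipeline.stage_*` functions chain the stages over a run directory created
by `stage_simulate` (data, planted truth, YAML manifest + full config echo);
outputs are deterministic given config and seed, a failing stage removes its
partial output directory, and `stage_compare` runs the cross-course
SCC/PC1/insulation comparisons between two completed runs. The `hicdyn` CLI
is a thin click wrapper over these functions; library use needs no CLI.
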