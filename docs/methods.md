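# Methods

This note documents the models, the parameter choices behind them, what
the synthetic-data generator does and does not emulate, and the
numerical conventions used throughout the package.

## Coordinates and fragment storage

All coordinates are 0-based half-open, the convention of 10x
`fragments.tsv` files; Tn5 +4/−5 offsets are assumed already applied
upstream and no further shift is performed. Each fragment contributes
two insertion events, at `start` and `end − 1`, weighted by the
duplicate count, so total insertion weight is exactly twice total
fragment weight — a conservation law asserted by the tests.

The HDF5 store keeps one group per sample and one block of parallel
integer arrays (start, length, barcode id, count) per chromosome, sorted
by start. Queries and matrix construction therefore stream one
chromosome block at a time and never materialise the whole file. Barcode
lookups scan a chromosome block with a vectorised mask rather than
per-barcode row ranges; at the scales this package targets the scan is
bound by the same I/O as any range index would be. Duplicate fragments
are kept (multiplicity preserved); `dedup=True` at import collapses
identical records and sums counts.

## TSS enrichment

Insertions within ±2,000 bp of any annotated TSS are accumulated into a
strand-oriented profile per cell (minus-strand TSS are mirrored). The
score is the mean per-base insertion count in the central 101 bp over
the mean in the two outermost 100-bp flanks, with 0.1 added to both
numerator and denominator. The pseudocount on both sides makes a flat
profile score exactly 1 and keeps empty flanks finite; it also means the
score is scale-invariant only once window counts dominate 0.1 — at very
shallow depth scores compress toward 1, which is the desired behaviour
for a quality metric. The 101/100-bp window widths and the ±2,000-bp
span are package choices; they are exposed in `TSSParams`. Default
filtering keeps cells with score ≥ 4 and ≥ 1,000 fragments (inclusive).
Fraction-of-insertions-in-regions is computed on request but not used
for filtering: TSS enrichment separates quality tiers more cleanly.

## TF–IDF, LSI, and the iterative scheme

The normalisation is `log(1 + tf · idf · 10⁴)`; the scale constant 10⁴
puts typical values in a numerically comfortable range and cancels in
correlations. The SVD is Lanczos (`scipy.sparse.linalg.svds`) with a
seed-derived start vector and a deterministic sign convention (the
largest-magnitude loading of each component is positive), so fits are
bit-reproducible. Components whose cell coordinates correlate with
log₁₀ depth at |r| > 0.75 are excluded from the retained set — the first
component of near-binary accessibility data is essentially sequencing
depth.

Iterative LSI (default 2 iterations) starts from the 25,000 most
accessible tiles, clusters the preliminary embedding
(SNN graph, Jaccard weights, Leiden modularity at resolution 0.8), forms
per-cluster pseudo-bulk log₂ counts-per-million profiles, and reseeds
the next round with the features of highest across-cluster variance.
If the preliminary clustering yields fewer than two clusters the
top-accessible features are kept with a warning. Estimated LSI samples
landmarks uniformly without replacement; at 100% landmarks it reduces
exactly to the full fit, which the tests assert.

Projection of new profiles (held-out cells, synthetic doublets, summed
bulk profiles) re-applies the stored IDF and loadings; the map is linear
in the normalised space and reproduces training coordinates to machine
precision.

## Doublet scoring

Synthetic doublets are element-wise sums of uniformly sampled distinct
cell pairs, one per real cell by default, projected post hoc into the
fitted LSI subspace (the model is not refit with synthetic cells).
Scoring uses the retained LSI components directly rather than a 2-D
embedding: deterministic, and distances there are what the clustering
itself sees. For each real cell, the number of synthetic points among
its k = 10 nearest pooled neighbours is compared with the binomial
expectation; the removal count is `round(filter_ratio · n²/10⁵)`,
encoding a doublet load that grows ~1% per 1,000 cells loaded. When the
simulated doublet load is set explicitly (the generator's
`doublet_fraction`), tests set `filter_ratio` so the removed fraction
matches that load — the formula's implicit loading model does not apply
to a generator dial.

## Gene scores

The default model integrates the whole gene body extended 5 kb upstream
of the TSS (distance 0 inside), decays as `exp(−d/5000) + e^(−1)` out to
100 kb beyond either end, truncates at the nearest neighbouring extended
gene body, up-weights short genes linearly in inverse length into
[1, 5], and depth-normalises each cell to 10,000 total
(`target_depth=0` disables normalisation). Distances are evaluated at
tile centers, which makes weights tie-free. A tile inside two gene
windows contributes to both genes. The model family
(`GeneScoreModelSpec`) spans region basis (promoter window vs body),
decay shape (none / linear / exponential) and boundary handling, with
named presets; `evaluate_gene_models` scores any set of models against
matched expression with four tests: {per-gene correlation across cell
aggregates, per-aggregate correlation across genes} × {top
differentially expressed genes, top variable genes}. "Differential" is
ranked by across-aggregate spread over mean; "variable" by
across-aggregate variance.

## Peak calling

Pseudo-bulk replicates are sample-aware: samples contributing ≥ 40 cells
to a cluster each become a replicate (capped at 500 by subsampling);
clusters without two qualifying samples fall back to two subsampled
replicates of 80% of the cluster, drawn to minimise cell reuse; clusters
that cannot support two replicates are flagged and skipped. The internal
summit caller smooths the per-base insertion profile with a 75-bp moving
average and takes local maxima (leftmost position on plateaus); MACS2
summit BEDs can be supplied instead, and the internal caller exists so
no external binary is ever required. Summits extend to 501-bp fixed
width (truncated at chromosome edges), per-replicate scores are
normalised to score-per-million, and the iterative overlap merge
greedily keeps the best-scoring candidate and discards everything
sharing ≥ 1 bp with it (ties: earlier start, then chromosome name).
Within a cluster, merged peaks must be overlapped by candidates from
≥ 2 replicates; cluster sets then merge globally the same way. An
optional blacklist removes candidates before merging.

## Differential testing

Each cluster is compared against background cells matched on
(log₁₀ fragments, TSS enrichment), quantile-scaled to [0, 1], by
nearest-neighbour assignment without replacement (1:1 by default;
sampling with replacement, with a warning, when the pool is too small).
The Wilcoxon rank-sum test uses exact enumeration of the rank-sum
permutation distribution when n₁+n₂ ≤ 20 and otherwise the tie-corrected
normal approximation without continuity correction — measured against
the exact enumeration at n₁ = n₂ = 10, the plain z agrees within 10%
relative for p ≥ 0.01 whereas the continuity-corrected version does not;
below p ≈ 0.01 no normal approximation holds 10% relative accuracy at
these sample sizes. Fold changes use pseudocount 1 on depth-normalised
(10⁴) means; FDR is Benjamini–Hochberg; markers require FDR ≤ 0.01 and
log₂FC ≥ 1.

## Motif deviations and footprints

PWM scanning is log-odds against a uniform 0.25 background on both
strands with a 0.5 pseudocount on count matrices. Motif enrichment in a
peak subset is the upper-tail hypergeometric probability, BH-adjusted
across motifs; the same operation serves arbitrary region-set overlap.
chromVAR-style deviations compare observed per-cell counts in a motif's
peaks with the depth-proportional expectation; background peak sets
(50 per peak) are sampled with replacement from the nearest neighbours
in standardised (GC, log1p mean accessibility) space — a deliberate
simplification of chromVAR's Mahalanobis bins that is easier to test and
behaves equivalently on matched covariates. Computation streams over
cell chunks. Raw deviations are exactly zero for counts proportional to
depth and for a motif covering all peaks; z-scores are invariant to
global depth scaling.

The hexamer bias table tallies the reference-strand 6-mer centred on
each insertion against the genome-wide 6-mer frequency. Footprints sum
strand-oriented insertions around motif sites; the expected profile sums
the bias ratio of the 6-mer at each offset; both are rescaled by their
mean over the outermost 50 bp per side and divided. Under a uniform bias
table the adjustment is the identity; insertions driven purely by
sequence bias yield a flat profile at 1; protein protection appears as a
central dip.

## Links and trajectories

Correlations are computed over low-overlap KNN aggregates (k cells per
seed, pairwise overlap ≤ 0.8k) because single-cell accessibility is too
sparse for per-cell correlation. Profiles are log1p of counts normalised
to 10⁴ per aggregate. Peak–peak pairs are tested within 250 kb
(midpoint distance); peak–gene pairs within 250 kb of the TSS, with
correlation p-values from the t-transform and BH-FDR; default link
threshold r ≥ 0.45. Note the aggregate axis is not i.i.d. when
aggregates share cells, so p-values are calibrated (and the null test is
run) on disjoint aggregates.

Supervised trajectories interpolate the ordered cluster means to 100
arc-length-uniform path points; each cell (within its cluster's 0.9
distance quantile) takes the index of its nearest path point, rescaled
to [0, 100]. Optional spline refinement fits one smoothing spline of
coordinates against initial pseudotime and re-aligns once.
Pseudotime-binned matrices take depth-normalised log1p means per
equal-width bin, linearly interpolate empty bins (error if > 50% are
empty) and smooth with an 11-bin moving average.

## The synthetic data generator

The generator emulates the features the suite's claims depend on:
cell-type-specific accessible peaks (intergenic, gene-body "marker", and
distal "enhancer" sites tied to designated genes), shared peaks,
TSS-proximal signal producing realistic TSS-enrichment separation
between quality tiers, uniform background, nucleosome-patterned fragment
lengths (65% at 50–120 bp, 35% at 180–250 bp), per-cell fragment counts
from truncated normal tiers — low (1,000 ± 500), medium (5,000 ± 1,000)
and high (10,000 ± 2,500) fragments per cell — heterotypic doublets
formed by merging two distinct-type cells' fragments under one barcode
with a 1.25× depth factor (so depth alone is a weak but non-trivial
doublet predictor, and neighbourhood enrichment must beat it), optional
hexamer insertion preference calibrated to a target observed/background
ratio, optional protected 20-bp cores at motif sites, matched Poisson
expression whose coupling to planted accessibility is a dial (0 =
independent), and a lineage mode placing cells on a latent time with
triangular stage-activity ramps.

It does **not** emulate: real genome sequence composition (the genome is
i.i.d. uniform ACGT), realistic motif grammar beyond planted consensus
sequences, barcode errors or ambient contamination, homotypic doublets,
copy-number or batch structure beyond the sample split, or realistic
peak count and genome scale. Recovery results on generator data
therefore demonstrate algorithmic correctness and calibration, not
performance on real tissue.

Default study conditions are three cell types × 500 cells at the
high-quality tier on a 2 × 2 Mb genome with 60 genes and ~150 planted
peaks; the doublet experiments use 8% planted heterotypic doublets; unit
tests run the same architecture at 450 cells, medium depth, and a
2 × 0.5 Mb genome. These sizes were chosen once as the smallest
configurations at which every planted structure is comfortably
recoverable by design, and the acceptance script reports the problem
size (`n`) alongside every measured value.

## Determinism

Every stochastic step takes an explicit seed: the generator, the SVD
start vector, Leiden, subsampling, background sampling, landmark choice.
The pipeline writes JSON provenance (parameters, input hashes) per
stage, skips stages whose provenance matches, and invalidates exactly
the downstream stages when a parameter changes; fixed-seed reruns are
byte-identical on all TSV outputs.

## Known limitations

- BAM input, barcode error correction and read-level simulation are out
  of scope; fragment files are the entry point.
- The Wilcoxon normal approximation is unreliable below p ≈ 0.01 at
  n ≈ 20 (the exact path covers that regime).
- Aggregate-correlation p-values assume disjoint aggregates; with
  overlapping aggregates treat them as ranking scores, not calibrated
  probabilities.
- The naive summit caller is adequate for well-separated planted peaks;
  for real data import MACS2 summits.
- UMAP visualisation and cross-platform expression integration are
  intentionally not part of the model contract; all quantitative
  operations live in LSI space and expression matrices are explicit
  inputs.
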