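# Methods

`mbstage` implements the computational chain that links transcriptomic
heterogeneity in SHH-activated medulloblastoma to the stages of cerebellar
granule-neuron (GN) development, together with the proteomic and spatial
metabolomic statistics that extend that chain. This note documents the
models, the parameter choices that matter, what the synthetic-data
generators do and do not emulate, and the numerical decisions taken where
the design was open.

## Signature derivation

Marker genes for cell clusters are found by one-vs-rest two-sided Wilcoxon
rank-sum tests per gene, optionally after downsampling every cluster without
replacement to the smallest cluster size (seeded; the seed is a required,
recorded argument). P-values are Bonferroni-adjusted over genes within each
cluster; only positively enriched genes are kept (log2 fold change of means
with pseudocount 1 inside the log, > 0). The ordering is fully
deterministic: adjusted p ascending, then log2FC descending, then gene name.
Marker ranking uses the adjusted p; raw and adjusted p differ only by a
constant factor within a cluster, so the ordering is the same either way
except where the adjusted values saturate at 1 — there the log2FC tie-break
takes over.

Bulk subtype markers rank-normalize each sample to [0, 1] (average ties,
`(r − 1)/(G − 1)`), then test each subtype against all other samples with a
two-sided Welch t-test; a gene with no within-group variance gets p = 1 and
is logged rather than raised, because rank-normalized bulk data can be
degenerate on small panels without invalidating the rest of the screen.

The per-cell QC filter removes a cell when any of five rules fires: UMI or
feature count strictly below its 5th or strictly above its 95th percentile,
mitochondrial fraction above 5%, or doublet score strictly above its 90th
percentile. Percentiles are computed on the input table with linear
interpolation, so an all-tied metric removes nobody.

Mouse signatures map to human symbols through a user-supplied ortholog
table; a gene missing from the table falls back to its upper-cased symbol
when that symbol exists in the target universe, and otherwise is dropped
with the next-ranked marker promoted in its place, keeping the signature at
its requested length whenever enough markers exist.

## Signature activation scoring

The scoring engine converts a genes × samples matrix into signatures ×
samples activation scores. Per gene i, a Gaussian-kernel CDF statistic

    z_ij = Σ_k Φ((x_ij − x_ik) / h_i),   h_i = s_i / 4

(with s_i the gene's sample SD) produces a smooth, strictly increasing
rank-generating statistic; the bandwidth divisor 4 is the continuous-data
convention of this family of methods. Zero-variance genes are dropped with
a warning. Per sample, genes are ranked by z descending (average ranks for
ties; the walk sequence breaks ties by gene name so results are
deterministic), and a weighted Kolmogorov–Smirnov random walk accumulates
`d^tau` over signature genes — `d = |p/2 − r|`, tau = 1 — against a uniform
penalty over the other genes. The score is the signed sum of the largest
positive and largest negative walk deviation. Scores live in [−1, 1]; the
endpoints are attained only when a signature occupies exactly the extreme
ranks, which happens in practice only when the kernel statistic is coarsely
banded (very few samples). Monotone per-gene transformations of the input
leave the per-sample ranking, hence every score, unchanged.

Per-cell display scores are simpler: the mean over signature genes of
gene-wise z-scored expression, optionally floored at zero for display.

## Consensus co-clustering

Signatures are clustered on their score profiles across tumors: per trial,
a seeded half (by default) of the sample columns is drawn without
replacement, k-means (Euclidean, 10 restarts, best inertia) partitions the
signature rows, and co-membership is accumulated. Signatures are never
subsampled, so each consensus entry is an exact count / n_trials. Defaults
follow the study design: 1000 trials, subsample fractions {0.3, 0.5, 0.7,
0.9} with 0.5 the default, k from 2 to 10.

k selection automates the elbow on the consensus-CDF area curve. For each k
the area under the empirical CDF of the off-diagonal consensus values is
computed; the relative increase over the previous k (Δ-area) quantifies how
much additional structure that k resolves. The chosen k is the largest one
whose Δ-area still reaches 0.1. A smaller absolute cutoff proved
non-operative: above the true k, k-means must split homogeneous blocks and
does so differently in every subsample, which keeps the Δ-area tail near
0.07 no matter how many trials are run, while null data produces large
Δ-area values generically as co-clustering dilutes with k. For the same
reason a separate no-structure check is needed: when more than 30% of the
consensus entries at the chosen k are ambiguous (strictly between 0.1 and
0.9), no stable grouping exists, the result is flagged and k falls back to
the smallest value. A `force_k` override bypasses the automation, matching
the study's visually chosen k = 5.

Display ordering is average-linkage hierarchical clustering of consensus
rows under correlation distance (1 − Pearson r; constant rows get distance
1 to everything, logged); flat groups come from cutting the dendrogram at
the chosen k.

## Composite scores and the CNV screen

Composites are linear in the signature scores: proliferation = cycling GCP
− GCP, progenitor = cycling GCP + GCP, late-stage GN = migrating GN +
postmigratory GN. The arm-level screen runs, for every (chromosome arm,
score) pair, up to two two-sided Mann–Whitney U tests — loss vs the rest,
gain vs the rest — skipping a test when its group is empty and excluding
samples with missing arm status from both sides. The per-test alpha is the
family-wise level divided by the number of tests actually performed; the
family-wise default 0.01 reproduces the published per-test threshold
(0.01 / 657 = 1.52e-5). Exact enumeration is used when the combined group
size is at most 20 and the data are tie-free; otherwise the normal
approximation with tie correction.

## Protein–RNA rank differences

Within each sample, protein and RNA abundances are separately
rank-normalized onto [−0.5, 0.5] (`(r − 1)/(G − 1) − 0.5`, average ties);
the per-gene rank difference Δ = protein rank − RNA rank is averaged over
each group's samples. Genes split into four categories by synaptic and
FMRP-target membership (user-supplied gene sets; no ontology downloads).
The focal category (SYN FMRP by default) is contrasted against each other
category with a two-sided Mann–Whitney U test, and every category's Δ is
tested against zero with a one-sample t-test; a zero-variance category
reports that t-test as missing rather than zero. The alternative synaptic
vs non-synaptic two-sample t-test is available but off by default.

One calibration subtlety: permuting sample-group labels does not form a
valid null for the planted protein shift, because every relabeled group
still contains shifted samples and the category contrast retains a diluted
effect. The null that destroys the planted structure permutes the gene
categories, and that is what the calibration test does; the delta = 0
generator setting provides the sample-level null.

## Spatial metabolomics

Spots are TIC-normalized (each intensity vector divided by its own sum;
zero-total spots are an error so callers drop them deliberately). Observed
m/z peaks are assigned to reference metabolites within a 2-ppm window
(boundary included); per spot the assigned value is the maximum intensity
among candidate peaks, and references with no candidate are flagged
unmatched. The metabolite quality filter — intensity strictly above 100,000
in strictly more than 50% of spots — applies to raw, pre-TIC intensities:
the 100,000 threshold is on instrument scale and would be meaningless after
normalization to unit sums, so the filter-then-normalize order is pinned
here even though it could be read either way.

Spatial weights are k-nearest-neighbor (default k = 24, two rings on the
spot grid), self excluded, row-standardized to 1/k; distance ties — common
at lattice symmetry points — break by ascending spot position in the input
so the neighbor set is reproducible. Bivariate Moran's I is the normalized
cross-product of z-scored x with the spatial lag of z-scored y, using
population SDs (the difference from sample SDs is O(1/n)). Per-section I
is reported without a permutation p by default; a permutation null is
available on request. Group differential means summarize each section by
its spot mean, each group by its mean of section means, rank metabolites by
|log2 fold change| (1e-12 floor inside the log), and test across sections
with a two-sided Mann–Whitney; a group with fewer than 2 sections keeps its
fold change but omits the p.

Spot-grid Leiden clustering and edge-artifact removal are not implemented:
the synthetic sections are artifact-free by construction, and in the
original workflow that step was partly a manual visual call.

## Joint graphical lasso

Per-section correlation matrices (population normalization, within-section
z-scoring) feed an ADMM solver for the group graphical lasso

    Σ_k [tr(S_k Θ_k) − log det Θ_k] + λ1 Σ_k Σ_{i≠j} |Θ_k,ij|
        + λ2 Σ_{i≠j} √(Σ_k Θ_k,ij²).

The Θ-step is the closed-form spectral update (eigendecomposition of
ρ(Z_k − U_k) − S_k), which keeps every iterate symmetric positive definite;
the Z-step soft-thresholds off-diagonals at λ1/ρ and applies the groupwise
shrinkage factor max(0, 1 − (λ2/ρ)/‖·‖₂) across sections; duals update in
scaled form. ρ is fixed at 1 — adaptive scaling buys speed, not
reproducibility, and is unnecessary at p ≤ 100. Iteration stops when the
max of primal and dual residual infinity norms falls below 1e-5 (cap 1000);
non-convergence returns a flagged solution rather than raising. The edge
support is read from the Z copy, whose zeros are exact; Θ carries the SPD
precision values.

Model selection sweeps λ1 ∈ {0.05..0.25} × λ2 ∈ {0.01..0.05} and minimizes

    eBIC = Σ_k [n_k (tr(S_k Θ_k) − log det Θ_k) + E_k log n_k
                + 4 γ E_k log p],

E_k the off-diagonal upper-triangle support size. γ defaults to 20 —
far outside the usual [0, 1] range, accepted verbatim as a deliberate
sparsity-forcing device (a warning is emitted whenever γ > 1). A practical
consequence: an edge survives selection only when its likelihood gain
n·(−log(1 − ρ²_partial)) exceeds roughly 4γ·log p per section, i.e. only
partial correlations ≳ 0.6 at n ≈ 500 are identifiable; the planted-truth
generators therefore plant conditional dependencies of that strength
(disjoint-pair precision structure with partial correlation value/(value +
margin)). Per-section sample sizes are used in the eBIC; the pooled-n
variant is exported alongside for comparison. Ties break toward larger λ1
then larger λ2.

Networks are the unweighted undirected support graphs (precision magnitudes
are exported separately); betweenness centrality is normalized by
(n−1)(n−2)/2. Edge-presence classification calls an edge present in a
group when its presence fraction is ≥ 0.5 (boundary counts as present in
both → shared); centrality differences are per-node group means of
betweenness, with absent nodes counting 0.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their arguments including the seed.
Expression noise is additive Gaussian on a log-like scale — matching the
variance structure the kernel scoring statistic assumes — with
nonnegativity enforced by shifting by the global minimum, never clipping,
so planted mean differences and covariance structures survive exactly.

- `generate_cell_data`: five ordered GN stages, disjoint planted markers
  per stage (default effect 3, noise SD 0.5, 50 cells/cluster, 200 genes).
  QC metrics are drawn from fixed recorded distributions (lognormal UMI and
  feature counts, Beta(2, 38) mitochondrial fraction with mean 0.05,
  uniform doublet score); the real filters are defined by rules, not
  distributions, so these are package choices.
- `generate_cohort`: subtype proportions by largest-remainder
  apportionment, additive per-(subtype, signature) effects, per-arm
  Bernoulli loss/gain statuses (default 0.2/0.2) with additive
  (arm, status, signature) effects.
- `generate_paired_omics`: protein = RNA + independent noise, plus a
  protein-specific delta on target genes in group B only.
- `generate_sections`: spot lattices with multivariate-normal metabolite
  vectors from group-specific sparse precisions; the anticorrelated pair
  receives ±field_scale × a smooth unit-SD diagonal gradient in LSGN
  sections only.

None of this simulates raw reads, UMI dropout structure, batch effects,
compositional count noise, or instrument-level MALDI spectra. Passing
recovery tests therefore demonstrate that each analysis stage inverts its
own generative assumptions at realistic sizes — they do not certify
performance on real tumors, where noise is non-Gaussian, signatures
overlap, and artifacts require the manual QC the pipeline deliberately
leaves out.

## Problem sizes used in the shipped checks

The end-to-end recovery checks run at sizes chosen to make every planted
effect decisively recoverable while keeping the whole suite quick on a
laptop: 1000 consensus trials × 10 seeds on 10 signatures × 40 samples;
20-seed CNV screens at 200 samples × 200 genes; 50-seed rank-difference
runs at 2000 genes; 10-seed spatial runs on 30 × 30 lattices; 5-seed GGL
sweeps at p = 15 with four 500-spot sections. The acceptance script
(`scripts/acceptance.py`) re-runs the same computations from scratch at the
same sizes.

## Known limitations

- The scoring engine implements only the Gaussian-kernel statistic; there
  is no Poisson-kernel variant for raw counts and no ssGSEA/z-score/PLAGE
  alternatives.
- The elbow automation is a heuristic around what is fundamentally a visual
  judgment; the diagnostics and the override exist for that reason.
- The Mann–Whitney exact/asymptotic switch at combined n = 20 is a
  convention; near the switch the two p-values differ at the third decimal.
- eBIC with γ = 20 is aggressively conservative: true but weak conditional
  dependencies (partial correlation below ≈ 0.6 at n = 500) are invisible
  by design.
- The CNV screen tests every performed comparison without a minimum group
  size beyond non-emptiness; tiny loss/gain groups yield tests with little
  power rather than being excluded.
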