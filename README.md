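# mbstage

Developmental-stage signature analysis for SHH-activated medulloblastoma.

SHH medulloblastomas contain malignant cells resembling each stage of
cerebellar granule-neuron (GN) development — cycling granule-cell
precursors (GCPs), GCPs, and premigratory, migrating and postmigratory GNs.
`mbstage` implements, as a tested and reusable pipeline, the computational
chain that maps bulk-tumor heterogeneity onto those stages and extends it
into proteomics and spatial metabolomics:

1. **Signature derivation** (`mbstage.signatures`) — per-cell QC filtering,
   one-vs-rest Wilcoxon marker detection with per-cluster downsampling,
   rank-normalized Welch-t bulk subtype markers, top-n signature assembly,
   mouse-to-human ortholog mapping.
2. **Activation scoring** (`mbstage.scoring`) — a Gaussian-kernel CDF /
   weighted random-walk enrichment statistic that turns a genes × samples
   matrix into a signatures × samples score matrix, per sample: for gene i,

       z_ij = Σ_k Φ((x_ij − x_ik)/h_i),  h_i = s_i/4,

   genes ranked by z per sample, and the enrichment score is the signed sum
   of the extreme deviations of a random walk weighted by d^τ,
   d = |p/2 − rank|. Scores lie in (−1, 1).
3. **Consensus co-clustering** (`mbstage.consensus`) — 1000-trial
   subsampled k-means co-clustering of signatures across tumors, consensus
   CDF / Δ-area elbow diagnostics with manual override, correlation-distance
   display ordering.
4. **Developmental scores & CNV screen** (`mbstage.devscores`) — composite
   scores (proliferation = cycling GCP − GCP, progenitor = cycling GCP +
   GCP, late-stage GN = migrating + postmigratory GN), subtype summaries,
   Pearson correlations, and the arm-level Mann–Whitney association screen
   with Bonferroni control (family-wise 0.01; with 657 performed tests the
   per-test alpha is 1.52e-5).
5. **Protein–RNA rank differences** (`mbstage.posttx`) — per-sample rank
   normalization to [−0.5, 0.5], Δ = protein rank − RNA rank as a proxy for
   post-transcriptional regulation, and four-way synaptic/FMRP-target
   category contrasts.
6. **Spatial metabolomics** (`mbstage.spatial`) — TIC normalization, 2-ppm
   peak-to-metabolite assignment, the raw-intensity prevalence filter,
   24-nearest-spot row-standardized weights, bivariate Moran's I
   (I = Σ zx·(W zy)/Σ zx²), and across-section differential means.
7. **Metabolite networks** (`mbstage.networks`) — a joint (group) graphical
   lasso solved by ADMM with eBIC model selection (γ = 20), per-section
   networks, betweenness centrality, cross-group edge-presence
   classification and centrality differences.
8. **Synthetic data** (`mbstage.synthetic`) — seeded generators for every
   input with planted, recoverable ground truth: staged cell matrices with
   known markers, cohorts with subtype/arm-coupled signature activations,
   paired omics with a planted protein shift, and spot lattices drawn from
   sparse precision matrices with a planted spatially anticorrelated
   metabolite pair.

The package is for computational biologists who want to run, extend or
stress-test this analysis chain without access to the original cohorts:
every stage is exercisable end to end on synthetic data.

## Worked example

```python
import mbstage as m

# a 60-tumor cohort in which subtype S1 activates the cycling-GCP program
sigs = {s: [f"{s}_g{i:02d}" for i in range(20)] for s in m.STAGES}
cohort = m.generate_cohort(n_samples=60, signatures=sigs,
                           effects={("S1", "cyclingGCP"): 2.0},
                           noise_sd=1.0, seed=7)

scores = m.enrichment_scores(cohort.expression, sigs)
scores = m.composite_scores(scores)

s1 = cohort.subtype == "S1"
print(round(scores.loc["cyclingGCP", s1.values].mean(), 3),
      round(scores.loc["cyclingGCP", (~s1).values].mean(), 3))
print(round(scores.loc["proliferation", s1.values].mean(), 3))

assoc = m.cnv_association(scores, cohort.arm_status, famwise_alpha=0.01)
print(len(assoc), assoc.alpha.iloc[0])
```

prints

```
0.52 -0.52
0.586
192 5.208333333333334e-05
```

The planted subtype activation separates cleanly (mean cycling-GCP score
0.52 in S1 vs −0.52 elsewhere, proliferation composite 0.586), and the
arm screen performed 192 loss/gain tests at the Bonferroni per-test alpha
0.01/192 ≈ 5.2e-5. No association is flagged, as none was planted on the
arms.

The same stages are scriptable from the shell, e.g.

```sh
mbstage synth cohort --seed 7 --out-dir demo
mbstage score bulk --expr demo/expression.tsv --gmt demo/signatures.gmt --out demo/scores.tsv
mbstage consensus --scores demo/scores.tsv --out-dir demo --trials 1000 --seed 0
```

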