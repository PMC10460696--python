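# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `isletgrid`.

## Data model

A *proteome image* is one TMT plex covering a 3×3 grid of laser-dissected
voxels (default pitch 200 µm × 300 µm), with exactly one voxel containing
an islet. Coordinates are 0-based `(row, col)`, row-major; this convention
is fixed so that file round trips are reproducible. Region labels partition
each grid: the islet voxel, its neighbours under 8-connectivity
(*proximal*), and the remainder (*distal*). 8-connectivity is the default
because an edge-middle islet then has exactly 5 proximal and 3 distal
neighbours, the configuration this design targets; 4-connectivity is
available. Distances are Euclidean between voxel centroids in µm
(`euclidean_centroid_um`); a unit-grid Euclidean and a Chebyshev
(king-move) metric are provided as alternatives. A *study* is an ordered
collection of images sharing a protein index (the sorted union across
images; proteins unmeasured in an image are missing in its voxels).

## Synthetic-data generator

`generate_study` emulates the statistical structure this pipeline assumes,
with planted ground truth for validation:

| parameter | default | meaning |
|---|---|---|
| `n_images` | 7 | images = plexes = biological replicates |
| `n_proteins` | 2000 | proteins in the shared index |
| `frac_islet_markers` | 0.02 | proteins elevated in the islet voxel only |
| `islet_effect` | 2.0 | marker elevation, log2 units |
| `frac_gradient` | 0.05 | proteins varying linearly with distance |
| `gradient_slope` | −0.002 | log2 per µm (≈ −1.4 log2 across the grid) |
| `plex_shift_sd` | 0.3 | per-image location shift (batch effect), log2 |
| `noise_sd` | 0.5 | residual measurement noise, log2 |
| `baseline_sd` | 1.0 | spread of per-protein baseline abundances |
| `missing_rate_base` | 0.02 | dropout probability at the baseline centre |
| `missing_abundance_coupling` | 1.0 | logistic slope of dropout vs abundance |

Islet voxels cycle deterministically through the four edge-middle positions
so every image shows the canonical 1/5/3 split. Dropout is logistic in the
*true* (noise-free) value, `P(miss) = expit(logit(base) − coupling·x)` — a
left-censoring mechanism chosen because voxel-structured missingness in
this kind of data is dominated by low-abundance dropout; the real
mechanism is not characterised, so this is an assumption. One global seed
drives everything; per-image substreams and the pathway/interactome
fixtures derive from it deterministically (`numpy` `SeedSequence`
spawning), so equal seeds give bit-identical studies.

Gradient proteins vary with *physical* distance (µm), matching the default
analysis metric. The defaults produce ≈3–4% overall missingness and
per-image marker contrasts recoverable within sampling error — comparable
in difficulty to, not a copy of, real microdissection data. What the
generator does **not** emulate: peptide-level rollup, correlated
protein co-regulation, carrier-channel ratio compression, spatially
autocorrelated noise, or non-rectangular geometries. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every artefact of real acquisitions.

`generate_pathways` emits the planted marker set, the planted gradient set
and uniformly drawn decoy sets (GMT format). `generate_interactome` plants
a random spanning tree over the markers (confidence 0.7–0.95), adds hidden
"HUB" nodes that bridge non-adjacent marker pairs at confidence 0.99 — by
construction on a cheapest path, to exercise Steiner-node recovery — and
sprinkles background edges over a sample of measured proteins.

## Preprocessing

Missingness is counted per voxel over the study-wide index. Imputation
replaces each missing entry of protein *p* with the median of *p*'s
observed values pooled across **all** voxels of all images (even counts:
midpoint of the central pair). Pooling across images, rather than
per-image medians, follows from treating the study as the unit of
inference, with the image term in the model absorbing batch shifts;
imputing per image would re-introduce exactly the centering this pipeline
avoids. Proteins observed nowhere cannot be imputed and are dropped with a
warning. Observed entries are never altered, so imputation is idempotent.
Cross-plex median centering is implemented (`median_center`) but off by
default — the log-ratio distributions are not normal enough to justify it,
and the image covariate handles the batch structure — keeping it available
lets users reproduce that comparison. PCA QC treats voxels as observations
on mean-centred protein features (components by decreasing explained
variance).

## Differential expression

Per protein, `abundance ~ region + image` is fitted by ordinary least
squares over the pooled 63 voxels (treatment coding, distal and the first
image as references). Because the design matrix is shared, the fit is one
matrix solve for all proteins. Residual variances are moderated with the
standard empirical-Bayes inverse-χ² shrinkage: the prior degrees of
freedom d₀ and scale s₀² are estimated by moment matching on log s²_g
(digamma/trigamma identities, trigamma inverted by Newton iteration), the
posterior variance is the df-weighted average, and the moderated t is
referred to Student's t with d + d₀ df. The implementation agrees with the
Bioconductor limma reference to machine precision on identical designs
(tested through Rscript). A plain-t mode (`moderation="none"`) and
explicit prior overrides are exposed; `df_prior=0` reproduces the ordinary
t exactly.

Choices fixed here: "corrected p" means Benjamini–Hochberg (the field
default); `islet_vs_rest` contrasts the islet coefficient against the
unweighted mean of proximal and distal; proteins with zero residual
variance receive the prior scale (and logFC 0 ⇒ p 1 when the data are
degenerate throughout). Confounded designs — a region level observed in
only one image while the image term is present, or any rank deficiency —
are rejected with the offending term named.

A note on the image covariate: with one islet voxel per image the region
pattern is balanced across images, so a pure plex shift cancels in the
region contrasts; omitting the covariate pushes the shift variance into
the residual and makes the tests *conservative* rather than anticonservative.
Including the image term restores nominal type-I error (and power); the
test suite asserts this direction.

## Enrichment

Sets mode: one-sided hypergeometric over-representation of the selected
proteins among each pathway's members, both restricted to the quantified
background (standard practice given proteomics coverage bias); pathways
with no background member are reported untested. Order mode: proteins are
mid-ranked by score; each pathway's rank sum is compared with its exact
sampling-without-replacement moments, giving a signed z (positive = members
concentrated at high scores) that is tie-exact, with a two-sided normal
p-value. The normal approximation is the default because consensus
aggregation only consumes z and a 0.05 threshold; an exact rank-sum p
(`method="exact"`) is available for small sets. Two-sided testing with a
signed z was chosen over one-sided so that distance-enrichment results
report direction explicitly. BH adjustment is applied across tested sets.

## Distance gradients and consensus

Variance scores are plain sample variances (n−1) across all voxels.
Distance correlations are Spearman's ρ per protein per image against
centroid distance from the islet. With n ≤ 9 voxels the asymptotic test is
invalid, so two-sided p-values are computed by exact enumeration of all n!
orderings. The permutation distribution of the centred rank inner product
depends only on the multisets of the two rank vectors, so the null is
enumerated once per distinct abundance tie pattern (imputation introduces
ties) and shared across proteins — full 9! enumeration for 2000 proteins
× 7 images takes about a second. Constant proteins are flagged undefined
and excluded from rankings; proteins observed in fewer than 3 voxels are
likewise flagged when running on unimputed data.

The protein score fed to rank enrichment is the signed t-form statistic of
ρ (a monotone transform of ρ; enrichment depends only on ranks, so this
choice is about reported magnitudes, not results). Region labels play no
role in this analysis — distance is continuous. A pathway is
consensus-flagged when its per-image enrichment has BH-adjusted p < α
(default 0.05) in at least `min_images` (default 4) of the images;
raw-p gating is exposed as a flag since either reading of "significant per
image" is defensible. Pathway profiles list, per image, the members whose
raw correlation p ≤ threshold, with abundances ordered by distance.

## Network integration

Prizes are |log2FC| of proteins passing the adjusted-p threshold, up- and
down-regulated sets solved separately. Edge costs are 1 − confidence + ε
(ε = 0.01 floor; the transform maps STRING-like confidences to positive
costs). The solver is the classic dummy-root heuristic: a virtual root is
joined to every prized node at cost ω, an approximate Steiner tree over
root + prized nodes is built by metric-closure shortest-path merging
(Mehlhorn's construction, via networkx), the root is removed, and each
resulting tree is strongly pruned bottom-up — a subtree is kept only when
the prize it captures exceeds the edge cost connecting it. Trees whose net
worth does not exceed ω are dropped, so a solution never scores worse than
the empty one and every leaf is prized. β (prize scaling) defaults to 1; ω
defaults to β × median positive prize, both configurable. Determinism
comes from lexicographic node ordering throughout. This heuristic was
chosen over re-implementing message-passing PCSF solvers because it is
deterministic and directly checkable against exhaustive search: on random
≤9-node instances it matches the brute-force optimum in ≈90% of cases and
stays well within 2× of it. The reported solution objective is
Σ edge costs + β·Σ excluded prizes; the per-tree charge ω·(#trees) is part
of the optimisation and of optimality comparisons.

## Problem sizes and tolerances

Simulation-based checks run at the study's design scale (7 × 3×3 voxels,
2000 proteins): type-I calibration uses 3 seeds × 2000 null proteins
(tolerance ±0.02 around 0.05), effect recovery uses 3 standard errors,
consensus detection uses 20 seeds with 15 decoy sets each, solver
optimality uses 100 random instances against exhaustive search, and the
permutation-null z check uses 1000 permutations (sd 1 ± 0.1). Numerical
tie-breaks: permutation p-values count `|ρ_null| ≥ |ρ_obs| − 1e-12`;
numerically null residual variances and effects are clamped to zero before
testing so exactly-fitted proteins report logFC 0, p 1.

## Limitations

- Fixed rectangular grids; no registration to histology, no irregular
  sampling.
- No mixed-effects or spatial-autocorrelation models (image is a fixed
  effect; voxels are otherwise exchangeable within region/distance).
- Median imputation understates uncertainty for heavily missing proteins;
  model-based imputation is out of scope.
- The PCSF heuristic is approximate; at interactome scale no optimality
  certificate is produced.
- Synthetic validation covers the stated generative model only (see
  generator section).
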