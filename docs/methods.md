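# Methods

This note records the models, parameter choices, and numerical conventions
behind `metatme`, and what the synthetic-cohort tests do and do not
demonstrate about real tissue data.

## Cell model and phenotyping

A cell is a point (x, y) in micrometres in a per-core frame (origin at the
core bounding-box corner; all radii in the pipeline — 150 µm for G-Cross,
100 µm for interaction scores — are metric, so µm coordinates are assumed
throughout). Each cell carries per-marker positivity probabilities in
[0, 1], as produced by a single-channel classifier, and/or binary calls.

**Thresholding.** Cohort-level thresholds sit at the minimum of a
Gaussian-KDE density (Scott bandwidth, 512-point grid on [0, 1]) of the
positive-prediction probabilities, searched inside the window
[0.02, 0.75]. The chosen minimum must be interior to the window: a minimum
on a window edge means the density is monotone there (no valley between a
negative and a positive mode), and the threshold falls back to 0.5.
Thresholds above 0.5 are reassigned to 0.5, fewer than 50 samples fall back
to 0.5, and probability equal to the threshold counts positive — a
deterministic tie rule.

**Typing.** The panel defines 14 mutually exclusive lineages via an ordered
list of gating rules (required-positive set, required-negative set); the
first matching rule wins, which is what makes overlapping canonical profiles
(e.g. the several CD45+CD3− myeloid/lymphoid gates) mutually exclusive.
Profiles matching a configured artifact pattern (implausible co-positivity,
e.g. PanCK+CD45+CD3+CD14+) are labeled `artifact` and excluded downstream;
the artifact pattern is configuration, not code, because it is an empirical
property of a staining batch. Cells matching no rule take the modal type of
their 5 nearest exactly-matched neighbors in per-marker-standardized
lineage-probability space, computed per core; modal-vote ties break by panel
rule order so the assignment is independent of row order. Functional states
are restricted per lineage (tumor: PD-L1, vimentin, Ki67, IDO1, HLA-A;
non-tumor: PD-1, PD-L1, granzyme B, ICOS, IDO1); metabolic states (the 7
pathway proxies ASCT2, ATPA5, CS, CPT1A, G6PD, GLUT1, pNRF2) are recorded
for every lineage.

## Neighborhoods

Each cell's neighborhood histogram counts its N nearest neighbors (self
excluded — a neighborhood describes a cell's surroundings, and the switch is
explicit). Two bases:

* **Cellular (CN)**: binary tumor / non-tumor counts, normalized to
  frequencies before k-means, N=50 for the K=2 tumor/stroma view and N=30
  for the K=3 tumor/interface/stroma view.
* **Metabolic (MBN)**: per-pathway counts of neighbors positive for the
  pathway's proxy marker (one neighbor can count toward several pathways),
  N=30, clustered raw at K=4 — raw counts make overall metabolic *density*
  part of the signal, which is what separates "high activity" from
  "minimal" regions.

K-means is Lloyd's algorithm with 10 restarts and a fixed seed, fit at the
cohort level and assigned per cell. Semantic labels come from centroid
ordering: CN clusters by descending tumor fraction (tumor, [interface,]
stroma); MBN clusters by ascending total pathway positivity (minimal, low,
medium_regulatory, high). Cores smaller than N+1 cells are skipped with a
warning and their cells left unlabeled.

The cluster-count check sweeps K (default 2–8), enforces monotone
non-increasing inertia, and places the knee at the maximum perpendicular
distance to the chord of the axis-normalized curve. A featureless inertia
decay (≈1/K, as for a single blob) yields a knee score ≲0.24 on this
normalization, so scores below 0.33 are reported as "not pronounced".

## Spatial metrics

**G-Cross.** For each reference cell the distance to its nearest target
cell (self-pairs excluded when reference and target are the same
phenotype). The summary is the exact integral of the empirical
nearest-neighbor CDF on [0, 150] µm divided by 150, i.e.
mean(150 − min(d, 150))/150 — exactly (150 − d)/150 for one pair at
distance d, and free of grid-discretization error (the 151-point CDF grid
is retained for plotting only). No edge correction; instead the radius is
kept well below the core radius. Empty reference or target sets give a null
(not zero) AUC; compartment restriction applies to both point sets.

**Edge cells.** Per CN region, the alpha shape is computed from the Delaunay
triangulation by keeping triangles with circumradius ≤ α (default: twice
the region's median nearest-neighbor spacing); boundary edges are those
used by exactly one kept triangle, and their endpoints (plus any points
isolated from all kept triangles) are the edge cells. Degenerate regions
(collinear, Delaunay failure) fall back to the convex hull with a warning;
regions under 4 cells are skipped. Cross-region edge-cell G-Cross uses these
point sets.

**JSD.** Isotropic Gaussian KDE per phenotype with Scott's-rule bandwidth
floored at 10 µm, evaluated on a 128×128 grid (64 in the pipeline's default
configs, a speed/accuracy trade-off) over the core bounding box padded by
three bandwidths, normalized to a probability mass function. The distance is
the square root of the base-2 Jensen–Shannon divergence, hence bounded in
[0, 1] and a metric. Either phenotype with fewer than 2 points gives a null,
imputed as 1 (complete separation) at assembly.

**Interaction z-score.** Mean count of target cells within 100 µm of each
reference cell, standardized against n_perm label permutations within the
compartment (positions fixed). Neighbor lists are precomputed once per
compartment so permutations are cheap.

All metrics are invariant to translation and rotation of the coordinate
frame, which the tests assert.

## Feature matrix

Feature names are `family|compartment|ref|target` with phenotype tokens
`type[+state[...]]`; parsing is exact and tested. Families follow the study
grouping — metric × neighborhood view (`prop.cn2`, `gcross.cn3`,
`jsd.mbn`, …). Imputation: null JSD → 1, all other nulls → 0. The
≥25-unique-value sparsity filter runs before scaling on raw values, with
null counted as one value (the order is a convention; it is applied
deterministically). Surviving features are standard-scaled (mean 0, sd 1,
population variance); both raw and scaled views are kept.

## Stability selection with decoy injection

Each real feature gets one artificial decoy: by default an independent
row-permutation of the column (identical marginal, broken joint structure).
Second-order Gaussian knockoffs (equicorrelated construction, matching the
empirical mean and covariance, ridge-regularized when singular) are
available but not the default: with p ≫ n the covariance estimate is too
poor and the resulting decoys mis-scale, which we verified empirically —
permutation decoys are the robust choice in the regime this pipeline
inhabits.

Over B subsamples (default 100; 50 in desk-scale studies — the configured
minimum) of 50% of patients (grouped mode draws 50% from each cohort;
Cox subsamples require ≥10 events and are redrawn up to 10 times), an
l1-penalized model is fit over a penalty grid: plain Lasso against the
binary endpoint, or an elastic-net Cox path (l1 ratio 1) against PFS. The
grid is 30 log-spaced penalties from the null-model penalty down to 0.1× it;
the floor matters — letting the grid reach very small penalties densifies
the active sets and destroys the decoy calibration. A feature's selection
frequency is the **maximum over penalties** of its per-penalty selection
frequency (the stability-path maximum).

The decoy frequencies estimate the false-discovery proportion above a
frequency threshold t: FDP⁺(t) = (1 + #decoys ≥ t)/max(1, #real ≥ t). The
selected set is the real features above a threshold chosen by two routes:

1. if the FDP⁺ curve dips below a signal gate (0.4) anywhere, the smallest
   threshold with FDP⁺ ≤ the cap (0.5) — maximum power subject to the
   bound, the knockoff-plus stopping rule;
2. independently, features whose frequency clears the maximum decoy
   frequency by a margin (0.2, with an absolute floor of 0.7) are kept —
   the +1 correction makes FDP⁺ ≥ 1/#real, so a one- or two-feature
   discovery can never be certified by route 1 no matter how strong it is,
   and the margin route covers exactly that case. In pure-noise designs the
   real and decoy frequency maxima nearly coincide, so the route stays
   empty there.

Decoys are never returned, by construction. Design notes: the FDP⁺ estimate
is calibrated for p ≳ n feature families (the regime the filter targets);
in low-dimensional families null features ride chance correlations that
permutation decoys cannot imitate, and the estimate can be optimistic by
about a factor of two — the planted-design tests hold it to that factor.
Selection runs per feature family, and the union of family selections feeds
the survival stage.

## Survival analysis

* **Mann–Whitney U** per feature (SciPy, exact for small samples), two-sided,
  with log2 fold change of group medians under a pseudocount and
  Benjamini–Hochberg adjustment within the analysis block. Constant
  features get p = 1 by convention.
* **Univariate Cox** per feature (lifelines); non-converged fits are flagged
  and excluded from the BH denominator.
* **Kaplan–Meier log-rank** by median split; when ties make the strict
  median split empty on one side the split falls back to ≥, and a still
  degenerate stratum is an error.
* **Repeated-split penalized Cox.** "k-fold with a 75/25 split" is
  internally inconsistent with standard k-fold, so it is implemented as k
  Monte-Carlo random 75/25 splits. Each split fits an l1 Cox path on the
  training portion, picks the penalty by concordance on an inner 25%
  holdout of the training data, and scores the held-out quarter with the
  inverse-probability-of-censoring-weighted cumulative/dynamic AUC on a
  monthly grid to 24 months, restricted to horizons inside the support of
  both the test follow-up and the train censoring distribution. Splits
  whose test part has no events are redrawn; failed folds contribute NaN
  and are excluded from the mean and 95% band.
* **Prognosis score**: score_i = Σ_k w_k z_ik with w_k the multivariate
  logHR (a lightly ridge-penalized lifelines fit supplies the logHRs and
  CIs; w = HR is a config switch since the hazard-weighting convention is
  ambiguous). Resistance/response signatures are the positive/negative
  weight subsets — disjoint and exhaustive by construction.

## Synthetic cohort: what it emulates, and what it does not

A core is a disc (default radius 300 µm, ~600 µm TMA core) with tumor cells
in isotropic Gaussian nests (default 3 nests of radius 90 µm, sd 0.4×radius)
over a uniform background of the 13 other lineages. Default lineage
frequencies follow the observed cohort composition (tumor 41.4%,
macrophages 14%, CD4 T 8.6%, CD8 T 4.5%, …; the structural remainder —
fibroblasts, myofibroblasts, endothelium — fills the unreported 19.5%).
Lineage positivity follows the gating rules exactly; classifier-style
probabilities are drawn Beta(10, 2) for positives and Beta(2, 10) for
negatives. Functional positivity is sampled per (lineage, marker) with
per-patient logit-normal jitter (sd 0.6) — the between-patient variation
that downstream feature selection consumes. Metabolic positivity
interpolates between nest-center and stromal levels, either as a smooth
Gaussian falloff or as four discrete distance bands ("levels" mode) for
planted-recovery tests.

Survival: per-patient η = Σ β_k z_k over standardized planted feature
values (descriptors like `fraction:macrophage:GranzymeB[@nest]`, evaluated
on the generated cells), PFS and OS exponential with hazard ∝ exp(η)
(baseline medians 6 and 15 months), independent exponential censoring
(rate 0.02/month). RECIST best overall response is assigned from PFS ranks
(6% CR / 22% PR / 34% SD / rest PD), with responders who progressed within
6 months downgraded, so the CB6 rule (CR/PR or PFS > 6 months, strict at
exactly 6) is consistent with the simulated outcomes by construction.

What passing tests show: the estimators are correct on data satisfying
their assumptions, the planted spatial and hazard structure is recovered at
realistic sample sizes, and error control holds under exchangeable nulls.
What they do not show: robustness to segmentation error, marker spillover
in dense regions, batch effects between TMAs, non-exponential hazards,
intra-patient heterogeneity (one core per patient here, as in the study
design), or misspecified gating rules — none of which the generator
simulates.

## Problem sizes and defaults used in checks

Planted-recovery and calibration studies run at desk scale, chosen once:
neighborhood recovery on 3,000–15,000-cell cores; selection on a
10-informative/990-null design at n=120 with B=50 subsamples over 20
replicates; Cox coverage over 500 replicates of n=300; the end-to-end demo
on 60 patients × ~2,000 cells with one planted hazard effect (β=2 on the
granzyme-B+ macrophage fraction, patient rate sd 0.8) selected on the PFS
endpoint — the binary CB6 endpoint caps the attainable biserial correlation
of any single feature near 0.55, which is below what reliable recovery at
n=60 requires, while the study's time-to-event selection variant carries
the full signal. The demo's spatial families (proportions in all three
views at base+functional level, G-Cross in the K=3 view, JSD in the K=2
view at a 64-point KDE grid) keep a full run under a minute without
changing any estimator.

## Known limitations

* The FDP⁺ estimate is approximate (see above); treat reported bounds as
  order-of-magnitude control, not exact FDR guarantees, particularly for
  small feature families.
* The elbow "pronounced" flag is a heuristic on the normalized inertia
  curve; it is reliable for well-separated planted clusters and
  conservative on spatially smoothed gradients.
* Time-dependent AUC is undefined at horizons outside the censoring
  support; folds that cannot be evaluated are dropped from the band rather
  than imputed.
* The h5ad/AnnData reader is not implemented; CSV is the interchange
  format.
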