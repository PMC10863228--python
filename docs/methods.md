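# Methods

`csfpairs` re-implements, as a tested pipeline on synthetic data, an
analysis strategy for multiplex antibody-bead-array CSF proteomics in
Alzheimer's disease: proteins are clustered by their correlation to the
core CSF markers, protein *pairs* matched across the tau- and
amyloid-associated clusters are screened as two-feature linear SVM
classifiers of AT status, and tau/amyloid protein *ratios* are correlated
with cognitive scores. The package's claims are all statements about what
the pipeline recovers from data generated by its own cohort simulator,
whose structure is described first.

## The synthetic cohort model (`synthgen`)

All measurements are multiplicative (log-normal): bead-array MFI readouts
are positive, right-skewed, relative intensities. Per individual *i* the
generator draws

- `s_i = exp(N(0, sigma_scale^2))` — a global CSF protein concentration
  factor shared by every CNS-derived protein. This encodes the hypothesis
  that most brain-derived proteins co-vary strongly within an individual,
  so that a ratio of two such proteins cancels inter-individual
  variability;
- `b_i` — amyloid/tau pathology burden: 0 for intended A-T- individuals,
  `|N(1, 0.25^2)|` for intended A+T+;
- `d_i = |N(0, sigma_impair^2)|` — an AT-independent impairment latent.
  It feeds the tau-block proteins and cognition but not the AT markers,
  so that clinical diagnosis can disagree with AT status (an AD-diagnosed
  individual can be A-T-) while the synaptic-protein ratios still track
  impairment within an AT stratum;
- `q_i` — an albumin CSF/serum quotient, log-normal around 5.7
  (blood-brain-barrier permeability proxy).

CSF markers are calibrated so group medians land on realistic values
(A-T- vs A+T+): Abeta42 `1160*s_i*exp(-0.75*b_i)` (≈1160 vs 540 pg/ml),
Abeta40 `11340*s_i` (ratio x10 ≈ 1.02 vs 0.48), p-tau `32*exp(0.95*b_i)`
(≈32 vs 82 pg/ml), t-tau `6.7*ptau` (≈214 vs 550), NfL weakly increasing
in burden. Marker assay noise (`sigma_marker = 0.08`) is smaller than
protein noise: the clinical immunoassays behind the markers are far more
precise than relative bead-array profiling.

Protein blocks (defaults 22/16/11 = 49 proteins, matching a post-QC
panel): peripheral proteins follow `q_i`; amyloid-associated proteins
follow `s_i` alone (their levels do **not** respond to pathology);
tau-associated proteins follow `s_i * exp(beta_p * (b_i + d_i))` with
per-protein slopes `beta_p = beta_tau * U(0.8, 1.2)` (heterogeneity keeps
within-tau pairs weakly informative). Cognitive scores (MMSE, MoCA, KOD,
RAVLT, RCF) decline linearly in `beta_cog*(b_i + d_i)` and age, are
clipped to their ranges and masked missing at `missing_cog_frac`.

Defaults: `sigma_scale = 0.6`, `sigma_noise = 0.25`, `beta_tau = 1.0`.
These were calibrated jointly so that (a) the median Spearman correlation
among CNS-block proteins within the A-T- group is ≈0.8, (b) a single tau
protein classifies A-T- vs A+T+ at AUC ≈0.85 while a cross-cluster pair
reaches ≈0.95–0.99, and (c) stratification by the marker cutoffs
reproduces the intended groups for ~96% of discovery samples. With
`b ~ |N(1, 0.25^2)|` and the p-tau cutoff at 58 pg/ml against a median of
82, T+ sensitivity is mathematically capped near 93–94%, so perfect
stratification is not attainable under this model; mis-stratified samples
are kept, with ground truth retaining the intended label.

Technical effects (`inject_technical_effects`) multiply each measurement
by `exp(drift_slope_p * position + plate_offset)`; three pool replicates
(the geometric-mean profile of all real samples plus technical noise,
`sigma_tech = 0.04`, giving intra-assay CVs of ~2–6%, median ≈3.5%) are
placed on every plate, and an optional duplicate run re-measures the
matrix for inter-assay QC. Proteins created with `n_qc_fail` get 12x
technical noise so they fail both the CV and the inter-assay rho ≥ 0.7
checks.

The validation cohort (26+26, single plate) is generated border-case-free:
samples whose markers would stratify against their intended group are
redrawn (`enforce_at_rule`). This mirrors pre-selected validation sets in
which AT status is part of the inclusion criteria; the discovery cohort
keeps its mis-stratified samples.

**What the generator does not emulate:** bead-count physics, antibody
cross-reactivity, assay saturation, age/sex effects on protein levels,
longitudinal change, and any correlation structure beyond the three latent
factors. Passing tests therefore show that the pipeline recovers the
planted structure under the stated model — not that it would perform
identically on clinical cohorts.

## Technical adjustment and QC (`preprocess`)

Two fixed steps, in order:

1. **Readout-drift adjustment.** Per protein, a Huber M-estimated line
   (tuning constant 1.345, IRLS via statsmodels RLM, max 50 iterations,
   tol 1e-8; least-squares fallback for degenerate inputs) of raw
   intensity on readout position; adjusted value = residual + median raw
   intensity, re-centred so each protein's median is preserved *exactly*.
   `adjust_position_drift` supports per-plate fits (plates with <3 samples
   are skipped with a warning), but the pipeline fits across the whole
   run: with ~45 samples per plate and log-SD ≈0.65 intensities, per-plate
   slope noise reaches ~20% of the protein median at plate edges and
   pushes low-intensity samples' adjusted values non-positive. Any
   remaining non-positive cell is clamped to half the protein's smallest
   positive adjusted value.
2. **MA normalization** against the global median log2 profile. The
   default scope fits the robust line `M = a + b*A` per sample
   (MA-individual normalization) — appropriate when per-sample offsets
   are technical. The pipeline instead uses `scope="plate"`: the line is
   fitted on each plate's median log2 profile and subtracted from all of
   that plate's samples. Rationale: with 11 of 49 proteins genuinely
   elevated ~1 log unit in A+T+ and two biological latent factors, the
   per-sample fit (i) leaks the tau elevation into every protein's
   offset, creating spurious group differences in the null blocks,
   (ii) redistributes the `s`/`q` factors so peripheral proteins acquire
   strong negative correlations to the amyloid peptides, and (iii)
   removes the very inter-individual variability whose cancellation by
   ratios is the point of the analysis. Plate scope removes plate offsets
   and intensity-dependent plate bias without these artifacts. Both
   variants are exposed; tests cover both.

QC: intra-assay CV% (sample SD over mean) per plate from pool replicates,
computed on *raw* pool intensities so drift-fit estimation noise does not
leak into the replicates; inter-assay Spearman rho between identically
processed duplicate runs (pass at ≥ 0.7); optional background ratio ≥ 3x
against a blank column when provided, otherwise skipped. A protein
failing any check is dropped.

## Stratification (`stratify`)

AT status is a pure function of the markers: A+ iff the amyloid metric is
*strictly below* its cutoff (ratio x10 < 0.68 in discovery; Abeta42 < 813
pg/ml in validation where Abeta40 is unavailable), T+ iff p-tau reaches
its cutoff (*inclusive* ≥ 58 in discovery, *strict* > 55 in validation).
Only A-T- and A+T+ samples enter the analyses; the A-T- group is
restricted to SCD by default. Samples with missing required markers are
excluded, not imputed. Demographics use the Wilcoxon rank-sum test for
age and Fisher's exact test (two-sided, sum of hypergeometric
probabilities ≤ observed) for sex, on complete cases.

## Clustering (`clusterlab`)

Protein profiles are the Spearman correlations (average ranks, pairwise-
complete) to the six markers, computed within the A+T+ group, where the
tau/amyloid sub-split exists; the A-T- matrix is reported for comparison.
Hierarchical clustering uses Euclidean distance and Ward.D2 linkage
(scipy's `ward`, which implements the Lance-Williams update on squared
distances with heights on the distance scale; determinism follows from
scipy's implementation for a fixed input order). The tree is cut at k = 3
and labelled: lowest mean |rho| over the six markers → peripheral; of the
remaining two, higher mean rho to t-tau/p-tau → tau-associated; the other
→ amyloid-associated. Exact ties raise rather than guess. The k = 2 cut
(peripheral vs CNS) is also reported. The protein-protein network keeps
edges with |rho| strictly greater than 0.5 (TSV edge list + GraphML; no
layout is computed).

## Univariate statistics (`diffstats`)

Per protein, the two-sided Wilcoxon rank-sum test between groups: exact
null when min(n) ≤ 25 with no ties, otherwise the normal approximation
with tie and continuity corrections. Benjamini-Hochberg step-up controls
FDR; significance at adjusted p < 0.05. The volcano effect size is the
log2 ratio of group medians (A+T+/A-T-), flagged missing on a zero
denominator.

## Pair screen (`pairscreen`)

All pairs within and between the tau- and amyloid-associated clusters
(peripheral excluded). Protocol per pair, with the identical sample set
and splits shared across pairs:

1. the majority class is undersampled once (seeded) to the minority size;
2. 101 stratified 70/30 splits (stratification prevents single-class test
   folds at n ≈ 120; the split seeds derive from one master seed);
3. per split, cost C tuned on the training part by stratified 10-fold CV
   over {0.1, 1, 10, 100} maximizing mean fold accuracy, ties to the
   smallest C; the SVM (linear kernel, libsvm) is refit on the full
   training part and scored on the test part by ROC AUC (Mann-Whitney
   form, ties ½);
4. features are natural-log transformed, centred to the training median
   and scaled to the training SD (fold-local statistics — the global
   alternative risks leakage; natural log is immaterial to linear-SVM
   predictions up to weight rescaling);
5. the pair summary is the median of the 101 AUCs (an order statistic of
   an odd-length list, hence an element of it; ties resolve to the lowest
   repeat index), and that repeat's fitted model is the "median model",
   with a stratified bootstrap percentile CI (1000 iterations) on its
   test AUC.

The median model transfers to the validation cohort by applying its
weights to validation features re-standardized on the validation cohort
(intensities are relative per assay run; reusing discovery statistics is
available via `recompute_stats=False`). All validation samples are used,
no undersampling. Baselines: single tau-cluster proteins (the four with
the strongest univariate evidence) under the identical protocol, and a
covariate variant adding log Q-Alb as a third feature (samples missing
Q-Alb dropped; requires ≥ 90% availability). Categories are compared by
two-sided Wilcoxon rank-sum tests on the sets of median AUCs, unadjusted.

## Ratios and cognition (`ratiocog`)

Ratios are computed on technically adjusted linear-scale intensities,
cross ratios always tau-protein / amyloid-protein, within-cluster ratios
oriented by a seeded coin flip recorded in the run report; t-tau/Abeta42
and p-tau/Abeta42 are appended when markers are supplied. Multiplying a
sample's full protein row by any constant leaves its ratios unchanged
(bit-identical for power-of-two factors; to floating-point rounding
otherwise). In the noise-free limit the log cross ratio is an exact
function of burden: the variance contributed by `s_i` is zero, while a
single tau protein retains `sigma_scale^2` — the cancellation property,
stated where it is literally true. Pearson correlations to the five
cognitive scores use pairwise-complete samples in the selected groups
(≥ 3 pairs per cell); |R| distributions are compared between categories
with Wilcoxon rank-sum tests, and ratios/proteins are compared between
diagnosis strata within each AT group without multiplicity adjustment.
No outliers are removed.

## Orchestration and reproducibility (`pipeline`, CLI)

`run_pipeline` executes simulate → preprocess → stratify → cluster →
diffstats → pairscreen → transfer → ratios; every stage consumes its
predecessors' outputs, and a requested stage whose prerequisite is
disabled refuses to run with the missing stage named. One global seed
deterministically derives all stage seeds (generator seeds, undersample
seed, the 101 split seeds, bootstrap seed, pair-subset seed, ratio
orientation seed), so a single integer reproduces a run bit-identically;
all seeds are recorded in `report.json` together with a manifest of every
file written. The default screen is a seeded subset of the exhaustive
pair list — 20 cross, 10 within-tau, 10 within-amyloid and 4 single
baselines at 101 repeats each (≈4 minutes on one CPU); `n_*: null`
screens every pair. The `csfpairs` CLI wraps these stages
(`simulate`, `validate`, stage commands, `run-all`) over a YAML config.

## Known limitations

- Semantic cluster labelling assumes the three planted profile shapes;
  on a cohort whose tau block correlates more with Abeta42 than with
  p-tau it would need manual labels (the tie error path).
- Cluster recovery is not guaranteed at ARI = 1.0 for every random
  cohort: one borderline protein occasionally lands in the neighbouring
  CNS cluster (observed ARI ≈ 0.95 on some realizations).
- Because the two null blocks are strongly internally correlated, the
  volcano's false-positive behaviour is dominated by a few effective
  tests; a small seed-dependent probability of one non-tau significant
  protein remains.
- The bead-array scale is relative: no concentration cutoffs can be
  derived from this pipeline, only rankings, separations and
  correlations.
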