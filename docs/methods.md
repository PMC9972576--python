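# Methods

## The problem

A two-time-point methylation cohort asks two complementary questions of
every CpG: *did it change* (differential methylation between T1 and T2,
adjusted for covariates) and *is it reliable* (does a subject's value at
T1 predict their value at T2). `methylstab` answers both and then layers
on the bookkeeping a real array demands: probes that track genotype rather
than methylation, cell-composition confounding, multiplicity, and set-level
interpretation.

## Reliability: ICC(C,1)

For a probe with measurements y_ij (subject i = 1..n, occasion j = 1..k,
k = 2 here), the two-way ANOVA decomposition gives mean squares for
subjects (MS_R), occasions (MS_C) and residual (MS_E), and

    ICC(C,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E).

This is the *consistency* form: an occasion-constant shift (e.g. a global
T2 offset) does not reduce it, but rescaling one occasion does. Both
properties are asserted in tests. The one-sided F test of H0: ICC ≤ 0 uses
F = MS_R/MS_E on (n−1, (n−1)(k−1)) df; the 95% CI is the standard F-based
interval. Conventions, chosen once and documented:

* computed on raw beta values, complete-case per probe, with **no**
  covariate adjustment or normalization — reliability is a property of the
  measurements as used;
* negative estimates are reported as-is and binned "poor"; truncating at
  zero would bias any census built from the bins;
* probes with fewer than 80% complete pairs (configurable) or fewer than
  3 pairs are flagged `low_coverage` and excluded from the genome-wide BH
  adjustment;
* degenerate probes: zero residual with between-subject signal → ICC 1,
  p 0, CI (1,1); an entirely constant probe → NA. Both carry a flag.

The vectorized genome-wide scan is validated two ways: against a
brute-force loop-based ANOVA oracle written independently in the test
suite (|Δ| < 1e−10 over 10^4 random matrices), and against
`pingouin.intraclass_corr`'s ICC3 row.

## Genotype artifacts

Bisulfite arrays cannot distinguish methylation from a sequence variant
under the probe; such probes show tight, gap-separated beta clusters that
follow genotype. The gap scan sorts each probe's values and cuts at
successive differences > 0.05 (threshold) into groups; probes with ≥ 2
groups are gap signals, and those whose non-largest groups jointly hold
< 1% of samples are outlier-driven and excluded from the predicted-GV set
by default (both defaults follow the established gap-hunting tool). Both
time points are pooled — genotypes are time-invariant, so pooling doubles
cluster occupancy without changing the group structure (asserted against
the generator's genotype truth). Note the cutoff is strict: one sample of
92 is 1.09% ≥ 1% and therefore *not* outlier-driven.

Probe classes are assigned with precedence qc_gv > annotated_gv >
predicted_gv > methylation, so each probe lands in exactly one class.
SMPs require ICC ≥ 0.75 with a BH-significant reliability test; HSMPs
additionally require ICC ≥ 0.9 and class "methylation" — stability that
cannot be explained by genotype.

## Cell composition

Reference-based deconvolution solves min_w ||y − Rw||², w ≥ 0 (NNLS) per
sample over the reference CpGs, reporting raw weights, sum-to-one
normalized weights and the residual norm; a strict simplex variant
(equality constraint, implemented as a heavily weighted sum-to-one row) is
available by flag. Composition is compared between time points with a
two-sided Mann-Whitney U per cell type (a paired signed-rank alternative
is available), alongside the subject-matched mean difference.

## Differential methylation

Per probe, OLS of beta on intercept, T2 indicator, sex, smoking, disease
and the estimated cell weights (one reference cell type — neutrophils —
dropped against the intercept; the choice of which column to drop does not
affect the time coefficient). Zero-variance columns are dropped with a
warning; rank deficiency is a hard error naming the dependent columns.
Fitting on beta keeps effect sizes on the methylation-fraction scale; an
M-value transform can be applied upstream where variance stabilization
matters. No subject random effect is included: with every subject present
at both occasions the design is balanced and the time contrast is
within-subject; a subject-blocked sensitivity fit is possible by adding
subject indicator covariates.

Variance moderation follows the standard empirical-Bayes scheme: a scaled
inverse-χ² prior (d0, s0²) on the residual variances, estimated by
matching the mean and variance of e_g = log s²_g − ψ(d_g/2) + log(d_g/2)
(ψ the digamma function; the trigamma equation is solved by Newton
iteration). Posterior variances s²_post = (d0 s0² + d_g s²_g)/(d0 + d_g)
give the moderated t on d0 + d_g df; d0 = ∞ (homogeneous variances) pools
to s0². The implementation is checked to ~1e−14 against a frozen run of
Bioconductor limma's `lmFit`/`eBayes` on a bundled fixture
(`tests/data/`, regeneration script included), and recovers generating
(d0, s0²) from simulated draws.

DMPs are called at BH-adjusted p < 0.05; the unadjusted mean paired
difference (delta beta) is reported next to the adjusted coefficient.
CpG-set structure (e.g. epigenetic-clock loci) is tested with a Wilcoxon
rank-sum of the set's moderated t against all other probes, with
directional alternatives (`down` captures coordinated hypomethylation at
T2) and an exact fallback below 5 members.

## Set enrichment with probe-count bias

A gene with many probes is more likely to contain ≥ 1 significant probe
under any per-probe selection, so hypergeometric (Fisher) gene-set tests
are anti-conservative on arrays. The corrected test maps probes to genes,
counts the set's significant genes, and evaluates it against a Wallenius
noncentral hypergeometric null whose odds are the ratio of mean per-gene
probe counts, set vs non-set. This is deliberately a *scalar-odds
approximation* to the full per-gene-weighted noncentral model: one odds
parameter per set rather than one per gene. With uniform coverage the odds
are 1 and the test reduces exactly to Fisher. Under a biased null in which
significant probes are drawn uniformly and sets favour probe-rich genes
(as real ontology terms favour large, well-annotated genes), Fisher's
type-I error inflates severalfold while the corrected test stays at its
nominal level up to mild conservatism from the scalar approximation and
the discreteness of small overlap counts; the acceptance suite measures
both. The exact multivariate version is a possible extension.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions every property is measured under.

* **Cohort**: 46 subjects, paired T1/T2 samples, inter-sampling interval
  uniform on 2–9 whole years (range and median ~7 chosen to match the
  emulated design; the exact interval distribution of a real cohort is
  cohort-specific). Ages 25–60 at T1; sex 50/50; 24% active smokers;
  disease 36:10 CD:UC; CRP log-normal (median 2.6 mg/L) and leukocyte
  counts (≈7×10⁹/L) drawn independently at each time point, i.e. with no
  true shift.
* **Variance-component probes**: latent m_ij = μ_p + b_i + ε_ij with
  μ_p ~ U[0.15, 0.85], b_i ~ N(0, σ²_r), ε ~ N(0, σ²_e), σ_e = 0.02
  (typical technical-plus-occasion noise on the beta scale) and σ_r set so
  σ²_r/(σ²_r+σ²_e) equals the configured true ICC; values clipped to
  [0.001, 0.999]. Clipping keeps the true ICC interpretable on the
  measurement scale (a logit-normal model would decouple the nominal ICC
  from the beta-scale estimand); the clipped fraction is < 1% by
  construction and asserted. True ICC 1 requires zero noise; otherwise the
  configuration is rejected as infeasible.
* **SNP probes**: genotype per subject from Hardy–Weinberg at MAF 0.3
  (default), constant across time points; cluster means {0.05, 0.5, 0.95},
  cluster sd 0.02. 59 additional QC-GV probes are drawn from the same
  model and flagged `is_qc_gv`, mirroring the rs-control probe count of
  EPIC-style designs; 30% of SNP probes carry a dbSNP id (`annotated_gv`).
* **Age-drift probes**: a moderate-ICC baseline plus slope × interval at
  T2; default slope −0.004 beta/year (−0.04/decade), a realistic
  magnitude for clock CpGs, negative to encode the global age-related
  hypomethylation the set test's `down` alternative targets.
* **Cell-driven probes**: beta = Σ_c w_ic m_pc + noise, with per-sample
  Dirichlet weights (concentration 50 around blood-like proportions,
  neutrophil-dominated) and T2 weights drawn around shifted means (B
  +0.02, CD4T +0.03, neutrophils −0.05) to encode the composition change;
  the reference panel separates each probe's marker cell type from the
  rest by ≥ 0.3.

What the generator does **not** emulate: raw intensities and detection
p-values, batch/chip effects, spatially correlated probes, beta-value
heteroscedasticity near the boundaries beyond clipping, and genotype-
methylation interactions in cis. Passing tests therefore demonstrate the
statistical machinery under a clean generative model, not robustness to
array artifacts that normalization pipelines address upstream.

## Numerical choices and degenerate inputs

* Degenerate-variance tolerance: MS_E ≤ 1e−12 × max(SS_total, 1) treats a
  probe as zero-residual.
* BH adjustment propagates NaN and is applied only across testable probes.
* Wilcoxon signed-rank discards zero differences (standard convention);
  all-zero differences report p = 1; fewer than 6 informative pairs fall
  back to the exact null with a warning.
* Nearest-variant distances are 1-based on both sides; ties between an
  upstream and downstream variant resolve to the smaller coordinate; the
  "< 1 kb" vicinity flag is a strict inequality. Mixed chromosome naming
  ("chr1" vs "1") is normalized with a warning.
* The simplex deconvolution variant enforces Σw = 1 via a 1e6-weighted
  equality row, accurate to ~1e−5 in the sum.
* All simulation is driven by one `numpy` Generator seeded from the
  config; pipeline summaries exclude wall-clock timings so same-seed runs
  are byte-identical.

## Problem sizes

Default cohorts use 46 subject pairs and ~5,400 probes (4,000
variance-component across four ICC levels, 500 SNP, 500 age-drift, 300
cell-driven, 59 QC). Property simulations use 10^4 probes (calibration,
prior recovery), 20 replicate cohorts (ICC recovery, FDR control) and
10^3 replicates (enrichment calibration) — sizes at which every interval
asserted in the acceptance suite is decisively informative while the whole
suite runs in well under a minute of compute per criterion. The genome-wide
ICC scan is fully vectorized and handles 850k probes × 46 pairs in seconds.

## Known limitations

* The scalar-odds Wallenius test is mildly conservative under strong
  per-gene weight heterogeneity (see above).
* The ICC p-value follows the one-sided F convention of standard
  reliability software; other tail conventions would change p but not the
  estimate or the bins.
* Gap hunting can flag broad-but-unimodal distributions (high-ICC probes
  with large between-subject spread); on real arrays these would be
  vetted against variant catalogues, which is why annotated-GV status
  takes precedence over the gap scan in the class partition.
* The pipeline treats the cell-weight covariates as fixed; uncertainty in
  the deconvolution is not propagated into the differential tests.
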