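# methylstab

Longitudinal stability analysis of DNA methylation arrays.

Blood-based methylation biomarkers are only useful if the CpG loci behind
them keep their methylation state over years of follow-up — through aging,
treatment, and shifts in leukocyte composition. `methylstab` implements the
analysis toolkit for paired two-time-point EPIC/450k-style cohorts:

* **ICC screening** — per-CpG reliability between time points with the
  two-way mixed, single-measures, consistency intra-class correlation,
  ICC(C,1) = (MS_R − MS_E)/(MS_R + (k−1)·MS_E), with one-sided F test,
  95% CI, BH adjustment, and Koo–Li binning
  (poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤ excellent);
* **gap hunting** — flagging probes whose beta distribution splits into
  gap-separated clusters, the signature of an underlying germline variant;
* **probe-class partition and stability calling** — quality-control GV >
  annotated GV > predicted GV > methylation, with stably methylated
  positions (SMP: ICC ≥ 0.75, significant) and hyper-stable methylated
  positions (HSMP: ICC ≥ 0.9 and no genetic-variant evidence);
* **cell deconvolution** — non-negative least-squares projection onto a
  cell-type reference panel, with T1 vs T2 composition tests;
* **differential methylation** — per-probe OLS on time point plus
  covariates with empirical-Bayes variance moderation (moderated t), and a
  rank test for CpG sets such as epigenetic-clock loci;
* **set enrichment** — Wallenius noncentral hypergeometric gene-set test
  correcting the per-gene probe-count selection bias;
* **synthetic cohorts** — a generator producing paired cohorts with known
  per-probe ground truth (true ICC, genotypes, drift slopes, cell
  weights), against which every stage is validated.

## Worked example

`examples/` contains one short script per capability. The reliability
screen (`examples/02_icc_screen.py`) simulates the default 46-subject
paired cohort and screens every probe:

```
screened 5359 probes over 46 subject pairs
stability-class census:
poor         2091
excellent    1555
moderate      908
good          805
true ICC 0.2: mean estimate 0.194
true ICC 0.5: mean estimate 0.492
true ICC 0.8: mean estimate 0.796
true ICC 0.95: mean estimate 0.948
```

Per-level mean estimates track the generating ICC to within ~0.005 at this
sample size. The full pipeline (`examples/07_full_pipeline.py`) adds gap
hunting, classification, deconvolution and differential methylation:

```
5359 probes, 46 subject pairs
SMPs (ICC >= 0.75, significant): 2360
HSMPs (ICC >= 0.9, no GV evidence): 681
time-associated DMPs (FDR < 0.05): 407
```

The class-by-stability census it prints shows the expected structure:
genotype-driven probe classes pile up in the "excellent" column (a
genotype does not change between samplings), while ordinary methylation
probes spread across all four bins — exactly the pattern that motivates
excluding genetic-variant classes from the hyper-stable set.

A thin CLI mirrors the library:

```bash
methylstab simulate --out cohort/ --seed 1
methylstab icc --beta cohort/beta.tsv --samples cohort/samples.csv --out icc.tsv
methylstab report --out results/ --seed 1
```

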