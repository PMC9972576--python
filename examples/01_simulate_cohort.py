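"""Generate a paired methylation cohort with known ground truth.

The generator emulates a two-time-point peripheral-blood study: 46
subjects sampled twice, 2-9 years apart, with variance-component probes at
chosen true ICC levels, Hardy-Weinberg trimodal (genotype-driven) probes,
age-drift probes and cell-composition-driven probes.
"""

from methylstab import SimConfig, simulate_cohort

config = SimConfig(seed=1)
beta, sheet, annotation, reference, truth = simulate_cohort(config)

print(f"beta matrix: {beta.shape[0]} probes x {beta.shape[1]} samples")
print(f"subjects: {sheet.data['subject_id'].nunique()}, "
      f"time points: {sorted(sheet.data['timepoint'].unique())}")
print("probe classes:")
print(truth.probes["probe_class"].value_counts().to_string())
print(f"reference panel: {reference.shape[0]} CpGs x {reference.shape[1]} cell types")
# Every probe's generating parameters (true ICC, genotype, drift slope,
# marker cell) are in `truth`, so downstream estimates can be scored.
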