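"""Run the complete stability pipeline on a simulated cohort.

Executes pairing, genome-wide ICC, gap scan, probe-class partition,
SMP/HSMP calling with the class-by-stability census, cell deconvolution,
differential methylation, clock-set test, variant-vicinity annotation and
clinical comparisons; all tables land in the output directory together
with a JSON summary.
"""

import json

from methylstab import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(seed=1), "pipeline_output")

print(f"{summary['n_probes']} probes, {summary['n_pairs']} subject pairs")
print(f"SMPs (ICC >= 0.75, significant): {summary['n_smp']}")
print(f"HSMPs (ICC >= 0.9, no GV evidence): {summary['n_hsmp']}")
print(f"time-associated DMPs (FDR < 0.05): {summary['n_dmp']}")
print("class x stability census:")
print(json.dumps(summary["census"], indent=2))
print(f"clinical tests (paired Wilcoxon p): {summary['clinical']}")
# The census reproduces the expected structure: genetic-variant classes
# pile up in the 'excellent' column while ordinary methylation probes
# spread over all four stability bins.
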