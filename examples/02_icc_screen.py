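"""Per-probe reliability screening with ICC(C,1).

For each CpG the two-way mixed, single-measures, consistency intra-class
correlation quantifies how much of the variation is between subjects
rather than within a subject across the two time points.  Estimates are
binned poor (<0.5) / moderate / good / excellent (>=0.9).
"""

from methylstab import SimConfig, align_pairs, icc_genomewide, simulate_cohort

beta, sheet, _, _, truth = simulate_cohort(SimConfig(seed=1))
view = align_pairs(beta, sheet)
table = icc_genomewide(view)

print(f"screened {len(table)} probes over {view.n_pairs} subject pairs")
print("stability-class census:")
print(table["stability_class"].value_counts().to_string())

for level in (0.2, 0.5, 0.8, 0.95):
    ids = truth.probes.index[truth.probes["true_icc"] == level]
    print(f"true ICC {level}: mean estimate {table.loc[ids, 'icc'].mean():.3f}")
# Mean estimates track the generating ICC; the census shows how 46 pairs
# spread point estimates across the Koo-Li bins.
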