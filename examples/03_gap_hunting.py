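"""Detect genotype-driven probes from gap-separated beta clusters.

Probes overlapping a germline variant show two or three tight beta
clusters (one per genotype).  The scan cuts each probe's sorted values at
jumps larger than 0.05 and flags multi-group probes; tiny split-off groups
are marked outlier-driven and excluded from the predicted-GV set.
"""

from methylstab import SimConfig, gaps_genomewide, simulate_cohort

beta, _, _, _, truth = simulate_cohort(SimConfig(seed=1))
table = gaps_genomewide(beta)

snp = truth.probes.index[truth.probes["probe_class"] == "snp_trimodal"]
vc = truth.probes.index[truth.probes["probe_class"] == "variance_component"]
print(f"predicted-GV probes: {int(table['predicted_gv'].sum())} of {len(table)}")
print(f"sensitivity on simulated SNP probes: {table.loc[snp, 'predicted_gv'].mean():.3f}")
print(f"rate on variance-component probes:  {table.loc[vc, 'predicted_gv'].mean():.3f}")
print("group-count census among SNP probes:")
print(table.loc[snp, "n_groups"].value_counts().sort_index().to_string())
# Nearly all trimodal probes are recovered; broad-but-unimodal probes are
# occasionally flagged, mirroring what gap scans do on real arrays.
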