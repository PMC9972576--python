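"""Probe-class precedence, SMP/HSMP calling, vicinity annotation, clinical
comparisons and end-to-end pipeline determinism."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylstab.gap_hunting import gaps_genomewide
from methylstab.icc_screen import icc_genomewide
from methylstab.io_model import (
    CpGSet,
    ProbeAnnotation,
    SampleSheet,
    VariantTable,
    align_pairs,
)
from methylstab.stability_pipeline import (
    PipelineConfig,
    annotate_gv_vicinity,
    assign_probe_classes,
    call_stability,
    clinical_compare,
    interrogate_cpg_list,
    run_pipeline,
)
from methylstab.synthetic_data import SimConfig


@pytest.fixture(scope="module")
def analyzed(small_cohort):
    beta, sheet, annotation, reference, truth = small_cohort
    view = align_pairs(beta, sheet)
    icc_table = icc_genomewide(view)
    gap_table = gaps_genomewide(beta)
    classes = assign_probe_classes(annotation, gap_table)
    return beta, sheet, annotation, truth, icc_table, gap_table, classes


class TestProbeClasses:
    def test_precedence_qc_over_gap(self, analyzed):
        *_, truth, icc_table, gap_table, classes = analyzed
        qc = truth.probes.loc[truth.probes["probe_class"] == "qc_gv", "probe_id"]
        assert (classes.loc[qc, "probe_class"] == "qc_gv").all()

    def test_snp_probes_mostly_gv_classed(self, analyzed):
        *_, truth, icc_table, gap_table, classes = analyzed
        snp = truth.probes.loc[truth.probes["probe_class"] == "snp_trimodal", "probe_id"]
        in_gv = classes.loc[snp, "probe_class"].isin(["annotated_gv", "predicted_gv"])
        assert in_gv.mean() >= 0.95

    def test_unflagged_probe_is_methylation_class(self):
        ann = ProbeAnnotation(pd.DataFrame(
            {"probe_id": ["cg1"], "chrom": ["chr1"], "pos": [100]}
        ))
        gaps = pd.DataFrame(
            {"probe_id": ["cg1"], "predicted_gv": [False]}
        ).set_index("probe_id", drop=False)
        classes = assign_probe_classes(ann, gaps)
        assert classes.loc["cg1", "probe_class"] == "methylation"

    def test_gap_probe_missing_from_annotation_rejected(self):
        ann = ProbeAnnotation(pd.DataFrame(
            {"probe_id": ["cg1"], "chrom": ["chr1"], "pos": [100]}
        ))
        gaps = pd.DataFrame(
            {"probe_id": ["cg1", "cg2"], "predicted_gv": [False, True]}
        ).set_index("probe_id", drop=False)
        with pytest.raises(ValueError, match="absent from the annotation"):
            assign_probe_classes(ann, gaps)


class TestCallStability:
    def test_crosstab_conserves_class_sizes(self, analyzed):
        *_, icc_table, gap_table, classes = analyzed
        calls, crosstab = call_stability(icc_table, classes)
        counts = classes["probe_class"].value_counts()
        classified = calls.dropna(subset=["stability_class"])
        for cls in crosstab.index:
            assert crosstab.loc[cls].sum() == (classified["probe_class"] == cls).sum()
        assert crosstab.to_numpy().sum() == len(classified)

    def test_hsmp_disjoint_from_gv_classes(self, analyzed):
        *_, icc_table, gap_table, classes = analyzed
        calls, _ = call_stability(icc_table, classes)
        hsmp = calls[calls["is_hsmp"]]
        assert (hsmp["probe_class"] == "methylation").all()
        assert (hsmp["icc"] >= 0.9).all()

    def test_smp_requires_significance_and_threshold(self, analyzed):
        *_, icc_table, gap_table, classes = analyzed
        calls, _ = call_stability(icc_table, classes)
        smp = calls[calls["is_smp"]]
        assert (smp["icc"] >= 0.75).all()
        assert (smp["p_adjusted"] < 0.05).all()
        assert calls["is_hsmp"].sum() <= calls["is_smp"].sum()

    def test_high_icc_methylation_probes_called_hsmp(self, analyzed):
        _, _, _, truth, icc_table, gap_table, classes = analyzed
        calls, _ = call_stability(icc_table, classes)
        tp = truth.probes
        stable = tp[(tp["probe_class"] == "variance_component") & (tp["true_icc"] == 0.95)][
            "probe_id"
        ]
        meth = calls.loc[stable]
        meth = meth[meth["probe_class"] == "methylation"]
        assert (meth["stability_class"] == "excellent").mean() >= 0.9
        assert meth.loc[meth["stability_class"] == "excellent", "is_hsmp"].all()


class TestInterrogate:
    def test_report_and_proportions(self, analyzed):
        _, _, _, truth, icc_table, gap_table, classes = analyzed
        ids = tuple(truth.probes["probe_id"].iloc[:10])
        report, props = interrogate_cpg_list(CpGSet("list", ids), icc_table, classes)
        assert len(report) == 10
        assert props.sum() == pytest.approx(1.0)

    def test_stable_list_recovers_truth_proportions(self, analyzed):
        _, _, _, truth, icc_table, gap_table, classes = analyzed
        tp = truth.probes
        stable = tuple(
            tp[(tp["probe_class"] == "variance_component") & (tp["true_icc"] == 0.95)][
                "probe_id"
            ]
        )
        _, props = interrogate_cpg_list(CpGSet("stable", stable), icc_table, classes)
        assert props["good"] + props["excellent"] >= 0.9

    def test_misses_warn_empty_errors(self, analyzed):
        *_, icc_table, gap_table, classes = analyzed
        with pytest.warns(UserWarning, match="not in the universe"):
            interrogate_cpg_list(
                CpGSet("partial", (icc_table.index[0], "cg_missing")), icc_table, classes
            )
        with pytest.raises(ValueError, match="no member"):
            interrogate_cpg_list(CpGSet("none", ("cg_nope",)), icc_table, classes)


class TestVicinity:
    def _ann(self, rows):
        return ProbeAnnotation(pd.DataFrame(
            [{"probe_id": f"cg{i}", "chrom": c, "pos": p} for i, (c, p) in enumerate(rows)]
        ))

    def _variants(self, rows):
        return VariantTable(pd.DataFrame(
            [{"variant_id": f"v{i}", "chrom": c, "pos": p, "phenotype": "CD"}
             for i, (c, p) in enumerate(rows)]
        ))

    def test_boundary_distances(self):
        ann = self._ann([("chr6", 100_000), ("chr6", 99_000), ("chr7", 100_000)])
        var = self._variants([("chr6", 100_999), ("chr6", 100_000)])
        out = annotate_gv_vicinity(ann, var, window=1000)
        assert out.loc["cg0", "distance"] == 0
        assert out.loc["cg1", "distance"] == 1000
        assert out.loc["cg1", "within_window"] == False  # strict <
        assert pd.isna(out.loc["cg2", "distance"])
        assert pd.isna(out.loc["cg2", "within_window"])

    def test_probe_999_away_flagged(self):
        ann = self._ann([("chr6", 100_000)])
        var = self._variants([("chr6", 100_999)])
        out = annotate_gv_vicinity(ann, var)
        assert out.loc["cg0", "distance"] == 999
        assert bool(out.loc["cg0", "within_window"])

    def test_tie_prefers_smaller_coordinate(self):
        ann = self._ann([("chr1", 500)])
        var = self._variants([("chr1", 400), ("chr1", 600)])
        out = annotate_gv_vicinity(ann, var)
        assert out.loc["cg0", "nearest_variant"] == "v0"

    def test_chrom_style_normalized_with_warning(self):
        ann = self._ann([("6", 100_000)])
        var = self._variants([("chr6", 100_500)])
        with pytest.warns(UserWarning, match="chromosome naming"):
            out = annotate_gv_vicinity(ann, var)
        assert out.loc["cg0", "distance"] == 500

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(0)
        chroms = [f"chr{c}" for c in (1, 2, 3)]
        probes = [(rng.choice(chroms), int(rng.integers(1, 10_000))) for _ in range(300)]
        variants = [(rng.choice(chroms), int(rng.integers(1, 10_000))) for _ in range(40)]
        out = annotate_gv_vicinity(self._ann(probes), self._variants(variants))
        for i, (pc, pp) in enumerate(probes):
            ds = [abs(pp - vp) for vc, vp in variants if vc == pc]
            expected = min(ds) if ds else None
            got = out.loc[f"cg{i}", "distance"]
            if expected is None:
                assert pd.isna(got)
            else:
                assert got == expected


class TestClinical:
    def test_identical_pairs_give_p_one(self, tiny_sheet):
        df = tiny_sheet.data.copy()
        df["crp_mg_per_l"] = 3.0
        df["leukocytes_e9_per_l"] = 7.0
        out = clinical_compare(SampleSheet(df))
        assert (out["p_value"] == 1.0).all()
        assert (out["mode"] == "degenerate").all()

    def test_few_pairs_fall_back_to_exact(self, tiny_sheet):
        df = tiny_sheet.data.copy()
        rng = np.random.default_rng(1)
        df["crp_mg_per_l"] = rng.uniform(1, 5, size=len(df))
        with pytest.warns(UserWarning, match="exact"):
            out = clinical_compare(SampleSheet(df), min_pairs_normal=10)
        assert out.loc["crp", "mode"] == "exact"

    def test_null_cohort_no_signal(self, small_cohort):
        _, sheet, *_ = small_cohort
        out = clinical_compare(sheet)
        assert set(out.index) == {"crp", "leukocytes"}
        assert (out["n_pairs"] == 46).all()
        # CRP/leukocytes are drawn independently at T1 and T2: no true shift
        assert (out["p_value"] > 0.001).all()


class TestRunPipeline:
    @pytest.fixture(scope="class")
    def tiny_config(self):
        sim = SimConfig(n_subjects=20, n_variance_probes=200, n_snp_probes=40,
                        n_age_probes=60, n_cell_probes=60, n_qc_gv_probes=10)
        return PipelineConfig(sim=sim, seed=13)

    def test_same_seed_byte_identical(self, tiny_config, tmp_path):
        run_pipeline(tiny_config, tmp_path / "a")
        run_pipeline(tiny_config, tmp_path / "b")
        assert (tmp_path / "a/summary.json").read_bytes() == (
            tmp_path / "b/summary.json"
        ).read_bytes()

    def test_summary_conservation_and_outputs(self, tiny_config, tmp_path):
        summary = run_pipeline(tiny_config, tmp_path / "c")
        census_total = sum(sum(row.values()) for row in summary["census"].values())
        assert census_total <= summary["n_probes"]
        assert summary["n_hsmp"] <= summary["n_smp"]
        for f in ("icc.tsv", "gaps.tsv", "dmp.tsv", "census.tsv", "summary.json",
                  "stability_calls.tsv", "cell_estimates.tsv", "clinical_tests.tsv"):
            assert (tmp_path / "c" / f).exists()
        written = json.loads((tmp_path / "c/summary.json").read_text())
        assert written["n_smp"] == summary["n_smp"]

    def test_census_row_sums_equal_class_sizes(self, tiny_config, tmp_path):
        summary = run_pipeline(tiny_config, tmp_path / "d")
        calls = pd.read_csv(tmp_path / "d/stability_calls.tsv", sep="\t")
        classified = calls.dropna(subset=["stability_class"])
        for cls, row in summary["census"].items():
            assert sum(row.values()) == (classified["probe_class"] == cls).sum()
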