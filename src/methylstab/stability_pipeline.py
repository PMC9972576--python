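"""Full stability-analysis pipeline.

Orchestrates: pairing -> genome-wide ICC -> gap scan -> probe-class
partition (qc_gv > annotated_gv > predicted_gv > methylation) -> SMP/HSMP
calls and the class-by-stability census -> cell deconvolution ->
covariate-adjusted differential methylation -> clock-set rank test ->
optional CpG-list interrogation, variant-vicinity annotation and clinical
comparisons.  All outputs are TSV/CSV plus one JSON summary; the run is
deterministic given the seed.

Definitions: a stably methylated position (SMP) has ICC >= 0.75 with a
BH-significant reliability test; a hyper-stable methylated position (HSMP)
additionally has ICC >= 0.9 and no genetic-variant evidence of any kind
(probe class "methylation").
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import cell_deconvolution as cd
from . import diff_methylation as dm
from . import gap_hunting as gh
from . import icc_screen as icc
from .io_model import (
    BetaMatrix,
    CpGSet,
    ProbeAnnotation,
    SampleSheet,
    VariantTable,
    align_pairs,
)
from .synthetic_data import SimConfig, TruthTables, simulate_cohort, simulate_variant_table

logger = logging.getLogger("methylstab")

PROBE_CLASSES = ("qc_gv", "annotated_gv", "predicted_gv", "methylation")
STABILITY_ORDER = ("poor", "moderate", "good", "excellent")


def assign_probe_classes(annotation: ProbeAnnotation, gap_table: pd.DataFrame) -> pd.DataFrame:
    """Partition probes into mutually exclusive classes by precedence
    qc_gv > annotated_gv > predicted_gv > methylation."""
    ann = annotation.data
    missing = gap_table.index.difference(ann.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} gap-scanned probe(s) absent from the annotation, "
            f"e.g. {list(missing[:3])}"
        )
    predicted = gap_table["predicted_gv"].reindex(ann.index).fillna(False).astype(bool)
    cls = np.where(
        ann["is_qc_gv"],
        "qc_gv",
        np.where(ann["annotated_gv"], "annotated_gv",
                 np.where(predicted, "predicted_gv", "methylation")),
    )
    return pd.DataFrame({"probe_id": ann["probe_id"], "probe_class": cls}).set_index(
        "probe_id", drop=False
    )


def call_stability(
    icc_table: pd.DataFrame,
    classes: pd.DataFrame,
    smp_icc: float = 0.75,
    hsmp_icc: float = 0.9,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SMP/HSMP flags plus the 4x4 probe-class x stability census.

    Returns (calls, crosstab); crosstab rows are probe classes, columns the
    Koo-Li stability bins, cells are probe counts.
    """
    joined = icc_table.join(classes["probe_class"], how="inner")
    sig = joined["p_adjusted"] < alpha
    joined["is_smp"] = (joined["icc"] >= smp_icc) & sig
    joined["is_hsmp"] = (
        joined["is_smp"] & (joined["icc"] >= hsmp_icc) & (joined["probe_class"] == "methylation")
    )
    calls = joined[
        ["probe_id", "icc", "p_adjusted", "stability_class", "probe_class", "is_smp", "is_hsmp"]
    ]
    crosstab = (
        pd.crosstab(joined["probe_class"], joined["stability_class"])
        .reindex(index=list(PROBE_CLASSES), columns=list(STABILITY_ORDER), fill_value=0)
        .fillna(0)
        .astype(int)
    )
    return calls, crosstab


def interrogate_cpg_list(
    cpg_set: CpGSet,
    icc_table: pd.DataFrame,
    classes: pd.DataFrame | None = None,
    dm_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Joined ICC / class / differential-methylation report for a CpG list.

    Returns the per-probe report and the stability-class proportions
    (summing to 1 over the probes found).  Missing ids raise a warning;
    an empty intersection is an error.
    """
    ids = pd.Index(cpg_set.members)
    found = ids.intersection(icc_table.index)
    if found.empty:
        raise ValueError(f"no member of set {cpg_set.name!r} is present in the ICC table")
    missed = ids.difference(found)
    if len(missed):
        warnings.warn(
            f"set {cpg_set.name!r}: {len(missed)} member(s) not in the universe", stacklevel=2
        )
    report = icc_table.loc[found, ["probe_id", "icc", "ci_low", "ci_high",
                                   "p_adjusted", "stability_class"]].copy()
    if classes is not None:
        report = report.join(classes["probe_class"])
    if dm_table is not None:
        cols = [c for c in ("coef_time", "t_mod", "p_value", "p_adjusted", "delta_beta", "is_dmp")
                if c in dm_table.columns]
        report = report.join(dm_table[cols], rsuffix="_dm")
    props = (
        report["stability_class"].value_counts(normalize=True)
        .reindex(list(STABILITY_ORDER), fill_value=0.0)
    )
    return report, props


def _normalize_chrom(series: pd.Series) -> tuple[pd.Series, str]:
    s = series.astype(str)
    has_prefix = s.str.startswith("chr")
    style = "chr" if has_prefix.all() else ("bare" if not has_prefix.any() else "mixed")
    return s.where(has_prefix, "chr" + s), style


def annotate_gv_vicinity(
    annotation: ProbeAnnotation, variants: VariantTable, window: int = 1000
) -> pd.DataFrame:
    """Distance from each probe to its nearest variant on the same
    chromosome (1-based, both inclusive) and a strict ``< window`` flag.

    Chromosome naming styles ("chr1" vs "1") are normalized with a
    warning.  Equidistant ties resolve to the variant at the smaller
    coordinate; probes on variant-free chromosomes get NA.
    """
    ann = annotation.data
    probe_chrom, style_a = _normalize_chrom(ann["chrom"])
    var = variants.data
    var_chrom, style_v = _normalize_chrom(var["chrom"])
    if style_a != style_v or "mixed" in (style_a, style_v):
        warnings.warn(
            "mismatched chromosome naming styles ('chr1' vs '1'); normalized to 'chr' prefix",
            stacklevel=2,
        )

    dist = np.full(len(ann), np.nan)
    nearest = np.full(len(ann), "", dtype=object)
    for chrom in var_chrom.unique():
        pidx = np.flatnonzero((probe_chrom == chrom).to_numpy())
        if pidx.size == 0:
            continue
        sub = var[ (var_chrom == chrom).to_numpy() ].sort_values(["pos", "variant_id"])
        vpos = sub["pos"].to_numpy()
        vid = sub["variant_id"].to_numpy()
        ppos = ann["pos"].to_numpy()[pidx]
        right = np.searchsorted(vpos, ppos)
        left = np.clip(right - 1, 0, len(vpos) - 1)
        right = np.clip(right, 0, len(vpos) - 1)
        d_left = np.abs(ppos - vpos[left])
        d_right = np.abs(ppos - vpos[right])
        # tie -> smaller coordinate, i.e. prefer the left candidate on equality
        use_left = d_left <= d_right
        dist[pidx] = np.where(use_left, d_left, d_right)
        nearest[pidx] = np.where(use_left, vid[left], vid[right])

    within = pd.array(dist < window, dtype="boolean")  # strict inequality
    within[np.isnan(dist)] = pd.NA
    out = pd.DataFrame(
        {
            "probe_id": ann["probe_id"],
            "nearest_variant": nearest,
            "distance": dist,
            "within_window": within,
        }
    ).set_index("probe_id", drop=False)
    return out


def clinical_compare(sheet: SampleSheet, min_pairs_normal: int = 6) -> pd.DataFrame:
    """Paired T1 vs T2 Wilcoxon signed-rank tests of CRP and leukocyte count.

    Zero-difference pairs are discarded (standard signed-rank convention);
    if every pair is identical the p-value is reported as 1.  Fewer than
    ``min_pairs_normal`` informative pairs falls back to the exact null
    with a warning.
    """
    df = sheet.data
    rows = []
    for col, label in (("crp_mg_per_l", "crp"), ("leukocytes_e9_per_l", "leukocytes")):
        if col not in df.columns:
            continue
        wide = df.pivot_table(index="subject_id", columns="timepoint", values=col,
                              aggfunc="first")
        if "T1" not in wide.columns or "T2" not in wide.columns:
            continue
        paired = wide.dropna()
        diff = (paired["T2"] - paired["T1"]).to_numpy(dtype=float)
        nonzero = diff[diff != 0]
        if nonzero.size == 0:
            stat, p, mode = np.nan, 1.0, "degenerate"
        elif nonzero.size < min_pairs_normal:
            warnings.warn(
                f"{label}: only {nonzero.size} informative pairs; exact signed-rank test",
                stacklevel=2,
            )
            stat, p = stats.wilcoxon(nonzero, mode="exact")
            mode = "exact"
        else:
            stat, p = stats.wilcoxon(nonzero)
            mode = "auto"
        rows.append(
            {
                "measure": label,
                "n_pairs": int(len(paired)),
                "n_informative": int(nonzero.size),
                "statistic": float(stat) if np.isfinite(stat) else np.nan,
                "p_value": float(p),
                "mean_diff": float(diff.mean()) if len(diff) else np.nan,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows).set_index("measure", drop=False)


@dataclass
class PipelineConfig:
    """Configuration for a full run; either simulate or point at inputs."""

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    beta_path: str | None = None
    sheet_path: str | None = None
    annotation_path: str | None = None
    reference_path: str | None = None
    variants_path: str | None = None
    cpg_sets_path: str | None = None
    gap_threshold: float = gh.DEFAULT_THRESHOLD
    gap_out_cutoff: float = gh.DEFAULT_OUT_CUTOFF
    smp_icc: float = 0.75
    hsmp_icc: float = 0.9
    dmp_alpha: float = 0.05
    seed: int = 0


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write TSVs plus ``summary.json``.

    Returns the summary dict.  Deterministic: two runs with the same
    config and seed produce byte-identical summaries.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t_start = time.time()
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.time() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _Timer()

    try:
        with stage("load"):
            if config.simulate:
                sim = SimConfig(**{**vars(config.sim), "seed": config.seed})
                beta, sheet, annotation, reference, truth = simulate_cohort(sim)
                variants = simulate_variant_table(annotation, seed=config.seed)
                clock_set = CpGSet(
                    "age_drift_truth",
                    tuple(truth.probes.loc[truth.probes["probe_class"] == "age_drift",
                                           "probe_id"]),
                )
                cpg_sets = [clock_set] if clock_set.members else []
            else:
                from . import io_model as iom

                beta = iom.read_beta_matrix(config.beta_path)
                sheet = iom.read_sample_sheet(config.sheet_path)
                annotation = iom.read_probe_annotation(config.annotation_path)
                reference = (
                    pd.read_csv(config.reference_path, index_col=0)
                    if config.reference_path
                    else None
                )
                variants = (
                    iom.read_variant_table(config.variants_path)
                    if config.variants_path
                    else None
                )
                cpg_sets = (
                    iom.read_sets(config.cpg_sets_path, kind="cpg")
                    if config.cpg_sets_path
                    else []
                )
                truth = None

        with stage("align"):
            view = align_pairs(beta, sheet)

        with stage("icc"):
            icc_table = icc.icc_genomewide(view)
            icc_table.to_csv(out / "icc.tsv", sep="\t", index=False)

        with stage("gaps"):
            gap_table = gh.gaps_genomewide(
                beta, threshold=config.gap_threshold, out_cutoff=config.gap_out_cutoff
            )
            gap_table.to_csv(out / "gaps.tsv", sep="\t", index=False)

        cells = None
        if reference is not None and len(reference):
            with stage("deconvolve"):
                cells = cd.deconvolve_samples(beta.data, reference)
                cells.to_csv(out / "cell_estimates.tsv", sep="\t", index=False)
                composition = cd.compare_composition(cells, sheet)
                composition.to_csv(out / "cell_composition_tests.tsv", sep="\t", index=False)

        with stage("dmp"):
            design = dm.build_design(sheet, cells)
            fit = dm.fit_probes(beta, design)
            eb, moderated = dm.ebayes_moderate(fit)
            dmp_table = dm.call_dmps(moderated, beta, sheet, alpha=config.dmp_alpha)
            dmp_table.to_csv(out / "dmp.tsv", sep="\t", index=False)

        set_results = []
        with stage("settest"):
            for s in cpg_sets:
                set_results.append(
                    dm.set_rank_test(dmp_table["t_mod"], s, alternative="down")
                )
            if set_results:
                pd.DataFrame(set_results).to_csv(out / "set_tests.tsv", sep="\t", index=False)

        with stage("classify"):
            classes = assign_probe_classes(annotation, gap_table)
            calls, crosstab = call_stability(
                icc_table, classes, smp_icc=config.smp_icc, hsmp_icc=config.hsmp_icc
            )
            calls.to_csv(out / "stability_calls.tsv", sep="\t", index=False)
            crosstab.to_csv(out / "census.tsv", sep="\t")

        interrogations = {}
        with stage("interrogate"):
            for s in cpg_sets:
                _, props = interrogate_cpg_list(s, icc_table, classes, dmp_table)
                interrogations[s.name] = {k: round(v, 6) for k, v in props.items()}

        vicinity_summary = None
        if variants is not None:
            with stage("vicinity"):
                vicinity = annotate_gv_vicinity(annotation, variants)
                vicinity.to_csv(out / "gv_vicinity.tsv", sep="\t", index=False)
                vicinity_summary = int(vicinity["within_window"].sum(skipna=True))

        with stage("clinical"):
            clinical = clinical_compare(sheet)
            clinical.to_csv(out / "clinical_tests.tsv", sep="\t", index=False)

        summary = {
            "seed": config.seed,
            "n_probes": int(beta.shape[0]),
            "n_samples": int(beta.shape[1]),
            "n_pairs": int(view.n_pairs),
            "excluded_subjects": list(view.excluded),
            "n_smp": int(calls["is_smp"].sum()),
            "n_hsmp": int(calls["is_hsmp"].sum()),
            "n_dmp": int(dmp_table["is_dmp"].sum()),
            "n_predicted_gv": int(gap_table["predicted_gv"].sum()),
            "census": {
                cls: {b: int(crosstab.loc[cls, b]) for b in STABILITY_ORDER}
                for cls in PROBE_CLASSES
            },
            "stability_proportions": {
                b: round(float((calls["stability_class"] == b).mean()), 6)
                for b in STABILITY_ORDER
            },
            "ebayes": {"d0": (None if np.isinf(eb.d0) else round(eb.d0, 6)),
                       "s0_sq": round(eb.s0_sq, 10)},
            "set_tests": [
                {"set_name": r["set_name"], "p_value": r["p_value"],
                 "alternative": r["alternative"]}
                for r in set_results
            ],
            "interrogations": interrogations,
            "n_probes_near_variant": vicinity_summary,
            "clinical": {
                row["measure"]: round(row["p_value"], 6) for _, row in clinical.iterrows()
            },
            "parameters": {
                "gap_threshold": config.gap_threshold,
                "gap_out_cutoff": config.gap_out_cutoff,
                "smp_icc": config.smp_icc,
                "hsmp_icc": config.hsmp_icc,
                "dmp_alpha": config.dmp_alpha,
            },
            "timings_s": timings,
        }
        summary_det = {k: v for k, v in summary.items() if k != "timings_s"}
        with open(out / "summary.json", "w") as fh:
            json.dump(summary_det, fh, indent=2, sort_keys=True)
        logger.info("pipeline finished in %.2fs", time.time() - t_start)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
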