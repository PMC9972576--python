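"""Synthetic paired EPIC-like cohorts with known ground truth.

The generator emulates a two-time-point peripheral-blood methylation study:
46 subjects sampled twice, 2-9 years apart (median ~7), with four probe
classes whose generating parameters are recorded in ``TruthTables``:

* ``variance_component`` — latent Gaussian ``mu_p + b_i + eps_ij`` with
  between-subject variance chosen so that ``sigma_r^2/(sigma_r^2+sigma_e^2)``
  equals a configured true ICC, clipped into [0.001, 0.999];
* ``snp_trimodal`` — Hardy-Weinberg genotypes per subject (constant across
  time points) with genotype cluster means {0.05, 0.5, 0.95};
* ``age_drift`` — variance-component baseline plus a per-year drift applied
  at T2 over the subject's sampling interval (negative by default: global
  hypomethylation with age);
* ``cell_driven`` — mixtures of a cell-type reference panel with
  per-sample Dirichlet weights, T2 weights drawn with a shifted mean to
  encode a composition change (B and CD4+ T cells up, neutrophils down).

Everything is driven by one ``numpy`` Generator seeded from the config, so
cohorts are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import BetaMatrix, ProbeAnnotation, SampleSheet, VariantTable

CELL_TYPES = ("Bcell", "CD4T", "CD8T", "NK", "Mono", "Neu")
#: blood-like mean fractions (roughly: neutrophil-dominated leukocytes)
CELL_BASE_PROPS = {"Bcell": 0.07, "CD4T": 0.15, "CD8T": 0.10, "NK": 0.05, "Mono": 0.08, "Neu": 0.55}
#: mean composition change at T2 (added to base, renormalized)
CELL_T2_SHIFT = {"Bcell": +0.02, "CD4T": +0.03, "Neu": -0.05}

GENOTYPE_MEANS = (0.05, 0.5, 0.95)
CLIP_LO, CLIP_HI = 0.001, 0.999


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Cohort-generator configuration; defaults are the study conditions."""

    n_subjects: int = 46
    n_variance_probes: int = 4000        # split evenly across icc_levels
    icc_levels: tuple[float, ...] = (0.2, 0.5, 0.8, 0.95)
    n_snp_probes: int = 500
    maf: float = 0.3
    cluster_sd: float = 0.02
    n_age_probes: int = 500
    drift_per_year: float = -0.004       # delta-beta per year at T2
    n_cell_probes: int = 300
    n_cell_types: int = 6
    n_qc_gv_probes: int = 59
    annotated_gv_fraction: float = 0.3   # of SNP probes carrying a dbSNP id
    cell_concentration: float = 50.0     # Dirichlet concentration
    noise_sd: float = 0.02               # within-subject (occasion) sd
    interval_years: tuple[int, int] = (2, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise SimulationError(f"maf must be in [0,1], got {self.maf}")
        if self.annotated_gv_fraction < 0 or self.annotated_gv_fraction > 1:
            raise SimulationError("annotated_gv_fraction must be in [0,1]")
        for t in self.icc_levels:
            if not 0.0 <= t <= 1.0:
                raise SimulationError(f"true ICC must be in [0,1], got {t}")
            if t == 1.0 and self.noise_sd > 0:
                raise SimulationError("true ICC = 1 is infeasible with noise_sd > 0")
        for n in (
            self.n_subjects,
            self.n_variance_probes,
            self.n_snp_probes,
            self.n_age_probes,
            self.n_cell_probes,
            self.n_qc_gv_probes,
        ):
            if n < 0:
                raise SimulationError("probe/subject counts must be >= 0")
        if not 1 <= self.n_cell_types <= len(CELL_TYPES):
            raise SimulationError(f"n_cell_types must be in [1,{len(CELL_TYPES)}]")


@dataclass
class TruthTables:
    """Ground truth emitted with every simulated cohort."""

    probes: pd.DataFrame          # probe_id, class, true_icc, drift_slope, marker_cell
    genotypes: pd.DataFrame       # SNP probes x subjects, minor-allele counts
    cell_weights: pd.DataFrame    # sample_id x cell types (true simplex weights)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.cell_weights.to_numpy(dtype=float)
        if w.size and (np.any(w < -1e-12) or np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-8)):
            raise SimulationError("true cell weights must be a simplex per sample")
        t = self.probes["true_icc"].dropna()
        if len(t) and ((t < 0).any() or (t > 1).any()):
            raise SimulationError("true ICC must lie in [0,1]")


def _variance_components(true_icc: float, noise_sd: float) -> tuple[float, float]:
    """(sigma_r, sigma_e) reproducing the requested ICC with sigma_e = noise_sd."""
    if true_icc == 1.0:
        return 0.05, 0.0  # noise_sd validated to be 0; keep a real subject signal
    sigma_e = noise_sd
    sigma_r = sigma_e * np.sqrt(true_icc / (1.0 - true_icc))
    return sigma_r, sigma_e


def simulate_cohort(
    config: SimConfig,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, pd.DataFrame, TruthTables]:
    """Generate one paired cohort.

    Returns (beta, sample sheet, probe annotation, cell reference matrix,
    truth tables).  Sample ids are ``<subject>_T1`` / ``<subject>_T2``;
    probes are laid out on chr1..chr22 in blocks by class.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # --- sample sheet -----------------------------------------------------
    subjects = np.array([f"S{i:03d}" for i in range(1, n + 1)])
    age_t1 = np.round(rng.uniform(25, 60, size=n), 1)
    interval = rng.integers(config.interval_years[0], config.interval_years[1] + 1, size=n)
    sex = rng.choice(SEX_CHOICES, size=n, p=[0.5, 0.5])
    smoking = rng.choice(["active", "non-smoker"], size=n, p=[0.24, 0.76])
    disease = rng.choice(["CD", "UC"], size=n, p=[36 / 46, 10 / 46])
    crp = {tp: np.round(rng.lognormal(np.log(2.6), 0.8, size=n), 2) for tp in ("T1", "T2")}
    leuko = {tp: np.round(np.clip(rng.normal(7.0, 1.5, size=n), 2.0, None), 2) for tp in ("T1", "T2")}

    rows = []
    for j, tp in enumerate(("T1", "T2")):
        for i, subj in enumerate(subjects):
            rows.append(
                {
                    "sample_id": f"{subj}_{tp}",
                    "subject_id": subj,
                    "timepoint": tp,
                    "age_years": float(age_t1[i] + (interval[i] if tp == "T2" else 0)),
                    "sex": sex[i],
                    "smoking": smoking[i],
                    "disease": disease[i],
                    "crp_mg_per_l": float(crp[tp][i]),
                    "leukocytes_e9_per_l": float(leuko[tp][i]),
                }
            )
    sheet = SampleSheet(pd.DataFrame(rows))
    sample_ids = sheet.data["sample_id"].to_numpy()

    # --- probes -----------------------------------------------------------
    blocks: list[np.ndarray] = []   # each (n_probes, 2n) in sample order T1 block then T2 block
    truth_rows: list[dict] = []
    probe_ids: list[str] = []
    counter = 0

    def new_ids(k: int, prefix: str = "cg") -> list[str]:
        nonlocal counter
        ids = [f"{prefix}{counter + i:08d}" for i in range(k)]
        counter += k
        return ids

    # variance-component probes, one sub-block per true ICC level
    n_levels = len(config.icc_levels)
    per_level = [config.n_variance_probes // n_levels] * n_levels if n_levels else []
    for extra in range(config.n_variance_probes - sum(per_level)):
        per_level[extra] += 1
    for level, m in zip(config.icc_levels, per_level):
        if m == 0:
            continue
        ids = new_ids(m)
        y1, y2 = _simulate_variance_block(rng, m, n, level, config.noise_sd)
        blocks.append(np.hstack([y1, y2]))
        probe_ids.extend(ids)
        truth_rows.extend(
            {"probe_id": p, "probe_class": "variance_component", "true_icc": level,
             "drift_slope": 0.0, "marker_cell": ""}
            for p in ids
        )

    # SNP trimodal probes (plus QC-GV probes drawn from the same model)
    n_snp_total = config.n_snp_probes + config.n_qc_gv_probes
    geno = rng.binomial(2, config.maf, size=(n_snp_total, n))
    snp_ids = new_ids(config.n_snp_probes)
    qc_ids = [f"rs{i:06d}" for i in range(config.n_qc_gv_probes)]
    means = np.asarray(GENOTYPE_MEANS)[geno]
    y1 = np.clip(means + rng.normal(0, config.cluster_sd, size=means.shape), CLIP_LO, CLIP_HI)
    y2 = np.clip(means + rng.normal(0, config.cluster_sd, size=means.shape), CLIP_LO, CLIP_HI)
    blocks.append(np.hstack([y1, y2]))
    probe_ids.extend(snp_ids + qc_ids)
    truth_rows.extend(
        {"probe_id": p, "probe_class": "snp_trimodal", "true_icc": np.nan,
         "drift_slope": 0.0, "marker_cell": ""}
        for p in snp_ids
    )
    truth_rows.extend(
        {"probe_id": p, "probe_class": "qc_gv", "true_icc": np.nan,
         "drift_slope": 0.0, "marker_cell": ""}
        for p in qc_ids
    )
    genotypes = pd.DataFrame(geno, index=pd.Index(snp_ids + qc_ids, name="probe_id"),
                             columns=subjects)

    # age-drift probes: moderate-ICC baseline plus slope * interval at T2
    if config.n_age_probes:
        ids = new_ids(config.n_age_probes)
        sigma_r, sigma_e = _variance_components(0.5, config.noise_sd)
        mu = rng.uniform(0.15, 0.85, size=(config.n_age_probes, 1))
        b = rng.normal(0, sigma_r, size=(config.n_age_probes, n))
        y1 = mu + b + rng.normal(0, sigma_e, size=(config.n_age_probes, n))
        y2 = (
            mu
            + b
            + rng.normal(0, sigma_e, size=(config.n_age_probes, n))
            + config.drift_per_year * interval[None, :]
        )
        blocks.append(np.clip(np.hstack([y1, y2]), CLIP_LO, CLIP_HI))
        probe_ids.extend(ids)
        truth_rows.extend(
            {"probe_id": p, "probe_class": "age_drift", "true_icc": np.nan,
             "drift_slope": config.drift_per_year, "marker_cell": ""}
            for p in ids
        )

    # cell-driven probes + reference panel
    cell_types = list(CELL_TYPES[: config.n_cell_types])
    base = np.array([CELL_BASE_PROPS[c] for c in cell_types])
    base = base / base.sum()
    shifted = base + np.array([CELL_T2_SHIFT.get(c, 0.0) for c in cell_types])
    shifted = np.clip(shifted, 0.01, None)
    shifted = shifted / shifted.sum()
    w1 = rng.dirichlet(base * config.cell_concentration, size=n)
    w2 = rng.dirichlet(shifted * config.cell_concentration, size=n)
    weights = pd.DataFrame(
        np.vstack([w1, w2]),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=cell_types,
    )
    reference = pd.DataFrame(index=pd.Index([], name="probe_id"), columns=cell_types, dtype=float)
    if config.n_cell_probes:
        ids = new_ids(config.n_cell_probes)
        marker = np.arange(config.n_cell_probes) % len(cell_types)
        ref = rng.uniform(0.05, 0.30, size=(config.n_cell_probes, len(cell_types)))
        ref[np.arange(config.n_cell_probes), marker] = rng.uniform(
            0.65, 0.90, size=config.n_cell_probes
        )
        reference = pd.DataFrame(ref, index=pd.Index(ids, name="probe_id"), columns=cell_types)
        mix = weights.to_numpy() @ ref.T  # samples x probes
        y = np.clip(mix.T + rng.normal(0, config.noise_sd, size=(config.n_cell_probes, 2 * n)),
                    CLIP_LO, CLIP_HI)
        blocks.append(y)
        probe_ids.extend(ids)
        truth_rows.extend(
            {"probe_id": p, "probe_class": "cell_driven", "true_icc": np.nan,
             "drift_slope": 0.0, "marker_cell": cell_types[m]}
            for p, m in zip(ids, marker)
        )

    values = np.vstack(blocks) if blocks else np.empty((0, 2 * n))
    beta = BetaMatrix(pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                                   columns=sample_ids))

    truth_probes = pd.DataFrame(truth_rows).set_index("probe_id", drop=False)
    annotation = _make_annotation(rng, truth_probes, config)
    truth = TruthTables(truth_probes, genotypes, weights, config=asdict(config))
    return beta, sheet, annotation, reference, truth


SEX_CHOICES = ["F", "M"]


def _simulate_variance_block(
    rng: np.random.Generator, m: int, n: int, true_icc: float, noise_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two (m, n) occasion matrices for one true-ICC level."""
    sigma_r, sigma_e = _variance_components(true_icc, noise_sd)
    mu = rng.uniform(0.15, 0.85, size=(m, 1))
    b = rng.normal(0, sigma_r, size=(m, n)) if sigma_r > 0 else np.zeros((m, n))
    y1 = mu + b + (rng.normal(0, sigma_e, size=(m, n)) if sigma_e > 0 else 0.0)
    y2 = mu + b + (rng.normal(0, sigma_e, size=(m, n)) if sigma_e > 0 else 0.0)
    return np.clip(y1, CLIP_LO, CLIP_HI), np.clip(y2, CLIP_LO, CLIP_HI)


def _make_annotation(
    rng: np.random.Generator, truth_probes: pd.DataFrame, config: SimConfig
) -> ProbeAnnotation:
    """Spread probes over chr1..chr22 with skewed probes-per-gene counts."""
    m = len(truth_probes)
    chroms = np.array([f"chr{(i % 22) + 1}" for i in range(m)])
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        pos[idx] = np.sort(rng.choice(np.arange(10_000, 50_000_000, 500), size=len(idx),
                                      replace=False))
    # genes: geometric-ish size distribution so probe-per-gene counts are skewed
    genes: list[str] = []
    gene_no = 0
    while len(genes) < m:
        gene_no += 1
        size = int(rng.geometric(0.25))
        genes.extend([f"GENE{gene_no:05d}"] * size)
    genes = genes[:m]
    regions = rng.choice(["TSS1500", "TSS200", "body", "5'UTR", "3'UTR"], size=m)

    is_qc = (truth_probes["probe_class"] == "qc_gv").to_numpy()
    is_snp = (truth_probes["probe_class"] == "snp_trimodal").to_numpy()
    annotated = np.zeros(m, dtype=bool)
    snp_idx = np.flatnonzero(is_snp)
    n_annot = int(round(config.annotated_gv_fraction * len(snp_idx)))
    if n_annot:
        annotated[rng.choice(snp_idx, size=n_annot, replace=False)] = True
    dbsnp = np.where(annotated, [f"rs{10_000_000 + i}" for i in range(m)], "")

    df = pd.DataFrame(
        {
            "probe_id": truth_probes["probe_id"].to_numpy(),
            "chrom": chroms,
            "pos": pos,
            "gene": genes,
            "gene_region": regions,
            "is_qc_gv": is_qc,
            "annotated_gv": annotated,
            "dbsnp_id": dbsnp,
        }
    )
    return ProbeAnnotation(df)


def simulate_variant_table(
    annotation: ProbeAnnotation, n_variants: int = 20, seed: int = 0, max_offset: int = 5000
) -> VariantTable:
    """Place known variants near randomly chosen probes (for vicinity tests)."""
    rng = np.random.default_rng(seed)
    ann = annotation.data
    picks = rng.choice(len(ann), size=min(n_variants, len(ann)), replace=False)
    offs = rng.integers(-max_offset, max_offset + 1, size=len(picks))
    df = pd.DataFrame(
        {
            "variant_id": [f"var{i:04d}" for i in range(len(picks))],
            "chrom": ann["chrom"].to_numpy()[picks],
            "pos": np.maximum(1, ann["pos"].to_numpy()[picks] + offs),
            "phenotype": rng.choice(["CD", "UC"], size=len(picks)),
        }
    )
    return VariantTable(df)


def write_truth(truth: TruthTables, out_dir: str | Path) -> dict[str, Path]:
    """Write truth tables as CSVs keyed by probe/sample id."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": out / "truth_probes.csv",
        "genotypes": out / "truth_genotypes.csv",
        "cell_weights": out / "truth_cell_weights.csv",
    }
    truth.probes.to_csv(paths["probes"], index=False)
    truth.genotypes.to_csv(paths["genotypes"], index_label="probe_id")
    truth.cell_weights.to_csv(paths["cell_weights"], index_label="sample_id")
    return paths


def read_truth(out_dir: str | Path) -> TruthTables:
    out = Path(out_dir)
    probes = pd.read_csv(out / "truth_probes.csv").fillna({"marker_cell": ""})
    probes = probes.set_index("probe_id", drop=False)
    genotypes = pd.read_csv(out / "truth_genotypes.csv", index_col="probe_id")
    weights = pd.read_csv(out / "truth_cell_weights.csv", index_col="sample_id")
    return TruthTables(probes, genotypes, weights)
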