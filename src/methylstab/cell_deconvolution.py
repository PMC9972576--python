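"""Reference-based leukocyte deconvolution by constrained projection.

Each sample's beta values over a panel of cell-type-discriminating CpGs are
projected onto the reference matrix R (CpGs x cell types) by non-negative
least squares, min_w ||y - R w||^2 s.t. w >= 0.  Raw weights are kept and a
sum-to-one normalization provides interpretable fractions; a strict simplex
fit (equality-constrained quadratic program) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_model import SampleSheet


@dataclass
class CellEstimate:
    sample_id: str | None
    raw_weights: np.ndarray
    weights: np.ndarray          # normalized to sum 1 (or raw if sum ~ 0)
    cell_types: tuple[str, ...]
    residual_norm: float


def _check_reference(reference: np.ndarray, cell_types: list[str]) -> None:
    m, c = reference.shape
    if m < c:
        raise ValueError(f"reference needs at least as many CpGs ({m}) as cell types ({c})")
    rank = np.linalg.matrix_rank(reference)
    if rank < c:
        # identify columns whose removal restores full rank
        collinear = [
            cell_types[j]
            for j in range(c)
            if np.linalg.matrix_rank(np.delete(reference, j, axis=1)) == rank
        ]
        raise ValueError(f"reference matrix is rank-deficient; collinear columns: {collinear}")


def deconvolve(
    sample_beta: np.ndarray,
    reference: pd.DataFrame | np.ndarray,
    sample_id: str | None = None,
    simplex: bool = False,
) -> CellEstimate:
    """Estimate cell-type weights for one sample.

    ``sample_beta`` is the sample's beta values over the reference CpGs, in
    the reference's row order.  With ``simplex=True`` the weights are
    additionally constrained to sum to exactly one.
    """
    if isinstance(reference, pd.DataFrame):
        cell_types = [str(c) for c in reference.columns]
        R = reference.to_numpy(dtype=float)
    else:
        R = np.asarray(reference, dtype=float)
        cell_types = [f"cell{j}" for j in range(R.shape[1])]
    y = np.asarray(sample_beta, dtype=float)
    if y.shape[0] != R.shape[0]:
        raise ValueError(f"sample has {y.shape[0]} values but reference has {R.shape[0]} CpGs")
    ok = np.isfinite(y)
    _check_reference(R[ok] if ok.sum() < y.size else R, cell_types)
    if simplex:
        c = R.shape[1]
        res = optimize.lsq_linear(
            np.vstack([R[ok], np.full((1, c), 1e6)]),
            np.concatenate([y[ok], [1e6]]),
            bounds=(0, np.inf),
        )
        w = res.x
        resid = float(np.linalg.norm(R[ok] @ w - y[ok]))
    else:
        w, resid = optimize.nnls(R[ok], y[ok])
        resid = float(resid)
    total = w.sum()
    norm = w / total if total > 1e-12 else w.copy()
    return CellEstimate(sample_id, w, norm, tuple(cell_types), resid)


def deconvolve_samples(
    beta: pd.DataFrame, reference: pd.DataFrame, simplex: bool = False
) -> pd.DataFrame:
    """Deconvolve every sample (column) of a beta matrix restricted to the
    reference CpGs; returns samples x cell types normalized weights plus
    raw weights and residual norm columns."""
    common = reference.index.intersection(beta.index)
    if len(common) < reference.shape[1]:
        raise ValueError(
            f"only {len(common)} reference CpGs found in the beta matrix; "
            f"need >= {reference.shape[1]}"
        )
    R = reference.loc[common]
    rows = []
    for sample in beta.columns:
        est = deconvolve(beta.loc[common, sample].to_numpy(), R, sample_id=str(sample),
                         simplex=simplex)
        row = {"sample_id": est.sample_id, "residual_norm": est.residual_norm}
        row.update({ct: w for ct, w in zip(est.cell_types, est.weights)})
        row.update({f"raw_{ct}": w for ct, w in zip(est.cell_types, est.raw_weights)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def compare_composition(
    estimates: pd.DataFrame,
    sheet: SampleSheet,
    cell_types: list[str] | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-cell-type T1 vs T2 comparison of normalized weights.

    Default is the two-sided Mann-Whitney U test on the two time-point
    groups; ``paired=True`` switches to the Wilcoxon signed-rank test on
    subject-matched differences.  The paired mean difference (T2 - T1,
    matched by subject) is reported either way.
    """
    meta = sheet.data.set_index("sample_id")
    est = estimates.join(meta[["subject_id", "timepoint"]], how="inner")
    if cell_types is None:
        cell_types = [
            c
            for c in estimates.columns
            if c not in ("sample_id", "residual_norm", "subject_id", "timepoint")
            and not str(c).startswith("raw_")
        ]
    g1 = est[est["timepoint"] == "T1"]
    g2 = est[est["timepoint"] == "T2"]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each timepoint needs at least 2 samples")
    wide = est.pivot_table(index="subject_id", columns="timepoint", values=cell_types,
                           aggfunc="first")
    rows = []
    for ct in cell_types:
        x1 = g1[ct].to_numpy(dtype=float)
        x2 = g2[ct].to_numpy(dtype=float)
        diff = wide[(ct, "T2")] - wide[(ct, "T1")]
        paired_mean_diff = float(diff.mean()) if diff.notna().any() else np.nan
        if paired:
            d = diff.dropna().to_numpy()
            d = d[d != 0]
            if d.size == 0:
                stat, p = np.nan, 1.0
            else:
                stat, p = stats.wilcoxon(d, alternative="two-sided")
        else:
            stat, p = stats.mannwhitneyu(x2, x1, alternative="two-sided")
        rows.append(
            {
                "cell_type": ct,
                "statistic": float(stat),
                "p_value": float(p),
                "mean_t1": float(x1.mean()),
                "mean_t2": float(x2.mean()),
                "paired_mean_diff": paired_mean_diff,
                "test": "wilcoxon_signed_rank" if paired else "mann_whitney_u",
            }
        )
    return pd.DataFrame(rows).set_index("cell_type", drop=False)
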