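"""Covariate-adjusted paired differential methylation with empirical-Bayes
variance moderation, plus a CpG-set rank (enrichment) test.

Per probe g an ordinary least-squares fit of beta on the design
(intercept, time point T2, sex, smoking, disease, cell-weight covariates)
yields a coefficient b_g, residual variance s_g^2 on d_g degrees of
freedom, and unscaled standard errors from (X'X)^-1.  The residual
variances are shrunk toward a common prior by the standard moderated-t
scheme: assuming s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_{d_g}/d_g and a scaled
inverse-chi^2 prior sigma_g^2 ~ s_0^2 d_0 / chi^2_{d_0}, the posterior
variance is

    s_post^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

and the moderated t uses s_post with d_0 + d_g degrees of freedom.  d_0 and
s_0^2 are estimated by matching moments of e_g = log s_g^2 - psi(d_g/2)
+ log(d_g/2): solve psi'(d_0/2) = var(e) - psi'(d_g/2) (d_0 = inf when the
right side is <= 0) and s_0^2 = exp(mean(e) + psi(d_0/2) - log(d_0/2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .icc_screen import bh_adjust
from .io_model import BetaMatrix, CpGSet, SampleSheet


@dataclass
class EBayesParams:
    d0: float       # prior degrees of freedom (may be inf)
    s0_sq: float    # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


@dataclass
class ProbeFit:
    """Per-probe OLS results aligned to ``probe_ids``."""

    probe_ids: pd.Index
    coef: np.ndarray             # probes x p
    stdev_unscaled: np.ndarray   # probes x p, sqrt of diag((X'X)^-1)
    s2: np.ndarray               # residual variances
    df_resid: np.ndarray         # per-probe residual df
    columns: tuple[str, ...]
    skipped: np.ndarray          # probes dropped for excess missingness


def build_design(
    sheet: SampleSheet,
    cells: pd.DataFrame | None = None,
    reference_cell: str = "Neu",
    extra_numeric: list[str] | None = None,
) -> pd.DataFrame:
    """Design matrix: intercept, T2 indicator, dummy-coded covariates and
    cell-weight columns (reference cell dropped against the intercept).

    Zero-variance columns are dropped with a warning (e.g. an all-female
    cohort loses the sex column); the result is checked to be full rank.
    ``extra_numeric`` names sample-sheet columns (e.g. CRP) appended as-is.
    """
    df = sheet.data.set_index("sample_id")
    design = pd.DataFrame(index=df.index)
    design["intercept"] = 1.0
    design["timepoint_T2"] = (df["timepoint"] == "T2").astype(float)
    for col, one in (("sex", "M"), ("smoking", "active"), ("disease", "UC")):
        if col in df.columns:
            design[f"{col}_{one}"] = (df[col] == one).astype(float)
    if cells is not None:
        cell_cols = [
            c
            for c in cells.columns
            if c not in ("sample_id", "residual_norm") and not str(c).startswith("raw_")
        ]
        keep = [c for c in cell_cols if c != reference_cell]
        if len(keep) == len(cell_cols) and len(cell_cols) > 1:
            warnings.warn(
                f"reference cell {reference_cell!r} not among {cell_cols}; dropping "
                f"{cell_cols[-1]!r} instead",
                stacklevel=2,
            )
            keep = cell_cols[:-1]
        aligned = cells.reindex(design.index)
        if aligned[keep].isna().any().any():
            raise ValueError("cell estimates missing for some samples in the sheet")
        for c in keep:
            design[f"cell_{c}"] = aligned[c].astype(float)
    for c in extra_numeric or []:
        design[c] = pd.to_numeric(df[c], errors="raise")

    zero_var = [c for c in design.columns if c != "intercept" and design[c].nunique() <= 1]
    if zero_var:
        warnings.warn(f"dropping zero-variance design column(s): {zero_var}", stacklevel=2)
        design = design.drop(columns=zero_var)

    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dependent = [
            design.columns[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank-deficient; dependent columns: {dependent}")
    return design


def fit_probes(
    beta: BetaMatrix | pd.DataFrame,
    design: pd.DataFrame,
    max_missing_frac: float = 0.2,
) -> ProbeFit:
    """Vectorized per-probe OLS of beta on the design.

    Probes with missing values are re-fit individually on their complete
    samples; probes missing more than ``max_missing_frac`` of samples (or
    with too few residual df) are skipped with a flag.
    """
    data = beta.data if isinstance(beta, BetaMatrix) else beta
    Y = data[design.index].to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    m = Y.shape[0]
    xtx_inv = np.linalg.inv(X.T @ X)
    stdev_unscaled_full = np.sqrt(np.diag(xtx_inv))

    coef = np.full((m, p), np.nan)
    stdev = np.full((m, p), np.nan)
    s2 = np.full(m, np.nan)
    dfr = np.zeros(m, dtype=int)
    skipped = np.zeros(m, dtype=bool)

    complete = np.isfinite(Y).all(axis=1)
    if complete.any():
        Yc = Y[complete]
        B = Yc @ X @ xtx_inv.T            # (m_c, p)
        resid = Yc - B @ X.T
        rss = (resid**2).sum(axis=1)
        coef[complete] = B
        stdev[complete] = stdev_unscaled_full
        s2[complete] = rss / (n - p)
        dfr[complete] = n - p

    for i in np.flatnonzero(~complete):
        ok = np.isfinite(Y[i])
        if ok.sum() < n * (1 - max_missing_frac) or ok.sum() <= p:
            skipped[i] = True
            continue
        Xi = X[ok]
        try:
            xtx_i = np.linalg.inv(Xi.T @ Xi)
        except np.linalg.LinAlgError:
            skipped[i] = True
            continue
        b = xtx_i @ Xi.T @ Y[i, ok]
        r = Y[i, ok] - Xi @ b
        coef[i] = b
        stdev[i] = np.sqrt(np.diag(xtx_i))
        dfr[i] = ok.sum() - p
        s2[i] = (r**2).sum() / dfr[i]

    return ProbeFit(
        data.index, coef, stdev, s2, dfr, tuple(design.columns), skipped
    )


def trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_ebayes_params(s2: np.ndarray, df_resid: np.ndarray | int) -> EBayesParams:
    """Method-of-moments fit of the variance prior (d0, s0^2)."""
    s2 = np.asarray(s2, dtype=float)
    dg = np.broadcast_to(np.asarray(df_resid, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (dg > 0)
    if ok.sum() < 100:
        raise ValueError(f"need >= 100 positive variances, got {int(ok.sum())}")
    z = np.log(s2[ok])
    e = z - special.digamma(dg[ok] / 2.0) + np.log(dg[ok] / 2.0)
    ebar = e.mean()
    ev = ((e - ebar) ** 2).sum() / (e.size - 1)
    rhs = ev - np.mean(special.polygamma(1, dg[ok] / 2.0))
    if rhs <= 0:
        return EBayesParams(np.inf, float(np.exp(ebar)))
    d0 = 2.0 * trigamma_inverse(rhs)
    s0_sq = np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return EBayesParams(float(d0), float(s0_sq))


def ebayes_moderate(
    fit: ProbeFit,
    coef_name: str = "timepoint_T2",
    params: EBayesParams | None = None,
) -> tuple[EBayesParams, pd.DataFrame]:
    """Moderated t-statistics for one design coefficient.

    Shrinks every probe's residual variance toward the estimated prior and
    returns a table with coef, s2, s2_post, t_mod, df_total and two-sided
    p from t(d0 + d_g).  With d0 = inf all posterior variances equal s0^2.
    """
    j = fit.columns.index(coef_name)
    if params is None:
        params = estimate_ebayes_params(fit.s2, fit.df_resid)
    d0, s0 = params.d0, params.s0_sq
    dg = fit.df_resid.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.where(np.isfinite(fit.s2), s0, np.nan)
            df_total = np.full_like(dg, np.inf)
        else:
            s2_post = (d0 * s0 + dg * fit.s2) / (d0 + dg)
            df_total = d0 + dg
        se = fit.stdev_unscaled[:, j] * np.sqrt(s2_post)
        t_mod = fit.coef[:, j] / se
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {
            "probe_id": fit.probe_ids,
            "coef_time": fit.coef[:, j],
            "s2": fit.s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_value": p,
            "skipped": fit.skipped,
        }
    ).set_index("probe_id", drop=False)
    return params, table


def call_dmps(
    moderated: pd.DataFrame,
    beta: BetaMatrix | None = None,
    sheet: SampleSheet | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """BH-adjust the moderated p-values and flag DMPs at FDR < alpha.

    When the beta matrix and sheet are supplied, the unadjusted mean
    paired difference (T2 - T1 per subject, averaged) is reported as
    ``delta_beta`` alongside the adjusted coefficient.
    """
    out = moderated.copy()
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    out["is_dmp"] = out["p_adjusted"] < alpha
    if beta is not None and sheet is not None:
        from .io_model import align_pairs

        view = align_pairs(beta, sheet)
        delta = np.nanmean(view.t2 - view.t1, axis=1)
        out["delta_beta"] = pd.Series(delta, index=view.probe_ids).reindex(out.index)
    return out


def set_rank_test(
    t_stats: pd.Series,
    cpg_set: CpGSet,
    alternative: str = "mixed",
) -> dict:
    """Rank-based CpG-set enrichment among per-probe statistics.

    Wilcoxon rank-sum of the set members' t-statistics against all other
    probes.  ``up``/``down`` test a directional shift of the set;
    ``mixed`` tests enrichment of large |t| regardless of sign.  Sets
    smaller than 5 members fall back to the exact null distribution with a
    warning.
    """
    if alternative not in ("up", "down", "mixed"):
        raise ValueError("alternative must be 'up', 'down' or 'mixed'")
    stats_clean = t_stats.dropna()
    members = [p for p in cpg_set.members if p in stats_clean.index]
    if not members:
        raise ValueError(f"set {cpg_set.name!r} has no members in the tested universe")
    in_set = stats_clean.index.isin(members)
    x = stats_clean[in_set].to_numpy()
    y = stats_clean[~in_set].to_numpy()
    method = "auto"
    if len(x) < 5:
        warnings.warn(
            f"set {cpg_set.name!r} has only {len(x)} tested members; using exact test",
            stacklevel=2,
        )
        method = "exact"
    if alternative == "mixed":
        u, p = stats.mannwhitneyu(np.abs(x), np.abs(y), alternative="greater", method=method)
    else:
        alt = "greater" if alternative == "up" else "less"
        u, p = stats.mannwhitneyu(x, y, alternative=alt, method=method)
    ranks = pd.Series(stats_clean.rank(), index=stats_clean.index)
    return {
        "set_name": cpg_set.name,
        "n_in_set": int(len(x)),
        "n_universe": int(len(stats_clean)),
        "statistic": float(u),
        "p_value": float(p),
        "median_rank": float(ranks[in_set].median()),
        "alternative": alternative,
    }
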