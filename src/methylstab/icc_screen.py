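"""Per-probe reliability screening with the two-way mixed, single-measures,
consistency intra-class correlation, ICC(C,1).

For a probes-by-(subjects x occasions) layout with n subjects and k
occasions the two-way ANOVA decomposition gives

    MS_R = k * sum_i (ybar_i. - ybar)^2 / (n - 1)      (rows = subjects)
    MS_C = n * sum_j (ybar_.j - ybar)^2 / (k - 1)      (columns = occasions)
    MS_E = (SS_tot - SS_R - SS_C) / ((n - 1)(k - 1))

    ICC(C,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

The one-sided F test of H0: ICC <= 0 uses F = MS_R / MS_E on
(n-1, (n-1)(k-1)) degrees of freedom, and the 95% confidence interval is
the standard F-based interval

    FL = F / F_{1-a/2, df1, df2},  FU = F * F_{1-a/2, df2, df1}
    CI = ((FL - 1)/(FL + k - 1), (FU - 1)/(FU + k - 1)).

Estimates are computed on raw beta values with no covariate adjustment;
negative estimates are reported as-is (classified "poor") rather than
truncated, so stability censuses are unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import PairedView

STABILITY_BINS = ("poor", "moderate", "good", "excellent")
_REL_TOL = 1e-12


@dataclass
class ICCResult:
    """ICC(C,1) estimate for one probe (or one n x k matrix)."""

    icc: float
    ci_low: float
    ci_high: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n_pairs: int
    degenerate: bool = False
    probe_id: str | None = None


def classify_icc(icc: float) -> str | float:
    """Koo-Li stability bin: poor (<0.5), moderate [0.5, 0.75),
    good [0.75, 0.9), excellent (>=0.9).  Negative estimates are poor;
    NaN stays NaN."""
    if icc is None or (isinstance(icc, float) and np.isnan(icc)):
        return np.nan
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def classify_icc_array(icc: np.ndarray) -> np.ndarray:
    """Vectorized Koo-Li binning; NaN -> NaN."""
    icc = np.asarray(icc, dtype=float)
    out = np.full(icc.shape, np.nan, dtype=object)
    finite = np.isfinite(icc)
    bins = np.digitize(icc[finite], [0.5, 0.75, 0.9])
    out[finite] = np.asarray(STABILITY_BINS, dtype=object)[bins]
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN propagates."""
    arr = np.asarray(p, dtype=float)
    if arr.size and np.nanmin(arr) < 0 or (arr.size and np.nanmax(arr) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.sum():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def icc_consistency(pairs: np.ndarray, ci_level: float = 0.95) -> ICCResult:
    """ICC(C,1) for one n x k matrix of repeated measurements.

    Rows with any missing value are dropped (complete-case); at least
    3 complete rows are required.  Degenerate inputs: zero residual with
    between-subject signal -> ICC 1, p 0, CI (1, 1); a constant matrix
    -> all-NaN result.  Both carry ``degenerate=True``.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] < 2:
        raise ValueError("pairs must be an n x k matrix with k >= 2")
    complete = ~np.isnan(pairs).any(axis=1)
    y = pairs[complete]
    n, k = y.shape
    if n < 3:
        raise ValueError(f"need >= 3 complete rows, got {n}")
    if not np.isfinite(y).all():
        raise ValueError("measurements must be finite")

    grand = y.mean()
    ss_tot = ((y - grand) ** 2).sum()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    df1, df2 = n - 1, (n - 1) * (k - 1)
    ms_r = ss_rows / df1
    ms_e = (ss_tot - ss_rows - ss_cols) / df2

    scale = max(ss_tot, 1.0)
    if ms_e <= _REL_TOL * scale:
        if ms_r <= _REL_TOL * scale:  # constant matrix: ICC undefined
            return ICCResult(np.nan, np.nan, np.nan, np.nan, df1, df2, np.nan, n, degenerate=True)
        return ICCResult(1.0, 1.0, 1.0, np.inf, df1, df2, 0.0, n, degenerate=True)

    f = ms_r / ms_e
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    p = float(stats.f.sf(f, df1, df2))
    alpha = 1.0 - ci_level
    fl = f / stats.f.isf(alpha / 2, df1, df2)
    fu = f * stats.f.isf(alpha / 2, df2, df1)
    ci_low = (fl - 1.0) / (fl + k - 1.0)
    ci_high = (fu - 1.0) / (fu + k - 1.0)
    return ICCResult(float(icc), float(ci_low), float(ci_high), float(f), df1, df2, p, n)


def icc_genomewide(
    view: PairedView,
    ci_level: float = 0.95,
    min_complete_frac: float = 0.8,
) -> pd.DataFrame:
    """Vectorized ICC(C,1) scan over every probe of a paired view (k = 2).

    Per probe, subjects with either occasion missing are dropped; probes
    with fewer than ``min_complete_frac`` of subjects complete (or < 3
    pairs) are flagged ``low_coverage`` and excluded from the BH
    adjustment.  Returns one row per probe with estimate, CI, F test,
    BH-adjusted p and Koo-Li stability class.
    """
    t1, t2 = view.t1, view.t2
    mask = np.isfinite(t1) & np.isfinite(t2)
    a = np.where(mask, t1, 0.0)
    b = np.where(mask, t2, 0.0)
    n = mask.sum(axis=1).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        grand = (a.sum(1) + b.sum(1)) / (2 * n)
        col1 = a.sum(1) / n
        col2 = b.sum(1) / n
        row_mean = (a + b) / 2.0
        ss_rows = 2.0 * (((row_mean - grand[:, None]) ** 2) * mask).sum(1)
        ss_cols = n * ((col1 - grand) ** 2 + (col2 - grand) ** 2)
        ss_tot = (((a - grand[:, None]) ** 2) * mask).sum(1) + (
            ((b - grand[:, None]) ** 2) * mask
        ).sum(1)
        df1 = n - 1.0
        df2 = n - 1.0  # (n-1)(k-1), k = 2
        ms_r = ss_rows / df1
        ms_e = (ss_tot - ss_rows - ss_cols) / df2

        scale = np.maximum(ss_tot, 1.0)
        zero_resid = ms_e <= _REL_TOL * scale
        constant = zero_resid & (ms_r <= _REL_TOL * scale)
        perfect = zero_resid & ~constant

        safe_ms_e = np.where(zero_resid, 1.0, ms_e)
        f = ms_r / safe_ms_e
        icc = (ms_r - safe_ms_e) / (ms_r + safe_ms_e)
        p = stats.f.sf(f, df1, df2)
        alpha = 1.0 - ci_level
        fl = f / stats.f.isf(alpha / 2, df1, df2)
        fu = f * stats.f.isf(alpha / 2, df2, df1)
        ci_low = (fl - 1.0) / (fl + 1.0)
        ci_high = (fu - 1.0) / (fu + 1.0)

    icc[perfect], p[perfect], f[perfect] = 1.0, 0.0, np.inf
    ci_low[perfect] = ci_high[perfect] = 1.0
    for arr in (icc, p, f, ci_low, ci_high):
        arr[constant] = np.nan

    low_cov = (n < 3) | (n < min_complete_frac * view.n_pairs)
    for arr in (icc, p, f, ci_low, ci_high):
        arr[low_cov] = np.nan

    p_adj = np.full_like(p, np.nan)
    testable = ~low_cov & ~constant
    p_adj[testable] = bh_adjust(p[testable])

    return pd.DataFrame(
        {
            "probe_id": view.probe_ids,
            "icc": icc,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "f_stat": f,
            "df1": df1.astype(int),
            "df2": df2.astype(int),
            "p_value": p,
            "p_adjusted": p_adj,
            "n_pairs": n.astype(int),
            "stability_class": classify_icc_array(icc),
            "degenerate": zero_resid | constant,
            "low_coverage": low_cov,
        }
    ).set_index("probe_id", drop=False)
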