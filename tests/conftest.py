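"""Shared fixtures and independent oracles.

The ICC oracle below computes the two-way mixed, single-measures,
consistency intra-class correlation from scratch with explicit loops over
the full ANOVA decomposition; it deliberately shares no code with the
package implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from methylstab.synthetic_data import SimConfig, simulate_cohort


def icc_oracle(y: np.ndarray) -> dict:
    """Brute-force two-way ANOVA ICC(C,1): loops, no vectorized shortcuts."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += y[i, j]
    grand /= n * k
    ss_rows = 0.0
    for i in range(n):
        row_mean = sum(y[i, j] for j in range(k)) / k
        ss_rows += k * (row_mean - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        col_mean = sum(y[i, j] for i in range(n)) / n
        ss_cols += n * (col_mean - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (y[i, j] - grand) ** 2
    ms_r = ss_rows / (n - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    return {"icc": icc, "ms_r": ms_r, "ms_e": ms_e, "f": ms_r / ms_e if ms_e > 0 else math.inf}


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared across read-only tests."""
    cfg = SimConfig(
        n_subjects=46,
        n_variance_probes=800,
        n_snp_probes=120,
        n_age_probes=150,
        n_cell_probes=120,
        n_qc_gv_probes=20,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_sheet():
    rows = []
    for i in range(1, 7):
        for tp in ("T1", "T2"):
            rows.append(
                {
                    "sample_id": f"S{i}_{tp}",
                    "subject_id": f"S{i}",
                    "timepoint": tp,
                    "age_years": 40 + i,
                    "sex": "F" if i % 2 else "M",
                    "smoking": "active" if i == 1 else "non-smoker",
                    "disease": "CD" if i < 5 else "UC",
                    "crp_mg_per_l": 2.0 + 0.1 * i,
                    "leukocytes_e9_per_l": 7.0,
                }
            )
    from methylstab.io_model import SampleSheet

    return SampleSheet(pd.DataFrame(rows))
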