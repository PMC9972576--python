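"""Detection of gap-separated beta-value clusters ("gap signals").

Probes overlapping a germline variant produce trimodal (or bimodal) beta
distributions whose clusters track the three genotypes; a probe whose
sorted sample values contain a jump larger than ``threshold`` between
successive values is flagged as a gap signal.  Probes where all groups but
the largest jointly hold fewer than ``out_cutoff`` of the samples are
deemed outlier-driven and, by default, excluded from the predicted-GV set.

Both time points are pooled by default: genotypes do not change between
samplings, so pooling doubles cluster occupancy without altering the group
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import BetaMatrix

DEFAULT_THRESHOLD = 0.05
DEFAULT_OUT_CUTOFF = 0.01


@dataclass
class GapResult:
    probe_id: str | None
    n_groups: int
    group_sizes: tuple[int, ...]
    threshold: float
    is_gap_signal: bool
    outlier_driven: bool


def hunt_gaps(
    beta_row: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    out_cutoff: float = DEFAULT_OUT_CUTOFF,
    keep_outliers: bool = False,
    probe_id: str | None = None,
    min_samples: int = 10,
) -> GapResult:
    """Gap scan of one probe's beta values.

    Sorts the non-missing values and cuts wherever the successive
    difference exceeds ``threshold``; the runs between cuts are the
    groups.  ``keep_outliers`` only affects set membership downstream
    (outlier-driven probes are always reported).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    values = np.asarray(beta_row, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        return GapResult(probe_id, 0, (), threshold, False, False)
    if n < min_samples:
        raise ValueError(f"need >= {min_samples} non-missing values, got {n}")
    srt = np.sort(values)
    cuts = np.flatnonzero(np.diff(srt) > threshold)
    bounds = np.concatenate([[0], cuts + 1, [n]])
    sizes = tuple(int(b - a) for a, b in zip(bounds[:-1], bounds[1:]))
    n_groups = len(sizes)
    is_gap = n_groups >= 2
    outlier = bool(is_gap and (n - max(sizes)) < out_cutoff * n)
    return GapResult(probe_id, n_groups, sizes, threshold, is_gap, outlier)


def gaps_genomewide(
    beta: BetaMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    out_cutoff: float = DEFAULT_OUT_CUTOFF,
    keep_outliers: bool = False,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Vectorized gap scan over all probes (all samples pooled).

    Returns one row per probe with the group census and the
    ``predicted_gv`` flag: a gap signal that is not outlier-driven (or any
    gap signal when ``keep_outliers`` is set).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    values = beta.values
    finite = np.isfinite(values)
    n_valid = finite.sum(axis=1)
    # NaN sorts to the end, so diffs within the first n_valid entries are real
    srt = np.sort(values, axis=1)
    diffs = np.diff(srt, axis=1)
    with np.errstate(invalid="ignore"):
        gap_here = diffs > threshold
    n_groups = 1 + np.where(np.isfinite(diffs), gap_here, False).sum(axis=1)
    n_groups[n_valid == 0] = 0

    m = values.shape[0]
    largest = n_valid.copy()
    multi = np.flatnonzero((n_groups >= 2) & (n_valid >= min_samples))
    group_sizes: dict[int, tuple[int, ...]] = {}
    for i in multi:
        row = srt[i, : n_valid[i]]
        cuts = np.flatnonzero(np.diff(row) > threshold)
        bounds = np.concatenate([[0], cuts + 1, [n_valid[i]]])
        sizes = tuple(int(b - a) for a, b in zip(bounds[:-1], bounds[1:]))
        group_sizes[i] = sizes
        largest[i] = max(sizes)

    usable = n_valid >= min_samples
    is_gap = usable & (n_groups >= 2)
    outlier = is_gap & ((n_valid - largest) < out_cutoff * n_valid)
    predicted = is_gap if keep_outliers else (is_gap & ~outlier)

    df = pd.DataFrame(
        {
            "probe_id": beta.probe_ids,
            "n_samples": n_valid,
            "n_groups": np.where(usable, n_groups, 0),
            "group_sizes": [
                ";".join(map(str, group_sizes.get(i, (int(n_valid[i]),) if n_valid[i] else ())))
                for i in range(m)
            ],
            "threshold": threshold,
            "is_gap_signal": is_gap,
            "outlier_driven": outlier,
            "predicted_gv": predicted,
            "usable": usable,
        }
    ).set_index("probe_id", drop=False)
    return df


def predicted_gv_set(gap_table: pd.DataFrame) -> set[str]:
    """Probe ids flagged as predicted genetic variants."""
    return set(gap_table.loc[gap_table["predicted_gv"], "probe_id"])
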