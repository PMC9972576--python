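"""Gene-set enrichment of probe lists with probe-count bias correction.

Array gene-set testing is biased: a gene covered by many probes is more
likely to contain at least one significant probe.  The test here maps
probes to genes (a gene is "significant" if any of its probes is), then
evaluates the set's significant-gene count against a Wallenius noncentral
hypergeometric null whose odds parameter is the ratio of mean probe counts
between set and non-set genes.  With equal probe coverage the odds are 1
and the test reduces to Fisher's exact (central hypergeometric).

This uses a single scalar odds per set — an approximation to the full
per-gene-weighted noncentral model; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .icc_screen import bh_adjust
from .io_model import GeneSet, ProbeAnnotation


@dataclass
class EnrichmentResult:
    set_name: str
    n_genes_in_set: int
    n_significant_genes: int
    n_significant_in_set: int
    odds: float
    p_value: float


def probe_bias_weights(annotation: ProbeAnnotation) -> pd.Series:
    """Per-gene selection-bias weight = number of probes annotated to it.

    Genes with no probes never appear (there is nothing to select), so the
    weights sum to the number of gene-annotated probes."""
    genes = annotation.data["gene"] if "gene" in annotation.data.columns else pd.Series(dtype=str)
    genes = genes.replace("", np.nan).dropna()
    return genes.value_counts().sort_index()


def _probes_to_genes(probes: Iterable[str], annotation: ProbeAnnotation) -> set[str]:
    ann = annotation.data
    sub = ann.loc[ann.index.intersection(pd.Index(probes))]
    genes = sub["gene"].replace("", np.nan).dropna()
    return set(genes)


def test_gene_set(
    significant_probes: Sequence[str],
    universe_probes: Sequence[str],
    gene_set: GeneSet,
    annotation: ProbeAnnotation,
    weights: pd.Series | None = None,
) -> EnrichmentResult:
    """Wallenius-corrected over-representation test for one gene set.

    ``significant_probes`` must be a subset of ``universe_probes``; the
    gene universe is every gene with at least one tested probe.  The
    p-value is P(X >= observed overlap) under Wallenius with the set's
    probe-count odds.
    """
    sig = set(significant_probes)
    uni = set(universe_probes)
    if not sig <= uni:
        raise ValueError("significant probes must be a subset of the universe")
    if weights is None:
        weights = probe_bias_weights(annotation)
    universe_genes = _probes_to_genes(uni, annotation)
    sig_genes = _probes_to_genes(sig, annotation)
    set_genes = set(gene_set.members) & universe_genes
    if not set_genes:
        return EnrichmentResult(gene_set.name, 0, len(sig_genes), 0, np.nan, np.nan)

    N = len(universe_genes)                       # population
    K = len(set_genes)                            # marked (in set)
    n_draw = len(sig_genes)                       # drawn (significant)
    k = len(sig_genes & set_genes)                # observed overlap

    w_set = weights.reindex(sorted(set_genes)).fillna(0)
    w_out = weights.reindex(sorted(universe_genes - set_genes)).fillna(0)
    if len(w_out) == 0 or w_out.mean() == 0 or w_set.mean() == 0:
        odds = 1.0
    else:
        odds = float(w_set.mean() / w_out.mean())

    if n_draw == 0:
        p = 1.0
    elif abs(odds - 1.0) < 1e-12:
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw))
    else:
        p = float(stats.nchypergeom_wallenius.sf(k - 1, N, K, n_draw, odds))
    return EnrichmentResult(gene_set.name, K, n_draw, k, odds, min(1.0, p))


def test_gene_sets(
    significant_probes: Sequence[str],
    universe_probes: Sequence[str],
    gene_sets: Sequence[GeneSet],
    annotation: ProbeAnnotation,
) -> pd.DataFrame:
    """Run ``test_gene_set`` for many sets and BH-adjust across them."""
    weights = probe_bias_weights(annotation)
    rows = [
        vars(test_gene_set(significant_probes, universe_probes, gs, annotation, weights))
        for gs in gene_sets
    ]
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    return df.set_index("set_name", drop=False)


def fisher_test_gene_set(
    significant_probes: Sequence[str],
    universe_probes: Sequence[str],
    gene_set: GeneSet,
    annotation: ProbeAnnotation,
) -> float:
    """Uncorrected Fisher's exact over-representation p (for comparison)."""
    universe_genes = _probes_to_genes(set(universe_probes), annotation)
    sig_genes = _probes_to_genes(set(significant_probes), annotation)
    set_genes = set(gene_set.members) & universe_genes
    if not set_genes:
        return np.nan
    k = len(sig_genes & set_genes)
    return float(
        stats.hypergeom.sf(k - 1, len(universe_genes), len(set_genes), len(sig_genes))
    )
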