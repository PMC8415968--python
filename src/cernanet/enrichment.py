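"""Over-representation analysis of gene lists against GMT gene sets.

Hypergeometric upper-tail test (the classic over-representation
statistic: probability of observing at least the seen overlap between a
gene list of size n and a set of size K inside a universe of N genes)
with Benjamini-Hochberg control across sets.  This is a generic,
self-contained replacement for web-service annotation tools: the user
supplies the gene sets.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DomainError

logger = logging.getLogger(__name__)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and min(k, K, n, N) >= 0):
        raise DomainError(
            f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    # survival function at k-1 gives the inclusive upper tail
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = list(p_values)
    if any((pi < 0 or pi > 1) for pi in p):
        raise DomainError("p-values must lie in [0, 1]")
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def overrepresentation(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided over-representation of ``gene_list`` in each gene set.

    Genes outside the universe are dropped with a warning; sets are
    intersected with the universe.  Returns one row per set (set_name,
    k, K, n, N, p, q) sorted by p ascending, ties by set name.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    genes = set(gene_list)
    outside = genes - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        genes &= universe
    rows = []
    for name in gene_sets:
        members = gene_sets[name] & universe
        k = len(genes & members)
        rows.append(
            {
                "set_name": name,
                "k": k,
                "K": len(members),
                "n": len(genes),
                "N": len(universe),
                "p": hypergeometric_tail(k, len(members), len(genes), len(universe)),
            }
        )
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    table["q"] = bh_adjust(table["p"]) if len(table) else []
    return table.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
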