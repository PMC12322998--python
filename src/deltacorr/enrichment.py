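"""Over-representation analysis (ORA) of significant delta-corr genes.

Gene sets from a user-supplied GMT are tested for enrichment of the query
(genes with q < alpha and |delta_corr| >= threshold) against a background
universe — by default all genes quantified in the cohort. The statistic is
the one-sided hypergeometric upper tail P(X >= k) for drawing k set members
in a query of size n from a universe of N genes containing K set members;
p-values are BH-adjusted across tested sets. All counts are computed after
intersecting query and sets with the background.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection
from .perm_inference import bh_adjust

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # survival function at k-1; scipy evaluates the pmf in log space
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, float(np.finfo(float).tiny)), 1.0)


def significant_genes(
    results: pd.DataFrame,
    alpha: float = 0.05,
    delta_threshold: float = 0.2,
    direction: str = "both",
) -> list[str]:
    """Query list for ORA: genes passing the FDR and effect-size gates.

    ``direction`` is "both" (default, the pooled significant list),
    "positive" (delta_corr > 0 only) or "negative".
    """
    mask = (results["q"] < alpha) & (results["delta_corr"].abs() >= delta_threshold)
    if direction == "positive":
        mask &= results["delta_corr"] > 0
    elif direction == "negative":
        mask &= results["delta_corr"] < 0
    elif direction != "both":
        raise ValueError("direction must be 'both', 'positive' or 'negative'")
    return sorted(results.loc[mask.fillna(False), "gene"].unique())


def ora(
    query: set[str] | list[str],
    collection: GeneSetCollection,
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes absent from the background are dropped (logged); sets are
    intersected with the background and skipped when empty there. Output is
    sorted by q then p.
    """
    background = set(background)
    query = set(query)
    dropped = query - background
    if dropped:
        logger.info(
            "dropping %d query genes absent from background: %s",
            len(dropped), sorted(dropped)[:10],
        )
    query &= background
    N = len(background)
    n = len(query)
    if n == 0:
        import warnings

        warnings.warn("empty query after background intersection")
        return pd.DataFrame(
            columns=["set_id", "description", "k", "K", "n", "N", "p", "q"]
        )
    rows = []
    for set_id, (desc, members) in collection:
        members_bg = members & background
        K = len(members_bg)
        if K == 0:
            logger.info("set %s has no members in background; skipped", set_id)
            continue
        k = len(members_bg & query)
        rows.append(
            {
                "set_id": set_id, "description": desc,
                "k": k, "K": K, "n": n, "N": N,
                "p": hypergeom_tail(k, K, n, N),
            }
        )
    table = pd.DataFrame(rows, columns=["set_id", "description", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return table


def enrich_results(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    background: set[str] | None = None,
    alpha: float = 0.05,
    delta_threshold: float = 0.2,
    direction: str = "both",
) -> pd.DataFrame:
    """ORA of the significant delta-corr genes of one result table.

    The default background is every gene with a defined delta_corr in the
    table (the genes quantified well enough to have been tested).
    """
    if background is None:
        background = set(results.loc[results["delta_corr"].notna(), "gene"])
    query = significant_genes(results, alpha, delta_threshold, direction)
    return ora(query, collection, background)
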