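"""Hypergeometric over-representation analysis of a query gene set.

For a query of n genes drawn from a measured universe of M genes, the
overlap k with a category of K genes is tested against the upper tail of
Hypergeometric(M, K, n); Benjamini-Hochberg correction is applied across
all tested categories.  The universe defaults to the genes measured in the
study, not the genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError
from .study import AnnotationSet


def hypergeom_enrich(
    query, annotation: AnnotationSet, universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in every category.

    Returns one record per category: overlap k, category size K, query
    size n, universe size M, raw p = P[X >= k], BH-adjusted p across the
    tested categories and ``strength`` = -log10(adj_p); sorted by adjusted
    p then category id.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ConsistencyError(
            f"query genes outside the universe: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    m_total = len(universe)
    n_query = len(query)
    rows = []
    for cid in annotation.ids():
        members = annotation.members(cid) & universe
        k = len(query & members)
        big_k = len(members)
        raw = float(stats.hypergeom.sf(k - 1, m_total, big_k, n_query))
        rows.append(
            {
                "category": cid,
                "name": annotation.name(cid),
                "overlap": k,
                "category_size": big_k,
                "query_size": n_query,
                "universe_size": m_total,
                "raw_p": min(raw, 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "category", "name", "overlap", "category_size",
            "query_size", "universe_size", "raw_p",
        ],
    )
    if len(df):
        df["adj_p"] = multipletests(df["raw_p"].to_numpy(), method="fdr_bh")[1]
        # extreme overlaps underflow the hypergeometric tail to 0.0
        df["strength"] = -np.log10(np.maximum(df["adj_p"].to_numpy(), 1e-300))
        df = df.sort_values(["adj_p", "category"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        df["adj_p"] = pd.Series(dtype=float)
        df["strength"] = pd.Series(dtype=float)
    return df
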