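"""Over-representation analysis of gene lists against gene sets.

Hypergeometric upper-tail tests of submodules or DE lists against pathway
GMT sets and cell-type marker lists (astrocyte, endothelial, microglia,
neuron, oligodendrocyte), with BH adjustment within each query. The test
universe is the set of expressed genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_adjust
from .io import GeneSet

CELL_TYPES = ("astrocyte", "endothelial", "microglia", "neuron", "oligodendrocyte")


def hypergeom_enrich(
    query: set[str], gene_set: set[str], universe: set[str]
) -> dict:
    """Upper-tail hypergeometric over-representation of ``query`` in ``gene_set``.

    p = P(overlap >= observed) drawing |query| genes from the universe with
    |set| successes; the odds ratio comes from the 2x2 table with a Haldane
    0.5 correction when a cell is zero.
    """
    query, gene_set, universe = set(query), set(gene_set), set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)}")
    gene_set = gene_set & universe
    N, K, n = len(universe), len(gene_set), len(query)
    k = len(query & gene_set)
    p = float(hypergeom.sf(k - 1, N, K, n))
    a, b = k, n - k
    c, d = K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return {
        "overlap": k,
        "query_size": n,
        "set_size": K,
        "universe_size": N,
        "p": min(max(p, np.finfo(float).tiny), 1.0),
        "odds_ratio": (a * d) / (b * c),
    }


def enrich_all(
    queries: dict[str, set[str]],
    gene_sets: list[GeneSet],
    universe: set[str],
) -> pd.DataFrame:
    """Test every (query, set) pair; BH within query; sort by q."""
    rows = []
    for qname, qgenes in queries.items():
        for gs in gene_sets:
            row = hypergeom_enrich(set(qgenes), set(gs.genes), universe)
            row.update(query=qname, set=gs.name)
            rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["query", "set", "overlap", "query_size", "set_size",
                     "universe_size", "p", "q", "odds_ratio"]
        )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for qname in queries:
        mask = table["query"] == qname
        table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    cols = ["query", "set", "overlap", "query_size", "set_size",
            "universe_size", "p", "q", "odds_ratio"]
    return table[cols].sort_values(["query", "q", "p"]).reset_index(drop=True)


def annotate_cell_types(
    submodules: dict[str, set[str]],
    marker_sets: list[GeneSet],
    universe: set[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Assign each submodule the marker set with minimal q, if q < 0.05."""
    table = enrich_all(submodules, marker_sets, universe)
    rows = []
    for name in submodules:
        sub = table[table["query"] == name]
        if sub.empty:
            rows.append((name, "unassigned", np.nan, np.nan))
            continue
        best = sub.iloc[0]
        if best["q"] < q_threshold:
            rows.append((name, best["set"], best["p"], best["q"]))
        else:
            rows.append((name, "unassigned", best["p"], best["q"]))
    return pd.DataFrame(rows, columns=["submodule", "cell_type", "p", "q"])
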