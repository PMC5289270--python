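"""Extra-edge betweenness and bottleneck enrichment on a native network.

The protocol: add each candidate (non-interacting) pair separately to the
native interaction network, measure the betweenness of the extra edge
(shortest-path traffic through it), call it a bottleneck when it ranks in
the top 10% of edge betweenness values of its augmented graph, and test
per-category bottleneck enrichment with log-odds and chi-squared
standardized residuals.

Graph primitives (connected components, Brandes edge betweenness) are
delegated to networkx; paths are unweighted hop counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "largest_connected_component",
    "edge_betweenness",
    "extra_edge_betweenness",
    "bottleneck_enrichment",
]


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component (ties: smallest node id)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(g))
    max_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == max_size]
    best = min(tied, key=lambda c: min(str(n) for n in c))
    return g.subgraph(best).copy()


def edge_betweenness(g: nx.Graph) -> dict[tuple, float]:
    """Raw edge betweenness: shortest-path counts per edge.

    Each unordered node pair contributes one unit of credit, split
    fractionally across multiple shortest paths (Brandes accumulation).
    """
    raw = nx.edge_betweenness_centrality(g, normalized=False)
    return {tuple(sorted(e, key=str)): v for e, v in raw.items()}


def extra_edge_betweenness(native: nx.Graph, candidate: tuple) -> float:
    """Betweenness of a candidate edge in native + {candidate}.

    The native graph is left unmodified.
    """
    u, v = candidate
    if u not in native or v not in native:
        raise ValueError(f"candidate endpoint missing from network: {candidate}")
    if native.has_edge(u, v):
        raise ValueError(f"candidate edge already present: {candidate}")
    aug = native.copy()
    aug.add_edge(u, v)
    eb = edge_betweenness(aug)
    return eb[tuple(sorted((u, v), key=str))]


@dataclass
class EnrichmentResult:
    """Per-category bottleneck enrichment over candidate edges."""

    table: pd.DataFrame  # category, n_edges, n_bottlenecks, fraction, log_odds, residual_p
    chi2_p: float  # overall chi-squared p (NaN when undefined)


def bottleneck_enrichment(
    native: nx.Graph,
    candidates: dict[tuple, str] | list[tuple[tuple, str]],
    top_fraction: float = 0.10,
    threshold_on: str = "augmented",
) -> EnrichmentResult:
    """Bottleneck calls and per-category enrichment for candidate edges.

    Each candidate is added separately to the native network; it is a
    bottleneck when its betweenness reaches the (1 - top_fraction)
    quantile of the edge betweenness values of that augmented graph
    (``threshold_on="native"`` instead uses the native graph's quantile,
    computed once).  Per category the enrichment is
    log2(observed bottleneck fraction / top_fraction); the category x
    bottleneck contingency is tested by chi-squared with standardized
    residual p-values.
    """
    if isinstance(candidates, dict):
        items = list(candidates.items())
    else:
        items = list(candidates)
    if not items:
        raise ValueError("no candidate edges")

    native_thr = None
    if threshold_on == "native":
        vals = np.array(list(edge_betweenness(native).values()))
        native_thr = np.quantile(vals, 1.0 - top_fraction)

    rows = []
    for edge, category in items:
        u, v = edge
        if u not in native or v not in native or native.has_edge(u, v):
            logger.warning("skipping unusable candidate %s", edge)
            continue
        aug = native.copy()
        aug.add_edge(u, v)
        eb = edge_betweenness(aug)
        value = eb[tuple(sorted((u, v), key=str))]
        if threshold_on == "augmented":
            thr = np.quantile(np.array(list(eb.values())), 1.0 - top_fraction)
        else:
            thr = native_thr
        rows.append(
            {
                "edge": tuple(sorted((u, v), key=str)),
                "category": category,
                "betweenness": value,
                "bottleneck": bool(value >= thr),
            }
        )
    per_edge = pd.DataFrame(rows)
    if per_edge.empty:
        raise ValueError("no usable candidate edges")

    cats = []
    for cat, sub in per_edge.groupby("category"):
        n = len(sub)
        b = int(sub["bottleneck"].sum())
        frac = b / n
        log_odds = math.log2(frac / top_fraction) if b > 0 else float("-inf")
        cats.append(
            {
                "category": cat,
                "n_edges": n,
                "n_bottlenecks": b,
                "fraction": frac,
                "expected_fraction": top_fraction,
                "log_odds": log_odds,
            }
        )
    table = pd.DataFrame(cats)

    # chi-squared on category x bottleneck, with standardized residuals
    if table.shape[0] < 2 or per_edge["bottleneck"].nunique() < 2:
        logger.warning("chi-squared undefined: need >= 2 categories and both outcomes")
        table["residual_p"] = float("nan")
        chi2_p = float("nan")
    else:
        cont = pd.crosstab(per_edge["category"], per_edge["bottleneck"])
        chi2, chi2_p, _, expected = sps.chi2_contingency(cont)
        row_frac = cont.sum(axis=1).to_numpy() / cont.to_numpy().sum()
        col_frac = cont.sum(axis=0).to_numpy() / cont.to_numpy().sum()
        denom = np.sqrt(
            expected * (1 - row_frac)[:, None] * (1 - col_frac)[None, :]
        )
        resid = (cont.to_numpy() - expected) / denom
        p_res = 2.0 * sps.norm.sf(np.abs(resid))
        # report the residual p of the bottleneck=True column per category
        col_idx = list(cont.columns).index(True)
        res_map = dict(zip(cont.index, p_res[:, col_idx]))
        table["residual_p"] = table["category"].map(res_map)
    return EnrichmentResult(table=table, chi2_p=float(chi2_p) if chi2_p == chi2_p else float("nan"))
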