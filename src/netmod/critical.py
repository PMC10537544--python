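"""Median-centrality filtering to a critical subnetwork, and hub selection.

The critical network is obtained by repeated passes of a conjunctive median
filter: a node survives a pass only if its degree AND betweenness AND
closeness each strictly exceed that metric's median over the current graph.
Centralities are recomputed on the filtered graph before every pass, and by
default each pass keeps only the largest connected component.

Hub genes are the intersection of the top-k rankings of the three
centralities, with all ties at the rank-k boundary included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph import centralities, induced_subgraph

logger = logging.getLogger(__name__)

__all__ = ["FilterConfig", "HubConfig", "median_filter_step", "build_critical_pin",
           "select_hubs"]

METRICS = ("degree", "betweenness", "closeness")


@dataclass(frozen=True)
class FilterConfig:
    passes: int = 2
    lcc_only: bool = True

    def __post_init__(self) -> None:
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


@dataclass(frozen=True)
class HubConfig:
    k: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def median_filter_step(g: nx.Graph) -> set[str]:
    """Nodes whose degree, betweenness and closeness all strictly exceed the medians.

    Medians are taken over all current nodes (even-length median = mean of the
    middle two).  Raises ``ValueError`` naming the degenerate metric(s) when no
    node passes — e.g. on vertex-transitive graphs where every metric is
    constant and nothing strictly exceeds its own median.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("median_filter_step: need >= 3 nodes")
    tab = centralities(g)
    medians = {m: float(np.median(tab[m].to_numpy())) for m in METRICS}
    mask = np.ones(len(tab), dtype=bool)
    for m in METRICS:
        mask &= tab[m].to_numpy() > medians[m]
    survivors = set(tab.index[mask])
    if not survivors:
        degenerate = [m for m in METRICS if not (tab[m].to_numpy() > medians[m]).any()]
        raise ValueError(
            "median_filter_step: no node exceeds all three medians"
            + (f"; degenerate metric(s): {', '.join(degenerate)}" if degenerate else "")
        )
    return survivors


def build_critical_pin(g: nx.Graph, cfg: FilterConfig = FilterConfig()) -> tuple[nx.Graph, pd.DataFrame]:
    """Iterate the median filter ``cfg.passes`` times over ``g``.

    Returns the final graph and a per-pass report (pass 0 is the input) with
    node/edge counts and the medians applied at each pass.  If a later pass
    empties the graph or leaves fewer than 3 nodes, iteration stops and the
    pre-pass graph is returned with a warning; emptiness on the very first
    pass propagates as an error.
    """
    current = g
    rows = [{"pass": 0, "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges(),
             "median_degree": np.nan, "median_betweenness": np.nan, "median_closeness": np.nan}]
    for i in range(1, cfg.passes + 1):
        tab = centralities(current)
        medians = {m: float(np.median(tab[m].to_numpy())) for m in METRICS}
        try:
            keep = median_filter_step(current)
            nxt = induced_subgraph(current, keep, lcc_only=cfg.lcc_only)
        except ValueError as exc:
            if i == 1:
                raise
            logger.warning("build_critical_pin: pass %d degenerate (%s); returning pass-%d graph",
                           i, exc, i - 1)
            break
        current = nxt
        rows.append({"pass": i, "n_nodes": current.number_of_nodes(),
                     "n_edges": current.number_of_edges(),
                     "median_degree": medians["degree"],
                     "median_betweenness": medians["betweenness"],
                     "median_closeness": medians["closeness"]})
        if current.number_of_nodes() < 3 and i < cfg.passes:
            logger.warning("build_critical_pin: pass %d left %d nodes; stopping early",
                           i, current.number_of_nodes())
            break
    return current, pd.DataFrame(rows)


def select_hubs(g: nx.Graph, cfg: HubConfig = HubConfig()) -> set[str]:
    """Intersection of the top-k node rankings of degree, betweenness and closeness.

    Each metric's top-k set includes every node tied with the k-th largest
    value, so the result is deterministic and invariant to node relabeling.
    An empty intersection is allowed (logged).
    """
    if g.number_of_nodes() < cfg.k:
        raise ValueError(f"select_hubs: graph has {g.number_of_nodes()} nodes, need >= k={cfg.k}")
    tab = centralities(g)
    hubs: set[str] | None = None
    for m in METRICS:
        vals = tab[m].sort_values(ascending=False)
        cutoff = vals.iloc[cfg.k - 1]
        top = set(vals.index[vals >= cutoff])
        hubs = top if hubs is None else hubs & top
    assert hubs is not None
    if not hubs:
        logger.info("select_hubs: no node is in the top-%d of all three centralities", cfg.k)
    return hubs
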