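"""Graph I/O, centralities and topological diagnostics for interaction networks.

The network model throughout the package is an undirected simple graph over
gene symbols (:class:`networkx.Graph`), with an optional per-edge
``confidence`` attribute in [0, 1].  This module covers reading STRING-style
weighted edge lists, induced subgraphs, the three node centralities used for
network filtering (degree, betweenness, closeness), the summary metrics
reported for protein-interaction networks (clustering coefficient, diameter,
radius, centralization, shortest-path count, characteristic path length,
heterogeneity), the degree distribution with a log-log power-law fit, and the
shortest-path-length distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
from scipy import stats

logger = logging.getLogger(__name__)

CONFIDENCE_SCALES = ("unit", "string1000")

__all__ = [
    "CONFIDENCE_SCALES",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "write_gene_list",
    "induced_subgraph",
    "largest_connected_component",
    "centralities",
    "TopologySummary",
    "topology_summary",
    "degree_distribution",
    "PowerLawFit",
    "fit_power_law",
    "path_length_distribution",
]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    min_confidence: float = 0.0,
    scale: str = "unit",
    header: bool = False,
) -> nx.Graph:
    """Read a TSV edge list into a simple undirected graph.

    Expected columns: ``node_a``, ``node_b`` and an optional confidence
    column.  Self-loops are dropped, duplicate pairs are merged keeping the
    maximum confidence, and only edges with confidence >= ``min_confidence``
    are retained.  ``scale="string1000"`` interprets scores on the 0-1000
    integer scale used by STRING combined scores and rescales them by /1000;
    the scale is never auto-detected.

    Parameters
    ----------
    path
        TSV file; tab-separated, whitespace-separated accepted as fallback.
    min_confidence
        Retention threshold on the unit scale, in [0, 1].
    scale
        ``"unit"`` (scores already in [0, 1]) or ``"string1000"``.
    header
        Skip the first line.
    """
    if scale not in CONFIDENCE_SCALES:
        raise ValueError(f"unknown confidence scale {scale!r}; expected one of {CONFIDENCE_SCALES}")
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    path = Path(path)
    hi = 1000.0 if scale == "string1000" else 1.0

    best: dict[tuple[str, str], float | None] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, found {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                continue
            conf: float | None = None
            if len(fields) == 3:
                try:
                    raw = float(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed confidence {fields[2]!r}") from exc
                if not 0.0 <= raw <= hi:
                    raise ValueError(
                        f"{path}:{lineno}: confidence {raw} outside [0, {hi:g}] for scale {scale!r}"
                    )
                conf = raw / hi
            key = (a, b) if a <= b else (b, a)
            if key not in best:
                best[key] = conf
            elif best[key] is None or conf is None:
                # an unscored row keeps the edge unconditionally
                best[key] = None
            else:
                best[key] = max(best[key], conf)

    g = nx.Graph()
    for (a, b), conf in best.items():
        if conf is None or conf >= min_confidence:
            if conf is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, confidence=conf)
    return g


def write_edge_list(g: nx.Graph, path: str | Path, header: bool = True) -> None:
    """Write the graph as a TSV edge list (``node_a\\tnode_b[\\tcombined_score]``)."""
    path = Path(path)
    scored = any("confidence" in d for _, _, d in g.edges(data=True))
    with path.open("w") as fh:
        if header:
            cols = ["node_a", "node_b"] + (["combined_score"] if scored else [])
            fh.write("\t".join(cols) + "\n")
        for a, b, d in sorted(g.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = (a, b) if a <= b else (b, a)
            if scored:
                fh.write(f"{a}\t{b}\t{d.get('confidence', 1.0):g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list; ``#`` comments and blanks ignored."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g_ in sorted(genes):
            fh.write(g_ + "\n")


# ---------------------------------------------------------------------------
# Subgraphs
# ---------------------------------------------------------------------------

def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Largest connected component; ties broken by lexicographically smallest member."""
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(comps[0]).copy()


def induced_subgraph(g: nx.Graph, keep: Iterable[str], lcc_only: bool = False) -> nx.Graph:
    """Induced subgraph on ``keep`` ∩ nodes, optionally restricted to the LCC.

    Symbols in ``keep`` that are not graph nodes are ignored with a warning.
    An empty result raises ``ValueError`` (a degenerate filter upstream).
    """
    keep = set(keep)
    unknown = keep - set(g.nodes)
    if unknown:
        logger.warning("induced_subgraph: %d symbols not in graph (e.g. %s)",
                       len(unknown), sorted(unknown)[:5])
    sub = g.subgraph(keep & set(g.nodes)).copy()
    if sub.number_of_nodes() == 0:
        raise ValueError("induced subgraph is empty: the node filter removed every node")
    if lcc_only:
        sub = largest_connected_component(sub)
    return sub


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------

def centralities(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness and closeness centralities.

    Betweenness is Brandes' pair-dependency sum normalized by (n-1)(n-2)/2
    with endpoints excluded.  Closeness follows the reachable-average
    convention: (number of reachable nodes) / (sum of distances to them),
    0 for isolated nodes.  Returns a DataFrame indexed by node with columns
    ``degree``, ``betweenness``, ``closeness``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("centralities: empty graph")
    bet = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g, wf_improved=False)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [g.degree(v) for v in nodes],
            "betweenness": [bet[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


# ---------------------------------------------------------------------------
# Topology summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologySummary:
    """The standard network-parameter set reported for an interaction network."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    diameter: int
    radius: int
    centralization: float
    shortest_path_count: int
    characteristic_path_length: float
    heterogeneity: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Number of nodes": self.n_nodes,
                "Number of edges": self.n_edges,
                "Clustering coefficient": self.clustering_coefficient,
                "Network diameter": self.diameter,
                "Network radius": self.radius,
                "Network centralization": self.centralization,
                "Shortest paths": self.shortest_path_count,
                "Characteristic path length": self.characteristic_path_length,
                "Network heterogeneity": self.heterogeneity,
            }
        )


def _distance_matrix(g: nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf where unreachable)."""
    adj = nx.to_scipy_sparse_array(g, nodelist=list(nodes), format="csr")
    return csgraph.shortest_path(adj, method="D", directed=False, unweighted=True)


def topology_summary(g: nx.Graph) -> TopologySummary:
    """Compute the summary metric set for ``g``.

    - clustering coefficient: mean local coefficient over nodes with degree >= 2
      (degree < 2 excluded, not counted as zero);
    - diameter / radius: max / min eccentricity over the largest connected
      component (a warning is logged for disconnected input);
    - centralization: (n/(n-2)) * (max_degree/(n-1) - density), clipped to [0, 1];
    - shortest_path_count: ordered node pairs at finite distance;
    - characteristic path length: mean distance over those pairs;
    - heterogeneity: sd(degree)/mean(degree) (population sd).
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("topology_summary: empty graph")
    degs = np.array([d for _, d in g.degree()], dtype=float)

    local = nx.clustering(g)
    eligible = [v for v in g.nodes if g.degree(v) >= 2]
    cc = float(np.mean([local[v] for v in eligible])) if eligible else 0.0

    if not nx.is_connected(g):
        logger.warning("topology_summary: graph is disconnected; diameter/radius use the largest component")
    lcc = largest_connected_component(g)
    if lcc.number_of_nodes() > 1:
        ecc = nx.eccentricity(lcc)
        diameter = int(max(ecc.values()))
        radius = int(min(ecc.values()))
    else:
        diameter = radius = 0

    if n < 3:
        logger.warning("topology_summary: centralization undefined for n < 3; reporting 0")
        centralization = 0.0
    else:
        density = 2.0 * g.number_of_edges() / (n * (n - 1))
        centralization = (n / (n - 2.0)) * (degs.max() / (n - 1.0) - density)
        centralization = float(min(1.0, max(0.0, centralization)))

    dist = _distance_matrix(g, sorted(g.nodes))
    finite = np.isfinite(dist) & (dist > 0)
    spc = int(finite.sum())
    cpl = float(dist[finite].mean()) if spc else 0.0

    mean_deg = degs.mean()
    het = float(degs.std(ddof=0) / mean_deg) if mean_deg > 0 else 0.0

    return TopologySummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        clustering_coefficient=cc,
        diameter=diameter,
        radius=radius,
        centralization=centralization,
        shortest_path_count=spc,
        characteristic_path_length=cpl,
        heterogeneity=het,
    )


# ---------------------------------------------------------------------------
# Degree distribution & power-law fit
# ---------------------------------------------------------------------------

def degree_distribution(g: nx.Graph) -> pd.DataFrame:
    """Histogram of node degrees restricted to k >= 1, as columns ``k``, ``count``."""
    if g.number_of_nodes() == 0:
        raise ValueError("degree_distribution: empty graph")
    degs = [d for _, d in g.degree() if d >= 1]
    if not degs:
        raise ValueError("degree_distribution: all nodes are isolated")
    ks, counts = np.unique(degs, return_counts=True)
    return pd.DataFrame({"k": ks.astype(int), "count": counts.astype(int)})


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log OLS fit of a degree histogram: count ≈ a * k^(-gamma)."""

    a: float
    gamma: float
    r2_log: float


def fit_power_law(dist: pd.DataFrame | Sequence[tuple[int, int]]) -> PowerLawFit:
    """Ordinary least squares of ln(count) on ln(k) over the raw histogram.

    No binning and no maximum-likelihood fitting: this is the straight-line
    fit on the log-log degree plot, matching the ``y = a·x^b`` equations that
    network-analysis plugins report.  Requires >= 3 distinct degrees with
    positive counts.
    """
    if isinstance(dist, pd.DataFrame):
        ks = dist["k"].to_numpy(dtype=float)
        counts = dist["count"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(dist), dtype=float)
        ks, counts = arr[:, 0], arr[:, 1]
    mask = (ks >= 1) & (counts > 0)
    ks, counts = ks[mask], counts[mask]
    if len(ks) < 3:
        raise ValueError(f"fit_power_law: need >= 3 positive-count degree points, got {len(ks)}")
    res = stats.linregress(np.log(ks), np.log(counts))
    return PowerLawFit(a=float(math.exp(res.intercept)), gamma=float(-res.slope),
                       r2_log=float(res.rvalue**2))


# ---------------------------------------------------------------------------
# Path-length distribution
# ---------------------------------------------------------------------------

def path_length_distribution(g: nx.Graph) -> pd.DataFrame:
    """Ordered-pair counts per shortest-path length, columns ``distance``, ``count``.

    Counts cover all ordered pairs at finite distance, so they sum to the
    shortest-path count of :func:`topology_summary` on the same graph.  A
    warning is logged for disconnected input.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("path_length_distribution: empty graph")
    if not nx.is_connected(g):
        logger.warning("path_length_distribution: graph is disconnected; "
                       "unreachable pairs are excluded")
    dist = _distance_matrix(g, sorted(g.nodes))
    finite = dist[np.isfinite(dist) & (dist > 0)].astype(int)
    if finite.size == 0:
        return pd.DataFrame({"distance": [], "count": []}, dtype=int)
    ds, counts = np.unique(finite, return_counts=True)
    return pd.DataFrame({"distance": ds.astype(int), "count": counts.astype(int)})
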