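"""Molecular Complex Detection (MCODE) implemented from its published
three-stage definition: vertex weighting, greedy complex prediction, and
post-processing.

Stage 1 weights each vertex by the product of the highest k-core level of its
closed neighborhood and the density of that k-core (the core-clustering
coefficient).  Stage 2 seeds complexes from the highest-weight unvisited
vertex and grows them breadth-first over unvisited neighbors whose weight is
within ``node_score_cutoff`` (as a fraction) of the seed weight.  Stage 3
discards complexes without a k-core of the configured order, optionally trims
singly-connected members ("haircut"), and scores each complex as
density x node count.  Modules here pass only with score strictly above 5.

A known property of the greedy expansion is that equally dense regions joined
by a bridge edge can merge into one complex: the bridge endpoints inherit the
full weight of their dense neighborhood core, so both sides clear the seed's
inclusion threshold.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, replace

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["McodeConfig", "ModuleResult", "vertex_weights", "find_complexes",
           "postprocess", "rank_and_filter", "detect_modules"]


@dataclass(frozen=True)
class McodeConfig:
    """MCODE parameters.

    Defaults are the plugin's standard advanced options: degree cutoff 2,
    k-core filter 2, node score cutoff 0.2, haircut on, fluff off, and the
    strictly-greater-than-5 module score filter.
    """

    degree_cutoff: int = 2
    kcore_filter: int = 2
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    min_module_score: float = 5.0

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0:
            raise ValueError("degree_cutoff must be >= 0")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")


@dataclass(frozen=True)
class ModuleResult:
    """A detected complex: members, loop-free density 2E/(n(n-1)), and
    score = density x n, with the seed vertex it grew from."""

    members: frozenset[str]
    density: float
    score: float
    seed: str
    rank: int | None = None


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(g: nx.Graph, cfg: McodeConfig = McodeConfig()) -> dict[str, float]:
    """Core-clustering weight of every vertex.

    For v with degree < ``degree_cutoff`` the weight is 0.  Otherwise, with H
    the subgraph induced on v and its neighbors and K the highest k-core of H,
    weight(v) = k_max(H) x density(K).
    """
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < cfg.degree_cutoff:
            weights[v] = 0.0
            continue
        h = g.subgraph(set(g.neighbors(v)) | {v})
        cores = nx.core_number(h)
        k_max = max(cores.values())
        core = h.subgraph([u for u, c in cores.items() if c >= k_max])
        weights[v] = k_max * _density(core)
    return weights


def find_complexes(
    g: nx.Graph, weights: dict[str, float], cfg: McodeConfig = McodeConfig()
) -> list[ModuleResult]:
    """Greedy complex prediction (pre-post-processing).

    Vertices are taken as seeds in decreasing weight order (ties broken
    lexicographically).  From each unvisited seed, a breadth-first expansion
    includes unvisited neighbors with weight >= seed_weight x
    (1 - node_score_cutoff); inclusion uses >= so threshold ties join the
    complex.  Included vertices are marked visited.  Complexes of >= 2 nodes
    are emitted.
    """
    missing = set(g.nodes) - set(weights)
    if missing:
        raise ValueError(f"find_complexes: weights missing for {len(missing)} nodes")
    visited: set[str] = set()
    complexes: list[ModuleResult] = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], v)):
        if seed in visited:
            continue
        threshold = weights[seed] * (1.0 - cfg.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        queue = deque([seed])
        while queue:
            u = queue.popleft()
            for nb in sorted(g.neighbors(u)):
                if nb not in visited and weights[nb] >= threshold:
                    visited.add(nb)
                    members.add(nb)
                    queue.append(nb)
        if len(members) >= 2:
            sub = g.subgraph(members)
            d = _density(sub)
            complexes.append(ModuleResult(members=frozenset(members), density=d,
                                          score=d * len(members), seed=seed))
    return complexes


def _haircut(sub: nx.Graph) -> nx.Graph:
    """Iteratively remove members with fewer than 2 intra-module neighbors."""
    sub = sub.copy()
    while True:
        drop = [v for v in sub.nodes if sub.degree(v) < 2]
        if not drop:
            return sub
        sub.remove_nodes_from(drop)


def postprocess(
    modules: list[ModuleResult], g: nx.Graph, cfg: McodeConfig = McodeConfig()
) -> list[ModuleResult]:
    """Filter and trim predicted complexes.

    Complexes not containing a ``kcore_filter``-core are discarded.  With
    haircut on, singly-connected members are removed iteratively; density and
    score are then recomputed and complexes reduced below 2 nodes are dropped.
    With fluff on, neighbors whose closed-neighborhood density exceeds the
    node score cutoff are appended after the haircut; fluffed modules may
    overlap.
    """
    out: list[ModuleResult] = []
    for mod in modules:
        sub = g.subgraph(mod.members)
        if cfg.kcore_filter > 0 and nx.k_core(sub, cfg.kcore_filter).number_of_nodes() == 0:
            continue
        if cfg.haircut:
            sub = _haircut(sub)
        if sub.number_of_nodes() < 2:
            continue
        members = set(sub.nodes)
        if cfg.fluff:
            fringe = {nb for v in members for nb in g.neighbors(v)} - members
            for nb in fringe:
                hood = g.subgraph(set(g.neighbors(nb)) | {nb})
                if _density(hood) > cfg.node_score_cutoff:
                    members.add(nb)
            sub = g.subgraph(members)
        d = _density(sub)
        out.append(replace(mod, members=frozenset(members), density=d,
                           score=d * sub.number_of_nodes()))
    return out


def rank_and_filter(
    modules: list[ModuleResult], cfg: McodeConfig = McodeConfig()
) -> list[ModuleResult]:
    """Keep modules with score strictly above ``min_module_score`` and rank them.

    Sorted descending by score, ties by larger size then lexicographic seed;
    ranks are assigned from 1.
    """
    kept = [m for m in modules if m.score > cfg.min_module_score]
    kept.sort(key=lambda m: (-m.score, -len(m.members), m.seed))
    return [replace(m, rank=i) for i, m in enumerate(kept, start=1)]


def detect_modules(g: nx.Graph, cfg: McodeConfig = McodeConfig()) -> list[ModuleResult]:
    """Full MCODE pass: weights -> complexes -> post-processing -> score filter."""
    weights = vertex_weights(g, cfg)
    complexes = find_complexes(g, weights, cfg)
    return rank_and_filter(postprocess(complexes, g, cfg), cfg)
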