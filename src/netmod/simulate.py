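"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the classes of real input the analysis consumes —
scale-free interaction graphs (preferential attachment), graphs with planted
dense modules, two-group log2 expression matrices with planted fold-changes,
overlapping pseudo-database target lists, and GMT collections with planted
enriched terms — and return the exact truth alongside each artifact.

A single integer seed drives a named, decoupled pseudo-random stream per
generator, so changing one input family never perturbs the others.
``generate_bundle`` ties the families together over one symbol universe
(planted differentially expressed genes contain the designated shared
targets; the interaction graph lives on the shared genes plus a halo, with
near-cliques planted among them) so a full pipeline run has recoverable
ground truth at every stage.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import GeneSetCollection, write_gmt
from .genesets import GeneSet, union_sets
from .graph import write_edge_list, write_gene_list

logger = logging.getLogger(__name__)

__all__ = ["gen_scale_free", "gen_planted_modules", "gen_expression",
           "gen_target_sets", "gen_gmt", "SimSpec", "generate_bundle"]

_STREAMS = {"graph": 11, "modules": 23, "expression": 37, "targets": 41,
            "gmt": 53, "bundle": 67}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _symbols(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Graphs
# ---------------------------------------------------------------------------

def gen_scale_free(n: int, m: int, seed: int = 0,
                   nodes: Sequence[str] | None = None,
                   rng: np.random.Generator | None = None) -> nx.Graph:
    """Preferential-attachment graph grown from an (m+1)-clique.

    Each of the remaining n-m-1 vertices attaches to m distinct existing
    vertices chosen with probability proportional to current degree, so the
    result is connected with exactly m(n-m-1) + C(m+1, 2) edges and an
    approximately power-law degree distribution.
    """
    if not (n > m >= 1):
        raise ValueError(f"gen_scale_free: need n > m >= 1, got n={n}, m={m}")
    if nodes is None:
        nodes = _symbols(n)
    elif len(nodes) != n:
        raise ValueError("gen_scale_free: len(nodes) must equal n")
    rng = rng if rng is not None else _rng(seed, "graph")

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(itertools.combinations(nodes[: m + 1], 2))
    # one entry per incident edge end: sampling uniformly == degree-proportional
    repeated: list[str] = [v for e in g.edges for v in e]
    for v in nodes[m + 1:]:
        targets: set[str] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in sorted(targets):  # stable order across processes
            g.add_edge(v, t)
            repeated.extend((v, t))
    return g


def gen_planted_modules(
    n_background: int = 300,
    p_background: float = 0.01,
    modules: Sequence[tuple[int, float, int]] = ((8, 1.0, 2), (7, 1.0, 2), (6, 1.0, 2)),
    seed: int = 0,
) -> tuple[nx.Graph, list[set[str]]]:
    """Sparse random background with embedded near-cliques and bridge edges.

    Each module spec is ``(size, internal_density, n_attach)``: a fresh set of
    ``size`` vertices whose internal pairs are present with probability
    ``internal_density`` (topped up to keep the module connected), attached to
    the background by ``n_attach`` bridge edges.  Returns the graph and the
    exact planted node sets.
    """
    rng = _rng(seed, "modules")
    bg_nodes = _symbols(n_background, prefix="B")
    g = nx.Graph()
    g.add_nodes_from(bg_nodes)
    iu, ju = np.triu_indices(n_background, k=1)
    mask = rng.random(len(iu)) < p_background
    g.add_edges_from((bg_nodes[i], bg_nodes[j]) for i, j in zip(iu[mask], ju[mask]))

    truths: list[set[str]] = []
    for idx, (size, density, attach) in enumerate(modules, start=1):
        if size < 3:
            raise ValueError("gen_planted_modules: module sizes must be >= 3")
        members = [f"M{idx}_{i:02d}" for i in range(size)]
        if any(set(members) & t for t in truths):
            raise ValueError("gen_planted_modules: planted sets overlap")
        g.add_nodes_from(members)
        for a, b in itertools.combinations(members, 2):
            if density >= 1.0 or rng.random() < density:
                g.add_edge(a, b)
        sub = g.subgraph(members)
        comps = list(nx.connected_components(sub))
        for c1, c2 in zip(comps, comps[1:]):  # stitch sparse modules together
            g.add_edge(sorted(c1)[0], sorted(c2)[0])
        for _ in range(attach):
            g.add_edge(members[rng.integers(size)], bg_nodes[rng.integers(n_background)])
        truths.append(set(members))
    return g, truths


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(
    n_genes: int = 2000,
    n1: int = 10,
    n2: int = 10,
    de_fraction: float = 0.1,
    lfc: float = 2.0,
    sigma: float = 1.0,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    de_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, set[str]]]:
    """Two-group log2 expression matrix with planted fold-changes.

    Baseline per-gene means are Normal(7, 1) on the log2 scale; a planted
    fraction of genes is shifted by +/-``lfc`` in group 1 ("tumor"), half up
    and half down, and i.i.d. Normal(0, sigma) noise is added everywhere.
    Returns (matrix, sample->group labels, truth {"up": set, "down": set}).
    ``de_genes`` overrides the random choice of planted genes.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("gen_expression: need >= 2 samples per group")
    rng = _rng(seed, "expression")
    if genes is None:
        genes = _symbols(n_genes)
    elif len(genes) != n_genes:
        raise ValueError("gen_expression: len(genes) must equal n_genes")
    genes = list(genes)

    if de_genes is None:
        n_de = int(round(de_fraction * n_genes))
        if de_fraction > 0 and n_de < 1:
            logger.warning("gen_expression: de_fraction*n_genes < 1; planting no DE genes")
        chosen = list(rng.choice(genes, size=n_de, replace=False)) if n_de else []
    else:
        chosen = list(de_genes)
        unknown = set(chosen) - set(genes)
        if unknown:
            raise ValueError(f"gen_expression: de_genes not in gene list: {sorted(unknown)[:5]}")
    if lfc == 0:  # no effect size, so nothing is truly differential
        chosen = []
    half = len(chosen) // 2 + len(chosen) % 2
    up, down = set(chosen[:half]), set(chosen[half:])

    samples = [f"T{i + 1:02d}" for i in range(n1)] + [f"N{i + 1:02d}" for i in range(n2)]
    labels = pd.Series(["tumor"] * n1 + ["normal"] * n2, index=samples, name="group")
    mu = rng.normal(7.0, 1.0, size=n_genes)
    shift = np.array([lfc if g_ in up else -lfc if g_ in down else 0.0 for g_ in genes])
    values = np.tile(mu[:, None], (1, n1 + n2))
    values[:, :n1] += shift[:, None]
    values += rng.normal(0.0, sigma, size=values.shape)
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return expr, labels, {"up": up, "down": down}


# ---------------------------------------------------------------------------
# Target sets and GMT collections
# ---------------------------------------------------------------------------

def gen_target_sets(
    universe_size: int = 2000,
    n_databases: int = 4,
    db_size: int = 150,
    overlap: float = 0.3,
    n_shared: int = 60,
    disease_size: int = 200,
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> tuple[list[GeneSet], GeneSet, set[str]]:
    """Pseudo-database target lists with controlled pairwise overlap.

    All databases share a common core of ``round(overlap * db_size)`` genes
    and draw the remainder disjointly, so every pair overlaps in exactly the
    configured fraction.  A designated shared subset of the herb union of
    size ``n_shared`` seeds a disease gene set (padded with genes outside the
    union), so the herb-union/disease intersection recovers it exactly.
    Returns (database sets, disease set, truth shared set).
    """
    if universe is None:
        universe = _symbols(universe_size)
    elif len(universe) != universe_size:
        raise ValueError("gen_target_sets: len(universe) must equal universe_size")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("gen_target_sets: overlap must be in [0, 1]")
    if db_size > universe_size:
        raise ValueError("gen_target_sets: db_size exceeds universe")
    rng = _rng(seed, "targets")

    core_size = int(round(overlap * db_size))
    uniq = db_size - core_size
    need = core_size + n_databases * uniq
    if need > universe_size:
        raise ValueError(f"gen_target_sets: infeasible overlap — needs {need} distinct "
                         f"genes from a universe of {universe_size}")
    drawn = list(rng.choice(list(universe), size=need, replace=False))
    core = drawn[:core_size]
    dbs = [GeneSet(label=f"DB{i + 1}",
                   members=frozenset(core + drawn[core_size + i * uniq: core_size + (i + 1) * uniq]))
           for i in range(n_databases)]

    herb_union = union_sets(dbs).members
    if n_shared > len(herb_union):
        raise ValueError("gen_target_sets: n_shared exceeds the herb union size")
    shared = set(rng.choice(sorted(herb_union), size=n_shared, replace=False))
    outside = sorted(set(universe) - herb_union)
    pad = disease_size - n_shared
    if pad < 0 or pad > len(outside):
        raise ValueError("gen_target_sets: infeasible disease_size")
    disease = GeneSet(label="DISEASE",
                      members=frozenset(shared | set(rng.choice(outside, size=pad, replace=False))))
    return dbs, disease, shared


def gen_gmt(
    universe: Sequence[str],
    n_terms: int = 50,
    term_size: tuple[int, int] = (10, 40),
    planted: dict[str, set[str]] | None = None,
    pad: int = 5,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[str]]:
    """Random GMT collection plus terms planted over designated gene sets.

    Each planted entry becomes a term containing the full designated set plus
    ``pad`` random extra genes, so the designated query ranks it first under
    over-representation analysis.  Returns (collection, planted term ids).
    """
    if term_size[0] < 5:
        raise ValueError("gen_gmt: term sizes must be >= 5")
    rng = _rng(seed, "gmt")
    universe = list(universe)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        terms[f"T{i + 1:04d}"] = (f"random term {i + 1}", members)
    truth: list[str] = []
    for name, genes in (planted or {}).items():
        extra = sorted(set(universe) - set(genes))
        padding = set(rng.choice(extra, size=min(pad, len(extra)), replace=False))
        tid = f"PLANTED_{name}"
        terms[tid] = (f"planted term for {name}", frozenset(set(genes) | padding))
        truth.append(tid)
    return GeneSetCollection(terms=terms), truth


# ---------------------------------------------------------------------------
# Coherent bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSpec:
    """One document describing every synthetic input of a full pipeline run.

    The defaults describe one self-consistent study: a 3000-symbol universe,
    four 200-gene target databases at pairwise overlap 0.3, a 10-vs-10
    expression profile with planted DE at |logFC| = 2 and unit noise covering
    the 300 designated shared genes, an interaction graph over those shared
    genes plus a 100-gene halo (preferential attachment, m = 4) carrying
    three planted cliques of sizes 12/10/9, and a 50-term GMT with one
    planted term per planted module.
    """

    seed: int = 42
    universe_size: int = 3000
    # targets
    n_databases: int = 4
    db_size: int = 200
    overlap: float = 0.3
    n_shared: int = 300
    # expression
    n1: int = 10
    n2: int = 10
    de_fraction: float = 0.1
    lfc: float = 2.0
    sigma: float = 1.0
    # interaction graph
    graph_halo: int = 100
    graph_m: int = 4
    module_sizes: tuple[int, ...] = (12, 10, 9)
    # gmt
    n_terms: int = 50
    term_size: tuple[int, int] = (10, 40)


def generate_bundle(spec: SimSpec, outdir: str | Path) -> dict:
    """Write a coherent input bundle under ``outdir`` and return its truth.

    Files: ``edges.tsv``, ``expr.tsv``, ``groups.tsv``, ``targets_db*.txt``,
    ``sets.gmt`` and ``truth/truth.json``.  Identical specs produce
    byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    universe = _symbols(spec.universe_size)

    dbs, _, shared = gen_target_sets(
        universe_size=spec.universe_size, n_databases=spec.n_databases,
        db_size=spec.db_size, overlap=spec.overlap, n_shared=spec.n_shared,
        disease_size=spec.n_shared, seed=spec.seed, universe=universe)
    herb_union = union_sets(dbs).members

    # plant DE on the designated shared genes plus extras outside the herb union
    n_de = max(int(round(spec.de_fraction * spec.universe_size)), len(shared))
    rng = _rng(spec.seed, "bundle")
    extras: list[str] = []
    if n_de > len(shared):
        pool = sorted(set(universe) - herb_union)
        extras = list(rng.choice(pool, size=n_de - len(shared), replace=False))
    de_order = sorted(shared) + extras
    rng.shuffle(de_order)
    expr, labels, de_truth = gen_expression(
        n_genes=spec.universe_size, n1=spec.n1, n2=spec.n2,
        de_fraction=spec.de_fraction, lfc=spec.lfc, sigma=spec.sigma,
        seed=spec.seed, genes=universe, de_genes=de_order)

    # interaction graph over shared genes + halo, with planted cliques in shared
    shared_sorted = sorted(shared)
    halo = list(rng.choice(sorted(set(universe) - shared - herb_union),
                           size=spec.graph_halo, replace=False))
    graph_nodes = shared_sorted + halo
    rng.shuffle(graph_nodes)
    g = gen_scale_free(len(graph_nodes), spec.graph_m, nodes=graph_nodes,
                       rng=_rng(spec.seed, "graph"))
    pool = list(shared_sorted)
    rng.shuffle(pool)
    module_truth: dict[str, list[str]] = {}
    offset = 0
    for i, size in enumerate(spec.module_sizes, start=1):
        members = pool[offset: offset + size]
        offset += size
        g.add_edges_from(itertools.combinations(members, 2))
        module_truth[f"module{i}"] = sorted(members)
    for a, b in g.edges:
        planted = any(a in m and b in m for m in module_truth.values())
        lo = 0.95 if planted else 0.85
        g.edges[a, b]["confidence"] = round(float(rng.uniform(lo, 1.0)), 3)

    collection, planted_terms = gen_gmt(
        universe, n_terms=spec.n_terms, term_size=spec.term_size,
        planted={k: set(v) for k, v in module_truth.items()}, seed=spec.seed)

    # --- write artifacts -------------------------------------------------
    write_edge_list(g, outdir / "edges.tsv", header=True)
    expr.to_csv(outdir / "expr.tsv", sep="\t")
    labels.rename_axis("sample").to_frame().to_csv(outdir / "groups.tsv", sep="\t")
    for db in dbs:
        write_gene_list(db.members, outdir / f"targets_{db.label.lower()}.txt")
    write_gmt(collection, outdir / "sets.gmt")

    truth = {
        "shared": sorted(shared),
        "herb_union": sorted(herb_union),
        "de_up": sorted(de_truth["up"]),
        "de_down": sorted(de_truth["down"]),
        "modules": module_truth,
        "planted_terms": sorted(planted_terms),
        "graph_nodes": sorted(g.nodes),
    }
    with (outdir / "truth" / "truth.json").open("w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    with (outdir / "truth" / "spec.json").open("w") as fh:
        json.dump(asdict(spec), fh, indent=1, sort_keys=True)
    return truth
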