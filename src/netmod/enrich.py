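"""Hypergeometric over-representation analysis against GMT gene-set collections.

For a query gene set (typically one detected module) and a collection of
annotated terms, each term is scored by the hypergeometric upper tail
P[X >= k] with X ~ Hypergeometric(N, K, n), where N is the background
universe, K the term size within it, n the annotated query size, and k the
query/term overlap.  P-values are Benjamini–Hochberg adjusted across tested
terms and complemented with Storey-style q-values; terms pass only when both
``adj_p`` and ``q`` fall below their cutoffs, and the top terms by adjusted
p-value are reported.

The background universe defaults to the union of the collection's genes; a
user-provided background is supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichConfig", "GeneSetCollection", "read_gmt", "write_gmt",
           "hypergeom_upper_tail", "storey_q", "ora"]


@dataclass(frozen=True)
class EnrichConfig:
    adj_p_cut: float = 0.05
    q_cut: float = 0.05
    top_n: int = 10

    def __post_init__(self) -> None:
        for name in ("adj_p_cut", "q_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass(frozen=True)
class GeneSetCollection:
    """Term id -> (description, member symbols); term ids unique, terms non-empty."""

    terms: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"GeneSetCollection: term {tid!r} is empty")

    def universe(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for _, members in self.terms.values():
            out |= members
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``term_id<TAB>description<TAB>gene1<TAB>...``."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 tab-separated fields")
            tid, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g.strip()]
            if tid in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {tid!r}")
            terms[tid] = (desc, frozenset(genes))
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for tid in sorted(collection.terms):
            desc, members = collection.terms[tid]
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), evaluated in log space."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"hypergeom_upper_tail: invalid parameters k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def storey_q(p: Iterable[float], lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda.

    pi0 = min(1, #(p > lambda) / (m (1 - lambda))), clipped below by 1/m so a
    degenerate estimate of 0 does not zero every q; q-values are the
    pi0-scaled BH quantities, monotonized from the largest p downward and
    clipped to [0, 1].  When pi0 reaches 1 this reduces exactly to BH.
    """
    p = np.asarray(list(p), dtype=float)
    m = len(p)
    if m == 0:
        return p
    pi0 = np.mean(p > lambda_) / (1.0 - lambda_)
    pi0 = float(min(1.0, max(1.0 / m, pi0)))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    cfg: EnrichConfig = EnrichConfig(),
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Over-representation analysis of ``query`` against every collection term.

    Returns the top ``cfg.top_n`` passing terms, sorted by ascending adjusted
    p-value (ties by larger overlap k, then term id), with columns term_id,
    description, k, K, n, N, p, adj_p, q, gene_ratio and the comma-joined hit
    genes.  A term passes only if adj_p < cfg.adj_p_cut AND q < cfg.q_cut.
    """
    query = set(query)
    if not query:
        raise ValueError("ora: empty query gene set")
    bg = frozenset(universe) if universe is not None else collection.universe()
    annotated = query & bg
    if not annotated:
        raise ValueError("ora: query disjoint from universe")
    n, N = len(annotated), len(bg)

    rows = []
    for tid in sorted(collection.terms):
        desc, members = collection.terms[tid]
        term_bg = members & bg
        K = len(term_bg)
        if K == 0:
            continue
        hits = annotated & term_bg
        k = len(hits)
        rows.append({"term_id": tid, "description": desc, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_upper_tail(k, K, n, N),
                     "gene_ratio": k / n, "hit_genes": ",".join(sorted(hits))})
    if not rows:
        raise ValueError("ora: no collection term overlaps the universe")
    df = pd.DataFrame(rows)
    df["adj_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["q"] = storey_q(df["p"].to_numpy())
    df = df[df["adj_p"].lt(cfg.adj_p_cut) & df["q"].lt(cfg.q_cut)]
    df = df.sort_values(["adj_p", "k", "term_id"], ascending=[True, False, True],
                        kind="stable").head(cfg.top_n)
    cols = ["term_id", "description", "k", "K", "n", "N", "p", "adj_p", "q",
            "gene_ratio", "hit_genes"]
    return df[cols].reset_index(drop=True)
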