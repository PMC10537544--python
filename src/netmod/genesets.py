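"""Gene-set algebra: unions of per-database target lists and intersections
with disease gene sets.

Symbols are normalized by trimming whitespace and uppercasing; no alias or
identifier mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .graph import read_gene_list, write_gene_list

__all__ = ["GeneSet", "normalize_symbols", "read_gene_set", "union_sets",
           "intersect_sets", "membership_table", "write_gene_set"]


def normalize_symbols(symbols: Iterable[str]) -> frozenset[str]:
    """Trim and uppercase; drop empties."""
    return frozenset(s.strip().upper() for s in symbols if s.strip())


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene symbols (a source database, a GEO profile, ...)."""

    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def read_gene_set(path: str | Path, label: str | None = None, normalize: bool = True) -> GeneSet:
    symbols = read_gene_list(path)
    members = normalize_symbols(symbols) if normalize else frozenset(symbols)
    return GeneSet(label=label or Path(path).stem, members=members)


def union_sets(sets: Sequence[GeneSet]) -> GeneSet:
    """Member-wise union; the label concatenates the source labels."""
    if not sets:
        raise ValueError("union_sets: need at least one set")
    members: frozenset[str] = frozenset()
    for s in sets:
        members |= s.members
    return GeneSet(label="|".join(s.label for s in sets), members=members)


def intersect_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Intersection; empty intersections are an error (downstream network would be empty)."""
    members = a.members & b.members
    if not members:
        raise ValueError(f"intersect_sets: {a.label!r} and {b.label!r} are disjoint")
    return GeneSet(label=f"{a.label}&{b.label}", members=members)


def membership_table(sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Per-symbol membership indicator across sources (Venn-style report)."""
    universe = sorted(set().union(*(s.members for s in sets))) if sets else []
    return pd.DataFrame(
        {s.label: [g in s.members for g in universe] for s in sets},
        index=pd.Index(universe, name="gene"),
    )


def write_gene_set(s: GeneSet, path: str | Path) -> None:
    write_gene_list(s.members, path)
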