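"""Two-group differential-expression screening on log2 microarray matrices.

Mirrors the classic GEO screening stage: quantile normalization, collapsing
probes to gene symbols, a per-gene two-group test, Benjamini–Hochberg
adjustment, and the up/down thresholds ``adj_p < 0.05`` and ``|logFC| >= 0.5``.

The per-gene test is a Welch two-sample t-test with a small variance floor.
This is a deliberate stand-in for moderated-statistics fits: the screening
thresholds, not the moderation, are what this stage implements, and the
variance floor keeps zero-variance genes (logFC-only effects) testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DegConfig",
    "quantile_normalize",
    "collapse_probes",
    "differential_expression",
    "filter_degs",
]


@dataclass(frozen=True)
class DegConfig:
    """Thresholds for calling differentially expressed genes.

    ``p_cut`` applies to the BH-adjusted p-value; ``lfc_cut`` to |logFC| in
    log2 units; ``variance_floor`` is the minimum per-group variance used in
    the Welch test so that constant genes yield p = 1 rather than NaN.
    """

    p_cut: float = 0.05
    lfc_cut: float = 0.5
    variance_floor: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cut < 1.0:
            raise ValueError(f"p_cut must be in (0, 1), got {self.p_cut}")
        if self.lfc_cut < 0:
            raise ValueError(f"lfc_cut must be >= 0, got {self.lfc_cut}")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be > 0")


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one empirical distribution.

    After the operation each column's sorted values equal the per-rank
    cross-column means of the input; ties within a column receive the mean of
    the values their ranks span.  A single-column matrix is returned unchanged
    with a warning.
    """
    if m.isna().any().any():
        raise ValueError("quantile_normalize: missing values are not supported")
    if m.shape[1] < 2:
        logger.warning("quantile_normalize: single-sample matrix, returning unchanged")
        return m.copy()
    values = m.to_numpy(dtype=float)
    rank_means = np.sort(values, axis=0).mean(axis=1)
    ranks = pd.DataFrame(values).rank(method="average").to_numpy()  # 1-based, maybe x.5
    lo = np.floor(ranks).astype(int) - 1
    hi = np.ceil(ranks).astype(int) - 1
    out = (rank_means[lo] + rank_means[hi]) / 2.0
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def collapse_probes(m: pd.DataFrame, probe_map: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene symbols.

    Probes mapping to zero or to more than one gene are dropped.  When several
    probes map to the same gene, the probe with the highest mean expression
    across samples represents it (ties broken by lexicographically smallest
    probe ID).
    """
    rows: dict[str, tuple[float, str]] = {}  # gene -> (mean, probe)
    for probe in m.index:
        genes = list(probe_map.get(probe, ()))
        if len(genes) != 1:
            continue
        gene = genes[0]
        mean = float(m.loc[probe].mean())
        cur = rows.get(gene)
        # highest mean wins; on an exact tie the smaller probe ID wins
        if cur is None or mean > cur[0] or (mean == cur[0] and probe < cur[1]):
            rows[gene] = (mean, probe)
    if not rows:
        raise ValueError("collapse_probes: no probe maps to exactly one gene")
    genes = sorted(rows)
    out = m.loc[[rows[g][1] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene")
    return out


def differential_expression(
    m: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    contrast: tuple[str, str] | None = None,
    cfg: DegConfig = DegConfig(),
) -> pd.DataFrame:
    """Per-gene Welch t-test between two sample groups on log2 values.

    Parameters
    ----------
    m
        Gene x sample matrix on the log2 scale.
    groups
        Sample name -> group label for every column of ``m``.
    contrast
        ``(group1, group2)``; logFC = mean(group1) - mean(group2).  Defaults
        to the two labels in order of first appearance among the columns.

    Returns a DataFrame with columns ``gene``, ``logFC``, ``p``, ``adj_p``,
    ``direction`` (up / down / ns per the thresholds in ``cfg``).
    """
    groups = dict(pd.Series(groups))
    missing = [c for c in m.columns if c not in groups]
    if missing:
        raise ValueError(f"differential_expression: samples without group label: {missing[:5]}")
    if m.columns.duplicated().any():
        raise ValueError("differential_expression: duplicate sample names")
    if contrast is None:
        seen: list[str] = []
        for c in m.columns:
            if groups[c] not in seen:
                seen.append(groups[c])
        if len(seen) != 2:
            raise ValueError(f"differential_expression: need exactly 2 groups, found {seen}")
        contrast = (seen[0], seen[1])
    g1, g2 = contrast
    cols1 = [c for c in m.columns if groups[c] == g1]
    cols2 = [c for c in m.columns if groups[c] == g2]
    n1, n2 = len(cols1), len(cols2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"differential_expression: each group needs >= 2 samples "
                         f"({g1}: {n1}, {g2}: {n2})")

    x1 = m[cols1].to_numpy(dtype=float)
    x2 = m[cols2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = np.maximum(x1.var(axis=1, ddof=1), cfg.variance_floor)
    v2 = np.maximum(x2.var(axis=1, ddof=1), cfg.variance_floor)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]

    logfc = m1 - m2
    direction = np.where(
        (adj_p < cfg.p_cut) & (logfc >= cfg.lfc_cut), "up",
        np.where((adj_p < cfg.p_cut) & (logfc <= -cfg.lfc_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {"gene": m.index, "logFC": logfc, "p": p, "adj_p": adj_p, "direction": direction}
    ).reset_index(drop=True)


def filter_degs(rows: pd.DataFrame, cfg: DegConfig = DegConfig()) -> tuple[set[str], set[str]]:
    """Split a DEG table into (up, down) gene sets by the configured thresholds."""
    if len(rows) == 0:
        raise ValueError("filter_degs: empty DEG table")
    sig = rows["adj_p"] < cfg.p_cut
    up = set(rows.loc[sig & (rows["logFC"] >= cfg.lfc_cut), "gene"])
    down = set(rows.loc[sig & (rows["logFC"] <= -cfg.lfc_cut), "gene"])
    return up, down
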