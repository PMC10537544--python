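"""End-to-end orchestration: screen -> integrate -> PIN -> critical PIN ->
topology -> modules -> hubs -> enrichment, from a single config document.

Stages communicate only through files under the output directory, so any
midpoint can be re-run by hand, and a JSON manifest records per-stage counts
(set sizes, node/edge counts, summary metrics, hubs, module table) plus a
hash of the configuration.  Runs are fully deterministic on fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .critical import FilterConfig, HubConfig, build_critical_pin, select_hubs
from .degs import DegConfig, collapse_probes, differential_expression, filter_degs, quantile_normalize
from .enrich import EnrichConfig, ora, read_gmt
from .genesets import GeneSet, intersect_sets, membership_table, read_gene_set, union_sets
from .graph import (degree_distribution, fit_power_law, induced_subgraph,
                    path_length_distribution, read_edge_list, topology_summary,
                    write_edge_list, write_gene_list)
from .mcode import McodeConfig, detect_modules

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class ExpressionInput:
    """One expression profile: matrix TSV, sample->group TSV, optional probe map."""

    label: str
    expr: str
    groups: str
    probe_map: str | None = None
    contrast: tuple[str, str] | None = None


@dataclass
class PipelineConfig:
    edges: str
    targets: list[str]
    expression: list[ExpressionInput]
    gmt: str
    outdir: str
    min_confidence: float = 0.9
    scale: str = "unit"
    edges_header: bool = True
    deg: DegConfig = field(default_factory=DegConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    hub: HubConfig = field(default_factory=HubConfig)
    mcode: McodeConfig = field(default_factory=McodeConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        try:
            exprs = [ExpressionInput(**{**e, "contrast": tuple(e["contrast"]) if e.get("contrast") else None})
                     for e in raw.pop("expression")]
            sub = {k: cls_(**raw.pop(k)) for k, cls_ in
                   [("deg", DegConfig), ("filter", FilterConfig), ("hub", HubConfig),
                    ("mcode", McodeConfig), ("enrich", EnrichConfig)] if k in raw}
            return cls(expression=exprs, **sub, **raw)
        except (KeyError, TypeError) as exc:
            raise ValueError(f"invalid pipeline config {path}: {exc}") from exc

    def canonical(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, sort_keys=True, default=str))


def _read_probe_map(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            probe, _, genes = line.partition("\t")
            out[probe.strip()] = [g for g in genes.replace(",", "\t").split("\t") if g.strip()]
    return out


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "netmod_version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.canonical(), sort_keys=True).encode()).hexdigest(),
        "stages": {},
    }

    # -- 1. differential-expression screening ------------------------------
    disease_sets: list[GeneSet] = []
    deg_counts = {}
    for prof in cfg.expression:
        try:
            expr = pd.read_csv(prof.expr, sep="\t", index_col=0)
            groups = pd.read_csv(prof.groups, sep="\t", index_col=0).iloc[:, 0]
            if prof.probe_map:
                expr = collapse_probes(expr, _read_probe_map(prof.probe_map))
            expr = quantile_normalize(expr)
            table = differential_expression(expr, groups, contrast=prof.contrast, cfg=cfg.deg)
            up, down = filter_degs(table, cfg.deg)
        except Exception as exc:
            raise StageError("deg_screen", f"profile {prof.label}: {exc}") from exc
        table.to_csv(out / f"degs_{prof.label}.tsv", sep="\t", index=False)
        disease_sets.append(GeneSet(label=prof.label, members=frozenset(up | down)))
        deg_counts[prof.label] = {"up": len(up), "down": len(down)}
    if not disease_sets:
        raise StageError("deg_screen", "no expression profiles configured")
    disease = union_sets(disease_sets)
    write_gene_list(disease.members, out / "disease_genes.txt")
    manifest["stages"]["deg_screen"] = {"profiles": deg_counts,
                                        "disease_genes": len(disease.members)}

    # -- 2. target integration ---------------------------------------------
    try:
        herb_sets = [read_gene_set(p) for p in cfg.targets]
        herb = union_sets(herb_sets)
        shared = intersect_sets(herb, disease)
    except Exception as exc:
        raise StageError("integrate", str(exc)) from exc
    write_gene_list(herb.members, out / "herb_union.txt")
    write_gene_list(shared.members, out / "shared_genes.txt")
    membership_table(herb_sets).to_csv(out / "target_membership.tsv", sep="\t")
    manifest["stages"]["integrate"] = {
        "per_database": {s.label: len(s.members) for s in herb_sets},
        "herb_union": len(herb.members), "shared": len(shared.members)}

    # -- 3. PIN construction + topology ------------------------------------
    try:
        background = read_edge_list(cfg.edges, min_confidence=cfg.min_confidence,
                                    scale=cfg.scale, header=cfg.edges_header)
        pin = induced_subgraph(background, shared.members, lcc_only=True)
        pin_summary = topology_summary(pin)
        pin_dd = degree_distribution(pin)
        pin_fit = fit_power_law(pin_dd)
        pin_pl = path_length_distribution(pin)
    except Exception as exc:
        raise StageError("pin", str(exc)) from exc
    write_edge_list(pin, out / "pin_edges.tsv")
    pin_summary.to_series().to_csv(out / "pin_summary.tsv", sep="\t", header=False)
    pin_dd.to_csv(out / "pin_degree_distribution.tsv", sep="\t", index=False)
    pin_pl.to_csv(out / "pin_path_lengths.tsv", sep="\t", index=False)
    manifest["stages"]["pin"] = {
        "background_nodes": background.number_of_nodes(),
        "background_edges": background.number_of_edges(),
        "n_nodes": pin_summary.n_nodes, "n_edges": pin_summary.n_edges,
        "summary": json.loads(pin_summary.to_series().to_json()),
        "power_law": {"a": pin_fit.a, "gamma": pin_fit.gamma, "r2_log": pin_fit.r2_log}}

    # -- 4. critical PIN -----------------------------------------------------
    try:
        critical, report = build_critical_pin(pin, cfg.filter)
        crit_summary = topology_summary(critical)
    except Exception as exc:
        raise StageError("critical", str(exc)) from exc
    write_edge_list(critical, out / "critical_edges.tsv")
    report.to_csv(out / "critical_report.tsv", sep="\t", index=False)
    crit_summary.to_series().to_csv(out / "critical_summary.tsv", sep="\t", header=False)
    pass_records = json.loads(report.to_json(orient="records"))  # NaN -> null
    manifest["stages"]["critical"] = {
        "n_nodes": crit_summary.n_nodes, "n_edges": crit_summary.n_edges,
        "passes": pass_records,
        "summary": json.loads(crit_summary.to_series().to_json())}

    # -- 5. hubs -------------------------------------------------------------
    try:
        hubs = select_hubs(critical, cfg.hub)
    except Exception as exc:
        raise StageError("hubs", str(exc)) from exc
    write_gene_list(hubs, out / "hub_genes.txt")
    manifest["stages"]["hubs"] = {"k": cfg.hub.k, "hubs": sorted(hubs)}

    # -- 6. MCODE modules ----------------------------------------------------
    try:
        modules = detect_modules(critical, cfg.mcode)
    except Exception as exc:
        raise StageError("mcode", str(exc)) from exc
    mod_rows = [{"rank": m.rank, "score": m.score, "n": len(m.members),
                 "density": m.density, "seed": m.seed,
                 "members": ",".join(sorted(m.members))} for m in modules]
    pd.DataFrame(mod_rows, columns=["rank", "score", "n", "density", "seed", "members"]) \
        .to_csv(out / "modules.tsv", sep="\t", index=False)
    for m in modules:
        write_gene_list(m.members, out / f"module_{m.rank}.txt")
    manifest["stages"]["mcode"] = {"n_modules": len(modules), "modules": mod_rows}

    # -- 7. per-module enrichment -------------------------------------------
    try:
        collection = read_gmt(cfg.gmt)
    except Exception as exc:
        raise StageError("enrich", str(exc)) from exc
    enrich_counts = {}
    for m in modules:
        try:
            table = ora(m.members, collection, cfg.enrich)
        except ValueError as exc:
            logger.warning("enrichment skipped for module %s: %s", m.rank, exc)
            table = pd.DataFrame()
        table.to_csv(out / f"enrichment_module{m.rank}.tsv", sep="\t", index=False)
        enrich_counts[f"module{m.rank}"] = {
            "passing_terms": len(table),
            "top_term": table["term_id"].iloc[0] if len(table) else None}
    manifest["stages"]["enrich"] = enrich_counts

    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
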