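"""End-to-end orchestration: catalog → projection → backbone → modules.

:func:`run_pipeline` runs every stage in order, writing each artifact
(networks, sweep table, comparison record, partition, module summary)
plus a machine-readable run manifest into the output directory.  All
randomness (community detection visit order) flows from the single
run-level seed recorded in the manifest, so identical configurations
produce identical manifests.  A failing stage leaves a ``FAILED``
marker naming the stage; partial outputs are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__, associations, backbone, communities, netbuild

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, fully serializable description of one pipeline run.

    Exactly one of ``alpha`` (explicit significance level) or
    ``target_edge_frac`` (pick α from the sweep whose retained-edge
    fraction is closest to the target) must be set.  ``gw_cutoff`` is a
    weight threshold for the global-weight baseline, or None to match
    the disparity backbone's achieved edge fraction automatically.
    """

    trait_genes: str
    gene_pathways: str
    out_dir: str
    tg_dialect: str = "simple"
    gp_format: str = "tsv"
    side: str = "trait"
    rule: str = "AND"
    alpha: float | None = None
    target_edge_frac: float | None = 0.08
    grid_points: int = 201
    gw_cutoff: float | None = None
    seed: int = 0
    top_n: int = 6
    formats: tuple[str, ...] = ("tsv", "graphml")

    def __post_init__(self) -> None:
        if (self.alpha is None) == (self.target_edge_frac is None):
            raise ValueError("set exactly one of alpha / target_edge_frac")
        if self.alpha is not None and not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.side not in ("trait", "pathway"):
            raise ValueError("side must be trait or pathway")
        if self.rule.upper() not in ("AND", "OR"):
            raise ValueError("rule must be AND or OR")
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        for f in self.formats:
            if f not in ("tsv", "graphml", "gml"):
                raise ValueError(f"unknown export format {f!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_net(net: nx.Graph, out: Path, stem: str, formats) -> None:
    for fmt in formats:
        netbuild.write_net(net, out / f"{stem}.{fmt}", fmt)


def _summary_dict(net: nx.Graph) -> dict:
    return netbuild.summarize(net).as_dict()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages and return the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
    manifest: dict = {
        "pipeline_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }
    stage = "associations"
    try:
        tg = associations.read_trait_genes(cfg.trait_genes, cfg.tg_dialect)
        gp = associations.read_gene_pathways(cfg.gene_pathways, cfg.gp_format)
        tp_map = associations.build_trait_pathway_map(tg, gp)
        manifest["stages"][stage] = {
            "n_trait_gene_rows": len(tg.rows),
            "n_trait_gene_rows_skipped": tg.n_skipped,
            "n_gene_pathway_rows": len(gp.rows),
            "n_gene_pathway_rows_skipped": gp.n_skipped,
            "n_traits": len(tp_map.traits),
            "n_traits_without_pathways": len(tp_map.pathwayless_traits),
        }

        stage = "projection"
        bn = netbuild.build_bipartite(tp_map)
        proj = netbuild.project(bn, cfg.side)
        n_isolates = proj.number_of_nodes()
        net = netbuild.remove_isolates(proj)
        n_isolates -= net.number_of_nodes()
        _write_net(net, out, "unfiltered", cfg.formats)
        manifest["stages"][stage] = {
            "bipartite_nodes": bn.number_of_nodes(),
            "bipartite_edges": bn.number_of_edges(),
            "isolates_removed": n_isolates,
            "summary": _summary_dict(net),
        }

        if net.number_of_edges() == 0:
            # nothing to filter or cluster; record the decision and stop
            manifest["stages"]["backbone"] = {"skipped": "projection has no edges"}
            manifest["stages"]["modules"] = {"skipped": "projection has no edges"}
            logger.warning("projection has no edges; backbone and module "
                           "stages skipped")
            _finish(out, manifest)
            return out

        stage = "backbone"
        grid = backbone.default_grid(cfg.grid_points)
        table = backbone.sweep(net, grid, cfg.rule)
        table.to_csv(out / "sweep.tsv", sep="\t", index=False)
        if cfg.alpha is not None:
            alpha = cfg.alpha
        else:
            alpha = backbone.pick_alpha(table, cfg.target_edge_frac)
        df_net = backbone.extract_backbone(net, alpha, cfg.rule)
        df_frac = df_net.number_of_edges() / net.number_of_edges()
        if cfg.gw_cutoff is not None:
            cutoff, gw_frac = cfg.gw_cutoff, None
        else:
            cutoff, gw_frac = backbone.match_edge_fraction(
                net, df_frac if df_frac > 0 else 1.0)
        gw_net = backbone.global_weight_filter(net, cutoff)
        _write_net(df_net, out, "backbone_df", cfg.formats)
        _write_net(gw_net, out, "backbone_gw", cfg.formats)
        comparison = backbone.compare_filters(net, df_net, gw_net)
        (out / "comparison.json").write_text(
            json.dumps(comparison, indent=2, sort_keys=True) + "\n")
        manifest["stages"][stage] = {
            "rule": cfg.rule.upper(),
            "alpha": alpha,
            "df_edge_fraction": df_frac,
            "gw_cutoff": cutoff,
            "gw_matched_fraction": gw_frac,
            "df": _summary_dict(df_net),
            "gw": _summary_dict(gw_net),
        }

        stage = "modules"
        if df_net.number_of_nodes() == 0:
            manifest["stages"][stage] = {"skipped": "backbone is empty"}
            logger.warning("backbone is empty; module stage skipped")
        else:
            part = communities.detect_modules(df_net, seed=cfg.seed)
            part.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
            summary = communities.summarize_modules(df_net, part, cfg.top_n)
            summary.table.to_csv(out / "modules.tsv", sep="\t", index=False)
            mod_graph = df_net.copy()
            nx.set_node_attributes(
                mod_graph, {n: int(c) for n, c in part.assignment.items()},
                "module")
            if "graphml" in cfg.formats:
                nx.write_graphml(mod_graph, out / "backbone_df_modules.graphml")
            manifest["stages"][stage] = {
                "n_modules": summary.n_modules,
                "n_in_largest_component": summary.n_in_largest_component,
                "n_satellite": summary.n_satellite,
                "modularity": part.q,
            }
    except Exception as exc:  # noqa: BLE001 - marker + re-raise with stage name
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        _finish(out, manifest)
        raise PipelineError(stage, exc) from exc

    _finish(out, manifest)
    return out


def _finish(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _pct(x: float | None) -> str:
    return "n/a" if x is None else f"{x:.1f}%"


def _num(x: float | None) -> str:
    return "n/a" if x is None else f"{x:.3g}"


def report(out_dir: str | Path) -> str:
    """Render a Markdown summary of a completed run directory.

    Every number comes from the persisted artifacts (manifest,
    comparison record, module table); nothing is recomputed from graphs.
    """
    out = Path(out_dir)
    required = ["manifest.json"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"run directory {out} lacks: {missing}")
    manifest = json.loads((out / "manifest.json").read_text())
    lines = [f"# Pipeline run report ({out.name})", ""]
    assoc = manifest["stages"].get("associations", {})
    proj = manifest["stages"].get("projection", {})
    lines += [
        f"- traits: {assoc.get('n_traits', 'n/a')} "
        f"({assoc.get('n_traits_without_pathways', 0)} without pathway annotation)",
        f"- projected network: {proj.get('summary', {}).get('n_nodes', 0)} nodes, "
        f"{proj.get('summary', {}).get('n_edges', 0)} edges "
        f"({proj.get('isolates_removed', 0)} isolates removed)",
        "",
    ]
    if (out / "comparison.json").exists():
        comp = json.loads((out / "comparison.json").read_text())
        bb = manifest["stages"].get("backbone", {})
        lines += [
            f"Backbone: rule {bb.get('rule')}, alpha = {bb.get('alpha')}, "
            f"global-weight cutoff = {bb.get('gw_cutoff')}",
            "",
            "| statistic | unfiltered | disparity filter | global weight |",
            "|---|---|---|---|",
        ]
        rows = [
            ("nodes", "n_nodes", "pct_nodes"),
            ("edges", "n_edges", "pct_edges"),
            ("total weight", "total_weight", "pct_weight"),
            ("mean degree", "mean_degree", None),
            ("clustering coefficient", "avg_clustering", None),
            ("avg path length", "avg_path_length", None),
        ]
        for label, key, pkey in rows:
            cells = [label, _num(comp["unfiltered"].get(key))]
            for col in ("disparity", "global_weight"):
                val = _num(comp[col].get(key))
                if pkey is not None:
                    val += f" ({_pct(comp[col].get(pkey))})"
                cells.append(val)
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    else:
        lines.append("Backbone stage skipped (no edges to filter).")
        lines.append("")
    if (out / "modules.tsv").exists():
        mod = manifest["stages"]["modules"]
        lines += [
            f"Modules: {mod['n_modules']} "
            f"({mod['n_in_largest_component']} in the largest component, "
            f"{mod['n_satellite']} satellites), Q = {mod['modularity']:.4f}",
            "",
            "| module | size | top members (by strength) |",
            "|---|---|---|",
        ]
        table = pd.read_csv(out / "modules.tsv", sep="\t")
        for module, grp in table.groupby("module", sort=True):
            members = ", ".join(grp.sort_values("rank")["node"].astype(str))
            lines.append(f"| {module} | {grp['size'].iloc[0]} | {members} |")
        lines.append("")
    return "\n".join(lines)
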