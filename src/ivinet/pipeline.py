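"""End-to-end orchestration: overlap -> network -> scores -> modules -> energy.

A run is driven by a plain dict configuration (usually parsed from YAML).
Every default is resolved up front and echoed into ``manifest.json``, so a
manifest is sufficient to reproduce a bundle byte for byte; nothing in the
bundle depends on wall-clock time or filesystem iteration order.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .centrality import ScoreConfig, all_centralities, write_centrality_table
from .degs import (
    OverlapResult,
    Thresholds,
    build_condition_sets,
    overlap,
    read_series_table,
)
from .energy import EnergyParams, EnergyProfile, level_energy_profile
from .graph import Network, network_summary, read_network, write_network
from .influence import InfluenceTable, ivi, rank_top, write_influence_table
from .mcode import (
    McodeParams,
    Module,
    ModuleHierarchy,
    annotate_seed_genes,
    decompose_hierarchy,
    write_module_table,
)
from .synthetic import SeriesTable, gen_deg_series, gen_ppin, write_series_table

log = logging.getLogger("ivinet")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": None,  # or {"deg": {...}, "network": {...}}
    "inputs": None,  # or {"series_tables": [...], "network": path, "network_format": ...}
    "conditions": ["A", "B"],
    "thresholds": {"default": {"p_max": 0.05, "lfc_low": 0.5, "lfc_high": 2.0}, "per_series": {}},
    "centrality": {"ci_radius": 3, "clusterrank_base": 10.0, "lh_second_order": False},
    "mcode": {
        "degree_cutoff": 2,
        "node_score_cutoff": 0.2,
        "k_core": 2,
        "max_depth": 100,
        "haircut": True,
        "fluff": False,
        "fluff_density": 0.1,
    },
    "energy": {"gamma": 0.8},
    "report": {"top_k": 20},
}


def resolve_config(config: dict) -> dict:
    """Overlay ``config`` on the defaults (one level of nesting deep)."""
    full = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in config.items():
        if key not in full:
            raise KeyError(f"unknown config section {key!r}")
        if isinstance(full.get(key), dict) and isinstance(value, dict):
            full[key].update(value)
        else:
            full[key] = copy.deepcopy(value)
    if not full["synthetic"] and not full["inputs"]:
        raise ValueError("config must provide either a 'synthetic' or an 'inputs' section")
    return full


def _thresholds_from(cfg: dict) -> tuple[Thresholds, dict[str, Thresholds]]:
    default = Thresholds(**cfg["thresholds"]["default"])
    per_series = {s: Thresholds(**t) for s, t in (cfg["thresholds"]["per_series"] or {}).items()}
    return default, per_series


@dataclass
class PipelineResult:
    """In-memory artifact bundle of one pipeline run."""

    config: dict
    tables: list[SeriesTable]
    overlap: OverlapResult
    venn: dict
    network: Network
    centralities: object
    influence: InfluenceTable
    hierarchy: ModuleHierarchy
    modules: list[Module]
    seed_summary: dict
    energy_profile: EnergyProfile
    truth: object | None = None
    stage_counts: dict = field(default_factory=dict)
    seed_labels: dict = field(default_factory=dict)  # overlap gene -> up/down

    @property
    def retained_seed_labels(self) -> dict:
        """Seed genes present in the loaded network."""
        return {g: lab for g, lab in self.seed_labels.items() if g in self.network}


def run_pipeline(config: dict, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; optionally write the bundle under ``outdir``."""
    cfg = resolve_config(config)
    seed = int(cfg["seed"])
    counts: dict = {}

    # --- DEG tables ---------------------------------------------------------
    truth = None
    if cfg["synthetic"]:
        deg_cfg = dict(cfg["synthetic"].get("deg") or {})
        deg_cfg.setdefault("rng_seed", seed)
        if "lfc_signal_range" in deg_cfg:
            deg_cfg["lfc_signal_range"] = tuple(deg_cfg["lfc_signal_range"])
        tables, truth = gen_deg_series(**deg_cfg)
    else:
        tables = []
        for path in cfg["inputs"]["series_tables"]:
            recs = read_series_table(path)
            tables.append(SeriesTable(recs[0].series, recs[0].condition, recs))
    records = [r for t in tables for r in t.records]
    counts["series"] = len(tables)
    counts["deg_records"] = len(records)

    # --- overlap ------------------------------------------------------------
    default_th, per_series_th = _thresholds_from(cfg)
    thresholds = {**{t.series: default_th for t in tables}, **per_series_th}
    cond_a, cond_b = build_condition_sets(records, tuple(cfg["conditions"]), thresholds)
    ov = overlap(cond_a, cond_b)
    venn = ov.venn_counts(cond_a, cond_b)
    counts["overlap"] = venn
    log.info("overlap: %d up, %d down, %d discordant", *(venn[k] for k in ("up_overlap", "down_overlap", "discordant")))

    seed_labels = {g: "up" for g in ov.up_overlap}
    seed_labels.update({g: "down" for g in ov.down_overlap})

    # --- network ------------------------------------------------------------
    if cfg["synthetic"]:
        net_cfg = dict(cfg["synthetic"].get("network") or {})
        net_cfg.setdefault("rng_seed", seed)
        if "seed_genes" not in net_cfg:
            slots = sum(net_cfg.get("clique_sizes", []))
            net_cfg["seed_genes"] = sorted(seed_labels)[:slots]
        net, net_truth = gen_ppin(**net_cfg)
        if truth is not None:
            truth.planted_modules = net_truth.planted_modules
    else:
        net = read_network(cfg["inputs"]["network"], cfg["inputs"].get("network_format"))
    counts["network"] = {"nodes": len(net), "edges": net.n_edges}
    log.info("network: %d nodes, %d edges", len(net), net.n_edges)

    retained_seeds = {g: lab for g, lab in seed_labels.items() if g in net}
    counts["seeds_in_network"] = len(retained_seeds)
    dropped = sorted(set(seed_labels) - set(retained_seeds))
    if dropped:
        log.info("not retained by the network: %d seed genes (%s)", len(dropped), ",".join(dropped))

    # --- scores -------------------------------------------------------------
    score_cfg = ScoreConfig(**cfg["centrality"])
    ct = all_centralities(net, score_cfg)
    inf = ivi(ct)

    # --- modules + energy ---------------------------------------------------
    params = McodeParams(**cfg["mcode"])
    hierarchy = decompose_hierarchy(net, params)
    modules = [child.module for child in hierarchy.children]
    modules, seed_summary = annotate_seed_genes(modules, seed_labels)
    counts["modules"] = {
        "total": len(modules),
        "with_seeds": sum(1 for m in modules if m.seed_genes),
        "seed_genes_retained": seed_summary["total_retained"],
    }
    log.info(
        "modules: %d found, %d with seed genes, %d seed genes retained",
        counts["modules"]["total"], counts["modules"]["with_seeds"], seed_summary["total_retained"],
    )
    profile = level_energy_profile(hierarchy, net, EnergyParams(**cfg["energy"]))

    result = PipelineResult(
        config=cfg,
        tables=tables,
        overlap=ov,
        venn=venn,
        network=net,
        centralities=ct,
        influence=inf,
        hierarchy=hierarchy,
        modules=modules,
        seed_summary=seed_summary,
        energy_profile=profile,
        truth=truth,
        stage_counts=counts,
        seed_labels=seed_labels,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    """Write every artifact with fixed file names under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "series").mkdir(exist_ok=True)
    for t in result.tables:
        write_series_table(t, outdir / "series" / f"{t.series}.tsv")
    if result.truth is not None:
        result.truth.to_json(outdir / "truth.json")
    write_network(result.network, outdir / "network.tsv", "edgelist")
    result.overlap.to_json(outdir / "overlap.json")
    (outdir / "venn.json").write_text(json.dumps(result.venn, indent=2, sort_keys=True) + "\n")
    (outdir / "network_summary.json").write_text(
        json.dumps(network_summary(result.network).as_dict(), indent=2, sort_keys=True) + "\n"
    )
    write_centrality_table(result.centralities, outdir / "centralities.tsv")
    write_influence_table(result.influence, outdir / "influence.tsv")
    write_module_table(result.modules, outdir / "modules.tsv")
    result.hierarchy.to_json(outdir / "hierarchy.json")
    result.energy_profile.to_tsv(outdir / "energy_profile.tsv")
    report_tables(result, outdir)
    manifest = {
        "software": {"name": "ivinet", "version": __version__},
        "config": result.config,
        "stage_counts": result.stage_counts,
        "seed_summary": result.seed_summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def report_tables(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Ranked top-k tables, plus the seed-only score table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = int(result.config["report"]["top_k"])
    written = []

    for by in ("ivi", "spreading", "hubness"):
        path = outdir / f"top_{by}.tsv"
        with open(path, "w") as fh:
            fh.write(f"rank\tnode\t{by}\n")
            for rank, (node, score) in enumerate(rank_top(result.influence, k, by), start=1):
                fh.write(f"{rank}\t{node}\t{score:.5f}\n")
        written.append(path)

    for col in ("ci", "lh"):
        column = result.centralities.column(col)
        ordered = sorted(column.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        path = outdir / f"top_{col}.tsv"
        with open(path, "w") as fh:
            fh.write(f"rank\tnode\t{col}\n")
            for rank, (node, score) in enumerate(ordered, start=1):
                fh.write(f"{rank}\t{node}\t{score:.5f}\n")
        written.append(path)

    path = outdir / "seed_scores.tsv"
    labels = result.retained_seed_labels
    with open(path, "w") as fh:
        fh.write("node\tregulation\tivi\tspreading\thubness\n")
        rows = sorted(labels, key=lambda g: (-result.influence.ivi[g], g))
        for g in rows:
            fh.write(
                f"{g}\t{labels[g]}\t{result.influence.ivi[g]:.5f}\t"
                f"{result.influence.spreading[g]:.5f}\t{result.influence.hubness[g]:.5f}\n"
            )
    written.append(path)
    return written
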