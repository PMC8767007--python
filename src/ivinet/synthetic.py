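"""Synthetic DEG tables and interaction networks with planted ground truth.

Every generator is a pure function of its arguments including ``rng_seed``,
so two calls with equal inputs produce byte-identical serialized output.
Planted signal is constructed to pass the default DEG filter in every
series of both conditions; decoy genes are split over the filter's three
rejection paths (fail p, fail the fold-change window, significant in one
condition only) in fixed 40/30/30 proportions so each path is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .degs import DEGRecord, Thresholds
from .graph import Network

__all__ = ["SyntheticTruth", "SeriesTable", "gen_deg_series", "gen_ppin", "write_series_table"]


@dataclass
class SyntheticTruth:
    """What was planted, for downstream recovery checks."""

    planted_up_overlap: set[str] = field(default_factory=set)
    planted_down_overlap: set[str] = field(default_factory=set)
    planted_modules: list[set[str]] = field(default_factory=list)
    seed_gene_labels: dict[str, str] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_up_overlap & self.planted_down_overlap:
            raise ValueError("planted up and down overlaps must be disjoint")
        for mod in self.planted_modules:
            if len(mod) < 3:
                raise ValueError("every planted module needs >= 3 nodes")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_up_overlap": sorted(self.planted_up_overlap),
            "planted_down_overlap": sorted(self.planted_down_overlap),
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "seed_gene_labels": dict(sorted(self.seed_gene_labels.items())),
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_up_overlap=set(payload["planted_up_overlap"]),
            planted_down_overlap=set(payload["planted_down_overlap"]),
            planted_modules=[set(m) for m in payload["planted_modules"]],
            seed_gene_labels=payload["seed_gene_labels"],
            rng_seed=payload["rng_seed"],
        )


@dataclass
class SeriesTable:
    """All DEG records of one series."""

    series: str
    condition: str
    records: list[DEGRecord]

    def to_tsv(self) -> str:
        lines = ["gene\tlogFC\tpvalue\tseries\tcondition"]
        for r in self.records:
            lines.append(f"{r.gene}\t{r.logfc:.6f}\t{r.pvalue:.6e}\t{r.series}\t{r.condition}")
        return "\n".join(lines) + "\n"


def write_series_table(table: SeriesTable, path: str | Path) -> None:
    Path(path).write_text(table.to_tsv())


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def gen_deg_series(
    n_series_a: int,
    n_series_b: int,
    n_genes: int,
    n_shared_up: int,
    n_shared_down: int,
    p_signal: float = 0.01,
    lfc_signal_range: tuple[float, float] = (0.6, 1.8),
    rng_seed: int = 0,
    gene_symbols: list[str] | None = None,
) -> tuple[list[SeriesTable], SyntheticTruth]:
    """Generate per-series DEG tables with planted cross-condition signal.

    Planted shared genes pass the default thresholds with a concordant
    sign in *every* series of *both* conditions; all other genes fail the
    p cut, fall outside the fold-change window, or are significant in one
    condition only, and therefore never reach the overlap.
    """
    if n_series_a < 1 or n_series_b < 1:
        raise ValueError("need at least one series per condition")
    if n_shared_up + n_shared_down > n_genes:
        raise ValueError(
            f"cannot plant {n_shared_up}+{n_shared_down} shared genes among {n_genes} genes"
        )
    if not (0.5 <= lfc_signal_range[0] <= lfc_signal_range[1] <= 2.0):
        raise ValueError("lfc_signal_range must lie within [0.5, 2]")
    if not 0.0 < p_signal < 0.05:
        raise ValueError("p_signal must lie in (0, 0.05)")

    rng = np.random.default_rng(rng_seed)
    genes = gene_symbols if gene_symbols is not None else _gene_symbols(n_genes)
    if len(genes) != n_genes:
        raise ValueError("gene_symbols length must equal n_genes")
    genes = [g.strip().upper() for g in genes]
    if len(set(genes)) != n_genes:
        raise ValueError("gene symbols must be unique")

    perm = rng.permutation(n_genes)
    up_genes = [genes[i] for i in perm[:n_shared_up]]
    down_genes = [genes[i] for i in perm[n_shared_up : n_shared_up + n_shared_down]]
    decoys = [genes[i] for i in perm[n_shared_up + n_shared_down :]]
    # rejection paths: 40% fail p, 30% fail the window, 30% one-sided
    n_fail_p = int(round(len(decoys) * 0.4))
    n_fail_lfc = int(round(len(decoys) * 0.3))
    fail_p = decoys[:n_fail_p]
    fail_lfc = decoys[n_fail_p : n_fail_p + n_fail_lfc]
    one_sided = decoys[n_fail_p + n_fail_lfc :]

    lo, hi = lfc_signal_range
    series_ids = [("A", f"A{i + 1}") for i in range(n_series_a)] + [
        ("B", f"B{i + 1}") for i in range(n_series_b)
    ]
    one_sided_cond = {g: ("A" if i % 2 == 0 else "B") for i, g in enumerate(one_sided)}

    def sig_p(size: int) -> np.ndarray:
        return rng.uniform(1e-6, p_signal, size)

    def null_p(size: int) -> np.ndarray:
        return rng.uniform(0.05, 1.0, size)

    def sig_lfc(size: int) -> np.ndarray:
        return rng.uniform(lo, hi, size)

    def out_of_window_lfc(size: int) -> np.ndarray:
        small = rng.uniform(0.0, 0.45, size)
        large = rng.uniform(2.05, 4.0, size)
        sign = rng.choice([-1.0, 1.0], size)
        return sign * np.where(rng.random(size) < 0.5, small, large)

    tables: list[SeriesTable] = []
    for cond, sid in series_ids:
        recs: list[DEGRecord] = []
        for g, lfc, p in zip(up_genes, sig_lfc(len(up_genes)), sig_p(len(up_genes))):
            recs.append(DEGRecord(g, float(lfc), float(p), sid, cond))
        for g, lfc, p in zip(down_genes, sig_lfc(len(down_genes)), sig_p(len(down_genes))):
            recs.append(DEGRecord(g, float(-lfc), float(p), sid, cond))
        lfcs = sig_lfc(len(fail_p)) * rng.choice([-1.0, 1.0], len(fail_p))
        for g, lfc, p in zip(fail_p, lfcs, null_p(len(fail_p))):
            recs.append(DEGRecord(g, float(lfc), float(p), sid, cond))
        for g, lfc, p in zip(fail_lfc, out_of_window_lfc(len(fail_lfc)), sig_p(len(fail_lfc))):
            recs.append(DEGRecord(g, float(lfc), float(p), sid, cond))
        for g in one_sided:
            sign = 1.0 if hash_sign(g) else -1.0
            lfc = float(sign * rng.uniform(lo, hi))
            if one_sided_cond[g] == cond:
                p = float(rng.uniform(1e-6, p_signal))
            else:
                p = float(rng.uniform(0.05, 1.0))
            recs.append(DEGRecord(g, lfc, p, sid, cond))
        recs.sort(key=lambda r: r.gene)
        tables.append(SeriesTable(sid, cond, recs))

    truth = SyntheticTruth(
        planted_up_overlap=set(up_genes),
        planted_down_overlap=set(down_genes),
        seed_gene_labels={**{g: "up" for g in up_genes}, **{g: "down" for g in down_genes}},
        rng_seed=rng_seed,
    )
    _assert_planted_signal(tables, truth)
    return tables, truth


def hash_sign(symbol: str) -> bool:
    """Deterministic pseudo-sign for a gene symbol (stable across runs)."""
    return sum(symbol.encode()) % 2 == 0


def _assert_planted_signal(tables: list[SeriesTable], truth: SyntheticTruth) -> None:
    """Exhaustive check: every planted gene passes the filter in every series."""
    from .degs import filter_degs

    th = Thresholds()
    for table in tables:
        up, down = filter_degs(table.records, th)
        missing_up = truth.planted_up_overlap - up
        missing_down = truth.planted_down_overlap - down
        if missing_up or missing_down:  # pragma: no cover - construction guarantees
            raise AssertionError(
                f"planted signal lost in series {table.series}: {missing_up | missing_down}"
            )


# ---------------------------------------------------------------------------
# Network generation: preferential-attachment backbone + planted cliques
# wired in through degree-2 connector nodes.
# ---------------------------------------------------------------------------


def _preferential_attachment(labels: list[str], m: int, rng: np.random.Generator) -> Network:
    """Barabási–Albert-style growth over the given node labels."""
    n = len(labels)
    if m < 1:
        raise ValueError("attach_m must be >= 1")
    if m >= n:
        raise ValueError(f"attach_m={m} must be smaller than the backbone size {n}")
    net = Network(nodes=labels)
    # seed with a star on the first m+1 nodes, then grow
    repeated: list[str] = []
    for i in range(1, m + 1):
        net.add_edge(labels[0], labels[i])
        repeated += [labels[0], labels[i]]
    for i in range(m + 1, n):
        targets: set[str] = set()
        while len(targets) < m:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        for t in targets:
            net.add_edge(labels[i], t)
            repeated += [labels[i], t]
    return net


def gen_ppin(
    n_nodes: int,
    attach_m: int,
    clique_sizes: list[int],
    seed_genes: list[str] | None = None,
    rng_seed: int = 0,
) -> tuple[Network, SyntheticTruth]:
    """Scale-free-ish backbone with fully connected planted modules.

    Each planted clique is attached to the backbone through a dedicated
    connector node of degree 2 (one edge into the clique, one into a
    low-degree backbone node), which keeps the modules separable for
    density-based module detection. Total node count is exactly
    ``n_nodes`` = backbone + connectors + clique members.
    """
    if any(s < 3 for s in clique_sizes):
        raise ValueError("every clique size must be >= 3")
    n_planted = sum(clique_sizes)
    if n_nodes < n_planted:
        raise ValueError(f"n_nodes={n_nodes} < total clique nodes {n_planted}")
    n_backbone = n_nodes - n_planted - len(clique_sizes)
    if n_backbone < attach_m + 1:
        raise ValueError(
            f"backbone of {n_backbone} nodes too small for attach_m={attach_m} "
            f"(need n_nodes >= cliques + connectors + attach_m + 1)"
        )
    rng = np.random.default_rng(rng_seed)
    backbone_labels = [f"N{i:05d}" for i in range(1, n_backbone + 1)]
    net = _preferential_attachment(backbone_labels, attach_m, rng)

    seeds = [s.strip().upper() for s in (seed_genes or [])]
    if len(seeds) != len(set(seeds)):
        raise ValueError("seed gene symbols must be unique")
    if len(seeds) > n_planted:
        raise ValueError("more seed genes than planted clique slots")
    seed_iter = iter(seeds)

    planted_modules: list[set[str]] = []
    deg = net.degrees()
    for k, size in enumerate(clique_sizes, start=1):
        members = []
        for j in range(1, size + 1):
            label = next(seed_iter, None) or f"C{k:02d}M{j:02d}"
            members.append(label)
        for i in range(size):
            for j in range(i + 1, size):
                net.add_edge(members[i], members[j])
        # degree-2 connector bridges the clique to a low-degree backbone node
        connector = f"B{k:02d}"
        anchor = min(backbone_labels, key=lambda v: (deg[v], v))
        deg[anchor] += 1  # spread bridges over distinct anchors
        net.add_edge(connector, members[0])
        net.add_edge(connector, anchor)
        planted_modules.append(set(members))

    remaining = list(seed_iter)
    if remaining:
        raise AssertionError("unplaced seed genes")  # pragma: no cover
    truth = SyntheticTruth(planted_modules=planted_modules, rng_seed=rng_seed)
    return net, truth
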