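"""Dense-module detection: vertex weighting, seeded complex prediction,
post-processing, and recursive decomposition down to triangle motifs.

The three-stage algorithm scores every vertex by the density of the
highest k-core of its closed neighborhood, grows complexes outward from
high-weight seeds, and optionally trims (haircut) or pads (fluff) the
result. All tie-breaking is lexicographic on node symbol so module lists
are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .graph import Network

__all__ = [
    "McodeParams",
    "Module",
    "ModuleHierarchy",
    "core_numbers",
    "highest_k_core",
    "vertex_weights",
    "predict_complexes",
    "postprocess",
    "find_modules",
    "decompose_hierarchy",
    "annotate_seed_genes",
    "write_module_table",
]


@dataclass(frozen=True)
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff < 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1)")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class Module:
    """One detected complex, with its density-based score."""

    members: frozenset[str]
    edge_count: int
    mcode_score: float
    seed_genes: dict[str, str] = field(default_factory=dict)
    he: float | None = None

    @property
    def node_count(self) -> int:
        return len(self.members)

    @property
    def density(self) -> float:
        n = self.node_count
        if n < 2:
            return 0.0
        return 2.0 * self.edge_count / (n * (n - 1))

    @property
    def is_motif(self) -> bool:
        return self.node_count == 3 and self.edge_count == 3

    @staticmethod
    def from_nodes(net: Network, nodes) -> "Module":
        sub = net.induced_subgraph(nodes)
        module = Module(members=frozenset(sub.nodes), edge_count=sub.n_edges, mcode_score=0.0)
        module.mcode_score = module.density * module.node_count
        return module


def core_numbers(net: Network) -> dict[str, int]:
    """Core number per node via minimum-degree peeling.

    Peel the minimum-degree vertex repeatedly; the core number is the
    running maximum of the degrees seen at removal time.
    """
    remaining = net.degrees()
    nbrs = {v: net.neighbors(v) for v in remaining}
    by_degree: dict[int, set[str]] = {}
    for v, d in remaining.items():
        by_degree.setdefault(d, set()).add(v)
    core: dict[str, int] = {}
    k = 0
    for _ in range(len(remaining)):
        d = min(d for d, bucket in by_degree.items() if bucket)
        v = min(by_degree[d])
        by_degree[d].remove(v)
        k = max(k, d)
        core[v] = k
        for u in nbrs[v]:
            if u in core:
                continue
            du = remaining[u]
            by_degree[du].remove(u)
            remaining[u] = du - 1
            by_degree.setdefault(du - 1, set()).add(u)
        del remaining[v]
    return core


def highest_k_core(net: Network) -> tuple[int, Network]:
    """(k_max, subgraph) — the k-core with the largest k; empty graph -> (0, net)."""
    core = core_numbers(net)
    if not core:
        return 0, net
    k_max = max(core.values())
    nodes = [v for v, c in core.items() if c == k_max]
    return k_max, net.induced_subgraph(nodes)


def k_core_subgraph(net: Network, k: int) -> Network:
    core = core_numbers(net)
    return net.induced_subgraph([v for v, c in core.items() if c >= k])


def vertex_weights(net: Network, params: McodeParams | None = None) -> dict[str, float]:
    """weight(v) = k_max * density of the highest k-core of G[N(v) + v].

    Vertices with degree below ``degree_cutoff``, or whose closed
    neighborhood has no 2-core, weigh 0.
    """
    params = params or McodeParams()
    weights: dict[str, float] = {}
    for v in net.nodes:
        if net.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = net.induced_subgraph(net.neighbors(v) | {v})
        k_max, core_sub = highest_k_core(closed)
        weights[v] = k_max * core_sub.density() if k_max >= 2 else 0.0
    return weights


def predict_complexes(
    net: Network, weights: dict[str, float], params: McodeParams | None = None
) -> list[Module]:
    """Grow node-disjoint complexes outward from high-weight seed vertices.

    Seeds are visited in order of descending weight (ties lexicographic);
    a breadth-first traversal from each seed includes unassigned neighbors
    whose weight exceeds ``seed_weight * (1 - node_score_cutoff)``, up to
    ``max_depth`` hops.
    """
    params = params or McodeParams()
    assigned: set[str] = set()
    complexes: list[Module] = []
    for seed in sorted(weights, key=lambda v: (-weights[v], v)):
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for v in frontier:
                for u in sorted(net.neighbors(v)):
                    if u in assigned or u in members:
                        continue
                    if weights[u] > threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        assigned |= members
        complexes.append(Module.from_nodes(net, members))
    complexes.sort(key=lambda m: (-m.mcode_score, sorted(m.members)))
    return complexes


def postprocess(
    complexes: list[Module], net: Network, params: McodeParams | None = None
) -> list[Module]:
    """Filter complexes without a k-core; optional haircut and fluff.

    Haircut iteratively removes members of induced degree < 2; fluff adds
    outside neighbors whose closed-neighborhood density exceeds
    ``fluff_density`` (fluffed nodes may appear in several complexes).
    Complexes smaller than 3 nodes are dropped from the report.
    """
    params = params or McodeParams()
    out: list[Module] = []
    for module in complexes:
        sub = net.induced_subgraph(module.members)
        core = core_numbers(sub)
        if not core or max(core.values()) < params.k_core:
            continue
        members = set(sub.nodes)
        if params.haircut:
            changed = True
            while changed:
                changed = False
                sub2 = net.induced_subgraph(members)
                drop = {v for v in members if sub2.degree(v) < 2}
                if drop:
                    members -= drop
                    changed = True
        if params.fluff:
            extra = set()
            for v in sorted(members):
                for u in sorted(net.neighbors(v)):
                    if u in members or u in extra:
                        continue
                    closed = net.induced_subgraph(net.neighbors(u) | {u})
                    if closed.density() > params.fluff_density:
                        extra.add(u)
            members |= extra
        if len(members) < 3:
            continue
        out.append(Module.from_nodes(net, members))
    out.sort(key=lambda m: (-m.mcode_score, sorted(m.members)))
    return out


def find_modules(net: Network, params: McodeParams | None = None) -> list[Module]:
    """Full three-stage pass: weight, predict, post-process."""
    params = params or McodeParams()
    weights = vertex_weights(net, params)
    return postprocess(predict_complexes(net, weights, params), net, params)


@dataclass
class ModuleHierarchy:
    """Recursive decomposition; leaves are motifs or irreducible modules."""

    module: Module | None  # None at the root
    level: int
    children: list["ModuleHierarchy"] = field(default_factory=list)

    def walk(self):
        """Yield (level, module) pairs depth-first, skipping the root."""
        for child in self.children:
            if child.module is not None:
                yield child.level, child.module
            yield from child.walk()

    def to_dict(self) -> dict:
        node: dict = {"level": self.level}
        if self.module is not None:
            node["nodes"] = sorted(self.module.members)
            node["edge_count"] = self.module.edge_count
            node["mcode_score"] = self.module.mcode_score
        node["children"] = [c.to_dict() for c in self.children]
        return node

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def decompose_hierarchy(net: Network, params: McodeParams | None = None) -> ModuleHierarchy:
    """Apply module detection recursively until only motifs (or irreducible
    modules) remain. A module that reproduces itself is a leaf."""
    params = params or McodeParams()
    root = ModuleHierarchy(module=None, level=0)
    _decompose_into(root, net, set(net.nodes), params)
    return root


def _decompose_into(
    parent: ModuleHierarchy, net: Network, nodes: set[str], params: McodeParams
) -> None:
    sub = net.induced_subgraph(nodes)
    for module in find_modules(sub, params):
        if parent.module is not None and module.members == parent.module.members:
            continue  # module reproduces itself; the parent is a leaf
        child = ModuleHierarchy(module=module, level=parent.level + 1)
        parent.children.append(child)
        if module.is_motif:
            continue
        _decompose_into(child, net, set(module.members), params)


def annotate_seed_genes(
    modules: list[Module], seeds: dict[str, str]
) -> tuple[list[Module], dict]:
    """Attach seed-gene labels to each module; summarize retention.

    Returns the annotated modules plus a summary with per-module counts,
    the total retained across modules, and the seeds absent from every
    module ("not retained").
    """
    seeds = {k.strip().upper(): v for k, v in seeds.items()}
    retained: set[str] = set()
    for module in modules:
        module.seed_genes = {g: seeds[g] for g in sorted(module.members) if g in seeds}
        retained |= set(module.seed_genes)
    summary = {
        "per_module": [len(m.seed_genes) for m in modules],
        "total_retained": len(retained),
        "retained": sorted(retained),
        "not_retained": sorted(set(seeds) - retained),
    }
    return modules, summary


def write_module_table(modules: list[Module], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\tnodes\tedges\tseed_count\tseed_genes\tmcode_score\n")
        for i, m in enumerate(modules, start=1):
            fh.write(
                f"M{i}\t{m.node_count}\t{m.edge_count}\t{len(m.seed_genes)}\t"
                f"{','.join(sorted(m.seed_genes))}\t{m.mcode_score:.4f}\n"
            )
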