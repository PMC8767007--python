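"""Undirected simple-graph data model and I/O.

The graph type is deliberately minimal: gene symbols as nodes, an
adjacency-set representation, no weights (weights found in input files are
parsed and discarded — every downstream algorithm is purely topological).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from pathlib import Path

__all__ = ["Network", "NetworkFormatError", "read_network", "write_network", "network_summary"]


class NetworkFormatError(ValueError):
    """Raised when a network file cannot be parsed."""


class Network:
    """Undirected simple graph over string-labelled nodes.

    Self-loops and duplicate edges are silently ignored on insertion; node
    labels are stripped and uppercased so the node universe matches the
    DEG tables.
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        self._adj: dict[str, set[str]] = {}
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    @staticmethod
    def _norm(label: str) -> str:
        label = str(label).strip().upper()
        if not label:
            raise ValueError("empty node label")
        return label

    # -- construction -------------------------------------------------------

    def add_node(self, n: str) -> str:
        n = self._norm(n)
        self._adj.setdefault(n, set())
        return n

    def add_edge(self, u: str, v: str) -> None:
        u, v = self.add_node(u), self.add_node(v)
        if u == v:
            return
        self._adj[u].add(v)
        self._adj[v].add(u)

    def copy(self) -> "Network":
        g = Network()
        g._adj = {n: set(nbrs) for n, nbrs in self._adj.items()}
        return g

    # -- queries ------------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    @property
    def edges(self) -> list[tuple[str, str]]:
        out = []
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return sorted(out)

    def __len__(self) -> int:
        return len(self._adj)

    def __contains__(self, n: str) -> bool:
        return str(n).strip().upper() in self._adj

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._adj))

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def neighbors(self, n: str) -> set[str]:
        return set(self._adj[self._norm(n)])

    def degree(self, n: str) -> int:
        return len(self._adj[self._norm(n)])

    def degrees(self) -> dict[str, int]:
        return {n: len(self._adj[n]) for n in self.nodes}

    def has_edge(self, u: str, v: str) -> bool:
        u, v = self._norm(u), self._norm(v)
        return u in self._adj and v in self._adj[u]

    def induced_subgraph(self, nodes: Iterable[str]) -> "Network":
        """Subgraph on ``nodes``; raises on labels absent from the graph."""
        keep = {self._norm(n) for n in nodes}
        unknown = keep - set(self._adj)
        if unknown:
            raise KeyError(f"nodes not in network: {sorted(unknown)}")
        g = Network()
        for n in keep:
            g.add_node(n)
        for u in keep:
            for v in self._adj[u] & keep:
                g.add_edge(u, v)
        return g

    def connected_components(self) -> list[set[str]]:
        seen: set[str] = set()
        comps = []
        for start in self.nodes:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in self._adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            comps.append(comp)
        return comps

    def density(self) -> float:
        n = len(self)
        if n < 2:
            return 0.0
        return 2.0 * self.n_edges / (n * (n - 1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Network(n_nodes={len(self)}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float
    degree_min: int
    degree_median: float
    degree_max: int
    n_components: int

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "degree_min": self.degree_min,
            "degree_median": self.degree_median,
            "degree_max": self.degree_max,
            "n_components": self.n_components,
        }


def network_summary(net: Network) -> NetworkSummary:
    degs = sorted(net.degrees().values())
    if not degs:
        return NetworkSummary(0, 0, 0.0, 0, 0.0, 0, 0)
    k = len(degs)
    median = float(degs[k // 2]) if k % 2 else (degs[k // 2 - 1] + degs[k // 2]) / 2.0
    return NetworkSummary(
        n_nodes=len(net),
        n_edges=net.n_edges,
        density=net.density(),
        degree_min=degs[0],
        degree_median=median,
        degree_max=degs[-1],
        n_components=len(net.connected_components()),
    )


# ---------------------------------------------------------------------------
# I/O.  Three text formats: 2/3-column edge list, SIF, GraphML.
# Nodes that appear only in dropped self-loops are kept as isolated nodes so
# the node universe of downstream score tables is stable.
# ---------------------------------------------------------------------------

_FORMATS = ("edgelist", "sif", "graphml")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".sif":
        return "sif"
    if suffix == ".graphml":
        return "graphml"
    return "edgelist"


def read_network(path: str | Path, format: str | None = None) -> Network:
    """Parse a network file, dropping self-loops and duplicate edges.

    Raises :class:`NetworkFormatError` with a line number on malformed
    input and on an empty graph.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "graphml":
        net = _read_graphml(path)
    else:
        net = _read_delimited(path, fmt)
    if len(net) == 0:
        raise NetworkFormatError(f"{path}: empty graph")
    return net


def _read_delimited(path: Path, fmt: str) -> Network:
    net = Network()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "sif":
                # node [relation target1 target2 ...]; fan-out over targets
                if len(fields) == 1:
                    net.add_node(fields[0])
                elif len(fields) >= 3:
                    for target in fields[2:]:
                        net.add_node(fields[0])
                        net.add_node(target)
                        net.add_edge(fields[0], target)
                else:
                    raise NetworkFormatError(f"{path}:{lineno}: malformed SIF line: {line!r}")
            else:
                if len(fields) == 1:
                    net.add_node(fields[0])
                    continue
                if len(fields) not in (2, 3):
                    raise NetworkFormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}")
                if len(fields) == 3:
                    try:
                        float(fields[2])  # weight column: validated, ignored
                    except ValueError as exc:
                        raise NetworkFormatError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
                net.add_node(fields[0])
                net.add_node(fields[1])
                net.add_edge(fields[0], fields[1])
    return net


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def _read_graphml(path: Path) -> Network:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise NetworkFormatError(f"{path}: invalid GraphML: {exc}") from exc
    ns = {"g": _GRAPHML_NS}
    root = tree.getroot()
    net = Network()
    for node in root.iterfind(".//g:graph/g:node", ns):
        net.add_node(node.get("id", ""))
    for edge in root.iterfind(".//g:graph/g:edge", ns):
        net.add_edge(edge.get("source", ""), edge.get("target", ""))
    return net


def write_network(net: Network, path: str | Path, format: str | None = None) -> None:
    """Write ``net`` in a supported format, with sorted deterministic output."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "graphml":
        _write_graphml(net, path)
        return
    lines = []
    covered: set[str] = set()
    for u, v in net.edges:
        covered.add(u)
        covered.add(v)
        lines.append(f"{u}\tinteracts\t{v}" if fmt == "sif" else f"{u}\t{v}")
    for n in net.nodes:
        if n not in covered:
            lines.append(n)
    path.write_text("".join(line + "\n" for line in lines))


def _write_graphml(net: Network, path: Path) -> None:
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    graph = ET.SubElement(root, f"{{{_GRAPHML_NS}}}graph", edgedefault="undirected")
    for n in net.nodes:
        ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node", id=n)
    for i, (u, v) in enumerate(net.edges):
        ET.SubElement(graph, f"{{{_GRAPHML_NS}}}edge", id=f"e{i}", source=u, target=v)
    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="unicode")
    with open(path, "a") as fh:
        fh.write("\n")
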