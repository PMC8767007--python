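"""Component node centralities combined downstream into influence scores.

All seven measures are implemented from first principles on the package's
own :class:`~ivinet.graph.Network`; an external graph library is used only
in the test suite as an independent oracle.

Conventions (documented per function): distances are hop counts within a
connected component; betweenness is unnormalized with endpoints excluded;
the clustering coefficient of a node of degree < 2 is 0.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .graph import Network

__all__ = [
    "ScoreConfig",
    "degree_centrality",
    "betweenness",
    "neighborhood_connectivity",
    "h_index",
    "local_h_index",
    "clusterrank",
    "collective_influence",
    "all_centralities",
    "CentralityTable",
    "write_centrality_table",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Tunables for the component centralities.

    ci_radius
        Hop distance ``d`` of the collective-influence frontier.
    clusterrank_base
        Base ``b`` of the clustering penalty ``b ** (-c_i)``.
    lh_second_order
        If True, the local H-index is the H-index recomputed over
        second-order neighbor degrees instead of the default
        closed-neighborhood sum of first-order H-indices.
    """

    ci_radius: int = 3
    clusterrank_base: float = 10.0
    lh_second_order: bool = False

    def __post_init__(self) -> None:
        if self.ci_radius < 1:
            raise ValueError("ci_radius must be >= 1")


def degree_centrality(net: Network) -> dict[str, int]:
    """dc(i) = number of neighbors of i."""
    return net.degrees()


def betweenness(net: Network, exact: bool = False) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (Brandes' accumulation).

    Each unordered pair {s, t} contributes sigma_st(v) / sigma_st to every
    interior node v of its geodesics; disconnected pairs contribute 0.
    With ``exact=True`` the accumulation runs in rational arithmetic and
    returns :class:`fractions.Fraction` values.
    """
    from fractions import Fraction

    zero = Fraction(0) if exact else 0.0
    one = Fraction(1) if exact else 1.0
    bc = {v: zero for v in net.nodes}
    adj = {v: net.neighbors(v) for v in net.nodes}
    for s in net.nodes:
        # single-source shortest paths: counts sigma and predecessor DAG
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in adj}
        sigma = {v: zero for v in adj}
        dist = {v: -1 for v in adj}
        sigma[s] = one
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: zero for v in adj}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (one + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: x / 2 for v, x in bc.items()}


def neighborhood_connectivity(net: Network) -> dict[str, float]:
    """nc(i) = mean degree over N(i); 0 for isolated nodes."""
    deg = net.degrees()
    out = {}
    for v in net.nodes:
        nbrs = net.neighbors(v)
        out[v] = sum(deg[u] for u in nbrs) / len(nbrs) if nbrs else 0.0
    return out


def _h_of(values: list[int]) -> int:
    """Largest h such that at least h of ``values`` are >= h."""
    values = sorted(values, reverse=True)
    h = 0
    for i, v in enumerate(values, start=1):
        if v >= i:
            h = i
        else:
            break
    return h


def h_index(net: Network) -> dict[str, int]:
    """h(i): largest h with >= h neighbors of degree >= h."""
    deg = net.degrees()
    return {v: _h_of([deg[u] for u in net.neighbors(v)]) for v in net.nodes}


def local_h_index(net: Network, cfg: ScoreConfig | None = None) -> dict[str, int]:
    """Local H-index.

    Default: lh(i) = h(i) + sum of h(j) over neighbors j (closed
    neighborhood sum, propagating second-order information). With
    ``cfg.lh_second_order``, instead the H-index computed over the degrees
    of i's second-order neighbors.
    """
    cfg = cfg or ScoreConfig()
    h = h_index(net)
    if not cfg.lh_second_order:
        return {v: h[v] + sum(h[u] for u in net.neighbors(v)) for v in net.nodes}
    deg = net.degrees()
    out = {}
    for v in net.nodes:
        second = set()
        for u in net.neighbors(v):
            second |= net.neighbors(u)
        second.discard(v)
        out[v] = _h_of([deg[u] for u in second])
    return out


def _local_clustering(net: Network, v: str) -> float:
    nbrs = sorted(net.neighbors(v))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1 for i in range(k) for j in range(i + 1, k) if net.has_edge(nbrs[i], nbrs[j])
    )
    return 2.0 * links / (k * (k - 1))


def clusterrank(net: Network, cfg: ScoreConfig | None = None) -> dict[str, float]:
    """cr(i) = base^(-c_i) * sum over neighbors j of (deg(j) + 1)."""
    cfg = cfg or ScoreConfig()
    deg = net.degrees()
    out = {}
    for v in net.nodes:
        penalty = cfg.clusterrank_base ** (-_local_clustering(net, v))
        out[v] = penalty * sum(deg[u] + 1 for u in net.neighbors(v))
    return out


def _frontier_at(net: Network, source: str, d: int) -> set[str]:
    """Nodes at hop distance exactly d from ``source``."""
    dist = {source: 0}
    queue = deque([source])
    frontier: set[str] = set()
    while queue:
        v = queue.popleft()
        if dist[v] == d:
            frontier.add(v)
            continue
        for w in net.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return frontier


def collective_influence(net: Network, cfg: ScoreConfig | None = None) -> dict[str, float]:
    """ci(i) = (deg(i) - 1) * sum of (deg(j) - 1) over the distance-d frontier."""
    cfg = cfg or ScoreConfig()
    deg = net.degrees()
    out = {}
    for v in net.nodes:
        if deg[v] == 0:
            out[v] = 0.0
            continue
        frontier = _frontier_at(net, v, cfg.ci_radius)
        out[v] = float((deg[v] - 1) * sum(deg[u] - 1 for u in frontier))
    return out


#: column order of the serialized table
CENTRALITY_COLUMNS = ("dc", "bc", "nc", "h", "lh", "cr", "ci")


@dataclass(frozen=True)
class CentralityTable:
    """Per-node values of the seven component measures, same key set each."""

    dc: dict[str, int]
    bc: dict[str, float]
    nc: dict[str, float]
    h: dict[str, int]
    lh: dict[str, int]
    cr: dict[str, float]
    ci: dict[str, float]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.dc)

    def column(self, name: str) -> dict[str, float]:
        if name not in CENTRALITY_COLUMNS:
            raise KeyError(name)
        return getattr(self, name)


def all_centralities(net: Network, cfg: ScoreConfig | None = None) -> CentralityTable:
    cfg = cfg or ScoreConfig()
    return CentralityTable(
        dc=degree_centrality(net),
        bc=betweenness(net),
        nc=neighborhood_connectivity(net),
        h=h_index(net),
        lh=local_h_index(net, cfg),
        cr=clusterrank(net, cfg),
        ci=collective_influence(net, cfg),
    )


def write_centrality_table(table: CentralityTable, path) -> None:
    """Tab-separated table, one row per node, 6-decimal reals, sorted nodes."""
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(CENTRALITY_COLUMNS) + "\n")
        for v in table.nodes:
            cells = [v]
            for col in CENTRALITY_COLUMNS:
                val = table.column(col)[v]
                cells.append(str(val) if isinstance(val, int) else f"{val:.6f}")
            fh.write("\t".join(cells) + "\n")
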