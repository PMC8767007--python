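"""Composite influence scoring: spreading, hubness and IVI.

Score algebra, centralized here so alternates can be swapped in one place:

    x' = range_normalize(x, 1, 100)            for each component column
    spreading_raw = (nc' + cr') * (bc' + ci')
    hubness_raw   = dc' + lh'
    spreading     = range_normalize(spreading_raw)
    hubness       = range_normalize(hubness_raw)
    ivi_raw       = hubness * spreading
    ivi           = range_normalize(ivi_raw)

The lower normalization bound is 1 (not 0) so the multiplicative joins
never annihilate a node's score.
"""

from __future__ import annotations

from dataclasses import dataclass

from .centrality import CentralityTable

__all__ = [
    "range_normalize",
    "spreading_score",
    "hubness_score",
    "ivi",
    "rank_top",
    "InfluenceTable",
    "write_influence_table",
]

INFLUENCE_COLUMNS = ("spreading_raw", "hubness_raw", "ivi_raw", "spreading", "hubness", "ivi")


def range_normalize(values: dict[str, float], lo: float = 1.0, hi: float = 100.0) -> dict[str, float]:
    """Affine map of [min, max] onto [lo, hi]; constant vectors map to lo."""
    if not values:
        raise ValueError("cannot normalize an empty vector")
    if lo >= hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    vmin = min(values.values())
    vmax = max(values.values())
    if vmax == vmin:
        return {k: float(lo) for k in values}
    span = vmax - vmin
    return {k: lo + (v - vmin) / span * (hi - lo) for k, v in values.items()}


def spreading_score(ct: CentralityTable) -> tuple[dict[str, float], dict[str, float]]:
    """(raw, normalized) spreading score per node."""
    nc = range_normalize(ct.nc)
    cr = range_normalize(ct.cr)
    bc = range_normalize(ct.bc)
    ci = range_normalize(ct.ci)
    raw = {v: (nc[v] + cr[v]) * (bc[v] + ci[v]) for v in ct.nodes}
    return raw, range_normalize(raw)


def hubness_score(ct: CentralityTable) -> tuple[dict[str, float], dict[str, float]]:
    """(raw, normalized) hubness score per node."""
    dc = range_normalize({k: float(v) for k, v in ct.dc.items()})
    lh = range_normalize({k: float(v) for k, v in ct.lh.items()})
    raw = {v: dc[v] + lh[v] for v in ct.nodes}
    return raw, range_normalize(raw)


@dataclass(frozen=True)
class InfluenceTable:
    spreading_raw: dict[str, float]
    hubness_raw: dict[str, float]
    ivi_raw: dict[str, float]
    spreading: dict[str, float]
    hubness: dict[str, float]
    ivi: dict[str, float]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.ivi)

    def column(self, name: str) -> dict[str, float]:
        if name not in INFLUENCE_COLUMNS:
            raise KeyError(name)
        return getattr(self, name)


def ivi(ct: CentralityTable) -> InfluenceTable:
    """Full influence table: raw and [1,100]-normalized columns."""
    spreading_raw, spreading = spreading_score(ct)
    hubness_raw, hubness = hubness_score(ct)
    ivi_raw = {v: hubness[v] * spreading[v] for v in ct.nodes}
    return InfluenceTable(
        spreading_raw=spreading_raw,
        hubness_raw=hubness_raw,
        ivi_raw=ivi_raw,
        spreading=spreading,
        hubness=hubness,
        ivi=range_normalize(ivi_raw),
    )


def rank_top(tbl: InfluenceTable, k: int, by: str = "ivi") -> list[tuple[str, float]]:
    """Top-k (node, score) by a score column, descending; ties broken by symbol."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if by not in ("ivi", "spreading", "hubness"):
        raise KeyError(f"unknown ranking column {by!r}")
    col = tbl.column(by)
    ordered = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:k]


def write_influence_table(tbl: InfluenceTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(INFLUENCE_COLUMNS) + "\n")
        for v in tbl.nodes:
            cells = [v] + [f"{tbl.column(c)[v]:.5f}" for c in INFLUENCE_COLUMNS]
            fh.write("\t".join(cells) + "\n")
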