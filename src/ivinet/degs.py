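"""Differential-expression filtering and cross-condition overlap.

Per-series DEG tables are filtered with a p-value cut (strict ``<``) and a
closed absolute log-fold-change band (default [0.5, 2]); up/down sets are
unioned within each condition and intersected across the two conditions.
Genes landing in both the up- and down-overlap are reported as
``discordant`` and excluded from both sets, keeping the final overlap a
disjoint union.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "DEGRecord",
    "Thresholds",
    "ConditionSets",
    "OverlapResult",
    "collapse_probes",
    "filter_degs",
    "read_series_table",
    "build_condition_sets",
    "overlap",
]

SERIES_COLUMNS = ["gene", "logFC", "pvalue", "series", "condition"]


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression evidence in one series."""

    gene: str
    logfc: float
    pvalue: float
    series: str
    condition: str

    def __post_init__(self) -> None:
        if not self.gene or not str(self.gene).strip():
            raise ValueError("gene symbol must be nonempty")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue out of [0, 1]: {self.pvalue}")

    def normalized(self) -> "DEGRecord":
        sym = str(self.gene).strip().upper()
        if sym == self.gene:
            return self
        return DEGRecord(sym, self.logfc, self.pvalue, self.series, self.condition)


@dataclass(frozen=True)
class Thresholds:
    """Filtering thresholds; ``lfc_high=inf`` disables the upper band edge."""

    p_max: float = 0.05
    lfc_low: float = 0.5
    lfc_high: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lfc_low <= self.lfc_high:
            raise ValueError(f"need 0 < lfc_low <= lfc_high, got {self.lfc_low}, {self.lfc_high}")

    def without_upper(self) -> "Thresholds":
        return Thresholds(self.p_max, self.lfc_low, math.inf)


@dataclass
class ConditionSets:
    """Per-series and unioned up/down DEG sets of one condition."""

    condition: str
    up_by_series: dict[str, set[str]] = field(default_factory=dict)
    down_by_series: dict[str, set[str]] = field(default_factory=dict)

    @property
    def up_union(self) -> set[str]:
        return set().union(*self.up_by_series.values()) if self.up_by_series else set()

    @property
    def down_union(self) -> set[str]:
        return set().union(*self.down_by_series.values()) if self.down_by_series else set()


@dataclass(frozen=True)
class OverlapResult:
    up_overlap: frozenset[str]
    down_overlap: frozenset[str]
    discordant: frozenset[str]

    @property
    def all_overlap(self) -> frozenset[str]:
        return self.up_overlap | self.down_overlap

    def venn_counts(self, cond_a: ConditionSets | None = None, cond_b: ConditionSets | None = None) -> dict:
        counts = {
            "up_overlap": len(self.up_overlap),
            "down_overlap": len(self.down_overlap),
            "all_overlap": len(self.all_overlap),
            "discordant": len(self.discordant),
        }
        for cs in (cond_a, cond_b):
            if cs is not None:
                counts[f"up_union_{cs.condition}"] = len(cs.up_union)
                counts[f"down_union_{cs.condition}"] = len(cs.down_union)
        return counts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "up_overlap": sorted(self.up_overlap),
            "down_overlap": sorted(self.down_overlap),
            "all_overlap": sorted(self.all_overlap),
            "discordant": sorted(self.discordant),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def collapse_probes(records: list[DEGRecord]) -> list[DEGRecord]:
    """One record per (gene, series): keep the max-|logFC| probe.

    Symbols are uppercased/stripped before grouping, so probes mapping to
    case variants of one symbol collapse together. Ties on |logFC| are
    broken by the smaller p-value, then input order.
    """
    best: dict[tuple[str, str], DEGRecord] = {}
    for rec in records:
        rec = rec.normalized()
        key = (rec.gene, rec.series)
        cur = best.get(key)
        if cur is None or abs(rec.logfc) > abs(cur.logfc) or (
            abs(rec.logfc) == abs(cur.logfc) and rec.pvalue < cur.pvalue
        ):
            best[key] = rec
    return list(best.values())


def filter_degs(records: list[DEGRecord], thresholds: Thresholds | None = None) -> tuple[set[str], set[str]]:
    """(up, down) gene sets passing p < p_max and lfc_low <= |logFC| <= lfc_high."""
    th = thresholds or Thresholds()
    up, down = set(), set()
    for rec in records:
        rec = rec.normalized()
        if not rec.pvalue < th.p_max:
            continue
        if th.lfc_low <= rec.logfc <= th.lfc_high:
            up.add(rec.gene)
        elif -th.lfc_high <= rec.logfc <= -th.lfc_low:
            down.add(rec.gene)
    return up, down


def read_series_table(path: str | Path) -> list[DEGRecord]:
    """Read a tab-separated table with columns gene/logFC/pvalue/series/condition."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "series": str, "condition": str})
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DEGRecord(r.gene, float(r.logFC), float(r.pvalue), r.series, r.condition)
        for r in df.itertuples(index=False)
    ]


def build_condition_sets(
    records: list[DEGRecord],
    conditions: tuple[str, str],
    thresholds: Thresholds | dict[str, Thresholds] | None = None,
) -> tuple[ConditionSets, ConditionSets]:
    """Filter each series with its own thresholds and union per condition.

    ``thresholds`` may be a single global :class:`Thresholds` or a map
    series -> Thresholds (series missing from the map get defaults).
    """
    records = collapse_probes(records)
    known = set(conditions)
    by_cond: dict[str, ConditionSets] = {c: ConditionSets(c) for c in conditions}
    by_series: dict[tuple[str, str], list[DEGRecord]] = {}
    for rec in records:
        if rec.condition not in known:
            raise ValueError(f"series {rec.series!r} has unknown condition {rec.condition!r} (expected {conditions})")
        by_series.setdefault((rec.condition, rec.series), []).append(rec)
    for (cond, series), recs in sorted(by_series.items()):
        if isinstance(thresholds, dict):
            th = thresholds.get(series, Thresholds())
        else:
            th = thresholds or Thresholds()
        up, down = filter_degs(recs, th)
        by_cond[cond].up_by_series[series] = up
        by_cond[cond].down_by_series[series] = down
    return by_cond[conditions[0]], by_cond[conditions[1]]


def overlap(cond_a: ConditionSets, cond_b: ConditionSets) -> OverlapResult:
    """Cross-condition intersection of the up and down unions."""
    up = cond_a.up_union & cond_b.up_union
    down = cond_a.down_union & cond_b.down_union
    discordant = up & down
    return OverlapResult(
        up_overlap=frozenset(up - discordant),
        down_overlap=frozenset(down - discordant),
        discordant=frozenset(discordant),
    )
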