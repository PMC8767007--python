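"""Hamiltonian-energy profiling of module hierarchies.

A module with N nodes and E edges carries energy HE = E - gamma * N
(gamma defaults to 0.8), so dense modules dominate sparse ones of equal
size. Profiles report the energy per module at every hierarchy level plus
a monotonicity diagnostic (fraction of child modules whose energy falls
below their parent's) — decline across levels is an empirical tendency,
not a theorem, so it is reported rather than enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .graph import Network
from .mcode import ModuleHierarchy

__all__ = ["EnergyParams", "hamiltonian_energy", "level_energy_profile", "EnergyProfile"]


@dataclass(frozen=True)
class EnergyParams:
    gamma: float = 0.8

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def hamiltonian_energy(node_count: int, edge_count: int, params: EnergyParams | None = None) -> float:
    """HE = E - gamma * N for a module with N nodes and E edges."""
    if node_count < 0 or edge_count < 0:
        raise ValueError("node and edge counts must be nonnegative")
    params = params or EnergyParams()
    return edge_count - params.gamma * node_count


@dataclass
class EnergyProfile:
    """Energy per module, grouped by hierarchy level; level 0 is the root."""

    rows: list[tuple[int, str, int, int, float]]  # (level, module_id, nodes, edges, he)
    level_totals: dict[int, float]
    declining_fraction: float  # children with HE below their parent

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("level\tmodule_id\tnodes\tedges\the\n")
            for level, mid, n, e, he in self.rows:
                fh.write(f"{level}\t{mid}\t{n}\t{e}\t{he:.4f}\n")

    def plot(self, path: str | Path) -> None:
        """Bar chart of per-module energy grouped by level."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        xs = range(len(self.rows))
        ax.bar(xs, [r[4] for r in self.rows], color=["C" + str(r[0] % 10) for r in self.rows])
        ax.set_xticks(list(xs))
        ax.set_xticklabels([r[1] for r in self.rows], rotation=90, fontsize=6)
        ax.set_ylabel("Hamiltonian energy")
        ax.set_xlabel("module (grouped by level)")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def level_energy_profile(
    hierarchy: ModuleHierarchy, root: Network, params: EnergyParams | None = None
) -> EnergyProfile:
    """Profile the hierarchy: root at level 0, each module at its depth."""
    params = params or EnergyParams()
    rows: list[tuple[int, str, int, int, float]] = [
        (0, "root", len(root), root.n_edges, hamiltonian_energy(len(root), root.n_edges, params))
    ]

    n_children = 0
    n_declining = 0
    counter = {"i": 0}

    def visit(node: ModuleHierarchy, parent_he: float) -> None:
        nonlocal n_children, n_declining
        for child in node.children:
            m = child.module
            counter["i"] += 1
            he = hamiltonian_energy(m.node_count, m.edge_count, params)
            m.he = he
            rows.append((child.level, f"M{counter['i']}", m.node_count, m.edge_count, he))
            n_children += 1
            if he < parent_he:
                n_declining += 1
            visit(child, he)

    visit(hierarchy, rows[0][4])
    rows.sort(key=lambda r: (r[0], -r[4], r[1]))
    totals: dict[int, float] = {}
    for level, _, _, _, he in rows:
        totals[level] = totals.get(level, 0.0) + he
    frac = n_declining / n_children if n_children else 0.0
    return EnergyProfile(rows=rows, level_totals=totals, declining_fraction=frac)
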