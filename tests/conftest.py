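from __future__ import annotations

import pytest

from ivinet.graph import Network


def net_from_edges(*edges: tuple[str, str], nodes: tuple[str, ...] = ()) -> Network:
    return Network(nodes=nodes, edges=edges)


def path_graph(labels: str | list[str]) -> Network:
    labels = list(labels)
    return Network(nodes=labels, edges=list(zip(labels, labels[1:])))


def cycle_graph(labels: str | list[str]) -> Network:
    labels = list(labels)
    return Network(nodes=labels, edges=list(zip(labels, labels[1:] + labels[:1])))


def complete_graph(labels: str | list[str]) -> Network:
    labels = list(labels)
    edges = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    return Network(nodes=labels, edges=edges)


def star_graph(center: str, leaves: str | list[str]) -> Network:
    return Network(edges=[(center, leaf) for leaf in leaves])


@pytest.fixture
def triangle() -> Network:
    return complete_graph("ABC")


@pytest.fixture
def p3() -> Network:
    return path_graph("ABC")


@pytest.fixture
def k5() -> Network:
    return complete_graph("ABCDE")


@pytest.fixture
def star5() -> Network:
    # S5: one center, five leaves
    return star_graph("Z", "ABCDE")
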