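"""Shared fixtures and independent brute-force oracles for the suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from enteronet.io_tables import AbundanceTable, PhenotypeTable


@pytest.fixture
def toy_abundance() -> AbundanceTable:
    """Four samples × three taxa on the simplex."""
    df = pd.DataFrame(
        [
            [0.5, 0.3, 0.2],
            [0.4, 0.4, 0.2],
            [0.1, 0.2, 0.7],
            [0.2, 0.1, 0.7],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["taxA", "taxB", "taxC"],
    )
    return AbundanceTable(df)


@pytest.fixture
def toy_phenotypes() -> PhenotypeTable:
    df = pd.DataFrame(
        {"milk": [3.1, 3.3, 2.5, 2.4], "glucose": [2.9, 2.8, 2.6, 2.7]},
        index=["s1", "s2", "s3", "s4"],
    )
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# Independent oracles (brute force / enumeration) — never call package code.

def brute_force_medoids(d: np.ndarray, k: int) -> tuple[float, tuple[int, ...]]:
    """Exhaustive k-medoid search: minimum total nearest-medoid distance."""
    best_cost, best = np.inf, None
    for meds in itertools.combinations(range(d.shape[0]), k):
        cost = d[:, meds].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, meds
    return float(best_cost), best


def all_partitions(nodes: list):
    """All set partitions of ``nodes`` (restricted growth enumeration)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def brute_force_modularity(graph: nx.Graph) -> float:
    """Maximum modularity over every partition of the node set."""
    nodes = list(graph.nodes)
    return max(
        nx.community.modularity(graph, [set(block) for block in part])
        for part in all_partitions(nodes)
    )


def euclidean_distance_matrix(points: np.ndarray) -> np.ndarray:
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


def partitions_agree(a, b) -> bool:
    """True when two labelings induce the same partition (up to relabeling)."""
    a = np.asarray(a)
    b = np.asarray(b)
    pairs = set(zip(a.tolist(), b.tolist()))
    return len(pairs) == len(set(a.tolist())) == len(set(b.tolist()))
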