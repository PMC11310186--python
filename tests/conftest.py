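"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from cliqueflux import CohortSpec, generate_cohort, impute
from cliqueflux.graph import PatientGraph


def adjacency_from_edges(n: int, edges: list[tuple[int, int]] | list[tuple[int, int, int]]) -> sp.csr_matrix:
    rows, cols, data = [], [], []
    for e in edges:
        i, j = e[0], e[1]
        w = e[2] if len(e) == 3 else 1
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n), dtype=np.int64)


def graph_from_edges(n: int, edges) -> PatientGraph:
    return PatientGraph(adjacency=adjacency_from_edges(n, edges))


def random_graph(n: int, density: float, seed: int) -> PatientGraph:
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < density, k=1).astype(np.int64)
    return PatientGraph(adjacency=sp.csr_matrix(upper + upper.T))


def brute_force_maximal_cliques(g: PatientGraph) -> list[tuple[int, ...]]:
    """Exhaustive subset enumeration over all 2^n node subsets (n <= ~16).

    A subset is a clique iff every member is adjacent to all other members;
    maximal iff no outside node is adjacent to all members. Bitmask-based,
    fully independent of the recursive enumeration under test.
    """
    n = g.n_nodes
    csr = g.adjacency.tocsr()
    nbr = [0] * n
    for i in range(n):
        for j in csr.indices[csr.indptr[i] : csr.indptr[i + 1]]:
            nbr[i] |= 1 << j
    cliques = []
    for s in range(1, 1 << n):
        members = [v for v in range(n) if s >> v & 1]
        if any((nbr[v] | (1 << v)) & s != s for v in members):
            continue
        if any(u not in members and nbr[u] & s == s for u in range(n)):
            continue
        cliques.append(tuple(members))
    return sorted(cliques)


def brute_force_average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Explicit precision/recall sweep over descending unique score
    thresholds (tied scores grouped), summing precision-weighted recall
    increments."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        sel = scores >= t
        tp = int(labels[sel].sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


@pytest.fixture(scope="session")
def small_cohort():
    """Imputed 300-encounter cohort with the default cluster structure."""
    spec = CohortSpec(n_encounters=300, missing_rate=0.05, seed=42)
    return impute(generate_cohort(spec))


@pytest.fixture(scope="session")
def separable_cohort():
    """Labels a deterministic function of cluster membership."""
    spec = CohortSpec(
        n_encounters=500, cluster_outcome_strength=1.0, positive_rate=0.15, seed=11
    )
    return impute(generate_cohort(spec))


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def chorded_cycle():
    # 4-cycle with chord 0-2: maximal cliques {0,1,2} and {0,2,3}
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
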