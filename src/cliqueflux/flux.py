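"""Edge Flux: per-epoch stochastic perturbation of the patient graph.

During training, each absent node pair gains an edge with probability
``p_add`` and each present edge is dropped with probability ``p_delete``;
everything else is untouched. The perturbation is always applied to the
pristine clique-weighted graph, never compounded across epochs (compounding
would drift edge density toward the p_add/(p_add+p_delete) fixed point).
Surviving edges keep their clique weights; added edges get weight 1, since
no clique membership is known for them and cliques are not re-enumerated
inside the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import PatientGraph


@dataclass(frozen=True)
class FluxConfig:
    """Edge-flux probabilities and seed.

    Defaults keep the expected perturbation a small fraction of the edge set
    on sparse graphs; the values used in the original experiments are not
    published, so both are exposed as knobs.
    """

    p_add: float = 0.01
    p_delete: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_add <= 1.0:
            raise ValueError(f"p_add must lie in [0, 1], got {self.p_add}")
        if not 0.0 <= self.p_delete <= 1.0:
            raise ValueError(f"p_delete must lie in [0, 1], got {self.p_delete}")


def _epoch_rng(cfg: FluxConfig, epoch: int) -> np.random.Generator:
    # Deterministic function of (seed, epoch): same pair, same stream.
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(epoch,)))


def apply_edge_flux(g: PatientGraph, cfg: FluxConfig, epoch: int) -> PatientGraph:
    """Sample one perturbed graph A' from the pristine graph ``g``.

    Decisions are made once per unordered pair and mirrored, preserving the
    undirected contract. Absent pairs are handled without an O(N^2) scan:
    the number of additions is drawn Binomial(#absent pairs, p_add), then
    that many distinct absent pairs are chosen uniformly — distributionally
    equivalent to independent per-pair Bernoulli draws.
    """
    cfg.validate()
    rng = _epoch_rng(cfg, epoch)
    n = g.n_nodes
    upper = sp.triu(g.adjacency, k=1).tocoo()
    rows, cols, data = upper.row, upper.col, upper.data.astype(np.int64)

    keep = rng.random(rows.size) >= cfg.p_delete
    rows_k, cols_k, data_k = rows[keep], cols[keep], data[keep]

    m_total = n * (n - 1) // 2
    n_absent = m_total - rows.size
    n_add = int(rng.binomial(n_absent, cfg.p_add)) if n_absent > 0 else 0
    add_r = np.empty(0, dtype=np.int64)
    add_c = np.empty(0, dtype=np.int64)
    if n_add > 0 and n_add * 2 >= n_absent:
        # Dense regime (e.g. p_add near 1): enumerate absent pairs exactly.
        tri_r, tri_c = np.triu_indices(n, k=1)
        present = np.zeros(m_total, dtype=bool)
        # map (i, j), i<j to linear triangular index
        lin = rows * n + cols
        tri_lin = tri_r * n + tri_c
        present[np.searchsorted(tri_lin, lin)] = True
        absent_idx = np.flatnonzero(~present)
        pick = rng.choice(absent_idx, size=n_add, replace=False)
        add_r, add_c = tri_r[pick], tri_c[pick]
    elif n_add > 0:
        existing = set(zip(rows.tolist(), cols.tolist()))
        chosen: set[tuple[int, int]] = set()
        # Rejection-sample uniform absent pairs; vectorised batches.
        while len(chosen) < n_add:
            batch = max(2 * (n_add - len(chosen)), 16)
            i = rng.integers(0, n, size=batch)
            j = rng.integers(0, n, size=batch)
            lo, hi = np.minimum(i, j), np.maximum(i, j)
            for a, b in zip(lo.tolist(), hi.tolist()):
                if a == b or (a, b) in existing or (a, b) in chosen:
                    continue
                chosen.add((a, b))
                if len(chosen) == n_add:
                    break
        pairs = sorted(chosen)
        add_r = np.array([p[0] for p in pairs], dtype=np.int64)
        add_c = np.array([p[1] for p in pairs], dtype=np.int64)

    all_r = np.concatenate([rows_k, add_r])
    all_c = np.concatenate([cols_k, add_c])
    all_d = np.concatenate([data_k, np.ones(add_r.size, dtype=np.int64)])
    upper_new = sp.coo_matrix((all_d, (all_r, all_c)), shape=(n, n))
    return g.with_adjacency((upper_new + upper_new.T).tocsr())
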