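"""Patient-similarity graph construction by thresholded cosine similarity.

Two encounters are joined by an (undirected) edge when the cosine similarity
of their feature vectors strictly exceeds the threshold (default 0.85).
Edges start at weight 1; clique weighting may later raise integer weights.
The cosine kernel is symmetric, so the graph is stored symmetrically even
though directed arrows are sometimes drawn to illustrate message passing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .cohort import EncounterMatrix


@dataclass
class PatientGraph:
    """Undirected integer-weighted patient graph.

    ``adjacency`` is a symmetric N x N sparse matrix with zero diagonal;
    weights are positive integers (1 after construction, >= 1 after clique
    weighting). Self-loops are added only inside the encoder.
    """

    adjacency: sp.csr_matrix
    threshold: float = 0.85
    encounter_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency)
        a.eliminate_zeros()
        if a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if (abs(a - a.T) > 0).nnz:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        data = a.data
        if data.size and (np.mod(data, 1).any() or (data < 0).any()):
            raise ValueError("edge weights must be non-negative integers")
        self.adjacency = sp.csr_matrix(a, dtype=np.int64)
        if not self.encounter_ids:
            self.encounter_ids = [f"enc{i:06d}" for i in range(a.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def edges(self) -> list[tuple[int, int, int]]:
        """Sorted (i, j, weight) triples with i < j, one per undirected edge."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))

    def topology_hash(self) -> str:
        """Digest of the edge SET (weights excluded); binds clique sets to graphs."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        pairs = np.sort(np.stack([coo.row, coo.col], axis=1), axis=0)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        h = hashlib.sha256()
        h.update(str(self.n_nodes).encode())
        h.update(pairs[order].astype(np.int64).tobytes())
        return h.hexdigest()

    def with_adjacency(self, a: sp.spmatrix) -> "PatientGraph":
        return PatientGraph(adjacency=a, threshold=self.threshold, encounter_ids=list(self.encounter_ids))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two feature vectors, in [-1, 1].

    Raises on zero-norm input rather than silently dividing by zero.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"vector lengths differ: {a.shape[0]} vs {b.shape[0]}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def build_graph(
    x: EncounterMatrix | np.ndarray,
    threshold: float = 0.85,
    *,
    standardize: bool = False,
    block_size: int = 2048,
) -> PatientGraph:
    """Build the patient graph: edge (i, j) iff cos(x_i, x_j) > threshold.

    The comparison is strict, so ties at exactly the threshold produce no
    edge. Similarities are computed blockwise on row-normalised features, so
    the dense N x N similarity matrix is never materialised. Missing values
    and zero-norm rows are errors (they indicate a failed imputation
    upstream), with the offending encounters named.

    ``standardize`` optionally z-scores each column (constant columns are
    left centred) before computing similarities.
    """
    if isinstance(x, EncounterMatrix):
        feats = x.features
        ids = list(x.encounter_ids)
    else:
        feats = np.asarray(x, dtype=float)
        ids = [f"enc{i:06d}" for i in range(feats.shape[0])]
    if np.isnan(feats).any():
        rows = np.unique(np.where(np.isnan(feats))[0])
        raise ValueError(
            "features contain missing values (impute first); offending encounters: "
            + ", ".join(ids[i] for i in rows[:5])
        )
    if standardize:
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd == 0.0] = 1.0
        feats = (feats - mu) / sd

    norms = np.linalg.norm(feats, axis=1)
    zero = np.where(norms == 0.0)[0]
    if zero.size:
        raise ValueError(
            "zero-norm feature rows cannot enter cosine similarity; offending encounters: "
            + ", ".join(ids[i] for i in zero[:10])
        )
    unit = feats / norms[:, None]

    n = unit.shape[0]
    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        sims = unit[start:stop] @ unit.T
        r, c = np.where(sims > threshold)
        r = r + start
        keep = r < c  # upper triangle only: no self-edges, no duplicates
        rows_out.append(r[keep])
        cols_out.append(c[keep])
    rows = np.concatenate(rows_out) if rows_out else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols_out) if cols_out else np.empty(0, dtype=np.int64)
    data = np.ones(rows.size, dtype=np.int64)
    upper = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    adj = (upper + upper.T).tocsr()
    return PatientGraph(adjacency=adj, threshold=threshold, encounter_ids=ids)
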