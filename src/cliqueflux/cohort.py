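"""Synthetic EHR-like cohort generation and imputation.

Real ICU cohorts expose, per encounter, a sparse set of binary diagnosis and
treatment code indicators (on the order of 6-12 diagnoses and 4-5 treatments
per visit), a handful of numeric covariates, strong outcome imbalance
(roughly 7-17% positives), and missing values. The generator here emulates
that statistical shape with *known* latent structure: encounters are drawn
around per-cluster code prototypes so that within-cluster cosine similarity
is high and between-cluster similarity is low, and outcome labels are coupled
to cluster membership through a tunable strength dial. Every downstream stage
(graph construction, clique weighting, training) is thereby testable without
any protected data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic encounter cohort.

    Attributes
    ----------
    n_encounters : number of encounters (graph nodes) N.
    n_code_features : number of binary diagnosis/treatment indicator columns.
    n_numeric_features : number of continuous covariate columns.
    n_clusters : number of latent patient groups; each owns a disjoint
        prototype set of active codes, guaranteeing low between-cluster
        cosine overlap.
    positive_rate : target fraction of positive outcomes, in (0, 1).
    cluster_outcome_strength : probability that an encounter's label follows
        its cluster's dominant label (1.0 = labels a deterministic function
        of cluster, 0.0 = labels independent of cluster).
    code_noise_rate : per-code probability that a prototype code is toggled
        for an individual encounter (off for prototype codes, on for a
        matching expected number of background codes). 0.0 gives exact
        prototype copies within each cluster.
    missing_rate : fraction of feature cells replaced by the missing
        sentinel (NaN), in [0, 1).
    seed : RNG seed; identical (spec, seed) pairs produce bit-identical
        cohorts.
    """

    n_encounters: int = 500
    n_code_features: int = 120
    n_numeric_features: int = 4
    n_clusters: int = 8
    positive_rate: float = 0.15
    cluster_outcome_strength: float = 0.9
    code_noise_rate: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0
    codes_per_cluster: int = 12

    def validate(self) -> None:
        if self.n_encounters < 1:
            raise ValueError(f"n_encounters must be positive, got {self.n_encounters}")
        if self.n_code_features < 1:
            raise ValueError(f"n_code_features must be positive, got {self.n_code_features}")
        if self.n_numeric_features < 0:
            raise ValueError(f"n_numeric_features must be non-negative, got {self.n_numeric_features}")
        if self.n_clusters < 1:
            raise ValueError(f"n_clusters must be positive, got {self.n_clusters}")
        if self.n_clusters > self.n_encounters:
            raise ValueError(
                f"n_clusters ({self.n_clusters}) must not exceed n_encounters ({self.n_encounters})"
            )
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError(f"positive_rate must lie strictly in (0, 1), got {self.positive_rate}")
        if not 0.0 <= self.cluster_outcome_strength <= 1.0:
            raise ValueError(
                f"cluster_outcome_strength must lie in [0, 1], got {self.cluster_outcome_strength}"
            )
        if not 0.0 <= self.code_noise_rate < 1.0:
            raise ValueError(f"code_noise_rate must lie in [0, 1), got {self.code_noise_rate}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.codes_per_cluster < 1:
            raise ValueError(f"codes_per_cluster must be positive, got {self.codes_per_cluster}")
        if self.codes_per_cluster * self.n_clusters > self.n_code_features:
            raise ValueError(
                "n_code_features too small for disjoint cluster prototypes: need at least "
                f"{self.codes_per_cluster * self.n_clusters}, got {self.n_code_features}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)


@dataclass
class EncounterMatrix:
    """N x F encounter feature matrix with binary outcome labels.

    ``features`` is a float matrix; missing entries are NaN. ``feature_kinds``
    tags each column as ``numeric`` or ``categorical`` (binary code
    indicators are categorical). ``clusters`` records the latent group each
    encounter was generated from (synthetic provenance; absent for data read
    from disk).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_kinds: list[str]
    encounter_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    clusters: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        n, f = self.features.shape
        if self.labels.shape != (n,):
            raise ValueError(f"labels shape {self.labels.shape} does not match {n} encounters")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0/1")
        self.labels = self.labels.astype(np.int64)
        if len(self.feature_kinds) != f:
            raise ValueError(f"feature_kinds length {len(self.feature_kinds)} != {f} features")
        bad = set(self.feature_kinds) - {NUMERIC, CATEGORICAL}
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")
        if not self.encounter_ids:
            self.encounter_ids = [f"enc{i:06d}" for i in range(n)]
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(f)]

    @property
    def n_encounters(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.features).sum())


def _dominant_labels(cluster_sizes: np.ndarray, positive_rate: float) -> np.ndarray:
    """Mark clusters dominant-positive so their member share best tracks positive_rate.

    Greedy: add clusters (largest first, index tie-break) while doing so moves
    the cumulative member share closer to the target.
    """
    n = int(cluster_sizes.sum())
    target = positive_rate * n
    order = np.lexsort((np.arange(len(cluster_sizes)), -cluster_sizes))
    dominant = np.zeros(len(cluster_sizes), dtype=np.int64)
    total = 0
    for c in order:
        if abs(total + cluster_sizes[c] - target) < abs(total - target):
            dominant[c] = 1
            total += cluster_sizes[c]
    return dominant


def generate_cohort(spec: CohortSpec) -> EncounterMatrix:
    """Draw a synthetic encounter cohort with latent cluster structure.

    Each cluster owns ``codes_per_cluster`` codes drawn without replacement
    from the code vocabulary (prototypes are disjoint across clusters). An
    encounter copies its cluster prototype, then each prototype code is
    switched off with probability ``code_noise_rate`` and an expected-matching
    number of background codes is switched on. Numeric covariates are Gaussian
    around cluster-specific means. Labels follow the cluster's dominant label
    with probability ``cluster_outcome_strength``, else Bernoulli(positive_rate).
    Finally ``missing_rate`` of all cells are replaced by NaN.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_encounters, spec.n_clusters
    n_codes, n_num = spec.n_code_features, spec.n_numeric_features

    # Disjoint prototype code sets: permute the vocabulary, slice per cluster.
    perm = rng.permutation(n_codes)
    prototypes = [perm[c * spec.codes_per_cluster : (c + 1) * spec.codes_per_cluster] for c in range(k)]

    clusters = rng.integers(0, k, size=n)
    # Guarantee every cluster non-empty when n >= k (keeps dominant-label maths honest).
    if n >= k:
        clusters[:k] = np.arange(k)
        rng.shuffle(clusters)

    codes = np.zeros((n, n_codes), dtype=float)
    for i in range(n):
        proto = prototypes[clusters[i]]
        keep = proto[rng.random(len(proto)) >= spec.code_noise_rate]
        codes[i, keep] = 1.0
        if spec.code_noise_rate > 0.0:
            # Background activation rate chosen so expected extra codes match
            # the expected number of dropped prototype codes.
            bg_rate = spec.code_noise_rate * len(proto) / max(n_codes - len(proto), 1)
            mask = rng.random(n_codes) < bg_rate
            mask[proto] = False
            codes[i, mask] = 1.0
        if not codes[i].any():  # never emit a zero-norm code row
            codes[i, proto[0]] = 1.0

    if n_num > 0:
        # Small spread relative to the code-block norm (~sqrt(codes_per_cluster))
        # so numeric noise cannot erase the cluster signal in cosine space.
        centers = rng.normal(0.0, 0.5, size=(k, n_num))
        numeric = centers[clusters] + rng.normal(0.0, 0.25, size=(n, n_num))
        features = np.hstack([codes, numeric])
    else:
        features = codes

    sizes = np.bincount(clusters, minlength=k)
    dominant = _dominant_labels(sizes, spec.positive_rate)
    follow = rng.random(n) < spec.cluster_outcome_strength
    background = (rng.random(n) < spec.positive_rate).astype(np.int64)
    labels = np.where(follow, dominant[clusters], background)

    if spec.missing_rate > 0.0:
        miss = rng.random(features.shape) < spec.missing_rate
        # Keep at least one observed value per column so imputation is defined.
        full_cols = miss.all(axis=0)
        if full_cols.any():
            miss[rng.integers(0, n), full_cols] = False
        features = features.copy()
        features[miss] = np.nan

    kinds = [CATEGORICAL] * n_codes + [NUMERIC] * n_num
    names = [f"code{j:04d}" for j in range(n_codes)] + [f"num{j}" for j in range(n_num)]
    return EncounterMatrix(
        features=features,
        labels=labels,
        feature_kinds=kinds,
        feature_names=names,
        clusters=clusters,
    )


def impute(raw: EncounterMatrix) -> EncounterMatrix:
    """Fill missing entries: observed mean for numeric columns, observed mode
    for categorical columns (ties broken toward the smaller value). Observed
    entries are untouched; a column with no observed value is an error.
    """
    x = raw.features.copy()
    missing = np.isnan(x)
    for j in range(x.shape[1]):
        col_missing = missing[:, j]
        if not col_missing.any():
            continue
        observed = x[~col_missing, j]
        if observed.size == 0:
            raise ValueError(
                f"feature {raw.feature_names[j]!r} (column {j}) is entirely missing; "
                "no basis for imputation"
            )
        if raw.feature_kinds[j] == NUMERIC:
            fill = observed.mean()
        else:
            values, counts = np.unique(observed, return_counts=True)
            fill = values[np.argmax(counts)]  # np.unique sorts: ties -> smaller value
        x[col_missing, j] = fill
    return EncounterMatrix(
        features=x,
        labels=raw.labels.copy(),
        feature_kinds=list(raw.feature_kinds),
        encounter_ids=list(raw.encounter_ids),
        feature_names=list(raw.feature_names),
        clusters=None if raw.clusters is None else raw.clusters.copy(),
    )
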