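"""Training loop, split management, AUPRC evaluation and ablations.

Training is transductive: every forward pass runs on the whole graph, while
mini-batches of 128 training nodes define which labels enter the loss at
each Adam step. Edge flux resamples a perturbed adjacency from the pristine
clique-weighted graph once per epoch. Model selection keeps the checkpoint
with the best validation AUPRC; the experiment runner repeats (split, init,
flux) with independent derived seeds and reports mean +/- std test AUPRC,
the shape in which results are conventionally tabulated for the shrinking
train-fraction regimes (70/40/30/20% train).

AUPRC (area under the precision-recall step curve, average-precision
formulation) is the headline metric because the outcomes are heavily
imbalanced; an uninformative classifier scores the positive prevalence.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import average_precision_score

from . import encoder as enc
from .cohort import EncounterMatrix
from .encoder import Adam, EncoderModel
from .flux import FluxConfig, apply_edge_flux
from .graph import PatientGraph

ABLATIONS = ("full", "no_edge_flux", "no_clique")
SPLIT_REGIMES = {
    "70/15/15": (0.70, 0.15, 0.15),
    "40/30/30": (0.40, 0.30, 0.30),
    "30/35/35": (0.30, 0.35, 0.35),
    "20/40/40": (0.20, 0.40, 0.40),
}


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 250
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_repeats: int = 5
    flux: FluxConfig = field(default_factory=FluxConfig)
    ablation: str = "full"
    seed: int = 0
    embed_dim: int = enc.EMBED_DIM

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be positive, got {self.batch_size}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be positive, got {self.epochs}")
        fr = self.split_fractions
        if len(fr) != 3 or any(f <= 0 for f in fr):
            raise ValueError(f"split_fractions must be three positive numbers, got {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"split_fractions must sum to 1 within 1e-9, got sum {sum(fr)}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be positive, got {self.n_repeats}")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        self.flux.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d


@dataclass
class RunResult:
    per_repeat_auprc: list[float]
    mean_auprc: float
    std_auprc: float
    loss_history: list[dict]
    best_epoch: int
    ablation: str = "full"
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunResult":
        d = dict(d)
        d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)


def make_splits(
    n: int, fractions: tuple[float, float, float], seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniformly random disjoint train/val/test partition of range(n).

    Split sizes follow largest-remainder rounding of n * fractions so they
    always sum to n exactly. Encounters used for training never appear in
    validation or testing. An empty split is an error.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or (fr <= 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be three positive numbers summing to 1, got {fractions}")
    raw = fr * n
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    for idx in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[idx] += 1
    if (sizes == 0).any():
        raise ValueError(f"split sizes {sizes.tolist()} contain an empty split for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    train = np.sort(perm[: sizes[0]])
    val = np.sort(perm[sizes[0] : sizes[0] + sizes[1]])
    test = np.sort(perm[sizes[0] + sizes[1] :])
    return train, val, test


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (average-precision formulation).

    Sums precision-weighted recall increments over descending score
    thresholds, grouping tied scores into a single threshold. Both classes
    must be present: AUPRC is undefined for single-class labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    if uniq.size < 2:
        raise ValueError("AUPRC undefined: only one class present in labels")
    # float round-off can push the step-curve sum a hair past 1
    return float(min(max(average_precision_score(labels, scores), 0.0), 1.0))


def _sub_seed(master: int, stream: str, repeat: int = 0) -> int:
    """Named deterministic sub-seed below 2**31, so ablations differ only in
    their intended component."""
    tag = zlib.crc32(stream.encode())  # stable across processes, unlike hash()
    ss = np.random.SeedSequence(entropy=master, spawn_key=(tag, repeat))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class TrainOutput:
    model: EncoderModel
    best_epoch: int
    best_val_auprc: float
    loss_history: list[dict]
    test_auprc: float | None = None


def train(
    x: np.ndarray,
    a_weighted: PatientGraph | sp.spmatrix,
    y: np.ndarray,
    cfg: TrainConfig,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> TrainOutput:
    """Train the encoder + head on one split with per-epoch edge flux.

    Per epoch: sample A' from the pristine weighted graph (identity when
    ablation=no_edge_flux), then run Adam over mini-batches of training
    nodes, each step computing full-graph embeddings on A' and BCE on the
    batch labels only. The checkpoint with best validation AUPRC is kept.
    With ablation=no_clique all edge weights are forced to 1 first.
    """
    cfg.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training requires both outcome classes (single-class AUPRC undefined)")
    graph = a_weighted if isinstance(a_weighted, PatientGraph) else PatientGraph(adjacency=a_weighted)
    if graph.n_nodes != x.shape[0]:
        raise ValueError("graph and feature matrix disagree on the number of encounters")

    if cfg.ablation == "no_clique":
        binary = graph.adjacency.copy()
        binary.data[:] = 1
        graph = graph.with_adjacency(binary)

    if splits is None:
        splits = make_splits(x.shape[0], cfg.split_fractions, _sub_seed(cfg.seed, "splits"))
    train_idx, val_idx, test_idx = splits
    if val_idx.size == 0:
        raise ValueError("validation split is empty")

    model = EncoderModel.init(x.shape[1], cfg.embed_dim, seed=_sub_seed(cfg.seed, "init"))
    opt = Adam(model, lr=cfg.learning_rate)
    batch_rng = np.random.default_rng(_sub_seed(cfg.seed, "batching"))

    best = model.copy()
    best_val, best_epoch = -np.inf, -1
    history: list[dict] = []
    p_clean = enc.normalized_propagation(graph.adjacency)

    for epoch in range(cfg.epochs):
        if cfg.ablation == "no_edge_flux" or (cfg.flux.p_add == 0.0 and cfg.flux.p_delete == 0.0):
            p = p_clean
        else:
            perturbed = apply_edge_flux(graph, cfg.flux, epoch)
            p = enc.normalized_propagation(perturbed.adjacency)

        order = batch_rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss, cache = enc.forward_loss(x, p, model, y, batch)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf loss at epoch {epoch}, batch {start // cfg.batch_size}, "
                    f"learning rate {cfg.learning_rate}"
                )
            grads = enc.backward(p, model, cache)
            opt.step(model, grads)
            epoch_losses.append(loss)

        # Evaluation always uses the pristine (unperturbed) graph.
        scores = predict_scores(x, p_clean, model)
        val_ap = auprc(scores[val_idx], y[val_idx]) if np.unique(y[val_idx]).size > 1 else 0.0
        val_loss = enc.bce_loss(scores[val_idx], y[val_idx])
        history.append(
            dict(epoch=epoch, train_loss=float(np.mean(epoch_losses)), val_loss=val_loss, val_auprc=val_ap)
        )
        if val_ap > best_val:
            best_val, best_epoch = val_ap, epoch
            best = model.copy()

    out = TrainOutput(model=best, best_epoch=best_epoch, best_val_auprc=best_val, loss_history=history)
    if test_idx.size and np.unique(y[test_idx]).size > 1:
        scores = predict_scores(x, p_clean, best)
        out.test_auprc = auprc(scores[test_idx], y[test_idx])
    return out


def predict_scores(x: np.ndarray, p: sp.csr_matrix, model: EncoderModel) -> np.ndarray:
    h1 = np.maximum((p @ x) @ model.theta1, 0.0)
    h2 = np.maximum((p @ h1) @ model.theta2, 0.0)
    return enc.predict(h2, model).scores


def run_experiment(
    cohort: EncounterMatrix,
    cfg: TrainConfig,
    *,
    graph: PatientGraph | None = None,
    threshold: float = 0.85,
    clique_aggregator: str = "max",
) -> RunResult:
    """Full pipeline with repeated evaluation: graph -> cliques -> weights ->
    n_repeats x (split, init, flux) -> mean +/- std test AUPRC.

    Each repeat derives independent named sub-seeds from cfg.seed, so two
    runs with the same master seed are identical and ablations share
    everything except the ablated component. Pass a prebuilt clique-weighted
    ``graph`` to skip reconstruction (e.g. across ablation arms).
    """
    cfg.validate()
    if graph is None:
        from .cliques import assign_clique_weights, enumerate_maximal_cliques
        from .graph import build_graph

        g = build_graph(cohort, threshold)
        g = assign_clique_weights(g, enumerate_maximal_cliques(g), clique_aggregator)
    else:
        g = graph

    x, y = cohort.features, cohort.labels
    per_repeat: list[float] = []
    best_epochs: list[int] = []
    histories: list[dict] = []
    for r in range(cfg.n_repeats):
        splits = make_splits(x.shape[0], cfg.split_fractions, _sub_seed(cfg.seed, "splits", r))
        rep_cfg = dataclasses.replace(
            cfg,
            seed=_sub_seed(cfg.seed, "repeat", r),
            flux=dataclasses.replace(cfg.flux, seed=_sub_seed(cfg.seed, "flux", r)),
        )
        out = train(x, g, y, rep_cfg, splits=splits)
        if out.test_auprc is None:
            raise ValueError("test split lacked both classes; cannot score AUPRC")
        per_repeat.append(out.test_auprc)
        best_epochs.append(out.best_epoch)
        histories.append(dict(repeat=r, history=out.loss_history))

    arr = np.array(per_repeat)
    return RunResult(
        per_repeat_auprc=per_repeat,
        mean_auprc=float(arr.mean()),
        std_auprc=float(arr.std(ddof=0)),
        loss_history=histories,
        best_epoch=int(best_epochs[int(np.argmax(arr))]),
        ablation=cfg.ablation,
        split_fractions=cfg.split_fractions,
    )
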