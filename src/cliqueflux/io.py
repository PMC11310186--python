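"""Readers/writers binding the pipeline into reproducible runs.

Formats: cohort as CSV (header row, one encounter per row, final ``label``
column, empty field = missing) with a sidecar JSON recording feature kinds
and generation provenance; graphs as tab-separated edge lists (``i  j  w``,
0-based, i < j) or MatrixMarket .mtx; cliques one-per-line; results,
configs and manifests as JSON; training logs as JSON lines. Node indexing
is 0-based everywhere. All writers and readers are mutual inverses on
valid data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .cliques import CliqueSet
from .cohort import CATEGORICAL, NUMERIC, CohortSpec, EncounterMatrix
from .graph import PatientGraph
from .training import RunResult

ARTIFACT_VERSION = "0.1.0"


# ---------------------------------------------------------------- cohort CSV

def write_cohort_csv(cohort: EncounterMatrix, path: str | Path, spec: CohortSpec | None = None) -> None:
    """One row per encounter; missing entries become empty fields. A sidecar
    ``<path>.meta.json`` records feature kinds (and the generating spec, if
    given) so a round trip restores types exactly."""
    path = Path(path)
    df = pd.DataFrame(cohort.features, columns=cohort.feature_names)
    df.insert(0, "encounter_id", cohort.encounter_ids)
    df["label"] = cohort.labels
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "feature_kinds": dict(zip(cohort.feature_names, cohort.feature_kinds)),
        "spec": None if spec is None else spec.to_dict(),
    }
    _atomic_json(meta, path.with_suffix(path.suffix + ".meta.json"))


def read_cohort_csv(path: str | Path) -> EncounterMatrix:
    """Inverse of :func:`write_cohort_csv`; empty cells become NaN sentinels.

    Feature kinds come from the sidecar when present, otherwise a column is
    categorical iff its observed values are all in {0, 1}.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed cohort CSV {path}: {e}") from None
    if "label" not in df.columns:
        raise ValueError(f"cohort CSV {path} lacks the required 'label' column")
    ids = (
        df.pop("encounter_id").astype(str).tolist()
        if "encounter_id" in df.columns
        else []
    )
    labels = df.pop("label")
    if labels.isna().any():
        rows = labels.index[labels.isna()].tolist()
        raise ValueError(f"missing labels at rows {rows[:5]}")
    feature_names = list(df.columns)
    for col in feature_names:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"non-numeric values in feature column {col!r} at rows {bad.tolist()[:5]}"
            )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        kinds_map = json.loads(sidecar.read_text())["feature_kinds"]
        kinds = [kinds_map[c] for c in feature_names]
    else:
        kinds = [
            CATEGORICAL if df[c].dropna().isin([0, 1]).all() else NUMERIC
            for c in feature_names
        ]
    return EncounterMatrix(
        features=df.to_numpy(dtype=float),
        labels=labels.to_numpy(),
        feature_kinds=kinds,
        encounter_ids=ids,
        feature_names=feature_names,
    )


# ------------------------------------------------------------------- graphs

def write_edge_list(g: PatientGraph, path: str | Path) -> None:
    """``i<TAB>j<TAB>weight`` per undirected edge, i < j, preceded by a
    ``# nodes N`` header so isolated nodes survive the round trip."""
    with open(path, "w") as fh:
        fh.write(f"# nodes {g.n_nodes}\n")
        for i, j, w in g.edges():
            fh.write(f"{i}\t{j}\t{w}\n")


def read_edge_list(path: str | Path) -> PatientGraph:
    n_nodes = None
    rows, cols, data = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                if len(parts) == 3 and parts[1] == "nodes":
                    n_nodes = int(parts[2])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'i<TAB>j<TAB>weight', got {line!r}")
            rows.append(int(parts[0]))
            cols.append(int(parts[1]))
            data.append(int(parts[2]))
    if n_nodes is None:
        n_nodes = max(rows + cols, default=-1) + 1
    upper = sp.coo_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes))
    return PatientGraph(adjacency=(upper + upper.T).tocsr())


def write_graph_mtx(g: PatientGraph, path: str | Path) -> None:
    mmwrite(str(path), g.adjacency.tocoo(), field="integer", symmetry="symmetric")


def read_graph_mtx(path: str | Path) -> PatientGraph:
    return PatientGraph(adjacency=sp.csr_matrix(mmread(str(path))))


# ------------------------------------------------------------------ cliques

def write_cliques(cs: CliqueSet, path: str | Path) -> None:
    """One clique per line: space-separated sorted node indices; the source
    graph hash rides in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# source_graph_hash {cs.source_graph_hash}\n")
        for clique in cs.cliques:
            fh.write(" ".join(str(v) for v in clique) + "\n")


def read_cliques(path: str | Path) -> CliqueSet:
    source_hash = ""
    cliques = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                if len(parts) == 3 and parts[1] == "source_graph_hash":
                    source_hash = parts[2]
                continue
            cliques.append(tuple(int(v) for v in line.split()))
    return CliqueSet(cliques=cliques, source_graph_hash=source_hash)


# -------------------------------------------------------- results & manifest

@dataclass
class RunManifest:
    """Provenance of one pipeline run: resolved config, input digests, timing."""

    config_echo: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    artifact_version: str = ARTIFACT_VERSION
    started: str = ""
    finished: str = ""

    def stamp_start(self) -> None:
        self.started = datetime.now(timezone.utc).isoformat()

    def stamp_finish(self) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_json(obj: dict, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def write_results(result: RunResult, manifest: RunManifest, out_dir: str | Path) -> dict[str, Path]:
    """Write results JSON, a JSON-lines training log and the run manifest.

    Re-running with the same config overwrites atomically, so a directory
    always holds exactly one coherent (results, log, manifest) triple.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "results.json",
        "log": out / "training_log.jsonl",
        "manifest": out / "manifest.json",
    }
    res = result.to_dict()
    log_entries = res.pop("loss_history")
    _atomic_json(res, paths["results"])
    fd, tmp = tempfile.mkstemp(dir=out, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        for rep in log_entries:
            for entry in rep["history"] if "history" in rep else [rep]:
                fh.write(json.dumps({"repeat": rep.get("repeat", 0), **entry}) + "\n")
    os.replace(tmp, paths["log"])
    manifest.stamp_finish()
    _atomic_json(manifest.to_dict(), paths["manifest"])
    return paths


def read_results(out_dir: str | Path) -> RunResult:
    out = Path(out_dir)
    res = json.loads((out / "results.json").read_text())
    res["loss_history"] = []
    with open(out / "training_log.jsonl") as fh:
        by_repeat: dict[int, list[dict]] = {}
        for line in fh:
            entry = json.loads(line)
            by_repeat.setdefault(entry.pop("repeat"), []).append(entry)
    res["loss_history"] = [{"repeat": r, "history": h} for r, h in sorted(by_repeat.items())]
    return RunResult.from_dict(res)


def write_embeddings_csv(
    embeddings: np.ndarray, encounter_ids: list[str], path: str | Path
) -> None:
    """Encounter id + one column per embedding dimension (for external
    visualisation such as t-SNE)."""
    df = pd.DataFrame(embeddings, columns=[f"e{k}" for k in range(embeddings.shape[1])])
    df.insert(0, "encounter_id", encounter_ids)
    df.to_csv(path, index=False)


def save_model_json(model, path: str | Path) -> None:
    obj = {
        "theta1": model.theta1.tolist(),
        "theta2": model.theta2.tolist(),
        "head_weights": model.head_weights.tolist(),
        "head_bias": model.head_bias,
        "init_seed": model.init_seed,
        "shapes": {
            "theta1": list(model.theta1.shape),
            "theta2": list(model.theta2.shape),
            "head_weights": list(model.head_weights.shape),
        },
        "artifact_version": ARTIFACT_VERSION,
    }
    _atomic_json(obj, Path(path))


def load_model_json(path: str | Path):
    from .encoder import EncoderModel

    obj = json.loads(Path(path).read_text())
    return EncoderModel(
        theta1=np.array(obj["theta1"], dtype=float),
        theta2=np.array(obj["theta2"], dtype=float),
        head_weights=np.array(obj["head_weights"], dtype=float),
        head_bias=float(obj["head_bias"]),
        init_seed=int(obj["init_seed"]),
    )
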