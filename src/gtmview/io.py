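"""File formats: data CSV, model JSON, counts matrices, run manifests.

On disk, data matrices are observations-in-rows CSV with a header of
variable names and an optional leading ID column; internally everything is
variables-in-rows (p x N).  Models serialise to a single JSON document
(lattice, basis, W, beta, anchors, blend layers, fit trace).  Every CLI run
writes a manifest (config hash, seed, library versions) so outputs can be
replayed bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .core import (AnchorComponent, BlendLayer, DataMatrix, FitTrace,
                   GTMModel, LatentGrid, RadialBasisSet)
from .text import ImpIVector, TermDocCounts, WeightedTermDoc

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_data_csv",
    "write_data_csv",
    "write_projection_csv",
    "write_magnification_csv",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "read_counts_csv",
    "read_counts_triplets",
    "write_counts_csv",
    "write_scores_csv",
    "write_weighted_csv",
    "read_moves_jsonl",
    "write_manifest",
    "atomic_write_text",
]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Schema-validated JSON run configuration (model + interaction + text).

    Unknown keys are rejected so typos never silently fall back to defaults.
    """

    grid: str = "20x20"
    basis: str = "4x4"
    width_factor: float = 1.0
    ridge: float = 1e-6
    max_iter: int = 200
    rel_tol: float = 1e-5
    seed: int = 0
    stage: int = 3
    family: str = "delta3"
    h: float | None = None
    neighbors: int | None = None
    top_n: int = 1000
    dialect: str = "printed"


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): "
                         f"{', '.join(unknown)}")
    return RunConfig(**raw)


def atomic_write_text(path, text: str) -> None:
    """Write via a temp file + rename so failures never leave partial output."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# data matrices


def read_data_csv(path) -> DataMatrix:
    """Observations in rows; header of variable names; optional first ID
    column (detected when the first column is non-numeric)."""
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty data file")
    first = df.iloc[:, 0]
    if first.dtype == object:
        ids = [str(v) for v in first]
        df = df.iloc[:, 1:]
    else:
        ids = [f"obs{i + 1:04d}" for i in range(df.shape[0])]
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{path}: non-finite value at row {bad[0] + 2}, "
                         f"column {df.columns[bad[1]]!r}")
    return DataMatrix.from_rows(values, ids=ids,
                                var_names=[str(c) for c in df.columns])


def write_data_csv(path, data: DataMatrix) -> None:
    rows = data.values.T
    cols = list(data.var_names) if data.var_names else \
        [f"v{k + 1}" for k in range(rows.shape[1])]
    df = pd.DataFrame(rows, columns=cols)
    if data.ids:
        df.insert(0, "id", list(data.ids))
    df.to_csv(path, index=False)


def write_projection_csv(path, ids, coords: np.ndarray, mode: str) -> None:
    df = pd.DataFrame({"id": list(ids),
                       "q1": coords[:, 0], "q2": coords[:, 1],
                       "mode": mode})
    df.to_csv(path, index=False)


def write_magnification_csv(path, lattice: LatentGrid,
                            factors: np.ndarray) -> None:
    pts = lattice.points
    df = pd.DataFrame({"j": np.arange(pts.shape[1]),
                       "r1": pts[0], "r2": pts[1], "factor": factors})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model JSON


def _arr(a) -> list:
    return np.asarray(a).tolist()


def model_to_dict(model: GTMModel, trace: FitTrace | None = None,
                  config: dict | None = None) -> dict:
    d = {
        "format": "gtmview-model",
        "version": 1,
        "lattice": {
            "points": _arr(model.lattice.points),
            "grid_shape": list(model.lattice.grid_shape),
            "extent": [list(e) for e in model.lattice.extent],
        },
        "basis": {
            "centers": _arr(model.basis.centers),
            "width": model.basis.width,
            "has_bias": model.basis.has_bias,
        },
        "W": _arr(model.W),
        "beta": model.beta,
        "anchors": [
            {"obs_index": a.obs_index, "lattice_index": a.lattice_index,
             "basis_index": a.basis_index,
             "weights": _arr(a.weights) if a.weights is not None else None}
            for a in model.anchors
        ],
        "blend_layers": [
            {"W": _arr(b.W),
             "basis": {"centers": _arr(b.basis.centers),
                       "width": b.basis.width,
                       "has_bias": b.basis.has_bias},
             "r_star": _arr(b.r_star) if b.r_star is not None else None,
             "b": b.b}
            for b in model.blend_layers
        ],
    }
    if trace is not None:
        d["trace"] = {"log_likelihoods": _arr(trace.log_likelihoods),
                      "converged": trace.converged, "n_iter": trace.n_iter}
    if config is not None:
        d["config"] = config
    return d


def _basis_from(d: dict) -> RadialBasisSet:
    return RadialBasisSet(centers=np.asarray(d["centers"], float),
                          width=float(d["width"]),
                          has_bias=bool(d.get("has_bias", False)))


def model_from_dict(d: dict) -> GTMModel:
    if d.get("format") != "gtmview-model":
        raise ValueError("not a gtmview model document")
    lat = d["lattice"]
    lattice = LatentGrid(points=np.asarray(lat["points"], float),
                         grid_shape=tuple(lat["grid_shape"]),
                         extent=tuple(tuple(e) for e in lat["extent"]))
    basis = _basis_from(d["basis"])
    W = np.asarray(d["W"], float)
    anchors = tuple(
        AnchorComponent(obs_index=int(a["obs_index"]),
                        lattice_index=int(a["lattice_index"]),
                        basis_index=int(a["basis_index"]),
                        weights=(np.asarray(a["weights"], float)
                                 if a.get("weights") is not None else None))
        for a in d.get("anchors", []))
    layers = tuple(
        BlendLayer(W=np.asarray(b["W"], float), basis=_basis_from(b["basis"]),
                   r_star=(np.asarray(b["r_star"], float)
                           if b.get("r_star") is not None else None),
                   b=(float(b["b"]) if b.get("b") is not None else None))
        for b in d.get("blend_layers", []))
    from .core import manifold_at
    model = GTMModel(lattice=lattice, basis=basis, W=W, beta=float(d["beta"]),
                     manifold=np.zeros((W.shape[0], lattice.n_points)),
                     anchors=anchors, blend_layers=layers)
    manifold = manifold_at(model, lattice.points)
    return dataclasses.replace(model, manifold=manifold)


def save_model(path, model: GTMModel, trace: FitTrace | None = None,
               config: dict | None = None) -> None:
    atomic_write_text(path, json.dumps(model_to_dict(model, trace, config)))


def load_model(path) -> GTMModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# term-document counts and scores


def read_counts_csv(path) -> TermDocCounts:
    """Dense counts: terms x docs, header = doc ids, first column = terms."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty counts file")
    counts = df.to_numpy()
    return TermDocCounts(counts.astype(np.int64),
                         tuple(str(t) for t in df.index),
                         tuple(str(c) for c in df.columns))


def read_counts_triplets(path) -> TermDocCounts:
    """Sparse triplet TSV: term <tab> doc <tab> count."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["term", "doc", "count"])
    terms = tuple(sorted(df["term"].astype(str).unique()))
    docs = tuple(sorted(df["doc"].astype(str).unique()))
    t_idx = {t: i for i, t in enumerate(terms)}
    d_idx = {d: j for j, d in enumerate(docs)}
    counts = np.zeros((len(terms), len(docs)), dtype=np.int64)
    for _, row in df.iterrows():
        counts[t_idx[str(row["term"])], d_idx[str(row["doc"])]] += int(row["count"])
    return TermDocCounts(counts, terms, docs)


def write_counts_csv(path, counts: TermDocCounts) -> None:
    df = pd.DataFrame(counts.counts, index=list(counts.vocabulary),
                      columns=list(counts.doc_ids))
    df.to_csv(path)


def write_scores_csv(path, impi: ImpIVector) -> None:
    terms = impi.terms or tuple(f"t{i}" for i in range(len(impi.scores)))
    pd.DataFrame({"term": list(terms), "impi": impi.scores}).to_csv(
        path, index=False)


def write_weighted_csv(path, weighted: WeightedTermDoc) -> None:
    df = pd.DataFrame(weighted.values, index=list(weighted.vocabulary),
                      columns=list(weighted.doc_ids))
    df.to_csv(path)


def read_moves_jsonl(path, ids=None) -> list[dict]:
    """Interaction script: one JSON record per line.

    Records reference observations by 'obs_id' (resolved against ``ids``)
    or directly by 'obs_index'.
    """
    moves = []
    id_map = {v: i for i, v in enumerate(ids)} if ids is not None else {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as err:
                raise ValueError(
                    f"{path}:{lineno}:{err.colno}: invalid JSON") from err
            if "obs_index" not in rec:
                if "obs_id" not in rec:
                    raise ValueError(f"{path}:{lineno}: move needs obs_id or "
                                     "obs_index")
                if rec["obs_id"] not in id_map:
                    raise ValueError(f"{path}:{lineno}: unknown obs_id "
                                     f"{rec['obs_id']!r}")
                rec["obs_index"] = id_map[rec["obs_id"]]
            if "target" not in rec or len(rec["target"]) != 2:
                raise ValueError(f"{path}:{lineno}: move needs a 2-vector "
                                 "'target'")
            moves.append(rec)
    return moves


# ---------------------------------------------------------------------------
# manifests


def write_manifest(out_dir, command: str, config: dict, seed: int | None) -> Path:
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "gtmview": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"manifest_{command}.json"
    atomic_write_text(path, json.dumps(manifest, indent=2, default=str))
    return path
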