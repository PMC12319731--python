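"""Plain-text I/O: TSV matrices, manifests, and the StateModel JSON.

All artifacts are delimited text or JSON so a run is portable and
diffable. Matrices are written with 17 significant digits, which
round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .leida import LeidaStates

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_manifest",
    "read_region_table",
    "write_state_model",
    "read_state_model",
    "write_sequences",
    "read_sequences",
]

MANIFEST_COLUMNS = ["subject_id", "ts_path", "sc_path", "age", "behavior", "group"]
FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    pass


def read_matrix_tsv(path: str | Path, square: bool = False, symmetric: bool = False,
                    symmetry_tol: float = 1e-12) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing matrix file: {path}")
    try:
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric cell ({exc})") from exc
    if square and mat.shape[0] != mat.shape[1]:
        raise SchemaError(f"{path}: expected square matrix, got {mat.shape}")
    if symmetric and np.abs(mat - mat.T).max() > symmetry_tol:
        raise SchemaError(f"{path}: matrix is not symmetric")
    return mat


def write_matrix_tsv(path: str | Path, mat: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.atleast_2d(mat), fmt=FLOAT_FMT, delimiter="\t")
    return path


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Manifest TSV: subject_id, ts_path, sc_path, age, behavior, group.

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing manifest: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {missing}")
    base = path.parent
    for col in ("ts_path", "sc_path"):
        df[col] = [str((base / p)) if not Path(p).is_absolute() else p for p in df[col]]
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise SchemaError(f"{path}: duplicate subject ids {dupes}")
    if check_files:
        for _, row in df.iterrows():
            for col in ("ts_path", "sc_path"):
                if not Path(row[col]).exists():
                    raise FileNotFoundError(
                        f"manifest {path} row {row['subject_id']}: missing file {row[col]}"
                    )
    return df


def read_region_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("region_id", "region_name", "network_label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: region table missing column {col}")
    return df.sort_values("region_id").reset_index(drop=True)


def write_state_model(path: str | Path, model: LeidaStates) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "chosen_k": int(model.chosen_k_),
        "centroids": model.centroids_.tolist(),
        "centroids_raw": model.centroids_raw_.tolist(),
        "validity": model.validity_.reset_index().to_dict(orient="list"),
        "state_names": list(getattr(model, "state_names_", [])),
        "params": model.get_params(),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_state_model(path: str | Path) -> LeidaStates:
    payload = json.loads(Path(path).read_text())
    params = payload["params"]
    params["k_range"] = tuple(params["k_range"])
    model = LeidaStates(**params)
    model.chosen_k_ = payload["chosen_k"]
    model.centroids_ = np.asarray(payload["centroids"], dtype=float)
    model.centroids_raw_ = np.asarray(payload["centroids_raw"], dtype=float)
    model.validity_ = pd.DataFrame(payload["validity"]).set_index("k")
    if payload["state_names"]:
        model.state_names_ = payload["state_names"]
    model.n_features_in_ = model.centroids_.shape[1]
    return model


def write_sequences(path: str | Path, sequences: dict[str, np.ndarray]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("subject_id\tstates\n")
        for sid, seq in sequences.items():
            fh.write(f"{sid}\t{','.join(str(int(s)) for s in seq)}\n")
    return path


def read_sequences(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.subject_id: np.array([int(s) for s in row.states.split(",")])
            for row in df.itertuples()}
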