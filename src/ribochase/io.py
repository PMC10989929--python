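"""Table I/O and run provenance.

All tables are UTF-8 comma-separated with a header row; missing values
are empty fields.  Every artifact a pipeline stage writes gets a sidecar
JSON (``<artifact>.provenance.json``) recording the stage, parameters,
seed and SHA-256 of each input, enough to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd

from ribochase.simulate import QPCR_COLUMNS
from ribochase.quantify import RQ_COLUMNS
from ribochase.decay import FIT_COLUMNS


def _check_columns(df: pd.DataFrame, required, path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_qpcr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, QPCR_COLUMNS, path)
    # reference wells carry an empty region label, not a missing value
    df["region"] = df["region"].fillna("")
    return df[QPCR_COLUMNS]


def write_qpcr_csv(df: pd.DataFrame, path) -> None:
    df[QPCR_COLUMNS].to_csv(path, index=False)


def read_rq_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _check_columns(df, RQ_COLUMNS, path)[RQ_COLUMNS]


def write_rq_csv(df: pd.DataFrame, path) -> None:
    df[RQ_COLUMNS].to_csv(path, index=False)


def read_fits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _check_columns(df, FIT_COLUMNS, path)[FIT_COLUMNS]


def write_fits_csv(results, path) -> None:
    """Write a list of DecayFitResult (or an equivalent DataFrame)."""
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([r.to_row() for r in results])
    results[FIT_COLUMNS].to_csv(path, index=False)


def read_intensity_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _check_columns(df, ["comparison", "fc"], path)


def write_intensity_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(
    artifact_path,
    stage: str,
    params,
    seed: int | None = None,
    inputs: dict[str, str] | None = None,
) -> Path:
    """Write ``<artifact>.provenance.json`` next to an artifact.

    ``inputs`` maps role -> path; each is hashed.  ``params`` may be a
    dataclass, dict or anything JSON-serialisable via str fallback.
    """
    if is_dataclass(params) and not isinstance(params, type):
        params = asdict(params)
    sidecar = Path(str(artifact_path) + ".provenance.json")
    payload = {
        "stage": stage,
        "artifact": str(artifact_path),
        "seed": seed,
        "parameters": params,
        "inputs": {
            role: {"path": str(p), "sha256": sha256_of(p)}
            for role, p in (inputs or {}).items()
        },
    }
    sidecar.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return sidecar
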