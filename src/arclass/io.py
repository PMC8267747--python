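"""Readers and writers for the plain-text pipeline formats.

Formats (all CSV files are comma-separated UTF-8 with a mandatory header):

* data CSV: ``id,dock_score[,label]`` — one compound per row; an empty or
  missing score is treated as the 0 "no pose" sentinel with a logged warning.
* fingerprint file: ``id,bits`` with a 0/1 string per row, or the hex dialect
  ``id,fp_hex,length``.
* predictions CSV: ``id,procedure,probability,class``.
* model files and run manifests: JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .fingerprints import Fingerprint

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_fingerprints",
    "write_fingerprints",
    "write_manifest",
]

logger = logging.getLogger("arclass")


def read_fingerprints(path) -> dict:
    """Read an ``id -> Fingerprint`` mapping; detects the bit/hex dialect."""
    df = pd.read_csv(path, dtype=str)
    cols = set(df.columns)
    if {"id", "bits"} <= cols:
        decode = lambda row: Fingerprint(row["bits"])
    elif {"id", "fp_hex", "length"} <= cols:
        decode = lambda row: Fingerprint.from_hex(row["fp_hex"], int(row["length"]))
    else:
        raise ValueError(
            f"{path}: fingerprint file needs columns (id,bits) or "
            f"(id,fp_hex,length); found {sorted(cols)}"
        )
    fps = {}
    for i, row in df.iterrows():
        if row["id"] in fps:
            raise ValueError(f"{path}: duplicate fingerprint id {row['id']!r}")
        try:
            fps[row["id"]] = decode(row)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from exc
    lengths = {fp.length for fp in fps.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: mixed fingerprint lengths {sorted(lengths)}")
    return fps


def write_fingerprints(fps: dict, path, dialect: str = "bits") -> None:
    if dialect == "bits":
        df = pd.DataFrame(
            {"id": list(fps), "bits": [fp.to_string() for fp in fps.values()]}
        )
    elif dialect == "hex":
        df = pd.DataFrame(
            {
                "id": list(fps),
                "fp_hex": [fp.to_hex() for fp in fps.values()],
                "length": [fp.length for fp in fps.values()],
            }
        )
    else:
        raise ValueError("dialect must be 'bits' or 'hex'")
    df.to_csv(path, index=False)


def read_dataset(path, fp_path) -> LabeledDataset:
    """Join the data CSV with the fingerprint file on compound id."""
    df = pd.read_csv(path)
    if "id" not in df.columns or "dock_score" not in df.columns:
        raise ValueError(f"{path}: data file needs columns id,dock_score[,label]")
    ids = df["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate compound ids {dupes[:5]}")

    scores = pd.to_numeric(df["dock_score"], errors="coerce")
    n_missing = int(scores.isna().sum())
    if n_missing:
        logger.warning(
            "%s: %d rows have a missing docking score; treated as the 0 "
            "'no pose' sentinel",
            path,
            n_missing,
        )
        scores = scores.fillna(0.0)

    fps = read_fingerprints(fp_path)
    missing = [i for i in ids if i not in fps]
    if missing:
        raise ValueError(
            f"{path}: ids missing from fingerprint file {fp_path}: {missing[:5]}"
        )

    labels = None
    if "label" in df.columns and df["label"].notna().any():
        if df["label"].isna().any():
            bad = df["id"][df["label"].isna()].tolist()
            raise ValueError(f"{path}: rows with missing labels: {bad[:5]}")
        labels = df["label"].astype(int).to_numpy()

    return LabeledDataset(
        ids=ids,
        fingerprints=[fps[i] for i in ids],
        scores=scores.to_numpy(dtype=float),
        labels=labels,
    )


def write_dataset(dataset: LabeledDataset, path, fp_path) -> None:
    dataset.to_frame().to_csv(path, index=False, float_format="%.6g")
    write_fingerprints(
        dict(zip(dataset.ids, dataset.fingerprints)), fp_path
    )


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, command: str, config: dict, seed, inputs: list) -> Path:
    """Write the run manifest next to the primary output file."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _to_jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
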