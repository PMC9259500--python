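"""TSV/JSON readers and writers shared by all pipeline stages.

One dialect everywhere: tab-separated, header row, UTF-8, '.' decimal, no
quoting.  Feature tables travel in long format (bgc_id, domain, weight)
and are pivoted to wide nonnegative matrices on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_matrix",
    "write_matrix",
    "read_features_long",
    "write_features_long",
    "write_json",
    "file_sha256",
]


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={c: str for c in ()})


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_matrix(path) -> pd.DataFrame:
    """Square labelled matrix (e.g. ANI) with row labels in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
    return path


def read_features_long(path) -> pd.DataFrame:
    """Long-format feature table -> wide BGC x domain matrix (zeros filled)."""
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(
        index=long.columns[0], columns="domain", values="weight", fill_value=0.0
    )
    wide.columns.name = None
    return wide


def write_features_long(features: pd.DataFrame, path, id_name: str = "bgc_id") -> Path:
    long = features.stack().rename("weight").reset_index()
    long.columns = [id_name, "domain", "weight"]
    long = long[long["weight"] != 0]
    return write_tsv(long, path)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
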