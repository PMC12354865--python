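"""Clinical tables, score files and bag manifests.

Clinical CSV schema: patient_id, dfs_months, dfs_event, mrd_status
(positive/negative, blank for missing), age, sex, pT, pN, pM, act, msi.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = ["read_clinical", "write_clinical", "read_scores", "write_scores",
           "read_manifest", "write_manifest", "sha256_file"]

CLINICAL_COLUMNS = ["patient_id", "dfs_months", "dfs_event", "mrd_status",
                    "age", "sex", "pT", "pN", "pM", "act", "msi"]


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in ("patient_id", "dfs_months", "dfs_event") if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table lacks required column(s) {missing}")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in clinical table")
    if "mrd_status" in df.columns:
        df["mrd_status"] = (df["mrd_status"].fillna("missing").astype(str)
                            .str.strip().str.lower().replace("", "missing"))
    else:
        df["mrd_status"] = "missing"
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if not {"patient_id", "risk"} <= set(df.columns):
        raise ValueError("scores file needs columns patient_id, risk")
    return df


def write_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if not {"patient_id", "bag_path"} <= set(df.columns):
        raise ValueError("bag manifest needs columns patient_id, bag_path")
    return df


def write_manifest(pairs, path) -> None:
    pd.DataFrame(pairs, columns=["patient_id", "bag_path"]).to_csv(path, index=False)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
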