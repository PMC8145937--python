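"""Dataset CSV reader/writer with validation.

The dataset dialect is a flat CSV with header
``SUBJ,SEQ,PERIOD,TRT,DOSE,TIME,DV,BLQ`` (one record per subject x
period x time, concentrations in ug/L).  A YAML sidecar
(``<file>.meta.yaml``) carries the simulation metadata when available.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .population import ConcDataset

__all__ = ["DatasetError", "read_dataset", "write_dataset",
           "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ["SUBJ", "SEQ", "PERIOD", "TRT", "DOSE", "TIME", "DV",
                    "BLQ"]


class DatasetError(ValueError):
    """Malformed concentration dataset."""


def _meta_path(path: str) -> str:
    return f"{path}.meta.yaml"


def write_dataset(ds: ConcDataset, path: str) -> None:
    ds.df.to_csv(path, index=False)
    if ds.meta:
        with open(_meta_path(path), "w") as fh:
            yaml.safe_dump(ds.meta, fh, sort_keys=False)


def read_dataset(path: str) -> ConcDataset:
    """Read and validate a dataset CSV.

    Rejects missing columns, duplicated (SUBJ, PERIOD, TIME) keys and
    negative concentrations; records are returned sorted by subject,
    period and time.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing columns {missing}")
    dup = df.duplicated(subset=["SUBJ", "PERIOD", "TIME"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["SUBJ", "PERIOD", "TIME"]].drop_duplicates()
        raise DatasetError(
            "duplicated (SUBJ, PERIOD, TIME) records: "
            + "; ".join(f"({r.SUBJ}, {r.PERIOD}, {r.TIME})"
                        for r in keys.itertuples()))
    if (df["DV"] < 0).any():
        bad = df.loc[df["DV"] < 0, ["SUBJ", "PERIOD", "TIME"]].iloc[0]
        raise DatasetError(f"negative DV at (SUBJ={bad.SUBJ}, "
                           f"PERIOD={bad.PERIOD}, TIME={bad.TIME})")
    if (df["TIME"] < 0).any():
        raise DatasetError("negative TIME values")
    df = df.sort_values(["SUBJ", "PERIOD", "TIME"],
                        kind="mergesort").reset_index(drop=True)
    df["BLQ"] = df["BLQ"].astype(bool)

    meta = {}
    if os.path.exists(_meta_path(path)):
        with open(_meta_path(path)) as fh:
            meta = yaml.safe_load(fh) or {}
    return ConcDataset(df=df, meta=meta)
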