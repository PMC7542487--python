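"""Delimited-text dataset format: header ``group,label,f1..fd``."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError
from .style_transform import StyleGroupedDataset


def write_dataset(dataset: StyleGroupedDataset, path: str | Path) -> None:
    cols = {"group": dataset.group.astype(int),
            "label": dataset.y.astype(int)}
    for i in range(dataset.d):
        cols[f"f{i + 1}"] = dataset.X[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> StyleGroupedDataset:
    df = pd.read_csv(path)
    required = {"group", "label"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    feats = [c for c in df.columns if c not in required]
    if not feats:
        raise InputError(f"{path}: no feature columns (expected f1..fd)")
    return StyleGroupedDataset(df[feats].to_numpy(dtype=float),
                               df["label"].to_numpy(dtype=float),
                               df["group"].to_numpy(dtype=int))
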