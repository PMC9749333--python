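"""Readers and writers for the pipeline's tabular and image artifacts.

All tabular artifacts are plain CSV/TSV (diffable, round-trip faithful to
float text precision); masks are 8-bit PNG with 0/255 values. Malformed
inputs raise with the offending line or id in the message.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "write_feature_table", "read_feature_table",
    "write_clinical", "read_clinical",
    "write_scores", "read_scores",
    "write_expression", "read_expression",
    "write_mask_png", "read_mask_png",
    "write_image_png", "read_image_png",
]

_CLINICAL_REQUIRED = ("slide_id", "time_months", "event")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Feature CSV: one row per slide, ``slide_id`` plus canonical id columns."""
    table.to_csv(path, index=True, index_label="slide_id",
                 float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="slide_id", comment="#")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicated slide_id {dup!r} in {path}")
    return table


def write_clinical(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.12g")


def read_clinical(path) -> pd.DataFrame:
    records = pd.read_csv(path, comment="#")
    missing = [c for c in _CLINICAL_REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"clinical table {path} lacks columns: {missing}")
    if records["slide_id"].duplicated().any():
        dup = records.loc[records["slide_id"].duplicated(), "slide_id"].iloc[0]
        raise ValueError(f"duplicated slide_id {dup!r} in {path}")
    if not set(records["event"].unique()) <= {0, 1}:
        raise ValueError("event column must be 0/1")
    return records


def write_scores(scores: pd.Series, path) -> None:
    scores.rename("score").to_csv(path, index_label="slide_id",
                                  float_format="%.12g")


def read_scores(path) -> pd.Series:
    df = pd.read_csv(path, index_col="slide_id", comment="#")
    return df["score"]


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Expression TSV: rows = genes, columns = samples."""
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.12g")


def read_expression(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="gene", comment="#")
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicated gene id {dup!r} in {path}")
    return matrix


def write_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) >= 128


def write_image_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_image_png(path) -> np.ndarray:
    img = Image.open(path)
    return np.asarray(img)
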