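"""Assembling per-subject feature tables for model evaluation.

A feature table is a DataFrame with the meta columns ``subject_id,
label, language, task`` followed by feature columns — either the named
handcrafted battery or ``CNN:0000...`` deep-feature columns — one row
per (subject, task).  Tables round-trip through CSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .backbones import Backbone, deep_feature_names, extract_deep_features
from .features import extract_feature_vector
from .records import HandwritingRecord
from .render import render_offline_image

__all__ = [
    "handcrafted_feature_table",
    "deep_feature_table",
    "write_feature_table",
    "read_feature_table",
]


def _meta_row(rec: HandwritingRecord) -> dict:
    return {
        "subject_id": rec.meta.subject_id,
        "label": rec.meta.label,
        "language": rec.meta.language,
        "task": rec.meta.task,
    }


def handcrafted_feature_table(
    records: list[HandwritingRecord],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Extract the handcrafted battery for every record.

    Returns the table and a per-subject QC report (warnings about
    missing feature families).  All records must share one task so the
    column schema is identical.
    """
    tasks = {r.meta.task for r in records}
    if len(tasks) > 1:
        raise ValueError(f"records mix tasks {sorted(tasks)}; build one table per task")
    rows, qc = [], {}
    for rec in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv = extract_feature_vector(rec)
        rows.append({**_meta_row(rec), **fv.values})
        if fv.qc:
            qc[rec.meta.subject_id] = fv.qc
    return pd.DataFrame(rows), qc


def deep_feature_table(
    records: list[HandwritingRecord],
    backbone: Backbone | None = None,
) -> pd.DataFrame:
    """Render each record offline and extract frozen-backbone features."""
    rows = []
    names: list[str] | None = None
    for rec in records:
        image = render_offline_image(rec)
        dfv = extract_deep_features(image, backbone)
        if names is None:
            names = deep_feature_names(len(dfv.values))
        rows.append({**_meta_row(rec), **dict(zip(names, dfv.values))})
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    feature_cols = [
        c for c in df.columns
        if c not in ("subject_id", "label", "language", "task")
    ]
    df[feature_cols] = df[feature_cols].astype(float)
    return df
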