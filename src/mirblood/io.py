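"""Readers and writers for the pipeline's tabular formats.

All tables are plain text: tab-delimited with '.' decimal marks for
matrices and marker tables, CSV for sample annotation, JSON for summaries.
The marker table writer emits the exact column order of the published
marker table.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

MARKER_TABLE_HEADER = [
    "miRNA",
    "median melanoma",
    "median normal",
    "fold change",
    "wmw adjp",
    "ttest adjp",
    "limma adjp",
    "AUC",
]

VALID_GROUPS = {"C", "M", "N"}


def write_expression_tsv(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="miRNA")


def read_expression_tsv(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.index.duplicated().any():
        dupes = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes[:5]}")
    m.index.name = "miRNA"
    return m


def write_annotation_csv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, index=False)


def read_annotation_csv(path) -> pd.DataFrame:
    ann = pd.read_csv(path)
    required = {"sample_id", "group"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in annotation")
    unknown = set(ann["group"]) - VALID_GROUPS
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return ann


def check_samples_annotated(m: pd.DataFrame, ann: pd.DataFrame) -> None:
    """Every matrix sample must appear in the annotation; offenders are named."""
    missing = [s for s in m.columns if s not in set(ann["sample_id"])]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing}")


def write_marker_table(table: pd.DataFrame, path, formatted: bool = True) -> None:
    """Write a marker table in the published column order.

    ``formatted`` applies the reporting rounding (fold to 1 decimal, integer
    from 10 up; AUC to 2 decimals); otherwise full precision is kept.
    """
    from .markers import format_fold

    out = pd.DataFrame(index=table.index)
    out["median melanoma"] = table["median_case"]
    out["median normal"] = table["median_control"]
    if formatted:
        out["fold change"] = table["fold_change"].map(format_fold)
        out["AUC"] = table["auc"].round(2)
    else:
        out["fold change"] = table["fold_change"]
        out["AUC"] = table["auc"]
    out.insert(3, "wmw adjp", table["adj_wmw"])
    out.insert(4, "ttest adjp", table["adj_t"])
    out.insert(5, "limma adjp", table["adj_limma"])
    out.index.name = "miRNA"
    out.to_csv(path, sep="\t")


def read_marker_table(path) -> pd.DataFrame:
    """Read a marker table written by :func:`write_marker_table`."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    return raw.rename(
        columns={
            "median melanoma": "median_case",
            "median normal": "median_control",
            "fold change": "fold_change",
            "wmw adjp": "adj_wmw",
            "ttest adjp": "adj_t",
            "limma adjp": "adj_limma",
            "AUC": "auc",
        }
    )


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
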