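"""Packaged reference tables from the melanoma blood screening publication.

Two small fixtures ship with the package: the 51-row stringent marker table
(group medians, fold changes, adjusted p-values, AUCs) and the 13-miRNA
qPCR-versus-microarray validation table. Both are fully printed in the
publication; they let the fixture-level analyses run without any download.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("mirblood.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_marker_table() -> pd.DataFrame:
    """The published 51-miRNA stringent marker table, sorted by AUC."""
    t = _read("published_markers.tsv").set_index("miRNA")
    return t.rename(
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


def load_qpcr_validation() -> pd.DataFrame:
    """The published 13-miRNA qPCR vs microarray fold-change comparison."""
    t = _read("published_qpcr_validation.tsv").set_index("miRNA")
    return t.rename(
        columns={
            "fold change qRT-PCR": "qpcr_fold_change",
            "fold change microarray": "array_fold_change",
        }
    )


# Clinical stage composition of the screening cohort (35 melanoma patients).
STAGE_COUNTS = {"0-IIB": 31, "IIIB": 1, "IV": 3}


def stage_share_percent(stage: str = "0-IIB") -> float:
    """Percentage of melanoma patients in the given stage bracket."""
    total = sum(STAGE_COUNTS.values())
    return 100.0 * STAGE_COUNTS[stage] / total
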