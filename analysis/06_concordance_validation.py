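"""Cross-cohort and cross-platform concordance.

Fold quotients of the melanoma test arm and the validation arm against the
shared controls, correlated on the log scale over features with median
intensity >= 50 in at least one arm; then a simulated qPCR panel for 13
planted markers, ddCt fold changes against the endogenous control, and the
linear-scale correlation with the microarray fold changes.
"""
import sys
from pathlib import Path

import pandas as pd

from mirblood.concordance import (
    ddct_fold_change,
    log_fold_correlation,
    per_set_fold_quotients,
    platform_correlation,
)
from mirblood.io import read_annotation_csv, read_expression_tsv, write_json
from mirblood.simulate import SyntheticTruth, generate_qpcr_panel

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2010
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    m = read_expression_tsv(ROOT / "expression.tsv")
    ann = read_annotation_csv(ROOT / "cohort" / "annotation.csv")
    truth_frame = pd.read_csv(ROOT / "cohort" / "truth.tsv", sep="\t")
    truth = SyntheticTruth(
        planted_ids=tuple(truth_frame["feature_id"]),
        direction=dict(zip(truth_frame["feature_id"], truth_frame["direction"])),
        log2_effect=dict(zip(truth_frame["feature_id"], truth_frame["log2_effect"])),
        feature_ids=tuple(m.index),
    )

    by = ann.set_index("sample_id")["group"]
    ctrl = m[by[by == "C"].index]
    fq_test = per_set_fold_quotients(m[by[by == "M"].index], ctrl, label="test")
    fq_val = per_set_fold_quotients(m[by[by == "N"].index], ctrl, label="validation")
    r_sets = log_fold_correlation(fq_test, fq_val)
    print(f"test vs validation log fold-quotient correlation r = {r_sets:.3f}")

    picked = list(truth.planted_ids[:13])
    panel = generate_qpcr_panel(truth, picked, n_per_group=10, ct_sd=0.2, seed=SEED)
    panel.to_long_frame().to_csv(ROOT / "qpcr_panel.csv", index=False)
    qpcr = ddct_fold_change(panel)
    test_ids = by[by == "M"].index
    array = m.loc[picked, test_ids].median(axis=1) / ctrl.loc[picked].median(axis=1)
    r_platform = platform_correlation(qpcr, array)
    print(f"qPCR (ddCt) vs microarray fold-change correlation over "
          f"{len(picked)} planted miRNAs: r = {r_platform:.3f}")
    write_json(
        {"test_validation_log_fold_r": r_sets, "qpcr_array_r": r_platform},
        ROOT / "concordance.json",
    )


if __name__ == "__main__":
    main()
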