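"""Generate the study-shaped synthetic cohort all later stages analyze.

866 miRNA probes x 55 arrays (20 healthy controls C, 24 melanoma test M,
11 melanoma validation N), 7 replicate spots per probe, 51 planted
differential features with 2-8-fold effects in both directions.

Writes probe-level intensities, sample annotation and the planted truth
under results/cohort/.
"""
import sys
from pathlib import Path

from mirblood.config import SimulationConfig
from mirblood.io import write_annotation_csv
from mirblood.simulate import generate_cohort, write_probe_tsv, write_truth_tsv

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2010
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    probe, ann, truth = generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_probe_tsv(probe, OUT / "probe_level.tsv")
    write_annotation_csv(ann, OUT / "annotation.csv")
    write_truth_tsv(truth, OUT / "truth.tsv")
    n_up = sum(d == "up" for d in truth.direction.values())
    print(f"cohort: {len(probe.feature_ids)} features x {len(probe.sample_ids)} samples "
          f"x {probe.n_replicates} replicates (seed {SEED})")
    print(f"planted: {len(truth.planted_ids)} features "
          f"({n_up} up, {len(truth.planted_ids) - n_up} down)")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
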