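#!/usr/bin/env python
"""Group comparison on a full-size synthetic cohort (28 HC vs 22 PS).

Generates per-subject regional TACs from the group BP_ND distributions,
quantifies them with reference Logan and windowed SUVR, and computes the
statistics report: Glass's delta, exact Mann-Whitney p, ROC AUC with
bootstrap CI per region, the consistency ICC between the dynamic and static
measures, and the contralateral concordance among lateralized patients.
"""

from pathlib import Path

import pandas as pd

import datpipe as dp
from datpipe.pipeline import cohort_statistics, quantify_cohort_tacs

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    schedule = dp.make_default_schedule()
    spec = dp.CohortSpec(n_hc=28, n_ps=22, tac_noise_scale=0.3, seed=1)
    truth, tacs = dp.generate_cohort(spec, schedule=schedule)
    measured = quantify_cohort_tacs(truth, tacs, schedule)
    measured.to_csv(RESULTS / "cohort_measured.csv", index=False)

    report = cohort_statistics(measured, measures=("bp_nd", "suvr"), seed=1)
    per_region = pd.DataFrame(report["per_region"])
    icc = pd.DataFrame(report["icc"])
    laterality = pd.DataFrame(report["laterality"])
    per_region.to_csv(RESULTS / "cohort_stats_per_region.csv", index=False)
    icc.to_csv(RESULTS / "cohort_stats_icc.csv", index=False)
    laterality.to_csv(RESULTS / "cohort_stats_laterality.csv", index=False)

    print("Per-region group comparison (left/right-averaged):")
    print(per_region.round(3).to_string(index=False))
    print("\nConsistency ICC between dynamic BP_ND and static SUVR:")
    print(icc.round(3).to_string(index=False))
    print("\nContralateral concordance in lateralized patients:")
    print(laterality.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
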