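#!/usr/bin/env python
"""Full pipeline at the study size: imaging arm + statistics tables.

Runs the end-to-end chain once at the study's sample sizes (40 PD / 29
controls): simulate a calibrated cohort, inject one extreme-cholesterol
subject per group, image each subject's phantom under Rician noise at
SNR 40, fit R2* maps, summarise ROIs by trimmed means, apply the 2-SD
cholesterol exclusion, and emit the three report tables under
results/study_run/.
"""

import json
from pathlib import Path

import pandas as pd

from nigrastar.cohort import inject_outliers, simulate_cohort, default_cohort_spec
from nigrastar.pipeline import (
    PipelineConfig,
    _image_stage,
    analyze_tables,
    merge_measured_rois,
)


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "results" / "study_run"
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=303, out_dir=str(out), n_pd=40, n_control=29,
                         grid_shape=(24, 24, 12))

    from dataclasses import replace

    cohort = simulate_cohort(replace(default_cohort_spec(), seed=cfg.seed))
    cohort = inject_outliers(cohort, 1, 2.64, group="PD", seed=1)
    cohort = inject_outliers(cohort, 1, 2.3, group="control", seed=2)
    cohort.to_csv(out / "cohort.csv", index=False)

    roi_table = _image_stage(cfg, cohort)
    roi_table.to_csv(out / "roi.csv", index=False)
    measured = merge_measured_rois(cohort, roi_table)
    log = analyze_tables(measured, out)

    t3 = pd.read_csv(out / "table3.csv")
    print(f"Excluded as cholesterol outliers: {log['outliers_excluded']}")
    print("\nLipid correlation table (measured trimmed-mean R2*):")
    print(t3.to_string(index=False))
    key = t3.query("group=='PD' and roi=='SN' and variable=='total_chol' "
                   "and covariate_set=='basic'")
    print(f"\nSingle-cohort PD SN/total-cholesterol cell: rho="
          f"{key['rho'].iloc[0]:.3f} (p={key['p'].iloc[0]:.3f}); one n=39 "
          "draw scatters around the generating target by ~0.13 SD.")


if __name__ == "__main__":
    main()
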