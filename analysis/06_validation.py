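"""Estimator validation studies: recovery, GOF calibration, FST recovery.

Runs the seeded simulation studies that characterize the SCR engine and
the differentiation estimator (the same studies the acceptance checks
run), and writes their tables under results/validation/.
"""

import json

import numpy as np
from common import RESULTS, SEED

from linscr.experiments import (fst_recovery, gof_calibration, recovery_study,
                                recovery_summary)


def main() -> None:
    out = RESULTS / "validation"
    out.mkdir(exist_ok=True)

    df = recovery_study(n_sims=50, seed=SEED)
    df.to_csv(out / "recovery.csv", index=False)
    s = recovery_summary(df)
    print("parameter recovery (50 sims, default scenario):")
    print(f"  median relative bias: D {s['median_rel_bias_D_pct']:+.1f}%, "
          f"lambda0 {s['median_rel_bias_lam0_pct']:+.1f}%, "
          f"sigma {s['median_rel_bias_sigma_pct']:+.1f}%")
    print(f"  95% Wald CI coverage for D: {s['coverage_D']:.2f}")

    ps = gof_calibration(n_meta=20, n_gof_reps=25, seed=SEED)
    np.savetxt(out / "gof_pvalues.txt", ps)
    print(f"GOF calibration (20 meta-replicates x 25 reps): "
          f"fraction p < 0.05 = {np.mean(ps < 0.05):.2f}, "
          f"median p = {np.median(ps):.2f}")

    thetas = fst_recovery(n_reps=200, seed=SEED)
    np.savetxt(out / "fst_thetas.txt", thetas)
    print(f"FST recovery (target 0.10, 200 reps): "
          f"mean theta = {np.mean(thetas):.3f}, sd = {np.std(thetas):.3f}")

    with open(out / "summary.json", "w") as fh:
        json.dump({**s,
                   "gof_frac_p_below_005": float(np.mean(ps < 0.05)),
                   "fst_mean_theta": float(np.mean(thetas))}, fh, indent=2)


if __name__ == "__main__":
    main()
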