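"""Repeatable simulation experiments that characterize the estimators.

These are the package's own validation studies: parameter recovery for the
SCR engine on the default synthetic scenario, goodness-of-fit p-value
calibration under the true model, and recovery of a target differentiation
by the Weir-Cockerham estimator.  The analysis scripts and the acceptance
checks both run them; everything is seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import discretize
from .popgen import fst_weir_cockerham
from .scr import SCRModelSpec, fit
from .selection import simulate_gof
from .simulate import (SimulationConfig, generate_network, place_detectors,
                       simulate_detections, simulate_population,
                       simulate_two_populations)

__all__ = ["recovery_study", "gof_calibration", "fst_recovery"]


def _one_survey(cfg: SimulationConfig, seed: int, spacing_m: float):
    ss = np.random.SeedSequence(seed)
    s_net, s_pop, s_det = [int(c.generate_state(1)[0] % 2**31)
                           for c in ss.spawn(3)]
    net = generate_network(cfg, s_net)
    det = place_detectors(net, cfg, s_det)
    centers, _ = simulate_population(net, cfg.density_per_km, s_pop,
                                     prop_male=None)
    hist = simulate_detections(net, centers, det, cfg.lambda0_female,
                               cfg.sigma_m, s_det + 1).drop_empty()
    space = discretize(net, spacing_m)
    return net, det, hist, space


def recovery_study(
    n_sims: int = 50,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
    spacing_m: float = 500.0,
) -> pd.DataFrame:
    """Repeated simulate-and-refit at the default scenario (sexless model).

    Returns one row per simulation with estimates, SEs and the Wald-CI
    coverage indicator for density.  Summaries of interest: median relative
    bias of D, lambda0 and sigma, and the D CI coverage rate.
    """
    cfg = cfg or SimulationConfig()
    rows = []
    for r in range(n_sims):
        net, det, hist, space = _one_survey(cfg, seed * 100_003 + r, spacing_m)
        if hist.n_individuals < 5:
            continue
        f = fit(hist, space, det, SCRModelSpec(), n_starts=1, seed=0,
                mixture=False, warn_no_spatial_recaptures=False)
        d = f.derived()
        dd = d["density_per_km"]
        rows.append({
            "sim": r,
            "n_detected": hist.n_individuals,
            "converged": f.converged,
            "D_hat": dd.estimate, "D_se": dd.se,
            "D_lcl": dd.lcl, "D_ucl": dd.ucl,
            "D_covered": dd.lcl <= cfg.density_per_km <= dd.ucl,
            "lam0_hat": d["lam0_all_naive"].estimate,
            "sigma_hat": d["sigma"].estimate,
        })
    return pd.DataFrame(rows)


def recovery_summary(df: pd.DataFrame, cfg: SimulationConfig | None = None) -> dict:
    cfg = cfg or SimulationConfig()
    ok = df[df.converged]
    return {
        "n_sims": int(len(ok)),
        "median_rel_bias_D_pct": float(100 * np.median(
            (ok.D_hat - cfg.density_per_km) / cfg.density_per_km)),
        "median_rel_bias_lam0_pct": float(100 * np.median(
            (ok.lam0_hat - cfg.lambda0_female) / cfg.lambda0_female)),
        "median_rel_bias_sigma_pct": float(100 * np.median(
            (ok.sigma_hat - cfg.sigma_m) / cfg.sigma_m)),
        "coverage_D": float(ok.D_covered.mean()),
    }


def gof_calibration(
    n_meta: int = 20,
    n_gof_reps: int = 25,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
    spacing_m: float = 1000.0,
) -> np.ndarray:
    """P-values of the parametric-bootstrap GOF when the model is true.

    Under the generating model the p-values should be roughly uniform;
    the headline summary is the fraction below 0.05.
    """
    cfg = cfg or SimulationConfig(n_branches=2, total_length_km=50.0,
                                  n_detectors=10, n_occasions=6)
    ps = []
    for m in range(n_meta):
        net, det, hist, space = _one_survey(cfg, seed * 77_003 + m, spacing_m)
        if hist.n_individuals < 6:
            continue
        f = fit(hist, space, det, SCRModelSpec(), n_starts=1, seed=0,
                mixture=False, warn_no_spatial_recaptures=False)
        if not f.converged:
            continue
        g = simulate_gof(f, n_replicates=n_gof_reps, seed=seed * 11 + m)
        ps.append(g.p_value)
    return np.asarray(ps)


def fst_recovery(
    n_reps: int = 200,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
) -> np.ndarray:
    """Multilocus theta estimates across repeated two-population draws."""
    cfg = cfg or SimulationConfig(target_fst=0.10, popgen_n_loci=30,
                                  popgen_n_per_pop=50)
    thetas = []
    for r in range(n_reps):
        pa, pb = simulate_two_populations(cfg, seed * 13_007 + r)
        theta, _, _ = fst_weir_cockerham(pa, pb, n_boot=0)
        thetas.append(theta)
    return np.asarray(thetas)
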