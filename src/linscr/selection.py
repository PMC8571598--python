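"""Model selection, averaging, goodness of fit and population growth.

AICc uses the number of detected individuals as the effective sample size.
Models within 2 AICc of the best are the competing set; their derived
real-scale estimates are combined with Akaike weights and unconditional
(Burnham-Anderson) variances.  Goodness of fit follows the parametric
bootstrap: simulate detection data from the fitted model, refit, and
compare the observed deviance/df ratio W with its simulated distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scr import (DerivedEstimate, SCRFit, _lognormal_ci, _logit_ci,
                  _ParamLayout, fit as scr_fit)
from .simulate import simulate_detections, simulate_population_on_space

__all__ = [
    "aicc_table",
    "competing_set",
    "model_average",
    "GofResult",
    "simulate_gof",
    "GrowthEstimate",
    "exponential_growth",
]


def aicc_table(fits: list[SCRFit]) -> pd.DataFrame:
    """Rank fits by AICc with Akaike weights over the supplied set."""
    if not fits:
        raise ValueError("no fits supplied")
    n = {f.n_individuals for f in fits}
    if len(n) > 1:
        raise ValueError("fits are not on identical data")
    rows = [{
        "model": f.spec.label(),
        "K": f.k,
        "AIC": f.aic,
        "AICc": f.aicc,
        "logLik": f.loglik,
        "deviance": f.deviance,
        "usable": f.usable,
    } for f in fits]
    df = pd.DataFrame(rows)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    rel = np.exp(-df["dAICc"] / 2.0)
    df["weight"] = rel / rel.sum()
    df["competing"] = df["dAICc"] <= 2.0
    return df.sort_values("AICc").reset_index(drop=True)[
        ["model", "K", "AIC", "AICc", "dAICc", "logLik", "deviance",
         "weight", "competing", "usable"]]


def competing_set(fits: list[SCRFit], delta: float = 2.0) -> list[SCRFit]:
    """Usable fits within ``delta`` AICc of the best usable fit."""
    ok = [f for f in fits if f.usable]
    if not ok:
        return []
    best = min(f.aicc for f in ok)
    return [f for f in ok if f.aicc - best <= delta]


def model_average(fits: list[SCRFit]) -> dict[str, DerivedEstimate]:
    """Akaike-weighted averages of derived real-scale estimates.

    Weights are renormalized over the supplied (competing) fits.  The
    unconditional variance adds the between-model spread to each model's
    conditional variance.  A parameter absent from some models (e.g. the
    bk rate in models without bk) is averaged over the models where it is
    defined and flagged ``partial``.
    """
    if not fits:
        raise ValueError("at least one fit required")
    aicc = np.array([f.aicc for f in fits])
    rel = np.exp(-(aicc - aicc.min()) / 2.0)
    w = rel / rel.sum()
    per_fit = [f.derived() for f in fits]
    names: list[str] = []
    for d in per_fit:
        for k in d:
            if k not in names:
                names.append(k)
    out: dict[str, DerivedEstimate] = {}
    for name in names:
        idx = [i for i, d in enumerate(per_fit) if name in d]
        wi = w[idx] / w[idx].sum()
        ests = np.array([per_fit[i][name].estimate for i in idx])
        ses = np.array([per_fit[i][name].se for i in idx])
        mean = float(wi @ ests)
        var_u = float(wi @ (ses**2 + (ests - mean) ** 2))
        se = np.sqrt(var_u)
        if name.startswith("prop_"):
            lcl, ucl = _logit_ci(mean, se)
        else:
            lcl, ucl = _lognormal_ci(mean, se)
        out[name] = DerivedEstimate(name, mean, se, lcl, ucl,
                                    averaged_over=len(idx),
                                    partial=len(idx) < len(fits))
    return out


@dataclass
class GofResult:
    w_observed: float
    w_simulated_mean: float
    p_value: float
    n_replicates_ok: int
    n_replicates: int
    w_simulated: np.ndarray


def simulate_gof(fit_: SCRFit, n_replicates: int = 100, seed: int = 0) -> GofResult:
    """Parametric-bootstrap goodness of fit for a fitted SCR model.

    Each replicate simulates a population from the fitted density surface
    on the same state space, simulates detections from the fitted detection
    parameters, refits the same model, and records W = deviance / df with
    df = detected individuals - K.  The p-value is the fraction of
    replicates with W at least as large as observed.
    """
    if not fit_.converged:
        raise ValueError("goodness of fit requires a converged fit")
    rng = np.random.default_rng(seed)
    lay = _ParamLayout(fit_.spec, fit_.mixture)
    log_D = lay.log_density(fit_.params, fit_.space)
    classes = lay.class_params(fit_.params)
    if fit_.mixture:
        prop_male = classes[1][3]
        lam0 = {"female": np.exp(classes[0][0]), "male": np.exp(classes[1][0])}
        sigma = {"female": np.exp(classes[0][2]), "male": np.exp(classes[1][2])}
        bkb = {"female": classes[0][1], "male": classes[1][1]}
    else:
        prop_male = None
        lam0, sigma, bkb = (np.exp(classes[0][0]), np.exp(classes[0][2]),
                            classes[0][1])
    w_obs = fit_.deviance / (fit_.n_individuals - fit_.k)
    sims = []
    failures = 0
    for _ in range(n_replicates):
        centers, sexes = simulate_population_on_space(
            fit_.space, log_D, rng, prop_male)
        hist = simulate_detections(
            fit_.space.net, centers, fit_.detectors, lam0, sigma, rng,
            sexes=sexes, bk_beta=bkb).drop_empty()
        if hist.n_individuals - fit_.k <= 1:
            failures += 1
            continue
        try:
            refit = scr_fit(hist, fit_.space, fit_.detectors, fit_.spec,
                            start=fit_.params, n_starts=1,
                            mixture=fit_.mixture, compute_cov=False,
                            warn_no_spatial_recaptures=False)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        if not refit.converged:
            failures += 1
            continue
        sims.append(refit.deviance / (refit.n_individuals - refit.k))
    if failures > n_replicates / 2:
        raise RuntimeError(
            f"{failures}/{n_replicates} goodness-of-fit replicates failed")
    sims = np.asarray(sims)
    return GofResult(
        w_observed=float(w_obs),
        w_simulated_mean=float(sims.mean()),
        p_value=float(np.mean(sims >= w_obs)),
        n_replicates_ok=len(sims),
        n_replicates=n_replicates,
        w_simulated=sims,
    )


@dataclass
class GrowthEstimate:
    n0: float
    nt: float
    t_years: float
    lam: float
    lcl: float | None = None
    ucl: float | None = None


def exponential_growth(
    n0: float, nt: float, t_years: float,
    nt_ci: tuple[float, float] | None = None,
) -> GrowthEstimate:
    """Average annual exponential growth rate lambda = (Nt / N0)^(1/t).

    The CI, when abundance CI bounds are given, applies the same transform
    to the bounds.
    """
    if n0 <= 0 or nt <= 0 or t_years <= 0:
        raise ValueError("N0, Nt and t must be positive")
    lam = (nt / n0) ** (1.0 / t_years)
    lcl = ucl = None
    if nt_ci is not None:
        lcl = (nt_ci[0] / n0) ** (1.0 / t_years)
        ucl = (nt_ci[1] / n0) ** (1.0 / t_years)
    return GrowthEstimate(n0=n0, nt=nt, t_years=t_years, lam=float(lam),
                          lcl=lcl, ucl=ucl)
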