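"""Individual-level latrine site fidelity from capture-recapture data.

The standardized site-fidelity index (SSFI) is the harmonic mean of a
permanence component IT (span between first and last capture at a latrine,
relative to the survey duration) and a periodicity component It
(recurrence within that span).  An occurrence component IO (share of the
individual's detections falling at the latrine) is computed and reported
but does not enter the composite, which follows the printed two-component
harmonic-mean formula.  Time is measured in survey occasions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .history import DetectionHistory

__all__ = [
    "FidelityRecord",
    "ssfi",
    "fidelity_records",
    "sex_mean_ssfi",
    "latrine_use_irr",
]


@dataclass
class FidelityRecord:
    individual: str
    latrine: int | str
    n_capture_occasions: int
    io: float
    it_permanence: float   # IT
    it_periodicity: float  # It
    ssfi: float


def ssfi(
    capture_occasions,
    n_occasions: int,
    individual_total_detections: int | None = None,
) -> FidelityRecord:
    """SSFI for one individual at one latrine.

    ``capture_occasions`` are the (0-based) occasions with >= 1 detection
    there.  IT = (last - first) / (n_occasions - 1); It = (number of capture
    occasions - 1) / (last - first); SSFI = 2 / (1/IT + 1/It), defined as 0
    when either component is 0 (in particular for a single capture).
    """
    occ = sorted(set(int(o) for o in capture_occasions))
    if not occ:
        raise ValueError("at least one capture occasion required")
    if n_occasions < 2:
        raise ValueError("need >= 2 survey occasions")
    if occ[0] < 0 or occ[-1] >= n_occasions:
        raise ValueError("capture occasion outside the survey")
    span = occ[-1] - occ[0]
    it_perm = span / (n_occasions - 1)
    it_per = (len(occ) - 1) / span if span > 0 else 0.0
    s = 2.0 / (1.0 / it_perm + 1.0 / it_per) if it_perm > 0 and it_per > 0 else 0.0
    total = individual_total_detections if individual_total_detections else len(occ)
    return FidelityRecord(
        individual="", latrine="", n_capture_occasions=len(occ),
        io=len(occ) / total if total else 0.0,
        it_permanence=it_perm, it_periodicity=it_per, ssfi=s,
    )


def fidelity_records(history: DetectionHistory) -> pd.DataFrame:
    """Per individual-latrine SSFI table from a detection history."""
    rows = []
    for i in range(history.n_individuals):
        total = int(history.counts[i].sum())
        for k in range(history.n_detectors):
            occ = np.flatnonzero(history.counts[i, k] > 0)
            if len(occ) == 0:
                continue
            rec = ssfi(occ, history.n_occasions, total)
            rows.append({
                "individual": history.individual_ids[i],
                "sex": history.sexes[i],
                "latrine": k,
                "n_capture_occasions": rec.n_capture_occasions,
                "IO": history.counts[i, k].sum() / total,
                "IT": rec.it_permanence,
                "It": rec.it_periodicity,
                "SSFI": rec.ssfi,
            })
    return pd.DataFrame(
        rows, columns=["individual", "sex", "latrine", "n_capture_occasions",
                       "IO", "IT", "It", "SSFI"])


def sex_mean_ssfi(
    records: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Mean SSFI per sex with a 95% percentile bootstrap CI over individuals."""
    import warnings
    rng = np.random.default_rng(seed)
    out = []
    for sex in ("female", "male"):
        sub = records[records["sex"] == sex]
        if len(sub) == 0:
            warnings.warn(f"no records for sex {sex!r}; skipped")
            continue
        inds = sub["individual"].unique()
        by_ind = {i: g["SSFI"].to_numpy() for i, g in sub.groupby("individual")}
        point = float(sub["SSFI"].mean())
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(inds, size=len(inds), replace=True)
            boots[b] = np.concatenate([by_ind[i] for i in pick]).mean()
        lcl, ucl = np.percentile(boots, [2.5, 97.5])
        out.append({"sex": sex, "mean_SSFI": point, "lcl": float(lcl),
                    "ucl": float(ucl), "n_individuals": len(inds)})
    return pd.DataFrame(out)


def latrine_use_irr(history: DetectionHistory) -> dict:
    """Sex contrast in latrines used per individual (Poisson regression).

    Response: number of distinct latrines at which each known-sex individual
    was detected; covariate: male indicator.  The incident rate ratio
    exp(beta_male) equals the ratio of sex means for this binary design.
    Returns the IRR with a Wald CI on the log scale and the Wald p-value.
    """
    latrines = (history.counts.sum(axis=2) > 0).sum(axis=1)
    sex = np.asarray(history.sexes)
    known = sex != "unknown"
    y = latrines[known]
    male = (sex[known] == "male").astype(float)
    if male.all() or not male.any():
        raise ValueError("both sexes required")
    if y[male == 1].sum() == 0 or y[male == 0].sum() == 0:
        raise ValueError("a sex with all-zero counts: IRR degenerate (0 or inf)")
    X = sm.add_constant(male)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    beta, se = res.params[1], res.bse[1]
    return {
        "irr": float(np.exp(beta)),
        "lcl": float(np.exp(beta - 1.959964 * se)),
        "ucl": float(np.exp(beta + 1.959964 * se)),
        "p": float(res.pvalues[1]),
        "mean_male": float(y[male == 1].mean()),
        "mean_female": float(y[male == 0].mean()),
    }
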