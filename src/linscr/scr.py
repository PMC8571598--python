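"""Maximum-likelihood spatial capture-recapture on a 1-D network state space.

The model: animal activity centers follow an (in)homogeneous Poisson point
process with intensity D(s) (animals/km) along the discretized network.
A latrine k visited on occasion o registers Poisson-distributed counts of
individual i with rate

    mu = effort[k, o] * lambda0 * exp(-d(s_i, k)^2 / (2 sigma^2)),

where d is the along-network distance between the activity center and the
detector (hazard half-normal detection), lambda0 the baseline detection
rate and sigma the spatial scale.  lambda0 may differ by sex (a two-class
finite mixture with proportion psi of males; known sexes enter as
degenerate class memberships) and by a persistent detector-specific
behavioral response bk (the rate changes at detector k from the occasion
after the individual's first detection there).  sigma may differ by sex.

The full (unconditional) likelihood marginalizes each detected
individual's activity center over the state space and includes the
expected number of detected individuals

    Lambda = sum_s D(s) cell(s) E_class[ 1 - exp(-sum_{k,o} mu_naive) ],

so abundance and density are estimated directly.  All positive parameters
are estimated on the log scale, the mixture proportion on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .history import DetectionHistory
from .network import DetectorArray, StateSpace, position_distance_matrix

__all__ = [
    "SCRModelSpec",
    "SCRFit",
    "DerivedEstimate",
    "hazard",
    "expected_count",
    "neg_log_likelihood",
    "fit",
    "derive_density_abundance",
]

DENSITY_MODELS = ("1", "lat", "dist")
LAMBDA0_MODELS = ("1", "sex", "bk", "bk+sex", "bk*sex")
SIGMA_MODELS = ("1", "sex")
_COVARIATE_FOR = {"lat": "latitude", "dist": "dist_release"}


@dataclass(frozen=True)
class SCRModelSpec:
    """Model formula: density ~ {1, lat, dist}, lambda0 ~ {1, sex, bk, bk+sex,
    bk*sex}, sigma ~ {1, sex}."""

    density: str = "1"
    lambda0: str = "1"
    sigma: str = "1"

    def __post_init__(self) -> None:
        if self.density not in DENSITY_MODELS:
            raise ValueError(f"density model must be one of {DENSITY_MODELS}")
        if self.lambda0 not in LAMBDA0_MODELS:
            raise ValueError(f"lambda0 model must be one of {LAMBDA0_MODELS}")
        if self.sigma not in SIGMA_MODELS:
            raise ValueError(f"sigma model must be one of {SIGMA_MODELS}")

    @property
    def uses_sex(self) -> bool:
        return "sex" in self.lambda0 or self.sigma == "sex"

    @property
    def uses_bk(self) -> bool:
        return "bk" in self.lambda0

    def label(self) -> str:
        lam = self.lambda0.replace("*", "x")
        return f"D~{self.density} lam0~{lam} sigma~{self.sigma}"


def hazard(d, lam0, sigma):
    """Hazard half-normal expected count rate at network distance d (m)."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    if np.any(np.asarray(lam0) < 0):
        raise ValueError("lambda0 must be nonnegative")
    d = np.asarray(d, float)
    return lam0 * np.exp(-(d**2) / (2.0 * np.asarray(sigma, float) ** 2))


def expected_count(d, effort, lam0, sigma, bk_multiplier=1.0):
    """Expected Poisson count for one detector-occasion.

    ``bk_multiplier`` is exp(beta_bk) when the individual was detected at
    this detector on an earlier occasion, 1 otherwise.
    """
    return effort * bk_multiplier * hazard(d, lam0, sigma)


class _ParamLayout:
    """Maps the flat link-scale parameter vector to model pieces."""

    def __init__(self, spec: SCRModelSpec, mixture: bool):
        if spec.uses_sex and not mixture:
            raise ValueError("sex terms require the sex mixture")
        self.spec = spec
        self.mixture = mixture
        names = ["D.(Intercept)"]
        if spec.density != "1":
            names.append(f"D.{spec.density}")
        names.append("lam0.(Intercept)")
        if "sex" in spec.lambda0:
            names.append("lam0.sex")
        if "bk" in spec.lambda0:
            names.append("lam0.bk")
        if spec.lambda0 == "bk*sex":
            names.append("lam0.bk:sex")
        names.append("sigma.(Intercept)")
        if spec.sigma == "sex":
            names.append("sigma.sex")
        if mixture:
            names.append("psi.logit")
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}

    @property
    def k(self) -> int:
        return len(self.names)

    def get(self, params, name, default=0.0):
        i = self.index.get(name)
        return params[i] if i is not None else default

    def log_density(self, params, space: StateSpace) -> np.ndarray:
        """log D(s) in animals/km over state-space points."""
        out = np.full(space.n_points, params[self.index["D.(Intercept)"]])
        if self.spec.density != "1":
            z = space.covariate_z(_COVARIATE_FOR[self.spec.density])
            out = out + params[self.index[f"D.{self.spec.density}"]] * z
        return out

    def class_params(self, params):
        """Per mixture class: (log lam0 naive, beta_bk, log sigma, weight)."""
        base = params[self.index["lam0.(Intercept)"]]
        b_sex = self.get(params, "lam0.sex")
        b_bk = self.get(params, "lam0.bk")
        b_int = self.get(params, "lam0.bk:sex")
        ls = params[self.index["sigma.(Intercept)"]]
        ls_sex = self.get(params, "sigma.sex")
        if not self.mixture:
            return [(base, b_bk, ls, 1.0)]
        psi = expit(params[self.index["psi.logit"]])
        female = (base, b_bk, ls, 1.0 - psi)
        male = (base + b_sex, b_bk + b_int, ls + ls_sex, psi)
        return [female, male]


class _Likelihood:
    """Precomputed data context; immutable during one optimization."""

    def __init__(
        self,
        history: DetectionHistory,
        space: StateSpace,
        detectors: DetectorArray,
        spec: SCRModelSpec,
        mixture: bool | None = None,
    ):
        if space.n_points == 0:
            raise ValueError("empty state space")
        if mixture is None:
            mixture = spec.uses_sex or any(s != "unknown" for s in history.sexes)
        self.layout = _ParamLayout(spec, mixture)
        self.spec = spec
        self.history = history
        self.space = space
        self.detectors = detectors

        counts = history.counts                      # (n, K, O)
        eff = detectors.effort                       # (K, O)
        if np.any((counts.sum(axis=0) > 0) & (eff == 0)):
            raise ValueError("detections recorded at zero-effort detector-occasions")
        self.dist = position_distance_matrix(space.net, space.positions,
                                             detectors.positions)  # (S, K) m
        self.cell_km = space.cell_lengths / 1000.0
        self.log_cell = np.log(self.cell_km)
        # bk state: detected at detector k on any earlier occasion
        prior = np.cumsum(counts, axis=2)
        b = np.zeros_like(counts)
        b[:, :, 1:] = prior[:, :, :-1] > 0
        self.N = counts.sum(axis=2).astype(float)    # (n, K)
        self.Ntot = self.N.sum(axis=1)               # (n,)
        self.nbk = (counts * b).sum(axis=(1, 2)).astype(float)
        self.E1 = eff.sum(axis=1)                    # (K,)
        self.Eb = (eff[None, :, :] * b).sum(axis=2).astype(float)  # (n, K)
        with np.errstate(divide="ignore"):
            log_eff = np.where(eff > 0, np.log(np.where(eff > 0, eff, 1.0)), 0.0)
        self.const = (counts * log_eff[None, :, :]).sum(axis=(1, 2)) - gammaln(
            counts + 1
        ).sum(axis=(1, 2))
        # class compatibility: column 0 = female, 1 = male
        sex = np.asarray(history.sexes)
        if self.layout.mixture:
            self.compat = np.stack(
                [(sex == "female") | (sex == "unknown"),
                 (sex == "male") | (sex == "unknown")], axis=1)
        else:
            self.compat = np.ones((len(sex), 1), bool)

    def __call__(self, params: np.ndarray) -> float:
        lay = self.layout
        log_D = lay.log_density(params, self.space)      # (S,)
        log_Dcell = log_D + self.log_cell
        Dcell = np.exp(log_Dcell)
        n = self.history.n_individuals

        Lambda = 0.0
        log_contrib = np.full((n, self.compat.shape[1]), -np.inf)
        for c, (log_lam0, b_bk, log_sig, w) in enumerate(lay.class_params(params)):
            lam0 = np.exp(log_lam0)
            sig = np.exp(log_sig)
            logH = -(self.dist**2) / (2.0 * sig**2)      # (S, K)
            H = np.exp(logH)
            pdot = -np.expm1(-lam0 * (H @ self.E1))       # (S,)
            Lambda += w * float(Dcell @ pdot)
            if n:
                B = self.N @ logH.T                       # (n, S)
                W = self.E1[None, :] + np.expm1(b_bk) * self.Eb  # (n, K)
                WH = W @ H.T                              # (n, S)
                ll = (B - lam0 * WH
                      + (self.Ntot * log_lam0 + b_bk * self.nbk + self.const)[:, None])
                with np.errstate(divide="ignore"):
                    log_w = np.log(w) if w > 0 else -np.inf
                lc = logsumexp(log_Dcell[None, :] + ll, axis=1)
                lc = np.where(self.compat[:, c], lc + log_w, -np.inf)
                log_contrib[:, c] = lc
        nll = Lambda
        if n:
            per_ind = logsumexp(log_contrib, axis=1)
            if np.any(~np.isfinite(per_ind)):
                return np.inf
            nll -= float(per_ind.sum())
        return float(nll) if np.isfinite(nll) else np.inf


def neg_log_likelihood(
    history: DetectionHistory,
    space: StateSpace,
    detectors: DetectorArray,
    spec: SCRModelSpec,
    params: np.ndarray,
    mixture: bool | None = None,
) -> float:
    """Negative log-likelihood at a link-scale parameter vector."""
    return _Likelihood(history, space, detectors, spec, mixture)(np.asarray(params, float))


@dataclass
class DerivedEstimate:
    """Real-scale estimate with SE and a Wald CI on the link scale."""

    name: str
    estimate: float
    se: float
    lcl: float
    ucl: float
    averaged_over: int = 1
    partial: bool = False


def _lognormal_ci(est: float, se: float, z: float = 1.959964) -> tuple[float, float]:
    """Asymmetric CI for a positive parameter from its real-scale SE."""
    if est <= 0 or not np.isfinite(se) or se <= 0:
        return (est, est)
    se_log = np.sqrt(np.log1p((se / est) ** 2))
    c = np.exp(z * se_log)
    return (est / c, est * c)


def _logit_ci(p: float, se: float, z: float = 1.959964) -> tuple[float, float]:
    if not 0 < p < 1 or not np.isfinite(se) or se <= 0:
        return (p, p)
    se_logit = se / (p * (1 - p))
    lo = np.log(p / (1 - p))
    return (float(expit(lo - z * se_logit)), float(expit(lo + z * se_logit)))


@dataclass
class SCRFit:
    """A fitted SCR model: link-scale MLEs, covariance and IC bookkeeping."""

    spec: SCRModelSpec
    param_names: list[str]
    params: np.ndarray
    cov: np.ndarray | None
    loglik: float
    n_individuals: int
    converged: bool
    history: DetectionHistory
    space: StateSpace
    detectors: DetectorArray
    mixture: bool
    n_starts_tried: int = 1
    message: str = ""
    _derived: dict = field(default_factory=dict, repr=False)

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def aicc(self) -> float:
        n, k = self.n_individuals, self.k
        if n - k - 1 <= 0:
            raise ValueError("AICc undefined: n - K - 1 <= 0")
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def usable(self) -> bool:
        """Converged with an invertible Hessian; eligible for averaging."""
        return self.converged and self.cov is not None

    def derived(self) -> dict[str, DerivedEstimate]:
        if not self._derived:
            self._derived = derive_density_abundance(self)
        return self._derived


def _numeric_hessian(f, x, step=1e-4):
    k = len(x)
    H = np.empty((k, k))
    h = step * (1.0 + np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _default_start(lik: _Likelihood) -> np.ndarray:
    hist, space, det = lik.history, lik.space, lik.detectors
    lay = lik.layout
    n = max(hist.n_individuals, 1)
    total_km = space.total_length / 1000.0
    x = np.zeros(lay.k)
    x[lay.index["D.(Intercept)"]] = np.log(1.5 * n / total_km)
    # sigma: half the mean distance between detectors used by the same individual
    dd = position_distance_matrix(space.net, det.positions, det.positions)
    pair_d = []
    for i in range(hist.n_individuals):
        used = np.flatnonzero(lik.N[i] > 0)
        for a in range(len(used)):
            for b in range(a + 1, len(used)):
                pair_d.append(dd[used[a], used[b]])
    if pair_d:
        sigma0 = max(float(np.mean(pair_d)) / 2.0, space.spacing)
    else:
        off = dd + np.diag(np.full(len(det.positions), np.inf))
        sigma0 = float(np.min(off, axis=1).mean())
    x[lay.index["sigma.(Intercept)"]] = np.log(sigma0)
    mean_eff = det.effort.sum() / det.n_occasions if det.n_occasions else 1.0
    lam0 = hist.total_detections / max(n * det.effort.sum() * 0.2, 1.0)
    x[lay.index["lam0.(Intercept)"]] = np.log(max(lam0, 1e-3))
    if lay.mixture:
        sexes = np.asarray(hist.sexes)
        known = sexes != "unknown"
        p = (sexes == "male")[known].mean() if known.any() else 0.5
        p = min(max(p, 0.05), 0.95)
        x[lay.index["psi.logit"]] = np.log(p / (1 - p))
    return x


def fit(
    history: DetectionHistory,
    space: StateSpace,
    detectors: DetectorArray,
    spec: SCRModelSpec = SCRModelSpec(),
    start: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    mixture: bool | None = None,
    warn_no_spatial_recaptures: bool = True,
    compute_cov: bool = True,
) -> SCRFit:
    """Fit an SCR model by maximum likelihood (quasi-Newton, multi-start).

    Optimizes the link-scale parameters with L-BFGS-B from ``n_starts``
    jittered starting points (the first unjittered), keeps the best
    converged solution, and computes the covariance from the inverse
    numerical Hessian.  A singular Hessian leaves ``cov`` as None and marks
    the fit unusable for model averaging.
    """
    import warnings as _warnings

    lik = _Likelihood(history, space, detectors, spec, mixture)
    if warn_no_spatial_recaptures and history.n_spatial_recaptures() == 0:
        _warnings.warn("no spatial recaptures: sigma is weakly identified")
    x0 = np.asarray(start, float) if start is not None else _default_start(lik)
    if len(x0) != lik.layout.k:
        raise ValueError(f"start vector needs {lik.layout.k} entries "
                         f"({lik.layout.names})")
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(n_starts, 1)):
        xs = x0 if s == 0 else x0 + rng.normal(0.0, 0.25, size=len(x0))
        res = minimize(lik, xs, method="L-BFGS-B",
                       options={"maxiter": 1000, "ftol": 1e-10, "gtol": 1e-6})
        if best is None or (res.fun < best.fun - 1e-8):
            best = res
    cov = None
    if compute_cov:
        H = _numeric_hessian(lik, best.x)
        try:
            cov = np.linalg.inv(H)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
                cov = None
        except np.linalg.LinAlgError:
            cov = None
    return SCRFit(
        spec=spec,
        param_names=lik.layout.names,
        params=best.x,
        cov=cov,
        loglik=-float(best.fun),
        n_individuals=history.n_individuals,
        converged=bool(best.success and np.isfinite(best.fun)),
        history=history,
        space=space,
        detectors=detectors,
        mixture=lik.layout.mixture,
        n_starts_tried=max(n_starts, 1),
        message=str(best.message),
    )


def _delta_se(fun, params, cov, step=1e-5):
    """SE of a scalar function of the MLEs by the delta method."""
    if cov is None:
        return np.nan
    k = len(params)
    g = np.empty(k)
    h = step * (1.0 + np.abs(params))
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        g[i] = (fun(params + e) - fun(params - e)) / (2 * h[i])
    v = float(g @ cov @ g)
    return np.sqrt(v) if v > 0 else np.nan


def _linear_real(fit_: SCRFit, coefs: dict[str, float]) -> tuple[float, float]:
    """exp(linear combination of link params): estimate and delta-method SE."""
    lay = _ParamLayout(fit_.spec, fit_.mixture)
    c = np.zeros(fit_.k)
    for name, w in coefs.items():
        if name not in lay.index:
            raise KeyError(name)
        c[lay.index[name]] = w
    eta = float(c @ fit_.params)
    est = np.exp(eta)
    if fit_.cov is None:
        return est, np.nan
    se_eta = float(np.sqrt(max(c @ fit_.cov @ c, 0.0)))
    return est, est * se_eta


def derive_density_abundance(fit_: SCRFit) -> dict[str, DerivedEstimate]:
    """Derived real-scale quantities from a converged fit.

    Abundance N = sum_s D(s) cell(s) over the state space; reported density
    is N / total network length (km) — identical to D itself under the
    homogeneous model.  CIs for positive parameters are Wald on the log
    scale (asymmetric); the sex ratio uses the logit scale.
    """
    lay = _ParamLayout(fit_.spec, fit_.mixture)
    space = fit_.space
    cell_km = space.cell_lengths / 1000.0
    total_km = space.total_length / 1000.0

    def abundance(params):
        return float(np.exp(lay.log_density(params, space)) @ cell_km)

    out: dict[str, DerivedEstimate] = {}

    def add_pos(name, est, se):
        lcl, ucl = _lognormal_ci(est, se)
        out[name] = DerivedEstimate(name, est, se, lcl, ucl)

    N = abundance(fit_.params)
    se_N = _delta_se(abundance, fit_.params, fit_.cov)
    add_pos("N", N, se_N)
    add_pos("density_per_km", N / total_km, se_N / total_km if np.isfinite(se_N) else np.nan)

    classes = (["female", "male"] if fit_.mixture else ["all"])
    for ci, cls in enumerate(classes):
        sex_on = 1.0 if cls == "male" else 0.0
        lam_coefs = {"lam0.(Intercept)": 1.0}
        if "lam0.sex" in lay.index:
            lam_coefs["lam0.sex"] = sex_on
        est, se = _linear_real(fit_, lam_coefs)
        add_pos(f"lam0_{cls}_naive", est, se)
        if fit_.spec.uses_bk:
            bk_coefs = dict(lam_coefs)
            bk_coefs["lam0.bk"] = 1.0
            if "lam0.bk:sex" in lay.index:
                bk_coefs["lam0.bk:sex"] = sex_on
            est, se = _linear_real(fit_, bk_coefs)
            add_pos(f"lam0_{cls}_prior", est, se)
        sig_coefs = {"sigma.(Intercept)": 1.0}
        if "sigma.sex" in lay.index:
            sig_coefs["sigma.sex"] = sex_on
        est, se = _linear_real(fit_, sig_coefs)
        if cls == "female" or fit_.spec.sigma == "sex" or cls == "all":
            add_pos(f"sigma_{cls}" if fit_.spec.sigma == "sex" else "sigma", est, se)

    if fit_.mixture:
        def prop_male(params):
            return float(expit(params[lay.index["psi.logit"]]))
        p = prop_male(fit_.params)
        se_p = _delta_se(prop_male, fit_.params, fit_.cov)
        lcl, ucl = _logit_ci(p, se_p)
        out["prop_male"] = DerivedEstimate("prop_male", p, se_p, lcl, ucl)
        lclf, uclf = _logit_ci(1 - p, se_p)
        out["prop_female"] = DerivedEstimate("prop_female", 1 - p, se_p, lclf, uclf)
    return out
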