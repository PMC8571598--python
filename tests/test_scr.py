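"""SCR likelihood against a brute-force marginalization oracle, fitting,
and derived quantities."""

import itertools

import numpy as np
import pytest

from linscr.history import DetectionHistory
from linscr.network import discretize
from linscr.scr import (SCRModelSpec, expected_count, fit, hazard,
                        neg_log_likelihood)
from linscr.simulate import (SimulationConfig, generate_network,
                             place_detectors, simulate_detections,
                             simulate_population)

from conftest import (brute_force_nll, make_detectors, make_history,
                      make_space, make_straight_net)


class TestHazard:
    def test_at_zero(self):
        assert hazard(0.0, 0.4, 1000.0) == pytest.approx(0.4)

    def test_half_distance(self):
        d = 1000.0 * np.sqrt(2 * np.log(2))
        assert hazard(d, 0.4, 1000.0) == pytest.approx(0.2)

    def test_three_sigma(self):
        assert hazard(3000.0, 0.4, 1000.0) == pytest.approx(0.4 * np.exp(-4.5))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            hazard(1.0, 0.4, 0.0)


class TestExpectedCount:
    def test_zero_effort(self):
        assert expected_count(500.0, 0.0, 0.3, 1000.0) == 0.0

    def test_no_bk_effect_identical_states(self):
        naive = expected_count(500.0, 2.0, 0.3, 1000.0, bk_multiplier=1.0)
        prior = expected_count(500.0, 2.0, 0.3, 1000.0, bk_multiplier=np.exp(0.0))
        assert naive == prior

    def test_hand_arithmetic(self):
        # effort 3 days, lam0 0.2, d = sigma -> multiplier e^-0.5, bk e^0.4
        val = expected_count(1000.0, 3.0, 0.2, 1000.0, bk_multiplier=np.exp(0.4))
        assert val == pytest.approx(3.0 * 0.2 * np.exp(-0.5) * np.exp(0.4))


def _tiny_instance(kind):
    """Hand-built single-edge instances small enough for the loop oracle."""
    net = make_straight_net(10_000.0)
    if kind == "minimal":
        space = make_space(net, [5000.0], [800.0])
        det = make_detectors(net, [4000.0], [[2.0]])
        hist = make_history(np.array([[[3]]]), ["unknown"])
        spec = SCRModelSpec()
        mixture = False
    elif kind == "mixture":
        space = make_space(net, [2000.0, 5000.0, 8000.0], [400.0, 500.0, 600.0])
        det = make_detectors(net, [3000.0, 7000.0], [[1.0, 2.0], [1.0, 0.0]])
        hist = make_history(
            np.array([[[1, 0], [2, 0]], [[0, 1], [0, 0]]]),
            ["female", "unknown"])
        spec = SCRModelSpec(lambda0="sex")
        mixture = True
    elif kind == "full":
        space = make_space(net, [1000.0, 3500.0, 6000.0, 9000.0],
                           [500.0, 450.0, 550.0, 500.0])
        det = make_detectors(net, [2000.0, 5000.0, 8000.0],
                             [[1.0, 1.0, 2.0], [2.0, 1.0, 1.0], [1.0, 0.0, 1.0]])
        hist = make_history(
            np.array([
                [[2, 1, 0], [0, 0, 1], [0, 0, 0]],
                [[0, 0, 0], [1, 0, 2], [0, 0, 1]],
                [[0, 1, 0], [0, 0, 0], [1, 0, 1]],
            ]),
            ["male", "female", "unknown"])
        spec = SCRModelSpec(density="lat", lambda0="bk*sex", sigma="sex")
        mixture = True
    elif kind == "empty":
        space = make_space(net, [2000.0, 8000.0], [700.0, 700.0])
        det = make_detectors(net, [5000.0], [[1.0, 1.0]])
        hist = make_history(np.zeros((0, 1, 2)), [])
        spec = SCRModelSpec()
        mixture = False
    return net, space, det, hist, spec, mixture


@pytest.mark.parametrize("kind", ["minimal", "mixture", "full", "empty"])
def test_likelihood_equals_brute_force_oracle(kind):
    _, space, det, hist, spec, mixture = _tiny_instance(kind)
    rng = np.random.default_rng(hash(kind) % 2**31)
    k = len([1]) if False else None
    # plausible center values per parameter block, then random jitter
    base = {"D": np.log(0.6), "lam0": np.log(0.3), "sigma": np.log(2500.0)}
    from linscr.scr import _ParamLayout
    lay = _ParamLayout(spec, mixture)
    for _ in range(5):
        params = np.empty(lay.k)
        for i, name in enumerate(lay.names):
            if name.startswith("D."):
                c = base["D"] if "Intercept" in name else 0.0
            elif name.startswith("lam0."):
                c = base["lam0"] if "Intercept" in name else 0.0
            elif name.startswith("sigma."):
                c = base["sigma"] if "Intercept" in name else 0.0
            else:
                c = 0.0
            params[i] = c + rng.normal(0, 0.4)
        ours = neg_log_likelihood(hist, space, det, spec, params, mixture)
        oracle = brute_force_nll(hist, space, det, spec, params, mixture)
        assert ours == pytest.approx(oracle, abs=1e-8)


def test_zero_individuals_is_expected_detected_count():
    _, space, det, hist, spec, _ = _tiny_instance("empty")
    D, lam0, sigma = 0.6, 0.3, 2500.0
    params = np.log([D, lam0, sigma])
    # closed form: Lambda = sum_s D*cell * (1 - exp(-lam0 * sum_ko eff * H))
    lam = 0.0
    for pos, cell in zip(space.positions, space.cell_lengths):
        h = sum(det.effort[0]) * lam0 * np.exp(
            -(pos.offset - det.positions[0].offset) ** 2 / (2 * sigma**2))
        lam += D * (cell / 1000.0) * (1 - np.exp(-h))
    assert neg_log_likelihood(hist, space, det, spec, params, False) == \
        pytest.approx(lam, rel=1e-12)


def test_single_point_closed_form():
    """One state point, one detector, one occasion: hand Poisson algebra."""
    net = make_straight_net(10_000.0)
    space = make_space(net, [5000.0], [1000.0])
    det = make_detectors(net, [4000.0], [[2.0]])
    hist = make_history(np.array([[[3]]]), ["unknown"])
    D, lam0, sigma = 0.8, 0.25, 2000.0
    mu = 2.0 * lam0 * np.exp(-(1000.0**2) / (2 * sigma**2))
    Lambda = D * 1.0 * (1 - np.exp(-mu))
    pois = mu**3 * np.exp(-mu) / 6.0
    expected = Lambda - np.log(D * 1.0 * pois)
    got = neg_log_likelihood(hist, space, det, SCRModelSpec(),
                             np.log([D, lam0, sigma]), False)
    assert got == pytest.approx(expected, rel=1e-12)


def test_covariate_coefficient_frozen_at_zero_matches_homogeneous():
    _, space, det, hist, _, _ = _tiny_instance("minimal")
    p_hom = np.log([0.5, 0.3, 2000.0])
    p_cov = np.array([np.log(0.5), 0.0, np.log(0.3), np.log(2000.0)])
    a = neg_log_likelihood(hist, space, det, SCRModelSpec(), p_hom, False)
    b = neg_log_likelihood(hist, space, det, SCRModelSpec(density="lat"),
                           p_cov, False)
    assert a == pytest.approx(b, rel=1e-12)


def _small_sim(seed=11, **kw):
    cfg = SimulationConfig(n_branches=3, total_length_km=60, n_detectors=12,
                           **kw)
    net = generate_network(cfg, seed)
    det = place_detectors(net, cfg, seed + 1)
    centers, sexes = simulate_population(net, cfg.density_per_km, seed + 2,
                                         prop_male=None)
    hist = simulate_detections(net, centers, det, 0.3, 5000.0, seed + 3
                               ).drop_empty()
    space = discretize(net, 500.0)
    return net, space, det, hist


class TestFit:
    def test_mle_matches_dense_grid_search(self):
        """Tiny instance: optimizer beats every point of a parameter grid."""
        net = make_straight_net(10_000.0)
        space = make_space(net, [2500.0, 5000.0, 7500.0], [500.0] * 3)
        det = make_detectors(net, [4000.0, 6000.0], np.ones((2, 3)))
        hist = make_history(
            np.array([[[1, 0, 1], [0, 1, 0]], [[0, 2, 0], [1, 0, 0]]]),
            ["unknown", "unknown"])
        f = fit(hist, space, det, SCRModelSpec(), n_starts=2, seed=1,
                warn_no_spatial_recaptures=False)
        assert f.converged
        grid_best = np.inf
        for ld in np.log(np.linspace(0.5, 30, 12)):
            for ll in np.log(np.linspace(0.02, 1.5, 12)):
                for ls in np.log(np.linspace(300, 8000, 12)):
                    v = neg_log_likelihood(hist, space, det, SCRModelSpec(),
                                           [ld, ll, ls], False)
                    grid_best = min(grid_best, v)
        assert -f.loglik <= grid_best + 1e-6

    def test_parameter_recovery_single_sim(self):
        net, space, det, hist = _small_sim()
        f = fit(hist, space, det, SCRModelSpec(), seed=0)
        d = f.derived()
        for name, truth in [("density_per_km", 0.5),
                            ("lam0_all_naive", 0.3), ("sigma", 5000.0)]:
            est, se = d[name].estimate, d[name].se
            assert abs(est - truth) < 3 * se, f"{name}: {est} vs {truth}"

    def test_nested_models_never_lose_loglik(self):
        net, space, det, hist = _small_sim()
        f0 = fit(hist, space, det, SCRModelSpec(), seed=0, mixture=True)
        f1 = fit(hist, space, det, SCRModelSpec(lambda0="bk"), seed=0,
                 mixture=True)
        f2 = fit(hist, space, det, SCRModelSpec(density="lat"), seed=0,
                 mixture=True)
        assert f1.loglik >= f0.loglik - 1e-4
        assert f2.loglik >= f0.loglik - 1e-4

    def test_homogeneous_abundance_is_density_times_length(self):
        net, space, det, hist = _small_sim()
        f = fit(hist, space, det, SCRModelSpec(), seed=0)
        d = f.derived()
        total_km = space.total_length / 1000.0
        assert d["N"].estimate == pytest.approx(
            d["density_per_km"].estimate * total_km, rel=1e-12)

    def test_ci_bounds_positive_and_ordered(self):
        net, space, det, hist = _small_sim()
        f = fit(hist, space, det, SCRModelSpec(), seed=0)
        for e in f.derived().values():
            assert e.lcl > 0 or e.estimate == e.lcl
            assert e.lcl <= e.estimate <= e.ucl

    def test_sex_terms_require_mixture(self):
        net, space, det, hist = _small_sim()
        with pytest.raises(ValueError):
            fit(hist, space, det, SCRModelSpec(lambda0="sex"), mixture=False)

    def test_detection_at_zero_effort_rejected(self):
        net = make_straight_net(10_000.0)
        space = make_space(net, [5000.0], [800.0])
        det = make_detectors(net, [4000.0], [[0.0]])
        hist = make_history(np.array([[[3]]]), ["unknown"])
        with pytest.raises(ValueError):
            neg_log_likelihood(hist, space, det, SCRModelSpec(),
                               np.log([0.5, 0.3, 2000.0]), False)
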