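"""Shared fixtures: tiny hand-built networks, detector arrays and the
independent brute-force SCR likelihood oracle used to verify the
vectorized implementation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import poisson

from linscr.history import DetectionHistory
from linscr.network import (DetectorArray, LinearNetwork, NetworkPosition,
                            StateSpace, build_network)


def make_straight_net(length_m: float = 10_000.0, vertical: bool = True):
    """One straight edge; vertical so the latitude covariate varies."""
    end = (0.0, length_m) if vertical else (length_m, 0.0)
    return build_network([[(0.0, 0.0), end]])


def make_space(net: LinearNetwork, offsets, cells) -> StateSpace:
    positions = [NetworkPosition(0, float(o)) for o in offsets]
    xy = np.array([net.to_xy(p) for p in positions])
    return StateSpace(net=net, positions=positions, xy=xy,
                      cell_lengths=np.asarray(cells, float), spacing=500.0,
                      covariates={"latitude": xy[:, 1].copy()})


def make_detectors(net: LinearNetwork, offsets, effort) -> DetectorArray:
    return DetectorArray(
        ids=[f"d{i}" for i in range(len(offsets))],
        positions=[NetworkPosition(0, float(o)) for o in offsets],
        effort=np.asarray(effort, float),
    )


def brute_force_nll(history, space, detectors, spec, params, mixture):
    """Independent SCR likelihood: explicit loops, scipy Poisson pmf.

    Works on single-edge instances so distances are plain offset
    differences; reconstructs the link-scale parameterization from the
    documented parameter-name order.
    """
    names = []
    names.append("D0")
    if spec.density != "1":
        names.append("Dbeta")
    names.append("lam0")
    if "sex" in spec.lambda0:
        names.append("lam_sex")
    if "bk" in spec.lambda0:
        names.append("lam_bk")
    if spec.lambda0 == "bk*sex":
        names.append("lam_bk_sex")
    names.append("sig")
    if spec.sigma == "sex":
        names.append("sig_sex")
    if mixture:
        names.append("psi")
    assert len(names) == len(params)
    p = dict(zip(names, params))

    S = space.n_points
    K = detectors.n_detectors
    O = detectors.n_occasions
    n_ind = history.n_individuals
    cell_km = [c / 1000.0 for c in space.cell_lengths]
    s_off = [pos.offset for pos in space.positions]
    k_off = [pos.offset for pos in detectors.positions]
    eff = detectors.effort

    # density per km at each point
    if spec.density == "1":
        logD = [p["D0"]] * S
    else:
        cov = {"lat": [xy[1] for xy in space.xy],
               "dist": list(space.covariates.get("dist_release", []))}[spec.density]
        mu, sd = np.mean(cov), np.std(cov)
        z = [(c - mu) / sd if sd > 0 else 0.0 for c in cov]
        logD = [p["D0"] + p["Dbeta"] * zi for zi in z]

    if mixture:
        psi = 1.0 / (1.0 + np.exp(-p["psi"]))
        class_w = {"female": 1.0 - psi, "male": psi}
    else:
        class_w = {"all": 1.0}

    def lam0_of(cls, bk_state):
        eta = p["lam0"]
        if cls == "male":
            eta += p.get("lam_sex", 0.0)
        if bk_state:
            eta += p.get("lam_bk", 0.0)
            if cls == "male":
                eta += p.get("lam_bk_sex", 0.0)
        return np.exp(eta)

    def sigma_of(cls):
        eta = p["sig"]
        if cls == "male":
            eta += p.get("sig_sex", 0.0)
        return np.exp(eta)

    # bk states from realized detections
    bk = np.zeros((n_ind, K, O), bool)
    for i in range(n_ind):
        for k in range(K):
            for o in range(1, O):
                bk[i, k, o] = history.counts[i, k, :o].sum() > 0

    Lambda = 0.0
    for s in range(S):
        for cls, w in class_w.items():
            h = 0.0
            for k in range(K):
                d = abs(s_off[s] - k_off[k])
                rate = lam0_of(cls, False) * np.exp(-d**2 / (2 * sigma_of(cls) ** 2))
                for o in range(O):
                    h += eff[k, o] * rate
            Lambda += np.exp(logD[s]) * cell_km[s] * w * (1.0 - np.exp(-h))

    total = Lambda
    for i in range(n_ind):
        contrib = 0.0
        for cls, w in class_w.items():
            sex = history.sexes[i]
            if mixture and sex != "unknown" and sex != cls:
                continue
            for s in range(S):
                prod = 1.0
                for k in range(K):
                    d = abs(s_off[s] - k_off[k])
                    for o in range(O):
                        rate = (eff[k, o] * lam0_of(cls, bk[i, k, o])
                                * np.exp(-d**2 / (2 * sigma_of(cls) ** 2)))
                        prod *= poisson.pmf(history.counts[i, k, o], rate)
                contrib += w * np.exp(logD[s]) * cell_km[s] * prod
        total -= np.log(contrib)
    return total


@pytest.fixture
def oracle_nll():
    return brute_force_nll


@pytest.fixture
def straight_net():
    return make_straight_net()


def make_history(counts, sexes) -> DetectionHistory:
    return DetectionHistory(counts=np.asarray(counts, int), sexes=list(sexes))
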