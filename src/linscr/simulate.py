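"""Seeded generators for every input the pipeline consumes.

The default scenario emulates the field study's structure at roughly a
third of its spatial scale, keeping single model fits fast: a ~100-km
sinuous dendritic network, 20 latrines surveyed over 8 occasions, hazard
half-normal detection with lambda0 = 0.3 and sigma = 5 km, density
0.5 animals/km, and replicate-PCR genotyping with 29% allelic dropout,
5% false alleles and partial sample failure.  Every generator is a pure
function of (config, seed): identical outputs on rerun.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import ReplicateCalls, call_consensus, match_genotypes, \
    build_detection_history, randomized_subsample
from .history import DetectionHistory
from .network import (DetectorArray, LinearNetwork, NetworkPosition,
                      build_network, position_distance_matrix)
from .popgen import PopulationGenotypes

__all__ = [
    "SimulationConfig",
    "generate_network",
    "place_detectors",
    "simulate_population",
    "simulate_population_on_space",
    "simulate_detections",
    "draw_allele_frequencies",
    "draw_true_genotypes",
    "simulate_genotyping",
    "simulate_two_populations",
    "simulate_survey",
    "genotypes_to_history",
    "SurveyData",
]


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic survey."""

    # network geometry
    n_branches: int = 5
    total_length_km: float = 100.0
    sinuosity: float = 0.5        # heading wiggle amplitude, radians
    wiggle_period_m: float = 5000.0
    step_m: float = 50.0
    # density model (animals/km); beta on the z-scored latitude covariate
    density_per_km: float = 0.5
    density_beta: float = 0.0
    prop_male: float | None = 0.5  # None -> sexless population
    # detection
    lambda0_female: float = 0.3
    lambda0_male: float = 0.3
    sigma_m: float = 5000.0
    sigma_male_m: float | None = None
    bk_beta: float = 0.0          # log rate multiplier after first detection
    # survey
    n_detectors: int = 20
    n_occasions: int = 8
    prob_effort_active: float = 1.0
    # genotyping
    n_loci: int = 10
    n_alleles: int = 6
    replicates_min: int = 4
    replicates_max: int = 6
    dropout: float = 0.29
    false_allele: float = 0.05
    sample_success: float = 0.3
    samples_per_scat: int = 2
    y_attempts_min: int = 3
    y_attempts_max: int = 6
    # two-population draws
    target_fst: float = 0.10
    popgen_n_loci: int = 30
    popgen_n_per_pop: int = 50

    def __post_init__(self) -> None:
        for r in (self.dropout, self.false_allele, self.sample_success):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.density_per_km < 0 or self.sigma_m <= 0:
            raise ValueError("need density >= 0 and sigma > 0")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target FST must be in [0, 1)")


def _sinuous_polyline(start, heading, length, cfg: SimulationConfig, rng):
    """Unit-speed walk with sinusoidal heading wiggle; arc length == length."""
    n = max(2, int(round(length / cfg.step_m)))
    ds = length / n
    phase = rng.uniform(0, 2 * np.pi)
    s = np.arange(n) * ds
    theta = heading + cfg.sinuosity * np.sin(2 * np.pi * s / cfg.wiggle_period_m + phase)
    steps = ds * np.column_stack([np.cos(theta), np.sin(theta)])
    pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
    return pts


def generate_network(cfg: SimulationConfig, seed: int) -> LinearNetwork:
    """Connected tree of sinuous branches with the requested total length.

    The first branch is the main stem (trending north); each further branch
    attaches at a random interior point of an existing branch, which is
    split there so every junction is a graph vertex.
    """
    if cfg.n_branches < 1:
        raise ValueError("need >= 1 branch")
    rng = np.random.default_rng(seed)
    total_m = cfg.total_length_km * 1000.0
    if cfg.n_branches == 1:
        lengths = np.array([total_m])
    else:
        w = np.sort(rng.dirichlet(np.full(cfg.n_branches, 2.0)))[::-1]
        lengths = total_m * w
    if np.any(lengths < 2 * cfg.step_m):
        raise ValueError("a branch came out shorter than two steps; "
                         "reduce n_branches or step_m")
    polylines = [_sinuous_polyline(np.zeros(2), np.pi / 2, lengths[0], cfg, rng)]
    for L in lengths[1:]:
        parent = int(rng.integers(len(polylines)))
        coords = polylines[parent]
        if len(coords) > 3:
            j = int(rng.integers(1, len(coords) - 1))
            polylines[parent] = coords[: j + 1]
            polylines.append(coords[j:])
            attach = coords[j]
        else:
            attach = coords[-1]
        heading = rng.uniform(0, 2 * np.pi)
        polylines.append(_sinuous_polyline(attach, heading, L, cfg, rng))
    return build_network(polylines, snap_tolerance=0.5)


def place_detectors(
    net: LinearNetwork, cfg: SimulationConfig, seed: int
) -> DetectorArray:
    """Detectors evenly spaced along the network, with per-occasion effort."""
    rng = np.random.default_rng(seed)
    cum = np.concatenate([[0.0], np.cumsum(net.lengths)])
    marks = (np.arange(cfg.n_detectors) + 0.5) * net.total_length / cfg.n_detectors
    positions = []
    for m in marks:
        e = int(np.searchsorted(cum, m, side="right") - 1)
        e = min(e, net.n_edges - 1)
        positions.append(NetworkPosition(e, float(m - cum[e])))
    effort = np.ones((cfg.n_detectors, cfg.n_occasions))
    if cfg.prob_effort_active < 1.0:
        mask = rng.random(effort.shape) < cfg.prob_effort_active
        mask[:, 0] |= ~mask.any(axis=1)  # every detector active at least once
        effort *= mask
    return DetectorArray(
        ids=[f"L{i:02d}" for i in range(cfg.n_detectors)],
        positions=positions, effort=effort,
    )


def _draw_sexes(n: int, prop_male, rng) -> list[str]:
    if prop_male is None:
        return ["unknown"] * n
    return ["male" if u < prop_male else "female" for u in rng.random(n)]


def simulate_population(
    net: LinearNetwork,
    density_per_km: float,
    seed_or_rng,
    prop_male: float | None = 0.5,
):
    """Homogeneous Poisson activity centers along the network.

    Count ~ Poisson(D * L); positions by length-weighted inversion over
    edges.  Returns (positions, sexes).
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    n = rng.poisson(density_per_km * net.total_length / 1000.0)
    edges = rng.choice(net.n_edges, size=n, p=net.lengths / net.total_length)
    offs = rng.uniform(0, net.lengths[edges]) if n else np.empty(0)
    positions = [NetworkPosition(int(e), float(o)) for e, o in zip(edges, offs)]
    return positions, _draw_sexes(n, prop_male, rng)


def simulate_population_on_space(
    space, log_density_per_km: np.ndarray, seed_or_rng, prop_male: float | None = 0.5
):
    """Inhomogeneous Poisson centers: per-cell Poisson(D(s) * cell(s)) draws,
    centers placed at cell midpoints."""
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    lam = np.exp(np.asarray(log_density_per_km)) * space.cell_lengths / 1000.0
    counts = rng.poisson(lam)
    positions = [space.positions[s] for s in np.repeat(np.arange(space.n_points), counts)]
    return positions, _draw_sexes(len(positions), prop_male, rng)


def _per_class(value, sexes, default):
    if isinstance(value, dict):
        return np.array([value.get(s, value.get("unknown", default)) for s in sexes])
    return np.full(len(sexes), float(value))


def simulate_detections(
    net: LinearNetwork,
    centers: list[NetworkPosition],
    detectors: DetectorArray,
    lam0,
    sigma,
    seed_or_rng,
    sexes: list[str] | None = None,
    bk_beta=0.0,
) -> DetectionHistory:
    """Poisson counts under hazard half-normal detection with a bk response.

    Occasions are simulated sequentially so the detector-specific behavioral
    state updates from realized detections.  ``lam0``, ``sigma`` and
    ``bk_beta`` may be scalars or per-sex dicts.  The returned history keeps
    all-zero individuals; call ``.drop_empty()`` for the observed history.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    n = len(centers)
    sexes = sexes if sexes is not None else ["unknown"] * n
    K, O = detectors.n_detectors, detectors.n_occasions
    counts = np.zeros((n, K, O), int)
    if n:
        d = position_distance_matrix(net, centers, detectors.positions)
        lam0_i = _per_class(lam0, sexes, 0.3)
        sig_i = _per_class(sigma, sexes, 5000.0)
        bkb_i = _per_class(bk_beta, sexes, 0.0)
        H = np.exp(-(d**2) / (2.0 * sig_i[:, None] ** 2))
        b = np.zeros((n, K))
        for o in range(O):
            mu = detectors.effort[None, :, o] * lam0_i[:, None] * np.exp(
                bkb_i[:, None] * b) * H
            counts[:, :, o] = rng.poisson(mu)
            b = np.maximum(b, counts[:, :, o] > 0)
    return DetectionHistory(counts=counts, sexes=list(sexes))


def draw_allele_frequencies(cfg: SimulationConfig, seed_or_rng) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    return {
        f"LOC{l:02d}": rng.dirichlet(np.ones(cfg.n_alleles))
        for l in range(cfg.n_loci)
    }


def draw_true_genotypes(n: int, freqs: dict[str, np.ndarray], seed_or_rng):
    """HWE draws: per individual, per locus, an unordered allele pair."""
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    out = []
    for _ in range(n):
        g = {}
        for locus, p in freqs.items():
            a = rng.choice(len(p), size=2, p=p)
            labels = tuple(sorted(f"{100 + 2 * int(x)}" for x in a))
            g[locus] = labels
        out.append(g)
    return out


def _replicate(pair, panel, cfg: SimulationConfig, rng) -> tuple[str, ...]:
    """One PCR replicate: allelic dropout then false-allele substitution."""
    shown = list(pair)
    if pair[0] != pair[1] and rng.random() < cfg.dropout:
        shown = [shown[int(rng.integers(2))]]
    if rng.random() < cfg.false_allele:
        i = int(rng.integers(len(shown)))
        others = [a for a in panel if a != shown[i]]
        shown[i] = others[int(rng.integers(len(others)))]
    return tuple(sorted(set(shown)))


def _sample_calls(true_geno, sex, panels, cfg: SimulationConfig, rng):
    """Replicate calls for one fecal sample (None when the sample fails)."""
    if rng.random() >= cfg.sample_success:
        return None
    n_rep = int(rng.integers(cfg.replicates_min, cfg.replicates_max + 1))
    calls = {
        locus: [_replicate(true_geno[locus], panels[locus], cfg, rng)
                for _ in range(n_rep)]
        for locus in true_geno
    }
    y_att = int(rng.integers(cfg.y_attempts_min, cfg.y_attempts_max + 1))
    y_pos = int(rng.binomial(y_att, 1.0 - cfg.dropout)) if sex == "male" else 0
    return calls, y_pos, y_att


def simulate_genotyping(
    true_history: DetectionHistory,
    true_genotypes,
    detectors: DetectorArray,
    cfg: SimulationConfig,
    seed: int,
):
    """Field samples and replicate-PCR calls for every detection (scat).

    Each detection count unit is a scat yielding ``samples_per_scat``
    duplicate field samples sharing a true genotype but with independent
    failure and PCR errors.  Returns (sample table, {sample_id:
    ReplicateCalls or None for failed samples}, allele panels).
    """
    rng = np.random.default_rng(seed)
    panels = {l: sorted({f"{100 + 2 * a}" for a in range(cfg.n_alleles)})
              for l in true_genotypes[0]} if true_genotypes else {}
    rows, calls = [], {}
    s = 0
    for i in range(true_history.n_individuals):
        for k in range(true_history.n_detectors):
            for o in range(true_history.n_occasions):
                for _ in range(int(true_history.counts[i, k, o])):
                    scat_id = f"S{s:05d}"
                    for dup in range(cfg.samples_per_scat):
                        sid = f"{scat_id}.{dup}"
                        rows.append({"sample_id": sid, "scat_id": scat_id,
                                     "individual": i,
                                     "latrine_id": detectors.ids[k],
                                     "occasion": o})
                        res = _sample_calls(true_genotypes[i],
                                            true_history.sexes[i],
                                            panels, cfg, rng)
                        if res is None:
                            calls[sid] = None
                        else:
                            c, y_pos, y_att = res
                            calls[sid] = ReplicateCalls(
                                sample_id=sid, latrine_id=detectors.ids[k],
                                occasion=o, calls=c,
                                y_positives=y_pos, y_attempts=y_att)
                    s += 1
    samples = pd.DataFrame(rows, columns=["sample_id", "scat_id", "individual",
                                          "latrine_id", "occasion"])
    return samples, calls, panels


def simulate_two_populations(cfg: SimulationConfig, seed: int):
    """Two populations at a target Weir-Cockerham differentiation.

    Per locus, an ancestral frequency vector is drawn and each population's
    frequencies follow a Balding-Nichols-style Dirichlet with concentration
    (1 - F)/F around it; genotypes are HWE draws.
    """
    rng = np.random.default_rng(seed)
    F = cfg.target_fst
    pops = []
    freqs_by_pop: list[dict[str, np.ndarray]] = [{}, {}]
    for l in range(cfg.popgen_n_loci):
        locus = f"LOC{l:02d}"
        anc = rng.dirichlet(np.full(cfg.n_alleles, 2.0))
        for p in range(2):
            if F == 0:
                freqs_by_pop[p][locus] = anc
            else:
                freqs_by_pop[p][locus] = rng.dirichlet(anc * (1 - F) / F)
    for p, label in enumerate("AB"):
        genos = draw_true_genotypes(cfg.popgen_n_per_pop, freqs_by_pop[p], rng)
        pops.append(PopulationGenotypes(label=label, genotypes=genos))
    return pops[0], pops[1]


@dataclass
class SurveyData:
    """Everything one synthetic survey produces."""

    cfg: SimulationConfig
    net: LinearNetwork
    detectors: DetectorArray
    true_positions: list[NetworkPosition]
    true_sexes: list[str]
    true_history: DetectionHistory       # all simulated individuals
    observed_history: DetectionHistory   # all-zero individuals dropped
    n_never_detected: int
    samples: pd.DataFrame = None
    replicate_calls: dict = field(default_factory=dict)
    allele_freqs: dict = field(default_factory=dict)
    true_genotypes: list = field(default_factory=list)


def simulate_survey(
    cfg: SimulationConfig, seed: int, genotyping: bool = True
) -> SurveyData:
    """End-to-end synthetic survey under the study conditions.

    Derives independent child seeds for each stage so the pieces are
    individually reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_net, s_pop, s_det, s_frq, s_gen = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    net = generate_network(cfg, s_net)
    detectors = place_detectors(net, cfg, s_det)
    centers, sexes = simulate_population(net, cfg.density_per_km, s_pop,
                                         cfg.prop_male)
    sigma = cfg.sigma_m if cfg.sigma_male_m is None else {
        "female": cfg.sigma_m, "male": cfg.sigma_male_m, "unknown": cfg.sigma_m}
    lam0 = {"female": cfg.lambda0_female, "male": cfg.lambda0_male,
            "unknown": cfg.lambda0_female}
    true_hist = simulate_detections(net, centers, detectors, lam0, sigma,
                                    s_det + 1, sexes=sexes, bk_beta=cfg.bk_beta)
    observed = true_hist.drop_empty()
    data = SurveyData(
        cfg=cfg, net=net, detectors=detectors,
        true_positions=centers, true_sexes=sexes,
        true_history=true_hist, observed_history=observed,
        n_never_detected=true_hist.n_individuals - observed.n_individuals,
    )
    if genotyping and true_hist.n_individuals:
        freqs = draw_allele_frequencies(cfg, s_frq)
        genos = draw_true_genotypes(true_hist.n_individuals, freqs, s_frq + 1)
        samples, calls, panels = simulate_genotyping(true_hist, genos,
                                                     detectors, cfg, s_gen)
        data.samples = samples
        data.replicate_calls = calls
        data.allele_freqs = freqs
        data.true_genotypes = genos
    return data


def genotypes_to_history(
    data: SurveyData, rule: str = "conservative", subsample_seed: int = 0
):
    """Run the genotype pipeline on a synthetic survey's samples.

    Applies the randomized subsampling protocol (3-4 per latrine-occasion,
    duplicate fallback on failure), consensus calling, and matching under
    the given rule.  Returns (assignment, DetectionHistory).
    """
    selected, fallback = randomized_subsample(data.samples, subsample_seed)
    consensus = []
    for sid in selected:
        rc = data.replicate_calls[sid]
        if rc is None and sid in fallback:
            rc = data.replicate_calls[fallback[sid]]
        if rc is None:
            continue
        consensus.append(call_consensus(rc))
    assignment = match_genotypes(consensus, rule=rule)
    history = build_detection_history(assignment, data.detectors,
                                      data.true_history.n_occasions)
    return assignment, history
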