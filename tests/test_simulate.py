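"""Generators: geometry, point processes, detection moments, genotyping
error rates, and the end-to-end recovery property."""

import numpy as np
import pytest

from linscr.genotypes import error_rates, call_consensus
from linscr.network import NetworkPosition, discretize
from linscr.scr import SCRModelSpec, fit
from linscr.simulate import (SimulationConfig, draw_allele_frequencies,
                             draw_true_genotypes, generate_network,
                             genotypes_to_history, place_detectors,
                             simulate_detections, simulate_genotyping,
                             simulate_population,
                             simulate_population_on_space, simulate_survey,
                             simulate_two_populations)
from linscr.popgen import fst_weir_cockerham

from conftest import make_detectors, make_straight_net


class TestNetworkGeneration:
    def test_straight_single_branch(self):
        cfg = SimulationConfig(n_branches=1, total_length_km=100, sinuosity=0.0)
        net = generate_network(cfg, 0)
        assert net.n_edges == 1
        assert net.total_length == pytest.approx(100_000.0, rel=1e-9)
        xy = np.asarray(net.geometries[0].coords)
        assert np.allclose(xy[:, 0], 0.0, atol=1e-6)  # due north

    def test_tree_connected_and_length_conserved(self):
        cfg = SimulationConfig(n_branches=5, total_length_km=80)
        net = generate_network(cfg, 3)
        assert net.n_components == 1
        assert net.total_length == pytest.approx(80_000.0, rel=0.01)

    def test_deterministic(self):
        cfg = SimulationConfig()
        n1 = generate_network(cfg, 9)
        n2 = generate_network(cfg, 9)
        assert n1.n_edges == n2.n_edges
        assert np.array_equal(n1.vertices, n2.vertices)
        for g1, g2 in zip(n1.geometries, n2.geometries):
            assert np.array_equal(np.asarray(g1.coords), np.asarray(g2.coords))

    def test_invalid(self):
        with pytest.raises(ValueError):
            generate_network(SimulationConfig(n_branches=0), 0)


class TestPopulation:
    def test_zero_density(self):
        net = make_straight_net(50_000.0)
        pos, sexes = simulate_population(net, 0.0, 0)
        assert pos == [] and sexes == []

    def test_poisson_moments(self):
        net = make_straight_net(100_000.0)
        rng = np.random.default_rng(0)
        counts = [len(simulate_population(net, 0.5, rng)[0])
                  for _ in range(1000)]
        band = 3 * np.sqrt(50) / np.sqrt(1000)
        assert abs(np.mean(counts) - 50.0) <= band

    def test_positions_uniform_over_length(self):
        net = make_straight_net(100_000.0)
        pos, _ = simulate_population(net, 20.0, 1)
        offs = np.array([p.offset for p in pos])
        assert abs(np.mean(offs) - 50_000) < 3 * 100_000 / np.sqrt(12 * len(offs))

    def test_loglinear_latitude_shifts_mass_north(self):
        net = make_straight_net(100_000.0)  # vertical: offset == latitude
        space = discretize(net, 1000.0)
        z = space.covariate_z("latitude")
        log_d = np.log(0.5) + 1.0 * z
        rng = np.random.default_rng(2)
        north = south = 0
        for _ in range(50):
            pos, _ = simulate_population_on_space(space, log_d, rng)
            for p in pos:
                if p.offset > 50_000:
                    north += 1
                else:
                    south += 1
        assert north > 1.5 * south


class TestDetections:
    def test_zero_rate_empty(self):
        net = make_straight_net(10_000.0)
        det = make_detectors(net, [5000.0], np.ones((1, 4)))
        h = simulate_detections(net, [NetworkPosition(0, 4000.0)], det,
                                0.0, 1000.0, 0).drop_empty()
        assert h.n_individuals == 0

    def test_tiny_sigma_hits_only_colocated_detector(self):
        net = make_straight_net(10_000.0)
        det = make_detectors(net, [2000.0, 8000.0], np.ones((2, 50)))
        h = simulate_detections(net, [NetworkPosition(0, 2000.0)], det,
                                2.0, 5.0, 1)
        assert h.counts[0, 0].sum() > 0
        assert h.counts[0, 1].sum() == 0

    def test_mean_counts_match_expected_rate(self):
        net = make_straight_net(10_000.0)
        det = make_detectors(net, [3000.0, 7000.0], 2.0 * np.ones((2, 4)))
        center = [NetworkPosition(0, 4000.0)]
        lam0, sigma = 0.3, 2000.0
        rng = np.random.default_rng(3)
        tot = np.zeros(2)
        reps = 1000
        for _ in range(reps):
            h = simulate_detections(net, center, det, lam0, sigma, rng)
            tot += h.counts[0].sum(axis=1)
        expected = 4 * 2.0 * lam0 * np.exp(
            -np.array([1000.0, 3000.0]) ** 2 / (2 * sigma**2))
        mc_se = np.sqrt(expected * reps) / reps
        assert np.all(np.abs(tot / reps - expected) <= 4 * mc_se)

    def test_bk_response_raises_rates_after_first_detection(self):
        net = make_straight_net(10_000.0)
        det = make_detectors(net, [5000.0], np.ones((1, 6)))
        center = [NetworkPosition(0, 5000.0)]
        rng = np.random.default_rng(4)
        base = sum(simulate_detections(net, center, det, 0.3, 2000.0, rng,
                                       bk_beta=0.0).total_detections
                   for _ in range(300))
        rng = np.random.default_rng(4)
        boosted = sum(simulate_detections(net, center, det, 0.3, 2000.0, rng,
                                          bk_beta=1.5).total_detections
                      for _ in range(300))
        assert boosted > base * 1.3


class TestGenotyping:
    def _bundle(self, cfg, seed=0, n=40):
        freqs = draw_allele_frequencies(cfg, seed)
        genos = draw_true_genotypes(n, freqs, seed + 1)
        return freqs, genos

    def test_error_free_replicates_equal_truth(self):
        cfg = SimulationConfig(dropout=0.0, false_allele=0.0, sample_success=1.0)
        data = simulate_survey(cfg, 7)
        for sid, rc in data.replicate_calls.items():
            i = int(data.samples.set_index("sample_id").loc[sid, "individual"])
            truth = data.true_genotypes[i]
            for locus, reps in rc.calls.items():
                want = tuple(sorted(set(truth[locus])))
                for r in reps:
                    assert r == want

    def test_dropout_rate_recovered(self):
        cfg = SimulationConfig(dropout=0.29, false_allele=0.0,
                               sample_success=1.0)
        data = simulate_survey(cfg, 8)
        single = total = 0
        lookup = data.samples.set_index("sample_id")["individual"]
        for sid, rc in data.replicate_calls.items():
            truth = data.true_genotypes[int(lookup.loc[sid])]
            for locus, reps in rc.calls.items():
                if truth[locus][0] == truth[locus][1]:
                    continue
                for r in reps:
                    total += 1
                    single += len(r) == 1
        assert total > 2000
        assert abs(single / total - 0.29) <= 0.02

    def test_measured_error_rates_consistent_with_defaults(self):
        """The first-two-replicate estimates recover the generating dropout
        rate; the false-allele estimate is positive but attenuated, because
        a homozygous locus polluted by a false allele cannot reach consensus
        and so drops out of the measurement."""
        cfg = SimulationConfig(sample_success=1.0)
        data = simulate_survey(cfg, 9)
        calls = [rc for rc in data.replicate_calls.values() if rc is not None]
        consensus = [call_consensus(rc) for rc in calls]
        er = error_rates(calls, consensus)
        assert er.dropout_rate == pytest.approx(0.29, abs=0.04)
        assert 0.01 < er.false_allele_rate < 0.07

    def test_seeded_reproducibility(self):
        cfg = SimulationConfig()
        d1 = simulate_survey(cfg, 11)
        d2 = simulate_survey(cfg, 11)
        assert np.array_equal(d1.true_history.counts, d2.true_history.counts)
        assert d1.samples.equals(d2.samples)
        for sid in d1.replicate_calls:
            a, b = d1.replicate_calls[sid], d2.replicate_calls[sid]
            assert (a is None) == (b is None)
            if a is not None:
                assert a.calls == b.calls and a.y_positives == b.y_positives


class TestTwoPopulations:
    def test_zero_target_near_zero(self):
        cfg = SimulationConfig(target_fst=0.0, popgen_n_loci=25,
                               popgen_n_per_pop=100)
        thetas = [fst_weir_cockerham(*simulate_two_populations(cfg, s),
                                     n_boot=0)[0] for s in range(5)]
        assert abs(np.mean(thetas)) < 0.02

    def test_monotone_in_target(self):
        lo = SimulationConfig(target_fst=0.10, popgen_n_loci=30)
        hi = SimulationConfig(target_fst=0.50, popgen_n_loci=30)
        t_lo = np.mean([fst_weir_cockerham(*simulate_two_populations(lo, s),
                                           n_boot=0)[0] for s in range(8)])
        t_hi = np.mean([fst_weir_cockerham(*simulate_two_populations(hi, s),
                                           n_boot=0)[0] for s in range(8)])
        assert t_hi > t_lo + 0.2


class TestEndToEnd:
    def test_matching_coarsening_and_count_conservation(self):
        cfg = SimulationConfig()
        for seed in (1, 2, 3):
            data = simulate_survey(cfg, seed)
            a_c, h_c = genotypes_to_history(data, "conservative")
            a_l, h_l = genotypes_to_history(data, "lenient")
            assert h_c.n_individuals <= h_l.n_individuals
            assert h_c.total_detections == h_l.total_detections
            assert h_c.total_detections == a_c.n_detections

    def test_density_recovered_through_genotyping_pipeline(self):
        """simulate -> genotype -> match -> SCR fit covers true D in >= 80%
        of seeded replicates."""
        cfg = SimulationConfig()
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            data = simulate_survey(cfg, 100 + seed)
            _, hist = genotypes_to_history(data, "conservative")
            space = discretize(data.net, 500.0)
            f = fit(hist, space, data.detectors, SCRModelSpec(lambda0="sex"),
                    n_starts=1, seed=0, warn_no_spatial_recaptures=False)
            d = f.derived()["density_per_km"]
            if abs(d.estimate - cfg.density_per_km) <= 2 * d.se:
                hits += 1
        assert hits >= 0.8 * n_rep
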