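"""Consensus calling, sexing, identity, matching and error-rate estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linscr.genotypes import (ConsensusGenotype, ReplicateCalls, assign_sex,
                              build_detection_history, call_consensus,
                              error_rates, match_genotypes, pi_sibs,
                              randomized_subsample)
from linscr.network import DetectorArray, NetworkPosition


def rep(sample="s1", latrine="L1", occasion=0, y=(0, 4), **loci):
    calls = {k: [tuple(sorted(r)) if r else () for r in v]
             for k, v in loci.items()}
    return ReplicateCalls(sample_id=sample, latrine_id=latrine,
                          occasion=occasion, calls=calls,
                          y_positives=y[0], y_attempts=y[1])


class TestConsensus:
    @pytest.mark.parametrize("reps,expected", [
        ([("A", "B"), ("A", "B"), ("A",), ("A", "A")], ("A", "B")),  # het: both >= 2
        ([("A", "A"), ("A", "A"), ("A", "A")], ("A", "A")),          # homo: only A, >= 3
        ([("A",), ("B",)], None),                                    # neither threshold
        ([("A", "A"), ("A", "A")], None),                            # homo needs 3
        ([("A", "B")], None),                                        # < 2 replicates
        ([("A", "B"), ("A", "C"), ("B", "C")], None),                # 3 confirmed: ambiguous
    ])
    def test_rule_table(self, reps, expected):
        cg = call_consensus(rep(loc1=reps))
        assert cg.genotype["loc1"] == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.sampled_from("ABC"), min_size=0, max_size=2),
                    min_size=0, max_size=6),
           st.randoms(use_true_random=False))
    def test_consensus_permutation_invariant(self, reps, rnd):
        reps = [tuple(sorted(set(r))) for r in reps]
        base = call_consensus(rep(loc1=list(reps))).genotype["loc1"]
        shuffled = list(reps)
        rnd.shuffle(shuffled)
        assert call_consensus(rep(loc1=shuffled)).genotype["loc1"] == base

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(0)
        reps = [("A", "B"), ("A",), ("B", "B"), ("A", "B"), ()]
        base = call_consensus(rep(loc1=reps)).genotype["loc1"]
        for _ in range(10):
            perm = [reps[i] for i in rng.permutation(len(reps))]
            assert call_consensus(rep(loc1=perm)).genotype["loc1"] == base


class TestSex:
    @pytest.mark.parametrize("y_pos,y_att,n_loci,expected", [
        (2, 6, 9, "confirmed_male"),
        (1, 4, 10, "unconfirmed_male"),
        (0, 5, 9, "female"),
        (0, 5, 5, "unknown"),
        (4, 6, 0, "confirmed_male"),
    ])
    def test_rules(self, y_pos, y_att, n_loci, expected):
        assert assign_sex(y_pos, y_att, n_loci) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            assign_sex(-1, 4, 8)

    def test_unusual_attempts_warn(self):
        with pytest.warns(UserWarning):
            assign_sex(2, 9, 8)


class TestPiSibs:
    def test_monomorphic_locus(self):
        assert pi_sibs([[1.0]]) == pytest.approx(1.0)

    def test_two_allele_half(self):
        assert pi_sibs([[0.5, 0.5]]) == pytest.approx(0.59375)

    def test_product_over_loci_vs_log_oracle(self):
        val = pi_sibs([[0.5, 0.5]] * 8)
        assert val == pytest.approx(0.59375**8, rel=1e-12)
        assert np.log(val) == pytest.approx(8 * np.log(0.59375))

    def test_non_increasing_in_loci(self):
        rng = np.random.default_rng(5)
        freqs = [rng.dirichlet(np.ones(4)) for _ in range(6)]
        vals = [pi_sibs(freqs[: k + 1]) for k in range(6)]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_sample_level_cutoff_predicate(self):
        from linscr.genotypes import meets_pi_sibs
        # informative loci (many even alleles) pass; few loci fail
        freqs = {f"loc{i}": np.full(8, 1 / 8) for i in range(10)}
        good = _geno("s1", [("A", "B")] * 10)
        poor = _geno("s2", [("A", "B")] * 3 + [None] * 7)
        assert meets_pi_sibs(good, freqs)
        assert not meets_pi_sibs(poor, freqs)

    def test_invalid_frequencies(self):
        with pytest.raises(ValueError):
            pi_sibs([[0.5, 0.4]])
        with pytest.raises(ValueError):
            pi_sibs([[1.2, -0.2]])


def _geno(sample, pairs, sex="unknown", latrine="L1", occ=0):
    loci = [f"loc{i}" for i in range(len(pairs))]
    return ConsensusGenotype(
        sample_id=sample,
        genotype={l: (tuple(sorted(p)) if p else None)
                  for l, p in zip(loci, pairs)},
        sex=sex, latrine_id=latrine, occasion=occ)


TEN = [("A", "B")] * 5 + [("C", "C")] * 5


class TestMatching:
    def test_identical_merge_under_both_rules(self):
        for rule in ("conservative", "lenient"):
            a = match_genotypes([_geno("s1", TEN), _geno("s2", TEN)], rule)
            assert a.n_individuals == 1

    def test_dropout_mismatch_splits_rules(self):
        pairs2 = TEN[:9] + [("C", "D")]  # s1 has C/C: dropout-consistent
        cons = match_genotypes([_geno("s1", TEN), _geno("s2", pairs2)],
                               "conservative")
        len_ = match_genotypes([_geno("s1", TEN), _geno("s2", pairs2)],
                               "lenient")
        assert cons.n_individuals == 1
        assert len_.n_individuals == 2

    def test_non_dropout_mismatches_split_both(self):
        pairs2 = TEN[:8] + [("A", "C"), ("D", "E")]  # vs C/C, C/C: not dropout
        for rule in ("conservative", "lenient"):
            a = match_genotypes([_geno("s1", TEN), _geno("s2", pairs2)], rule)
            assert a.n_individuals == 2

    def test_short_genotypes_excluded(self):
        short = _geno("s3", TEN[:7] + [None, None, None])
        a = match_genotypes([_geno("s1", TEN), short])
        assert a.excluded_samples == ["s3"]
        assert a.n_individuals == 1

    def test_sex_conflict_resolves_to_male(self):
        a = match_genotypes([
            _geno("s1", TEN, sex="female"),
            _geno("s2", TEN, sex="confirmed_male"),
        ])
        assert a.n_individuals == 1
        assert list(a.sexes.values()) == ["male"]

    def test_transitive_closure_flags_conflicts(self):
        # s1-s2 and s2-s3 match pairwise; s1 vs s3 conflict at 2 loci
        mid = TEN[:8] + [("A", "B"), ("C", "D")]
        left = TEN[:8] + [("A", "A"), ("C", "C")]
        right = TEN[:8] + [("B", "B"), ("D", "D")]
        a = match_genotypes([_geno("s1", left), _geno("s2", mid),
                             _geno("s3", right)], "conservative")
        assert a.n_individuals == 1
        assert len(a.flagged_individuals) == 1

    def test_detection_count_preserved(self):
        genos = [_geno(f"s{i}", TEN, latrine="L1", occ=i % 3) for i in range(6)]
        genos += [_geno("s9", TEN[:9] + [("C", "D")], latrine="L2", occ=1)]
        for rule in ("conservative", "lenient"):
            a = match_genotypes(genos, rule)
            assert a.n_detections == 7


class TestErrorRates:
    def test_error_free(self):
        r = rep(**{f"loc{i}": [("A", "B")] * 4 for i in range(8)})
        cg = call_consensus(r)
        er = error_rates([r], [cg])
        assert er.dropout_rate == 0.0
        assert er.false_allele_rate == 0.0

    def test_dropout_counting(self):
        # 8 het loci; first two replicates = 16 amplifications; 4 show one allele
        loci = {}
        for i in range(8):
            reps = [("A", "B"), ("A", "B"), ("A", "B"), ("A", "B")]
            if i < 4:
                reps[1] = ("A",)
            loci[f"loc{i}"] = reps
        r = rep(**loci)
        cg = call_consensus(r)
        assert cg.n_typed == 8
        er = error_rates([r], [cg])
        assert er.n_het_amplifications == 16
        assert er.dropout_rate == pytest.approx(4 / 16)

    def test_false_allele_counting(self):
        loci = {f"loc{i}": [("A", "B")] * 4 for i in range(5)}
        loci["loc0"] = [("A", "C"), ("A", "B"), ("A", "B"), ("A", "B")]
        loci.update({f"loc{i}": [("A", "B")] * 4 for i in range(5, 8)})
        r = rep(**loci)
        cg = call_consensus(r)
        er = error_rates([r], [cg])
        assert er.n_amplifications == 16
        assert er.false_allele_rate == pytest.approx(1 / 16)

    def test_zero_denominator_is_missing(self):
        r = rep(**{f"loc{i}": [("A", "A")] * 4 for i in range(8)})
        cg = call_consensus(r)
        er = error_rates([r], [cg])
        assert er.dropout_rate is None  # no heterozygous amplifications
        assert er.false_allele_rate == 0.0


class TestDetectionHistoryBuild:
    def setup_method(self):
        self.det = DetectorArray(
            ids=["L1", "L2"],
            positions=[NetworkPosition(0, 0.0), NetworkPosition(0, 1.0)],
            effort=np.ones((2, 3)))

    def test_empty(self):
        a = match_genotypes([])
        h = build_detection_history(a, self.det, 3)
        assert h.n_individuals == 0
        assert h.counts.shape == (0, 2, 3)

    def test_with_replacement_semantics(self):
        genos = [_geno("s1", TEN, latrine="L1", occ=1),
                 _geno("s2", TEN, latrine="L1", occ=1)]
        a = match_genotypes(genos)
        h = build_detection_history(a, self.det, 3)
        assert h.counts[0, 0, 1] == 2

    def test_hand_tabulation(self):
        other = [("E", "F")] * 10
        third = [("G", "G")] * 10
        genos = [
            _geno("s1", TEN, latrine="L1", occ=0, sex="female"),
            _geno("s2", TEN, latrine="L2", occ=2, sex="female"),
            _geno("s3", other, latrine="L2", occ=0, sex="confirmed_male"),
            _geno("s4", other, latrine="L2", occ=0, sex="confirmed_male"),
            _geno("s5", third, latrine="L1", occ=1),
        ]
        a = match_genotypes(genos)
        h = build_detection_history(a, self.det, 3)
        assert h.n_individuals == 3
        assert h.total_detections == 5
        by_id = {tuple(sorted(v for k, v in a.sample_to_individual.items()
                              if k in g)): None for g in (("s1", "s2"),)}
        # individual carrying s1+s2: counts at (L1, occ0) and (L2, occ2)
        i = h.individual_ids.index(a.sample_to_individual["s1"])
        assert h.counts[i, 0, 0] == 1 and h.counts[i, 1, 2] == 1
        j = h.individual_ids.index(a.sample_to_individual["s3"])
        assert h.counts[j, 1, 0] == 2
        assert sorted(h.sexes) == ["female", "male", "unknown"]

    def test_unknown_latrine_rejected(self):
        a = match_genotypes([_geno("s1", TEN, latrine="NOPE", occ=0)])
        with pytest.raises(KeyError):
            build_detection_history(a, self.det, 3)


class TestSubsample:
    def test_seeded_and_capped(self):
        import pandas as pd
        rows = []
        for scat in range(12):
            for dup in range(2):
                rows.append({"sample_id": f"S{scat:02d}.{dup}",
                             "scat_id": f"S{scat:02d}",
                             "latrine_id": "L1", "occasion": 0})
        df = pd.DataFrame(rows)
        sel1, fb1 = randomized_subsample(df, seed=4)
        sel2, _ = randomized_subsample(df, seed=4)
        assert sel1 == sel2
        assert 3 <= len(sel1) <= 4
        assert all(s.endswith(".0") for s in sel1)  # one per scat
        assert fb1[sel1[0]] == sel1[0].replace(".0", ".1")

    def test_no_op_when_few_samples(self):
        import pandas as pd
        df = pd.DataFrame([{"sample_id": "a.0", "scat_id": "a",
                            "latrine_id": "L1", "occasion": 0}])
        sel, _ = randomized_subsample(df, seed=0)
        assert sel == ["a.0"]
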