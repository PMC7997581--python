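import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_random_bundle
from oracles import brute_avg_mae, brute_best_alignment, brute_mae_dddelta
from shiftalign.alignment import (
    AlignmentScheme,
    avg_mae_per_alignment,
    count_alignments,
    count_pairs,
    dd_delta,
    enumerate_alignments,
    mae_dddelta,
    pair_difference_sets,
    rank_alignments,
)
from shiftalign.containers import (
    AtomRecord,
    Hybridization,
    Origin,
    ShiftSet,
    StudyBundle,
)
from shiftalign.synthetic import FixtureSpec, generate_bundle


class TestCounts:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (3, 6), (4, 24), (6, 720)])
    def test_alignment_counts_are_factorials(self, n, expected):
        assert count_alignments(n) == expected

    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (4, 6), (7, 21)])
    def test_pair_counts_are_binomials(self, n, expected):
        assert count_pairs(n) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            count_alignments(0)
        with pytest.raises(ValueError):
            count_pairs(1)


class TestEnumerateAlignments:
    def test_two_sets(self):
        schemes = enumerate_alignments(2)
        assert [s.permutation for s in schemes] == [(0, 1), (1, 0)]

    def test_three_sets_cover_all_six_orders(self):
        schemes = enumerate_alignments(3)
        assert len(schemes) == 6
        assert {s.permutation for s in schemes} == set(
            itertools.permutations(range(3))
        )

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_length_lexicographic_order_identity_first(self, n):
        schemes = enumerate_alignments(n)
        assert len(schemes) == count_alignments(n)
        perms = [s.permutation for s in schemes]
        assert perms == sorted(perms)
        assert perms[0] == tuple(range(n))

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError):
            AlignmentScheme((0, 0, 1))


class TestPairDifferenceSets:
    def test_identical_sets_zero(self):
        a = ShiftSet("a", Origin.CALCULATED, {"C1": 100.0})
        b = ShiftSet("b", Origin.CALCULATED, {"C1": 100.0})
        (pair,) = pair_difference_sets([a, b])
        assert pair.deltas == {"C1": 0.0}
        assert pair.pair == (0, 1)

    def test_signed_orientation_i_minus_j(self):
        a = ShiftSet("A", Origin.CALCULATED, {"C1": 100.0})
        b = ShiftSet("B", Origin.CALCULATED, {"C1": 97.0})
        (pair,) = pair_difference_sets([a, b])
        assert pair.deltas["C1"] == pytest.approx(3.0)

    def test_four_sets_give_six_pairs_matching_subtraction(self, rng):
        labels = [f"C{i}" for i in range(7)]
        sets = [
            ShiftSet(
                f"s{k}", Origin.CALCULATED,
                dict(zip(labels, rng.uniform(0, 200, 7))),
            )
            for k in range(4)
        ]
        pairs = pair_difference_sets(sets)
        assert len(pairs) == 6
        for p in pairs:
            i, j = p.pair
            for lab in labels:
                assert p.deltas[lab] == pytest.approx(
                    sets[i].shifts[lab] - sets[j].shifts[lab], abs=1e-12
                )


class TestDdDelta:
    def test_identical_pairs_zero(self):
        pairs = pair_difference_sets(
            [
                ShiftSet("a", Origin.CALCULATED, {"C1": 1.0, "C2": 5.0}),
                ShiftSet("b", Origin.CALCULATED, {"C1": 2.0, "C2": 4.0}),
            ]
        )
        assert dd_delta(pairs[0], pairs[0]) == {"C1": 0.0, "C2": 0.0}

    def test_absolute_difference(self):
        calc = pair_difference_sets(
            [
                ShiftSet("A", Origin.CALCULATED, {"C1": 2.0}),
                ShiftSet("B", Origin.CALCULATED, {"C1": 0.0}),
            ]
        )[0]
        exp = pair_difference_sets(
            [
                ShiftSet("1", Origin.EXPERIMENTAL, {"C1": 0.0}),
                ShiftSet("2", Origin.EXPERIMENTAL, {"C1": 1.0}),
            ]
        )[0]
        assert dd_delta(calc, exp)["C1"] == pytest.approx(3.0)

    def test_label_mismatch_errors(self):
        a = pair_difference_sets(
            [
                ShiftSet("a", Origin.CALCULATED, {"C1": 1.0}),
                ShiftSet("b", Origin.CALCULATED, {"C1": 2.0}),
            ]
        )[0]
        b = pair_difference_sets(
            [
                ShiftSet("a", Origin.EXPERIMENTAL, {"C9": 1.0}),
                ShiftSet("b", Origin.EXPERIMENTAL, {"C9": 2.0}),
            ]
        )[0]
        with pytest.raises(ValueError):
            dd_delta(a, b)


def identity(n):
    return AlignmentScheme(tuple(range(n)))


class TestMaeDdDelta:
    def test_zero_at_truth(self, bundle4):
        score = mae_dddelta(
            bundle4.calc_sets, list(bundle4.calc_sets), identity(4)
        )
        assert score.mae_dddelta == 0.0
        assert score.n_terms == count_pairs(4) * 10

    def test_constant_offset_on_one_group_cancels(self, bundle4):
        base = mae_dddelta(bundle4.calc_sets, bundle4.exp_sets, identity(4))
        shifted_calc = [
            ShiftSet(s.set_id, s.origin, {k: v + 5.43 for k, v in s.shifts.items()})
            for s in bundle4.calc_sets
        ]
        offset = mae_dddelta(shifted_calc, bundle4.exp_sets, identity(4))
        assert offset.mae_dddelta == pytest.approx(base.mae_dddelta, abs=1e-10)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(5):
            bundle = make_random_bundle(rng, n=4, n_atoms=6)
            for scheme in enumerate_alignments(4)[:8]:
                got = mae_dddelta(
                    bundle.calc_sets, bundle.exp_sets, scheme
                ).mae_dddelta
                expected = brute_mae_dddelta(
                    bundle.calc_sets, bundle.exp_sets, scheme.permutation
                )
                assert got == pytest.approx(expected, abs=1e-12)

    def test_mismatched_counts_error(self, bundle4):
        with pytest.raises(ValueError):
            mae_dddelta(bundle4.calc_sets, bundle4.exp_sets[:3], identity(4))
        with pytest.raises(ValueError):
            mae_dddelta(bundle4.calc_sets, bundle4.exp_sets, identity(3))

    def test_pair_order_invariance(self, rng):
        # flipping a pair's orientation flips both signed deltas; the
        # absolute comparison is unchanged, so unordered pairs suffice
        bundle = make_random_bundle(rng, n=3, n_atoms=5)
        labels = bundle.common_labels
        calc_pairs = pair_difference_sets(bundle.calc_sets)
        exp_pairs = pair_difference_sets(bundle.exp_sets)
        for cp, ep in zip(calc_pairs, exp_pairs):
            forward = dd_delta(cp, ep)
            cp.deltas = {k: -v for k, v in cp.deltas.items()}
            ep.deltas = {k: -v for k, v in ep.deltas.items()}
            backward = dd_delta(cp, ep)
            for lab in labels:
                assert forward[lab] == pytest.approx(backward[lab], abs=1e-12)


class TestAvgMae:
    def test_identity_on_identical_bundles_is_zero(self, bundle4):
        assert (
            avg_mae_per_alignment(
                bundle4.calc_sets, list(bundle4.calc_sets), identity(4)
            )
            == 0.0
        )

    def test_two_set_toy_mean(self):
        calc = [
            ShiftSet("cA", Origin.CALCULATED, {"C1": 1.0}),
            ShiftSet("cB", Origin.CALCULATED, {"C1": 10.0}),
        ]
        exp = [
            ShiftSet("e1", Origin.EXPERIMENTAL, {"C1": 0.0}),
            ShiftSet("e2", Origin.EXPERIMENTAL, {"C1": 7.0}),
        ]
        # per-set MAEs are 1.0 and 3.0
        assert avg_mae_per_alignment(calc, exp, identity(2)) == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        bundle = make_random_bundle(rng, n=4, n_atoms=9)
        for scheme in enumerate_alignments(4):
            got = avg_mae_per_alignment(
                bundle.calc_sets, bundle.exp_sets, scheme
            )
            expected = brute_avg_mae(
                bundle.calc_sets, bundle.exp_sets, scheme.permutation
            )
            assert got == pytest.approx(expected, abs=1e-12)


class TestRankAlignments:
    def test_recovers_known_permutation(self):
        bundle, truth = generate_bundle(
            FixtureSpec(contrast_sd=2.0, noise_sd=0.3, seed=42)
        )
        ranking = rank_alignments(bundle)
        assert ranking.best.permutation == truth
        assert len(ranking.scores) == 24

    def test_every_score_matches_direct_call(self, bundle4):
        ranking = rank_alignments(bundle4, metrics=("mae_dddelta", "avg_mae"))
        for s in ranking.scores:
            direct = mae_dddelta(
                bundle4.calc_sets, bundle4.exp_sets, s.scheme, with_avg_mae=True
            )
            assert s.mae_dddelta == pytest.approx(direct.mae_dddelta, abs=1e-12)
            assert s.avg_mae == pytest.approx(direct.avg_mae, abs=1e-12)

    def test_best_matches_exhaustive_oracle(self, rng):
        bundle = make_random_bundle(rng, n=4, n_atoms=6, noise=1.5)
        ranking = rank_alignments(bundle)
        perm, score = brute_best_alignment(bundle.calc_sets, bundle.exp_sets)
        assert ranking.best.permutation == perm
        assert ranking.scores[0].mae_dddelta == pytest.approx(score, abs=1e-12)

    def test_scores_sorted_and_counts_lawful(self, bundle4):
        ranking = rank_alignments(bundle4)
        values = [s.mae_dddelta for s in ranking.scores]
        assert values == sorted(values)
        assert len(ranking.scores) == count_alignments(4)
        assert all(
            s.n_terms == count_pairs(4) * len(bundle4.common_labels)
            for s in ranking.scores
        )

    def test_exact_duplicate_exp_sets_reported_as_ties(self, rng):
        labels = ["C1", "C2", "C3"]
        a = dict(zip(labels, rng.uniform(0, 200, 3)))
        b = dict(zip(labels, rng.uniform(0, 200, 3)))
        bundle = StudyBundle(
            [AtomRecord(l, Hybridization.SP3) for l in labels],
            [
                ShiftSet("cA", Origin.CALCULATED, a),
                ShiftSet("cB", Origin.CALCULATED, b),
            ],
            [
                ShiftSet("e1", Origin.EXPERIMENTAL, dict(a)),
                ShiftSet("e2", Origin.EXPERIMENTAL, dict(a)),
            ],
        )
        ranking = rank_alignments(bundle)
        assert len(ranking.ties) == 2

    def test_ceiling_enforced(self, rng):
        bundle = make_random_bundle(rng, n=4, n_atoms=4)
        with pytest.raises(ValueError, match="max_sets"):
            rank_alignments(bundle, max_sets=3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_relabeling_consistency(self, seed):
        # score(calc, permute(exp, pi), sigma) == score(calc, exp, pi∘sigma)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        bundle = make_random_bundle(rng, n=n, n_atoms=5)
        pi = AlignmentScheme(tuple(int(x) for x in rng.permutation(n)))
        sigma = AlignmentScheme(tuple(int(x) for x in rng.permutation(n)))
        permuted_exp = [bundle.exp_sets[j] for j in pi.permutation]
        lhs = mae_dddelta(bundle.calc_sets, permuted_exp, sigma).mae_dddelta
        rhs = mae_dddelta(
            bundle.calc_sets, bundle.exp_sets, pi.compose(sigma)
        ).mae_dddelta
        assert lhs == pytest.approx(rhs, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_calibration_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        bundle = make_random_bundle(rng, n=3, n_atoms=6)
        c = float(rng.uniform(-10, 10))
        shifted_exp = [
            ShiftSet(s.set_id, s.origin, {k: v + c for k, v in s.shifts.items()})
            for s in bundle.exp_sets
        ]
        for scheme in enumerate_alignments(3):
            base = mae_dddelta(
                bundle.calc_sets, bundle.exp_sets, scheme
            ).mae_dddelta
            shifted = mae_dddelta(
                bundle.calc_sets, shifted_exp, scheme
            ).mae_dddelta
            assert shifted == pytest.approx(base, abs=1e-9)
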