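"""Design construction: orthogonal arrays, generators, efficiency, searches."""

import itertools
import math

import numpy as np
import pytest

from dceana.construct import (
    DegeneratePairError,
    Generator,
    InfeasibleDesignError,
    bayesian_d_error,
    build_candidate_set,
    constrained_bayesian_search,
    count_candidate_pairs,
    d_error,
    enumerate_level_pairs,
    generator_design,
    mnl_information_matrix,
    modified_fedorov,
    orthogonal_array_25,
    street_burgess_efficiency,
    validate_generators,
)
from dceana.construct import NO_OVERLAP_GENERATORS, OVERLAP_GENERATORS
from dceana.core import ChoiceSet, Design, Profile, overlap_count, param_index


class TestOrthogonalArray:
    def test_strength_two_property(self, oa25):
        arr = np.array([p.levels for p in oa25.runs])
        assert arr.shape == (25, 5)
        for i, j in itertools.combinations(range(5), 2):
            pairs = {(a, b) for a, b in arr[:, [i, j]]}
            assert len(pairs) == 25  # every ordered level pair exactly once


class TestGeneratorDesign:
    def test_mod5_shift_example(self):
        g = Generator((1, 1, 1, 2, 2))
        assert g.apply(Profile.from_label("11111")).label == "22233"
        assert g.apply(Profile.from_label("55555")).label == "11122"

    def test_design_size_and_overlap(self, gendev_no_overlap, gendev_overlap):
        assert len(gendev_no_overlap) == 50
        assert len(gendev_overlap) == 50
        assert all(overlap_count(cs) == 0 for cs in gendev_no_overlap.choice_sets)
        assert all(overlap_count(cs) == 2 for cs in gendev_overlap.choice_sets)

    def test_all_zero_generator_rejected(self, oa25):
        with pytest.raises(DegeneratePairError):
            generator_design(oa25, [Generator((0, 0, 0, 0, 0))])

    @pytest.mark.parametrize(
        "gens,target,expected",
        [
            (list(NO_OVERLAP_GENERATORS), 0, True),
            (list(OVERLAP_GENERATORS), 2, True),
            ([Generator((1, 1, 1, 1, 1)), Generator((4, 4, 4, 4, 4))], 0, False),
        ],
    )
    def test_validate_generators(self, gens, target, expected):
        report = validate_generators(gens, target)
        assert report.passed is expected


class TestInformationMatrix:
    def test_zero_prior_quarter_rule(self, gendev_no_overlap):
        Z = gendev_no_overlap.difference_matrix()
        M = mnl_information_matrix(gendev_no_overlap, np.zeros(20))
        np.testing.assert_allclose(M, 0.25 * Z.T @ Z, atol=1e-12)

    def test_single_difference_outer_product(self):
        d = Design([ChoiceSet(Profile.from_label("11111"), Profile.from_label("21111"))])
        M = mnl_information_matrix(d)
        expected = np.zeros((20, 20))
        expected[param_index(0, 2), param_index(0, 2)] = 0.25
        np.testing.assert_allclose(M, expected, atol=1e-12)

    def test_rank_deficient_design_has_infinite_d_error(self):
        d = Design(
            [
                ChoiceSet(Profile.from_label("11111"), Profile.from_label("21111")),
                ChoiceSet(Profile.from_label("11111"), Profile.from_label("31111")),
            ]
        )
        assert d_error(d) == math.inf

    def test_symmetric_psd(self, gendev_overlap):
        M = mnl_information_matrix(gendev_overlap, np.full(20, -0.3))
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        assert np.linalg.eigvalsh(M).min() > -1e-10


class TestDError:
    def test_duplication_leaves_normalized_d_error_unchanged(self, gendev_no_overlap):
        doubled = Design(
            gendev_no_overlap.choice_sets * 2, allow_duplicates=True
        )
        assert d_error(doubled) == pytest.approx(d_error(gendev_no_overlap), rel=1e-12)

    def test_bayesian_with_zero_draw_equals_zero_prior(self, gendev_no_overlap):
        assert bayesian_d_error(gendev_no_overlap, [np.zeros(20)]) == pytest.approx(
            d_error(gendev_no_overlap)
        )

    def test_generator_design_beats_random_designs(self, gendev_no_overlap):
        pool = build_candidate_set(0, limit=2000, seed=9)
        rng = np.random.default_rng(17)
        errs = []
        for _ in range(20):
            idx = rng.choice(len(pool), size=50, replace=False)
            errs.append(d_error(Design([pool[i] for i in idx])))
        assert d_error(gendev_no_overlap) < np.median(errs)


class TestStreetBurgessEfficiency:
    def test_quoted_generators_are_100pct(self, gendev_no_overlap):
        assert street_burgess_efficiency(gendev_no_overlap) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_rank_one_design_scores_zero(self):
        cs = ChoiceSet(Profile.from_label("11111"), Profile.from_label("22222"))
        d = Design([cs] * 50, allow_duplicates=True)
        assert street_burgess_efficiency(d) == 0.0

    def test_rule_breaking_generators_fall_short(self, oa25):
        # both shifts in {1,4}: violates the level-difference rule
        d = generator_design(oa25, [Generator((1, 1, 1, 1, 1)), Generator((4, 4, 4, 4, 4))])
        eff = street_burgess_efficiency(d)
        assert eff < 1.0
        # closed form for this symmetric case: 2*sqrt(5)/5
        assert eff == pytest.approx(2 * math.sqrt(5) / 5, abs=1e-9)


class TestCandidateEnumeration:
    @pytest.mark.parametrize("o", [0, 2, 4])
    def test_closed_form_count(self, o):
        expected = math.comb(5, o) * 5**o * 20 ** (5 - o) // 2
        assert count_candidate_pairs(o) == expected

    def test_enumeration_matches_closed_form_single_difference(self):
        assert len(build_candidate_set(4)) == count_candidate_pairs(4) == 31250

    def test_toy_system_exhaustive(self):
        A, B = enumerate_level_pairs(1, n_attributes=2, n_levels=2)
        got = {(tuple(a), tuple(b)) for a, b in zip(A, B)}
        # independent oracle: brute-force over the 2x2 toy space
        space = list(itertools.product([1, 2], repeat=2))
        want = {
            tuple(sorted((p, q)))
            for p, q in itertools.combinations(space, 2)
            if sum(x == y for x, y in zip(p, q)) == 1
        }
        assert {tuple(sorted(pair)) for pair in got} == want
        assert len(got) == 4

    def test_overlap_and_dominance_postconditions(self):
        sets = build_candidate_set(2, limit=500, seed=4, exclude_dominated=True)
        assert all(overlap_count(cs) == 2 for cs in sets)
        assert not any(cs.has_dominated_option() for cs in sets)

    def test_limit_larger_than_population_errors(self):
        with pytest.raises(ValueError):
            build_candidate_set(4, limit=40000)

    def test_subsample_is_seeded(self):
        a = build_candidate_set(2, limit=50, seed=5)
        b = build_candidate_set(2, limit=50, seed=5)
        assert [cs.key for cs in a] == [cs.key for cs in b]


class TestModifiedFedorov:
    def test_full_pool_returned_without_search(self):
        pool = build_candidate_set(0, limit=30, seed=1)
        d = modified_fedorov(pool, 30, seed=0)
        assert {cs.key for cs in d.choice_sets} == {cs.key for cs in pool}

    def test_matches_exhaustive_optimum_on_small_pool(self):
        pool = build_candidate_set(0, limit=24, seed=3)
        brute = min(
            d_error(Design(list(sub)))
            for sub in itertools.combinations(pool, 21)
        )
        d = modified_fedorov(pool, 21, seed=1, n_restarts=5)
        assert d_error(d) == pytest.approx(brute, rel=1e-9)

    def test_seeded_determinism_and_monotone_trace(self):
        pool = build_candidate_set(0, limit=100, seed=2)
        d1 = modified_fedorov(pool, 25, seed=8)
        d2 = modified_fedorov(pool, 25, seed=8)
        assert [c.key for c in d1.choice_sets] == [c.key for c in d2.choice_sets]
        trace = d1.search_trace
        finite = [v for v in trace if math.isfinite(v)]
        assert all(b >= a - 1e-9 for a, b in zip(finite, finite[1:]))

    def test_never_worse_than_start(self):
        pool = build_candidate_set(0, limit=60, seed=6)
        rng = np.random.default_rng(8)
        start_idx = rng.choice(60, size=25, replace=False)
        start = Design([pool[i] for i in start_idx])
        d = modified_fedorov(pool, 25, seed=8)
        assert d_error(d) <= d_error(start) + 1e-12


@pytest.fixture(scope="module")
def searched():
    return constrained_bayesian_search(
        25, [np.zeros(20)], seed=4, overlap_target=2,
        candidate_limit=300, max_iter=4,
    )


class TestConstrainedBayesianSearch:

    def test_constraints_hold(self, searched):
        assert not any(cs.has_dominated_option() for cs in searched.choice_sets)
        keys = [cs.key for cs in searched.choice_sets]
        assert len(set(keys)) == len(keys)
        assert all(overlap_count(cs) == 2 for cs in searched.choice_sets)

    def test_level_balance_within_tolerance(self, searched):
        levels = np.array(
            [cs.option_a.levels for cs in searched.choice_sets]
            + [cs.option_b.levels for cs in searched.choice_sets]
        )
        target = 2 * len(searched) / 5
        for k in range(5):
            counts = np.bincount(levels[:, k], minlength=6)[1:]
            assert np.all(np.abs(counts - target) <= 1.0 + 1e-9)

    def test_zero_prior_objective_not_worse_than_start(self, searched):
        # the search's own reported objective matches an independent recompute
        assert searched.bayesian_d_error_ == pytest.approx(d_error(searched), rel=1e-9)

    def test_infeasible_pool_raises(self):
        with pytest.raises(InfeasibleDesignError):
            constrained_bayesian_search(
                40, [np.zeros(20)], seed=0, overlap_target=2, candidate_limit=30
            )
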