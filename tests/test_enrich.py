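import itertools

import numpy as np
import pytest
from scipy import stats

from mzldt.enrich import (
    compare_groups,
    fold_change,
    permutation_null,
    project_counts,
    ranksum_test,
    representation_scores,
    score_profile,
)
from mzldt.io_model import PathwayDB


@pytest.fixture
def toy20_pdb():
    """N = 20 universe: one 5-member pathway, one disjoint-from-universe pathway."""
    return PathwayDB(
        pathway_ids=("pwA", "pwOut"),
        names=("A", "Out"),
        members=(frozenset(f"u{i}" for i in range(5)), frozenset({"x1", "x2"})),
    )


UNIVERSE20 = [f"u{i}" for i in range(20)]


class TestProjection:
    def test_empty_selection_all_zero(self, toy_pdb):
        assert project_counts(set(), toy_pdb).tolist() == [0, 0, 0]

    def test_exact_pathway_membership(self, toy_pdb):
        k = project_counts({"m1", "m2", "m3"}, toy_pdb)
        assert k[0] == 3  # pw1 fully covered

    def test_matches_set_intersection_oracle(self, toy_pdb):
        rng = np.random.default_rng(0)
        pool = [f"m{i}" for i in range(1, 12)]
        for _ in range(25):
            sel = set(rng.choice(pool, 5, replace=False))
            k = project_counts(sel, toy_pdb)
            expected = [len(sel & mem) for mem in toy_pdb.members]
            assert k.tolist() == expected

    def test_idempotent_and_order_invariant(self, toy_pdb):
        sel = {"m1", "m3", "m5"}
        k1 = project_counts(sel, toy_pdb)
        k2 = project_counts(sorted(sel), toy_pdb)
        assert k1.tolist() == k2.tolist()


class TestPermutationNull:
    def test_same_seed_identical(self, toy20_pdb):
        a = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=500, seed=5)
        b = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=500, seed=5)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.hist, b.hist)

    def test_disjoint_pathway_has_degenerate_null(self, toy20_pdb):
        null = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=500, seed=0)
        assert null.mean[1] == 0 and null.sd[1] == 0

    def test_nsel_exceeding_universe_errors(self, toy20_pdb):
        with pytest.raises(ValueError):
            permutation_null(21, UNIVERSE20, toy20_pdb, n_draws=10, seed=0)

    def test_mean_matches_hypergeometric_expectation(self, toy20_pdb):
        R = 5000
        null = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=R, seed=1)
        expected = 4 * 5 / 20  # n·K/N
        mc_se = null.sd[0] / np.sqrt(R)
        assert abs(null.mean[0] - expected) <= 3 * mc_se

    def test_null_mean_linear_in_selection_size(self, toy20_pdb):
        R = 5000
        m2 = permutation_null(2, UNIVERSE20, toy20_pdb, n_draws=R, seed=2).mean[0]
        m8 = permutation_null(8, UNIVERSE20, toy20_pdb, n_draws=R, seed=3).mean[0]
        assert m8 / m2 == pytest.approx(4.0, rel=0.1)


class TestRepresentationScores:
    def test_zero_count_zero_score(self, toy20_pdb):
        null = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=500, seed=0)
        prof = representation_scores(np.array([0, 0]), null, toy20_pdb)
        assert prof["score"].tolist() == [0.0, 0.0]

    def test_count_equal_to_null_mean_scores_one(self, toy20_pdb):
        null = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=2000, seed=0)
        prof = representation_scores(np.array([null.mean[0], 0]), null, toy20_pdb)
        assert prof["score"].iloc[0] == pytest.approx(1.0)

    def test_empirical_p_positive_and_at_most_one(self, toy20_pdb):
        null = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=500, seed=0)
        prof = representation_scores(np.array([5, 0]), null, toy20_pdb)
        assert ((prof["p_empirical"] > 0) & (prof["p_empirical"] <= 1)).all()

    def test_tail_matches_exact_hypergeometric(self, toy20_pdb):
        R = 30_000
        null = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=R, seed=11)
        prof = representation_scores(np.array([3, 0]), null, toy20_pdb)
        exact = stats.hypergeom.sf(2, 20, 5, 4)  # P(X >= 3)
        mc_se = np.sqrt(exact * (1 - exact) / R)
        assert abs(prof["p_empirical"].iloc[0] - exact) <= 3 * mc_se

    def test_adding_member_never_decreases_score(self, toy20_pdb):
        null = permutation_null(4, UNIVERSE20, toy20_pdb, n_draws=2000, seed=0)
        sel = {"u5", "u6", "u7"}
        k_before = project_counts(sel, toy20_pdb)
        k_after = project_counts(sel | {"u0"}, toy20_pdb)  # u0 is in pwA
        s_before = representation_scores(k_before, null, toy20_pdb)["score"]
        s_after = representation_scores(k_after, null, toy20_pdb)["score"]
        assert (k_after >= k_before).all()
        assert (s_after >= s_before).all()

    def test_empty_selection_profile_is_all_zero(self, toy20_pdb):
        prof = score_profile(set(), UNIVERSE20, toy20_pdb, 100, 0)
        assert (prof["score"] == 0).all() and (prof["p_empirical"] == 1).all()


class TestFoldChange:
    @pytest.mark.parametrize(
        "case,control,expected",
        [(27.8, 8.6, 3.2), (21.4, 2.7, 7.9), (20.3, 4.6, 4.4), (14.4, 2.9, 5.0)],
    )
    def test_published_group_means(self, case, control, expected):
        assert fold_change(case, control) == expected

    def test_identity(self):
        assert fold_change(3.7, 3.7) == 1.0

    def test_zero_control_mean_undefined(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(1.0, 0.0)


class TestRankSum:
    def test_exact_small_sample_by_enumeration(self):
        p = ranksum_test([1, 2, 3], [4, 5, 6])
        # oracle: all C(6,3)=20 equally likely rank assignments; the observed
        # rank sum (6) is the most extreme on its side in exactly 1 of 20
        obs = sum([1, 2, 3])
        tails = 0
        for combo in itertools.combinations(range(1, 7), 3):
            s = sum(combo)
            if s <= obs or s >= (21 - obs):  # as-or-more extreme, two-sided
                tails += 1
        assert p == pytest.approx(tails / 20)
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert ranksum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_groups_smaller_than_three_error(self):
        with pytest.raises(ValueError):
            ranksum_test([1, 2], [3, 4, 5])

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        n_sim = 2000
        rejections = sum(
            ranksum_test(rng.normal(size=10), rng.normal(size=10)) < 0.05
            for _ in range(n_sim)
        )
        assert 0.03 <= rejections / n_sim <= 0.07


class TestCompareGroups:
    def test_perturbed_pathways_have_largest_folds(self, sim_default, study_default):
        comp = study_default.comparison
        perturbed = set(sim_default.config.perturbed_pathways)
        top2 = set(comp.sort_values("fold", ascending=False).head(2)["pathway_id"])
        assert top2 == perturbed
        sub = comp[comp.pathway_id.isin(perturbed)]
        assert (sub["fold"] > 2).all()
        assert (sub["ranksum_p"] < 0.01).all()
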