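import itertools

import numpy as np
import pandas as pd
import pytest

from usvkit.repertoire import (
    RepertoireCounts,
    anosim,
    bray_curtis,
    dissimilarity_matrix,
    diversity,
    nmds,
    permanova,
    simper,
    stress_interpretation,
)


def separated_matrix(within=0.1, between=0.9, n_per=3):
    n = 2 * n_per
    d = np.full((n, n), between)
    d[:n_per, :n_per] = within
    d[n_per:, n_per:] = within
    np.fill_diagonal(d, 0.0)
    return d, np.array(["a"] * n_per + ["b"] * n_per)


def random_symmetric(n, seed):
    rng = np.random.default_rng(seed)
    d = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    v = rng.random(iu.size)
    d[iu, ju] = v
    d[ju, iu] = v
    return d


class TestDiversity:
    def test_bounds_and_counting(self):
        assert diversity(np.zeros(15)) == 0
        assert diversity(np.ones(15)) == 15
        c = np.zeros(15)
        c[0], c[3] = 3, 1
        assert diversity(c) == 2

    def test_repertoire_counts_wrapper(self):
        rc = RepertoireCounts("m1", "0d", np.arange(15))
        assert diversity(rc) == 14
        with pytest.raises(ValueError):
            RepertoireCounts("m1", "0d", np.array([-1, 0]))


class TestBrayCurtis:
    def test_identity_disjoint_and_arithmetic(self):
        assert bray_curtis([3, 1, 0], [3, 1, 0]) == 0.0
        assert bray_curtis([2, 0, 0], [0, 3, 1]) == 1.0
        assert bray_curtis([2, 1, 0], [0, 1, 1]) == pytest.approx(0.6)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_excludes_silent_subjects(self):
        counts = np.array([[3, 1], [0, 0], [1, 2]])
        d, kept = dissimilarity_matrix(counts)
        assert list(kept) == [0, 2]
        assert d.shape == (2, 2) and d[0, 1] == d[1, 0] > 0
        with pytest.raises(ValueError):
            dissimilarity_matrix(counts, exclude_silent=False)


class TestAnosim:
    def test_maximal_separation_R_is_one(self):
        d, groups = separated_matrix()
        assert anosim(d, groups, 99, 0).statistic == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_toy(self):
        """Observed R and permutation p agree with brute force over all
        C(6,3) = 20 labelings of a 6-subject matrix."""
        d = random_symmetric(6, seed=42)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = anosim(d, groups, n_perm=999, seed=1)

        # independent oracle: rank dissimilarities by hand, enumerate labelings
        from scipy.stats import rankdata

        iu, ju = np.triu_indices(6, k=1)
        ranks = rankdata(d[iu, ju])

        def r_stat(members_a):
            in_a = np.isin(np.arange(6), members_a)
            within = in_a[iu] == in_a[ju]
            return (ranks[~within].mean() - ranks[within].mean()) / (len(ranks) / 2)

        observed = r_stat([0, 1, 2])
        assert res.statistic == pytest.approx(observed, abs=1e-12)
        all_r = [r_stat(c) for c in itertools.combinations(range(6), 3)]
        exact_p = np.mean([r >= observed - 1e-12 for r in all_r])
        assert res.p_value == pytest.approx(exact_p, abs=0.1)

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        d = random_symmetric(12, seed=3)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = anosim(d, np.array(groups), 99, 0).statistic
        theirs = skbio_anosim(DistanceMatrix(d), groups, permutations=0)
        assert ours == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_null_calibration_mean_R_near_zero(self):
        """On structureless dissimilarities, R averages ~0 over seeds."""
        d = random_symmetric(12, seed=10)
        stats = []
        rng = np.random.default_rng(0)
        base = np.array(["a"] * 6 + ["b"] * 6)
        for _ in range(200):
            groups = rng.permutation(base)
            stats.append(anosim(d, groups, n_perm=1, seed=0).statistic)
        assert abs(np.mean(stats)) <= 0.05

    def test_monotone_transform_invariance(self):
        d = random_symmetric(10, seed=5)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        r1 = anosim(d, groups, 99, 7)
        r2 = anosim(np.sqrt(d), groups, 99, 7)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == r2.p_value

    def test_degenerate_grouping_rejected(self):
        d = random_symmetric(4, seed=0)
        with pytest.raises(ValueError):
            anosim(d, np.array(["a", "a", "a", "b"]), 99, 0)


class TestPermanova:
    def test_equals_anova_F_on_euclidean_1d(self):
        import scipy.stats

        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 18)
        x[6:12] += 1.0
        groups = np.repeat(["a", "b", "c"], 6)
        d = np.abs(x[:, None] - x[None, :])
        ours = permanova(d, groups, 9, 0).statistic
        anova = scipy.stats.f_oneway(x[:6], x[6:12], x[12:]).statistic
        assert ours == pytest.approx(anova, abs=1e-9)

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        d = random_symmetric(12, seed=4)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = permanova(d, np.array(groups), 99, 0).statistic
        theirs = skbio_permanova(DistanceMatrix(d), groups, permutations=0)
        assert ours == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_perfect_separation_min_p(self):
        # three groups of four, identical within, distinct between
        n_per, levels = 4, ["a", "b", "c"]
        n = n_per * len(levels)
        d = np.full((n, n), 0.9)
        for k in range(len(levels)):
            d[k * n_per : (k + 1) * n_per, k * n_per : (k + 1) * n_per] = 0.0
        res = permanova(d, np.repeat(levels, n_per), 999, 0)
        assert res.statistic == np.inf
        assert res.p_value == pytest.approx(1 / (1 + 999))

    def test_add_one_p_convention(self):
        d = random_symmetric(8, seed=6)
        res = permanova(d, np.array(["a"] * 4 + ["b"] * 4), 999, 0)
        assert res.p_value >= 1 / 1000
        assert res.p_value <= 1.0


class TestNmds:
    def test_planar_configuration_embeds_perfectly(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        _, stress_best, stress_mean = nmds(d, k=2, n_starts=8, seed=2)
        assert stress_best <= 0.01
        assert stress_mean >= stress_best

    def test_monotone_transform_keeps_stress(self):
        d = random_symmetric(9, seed=7)
        _, s1, _ = nmds(d, n_starts=6, seed=3)
        _, s2, _ = nmds(d**2, n_starts=6, seed=3)  # rank-preserving
        assert s2 == pytest.approx(s1, abs=0.01)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((3, 3)), k=2)

    def test_stress_interpretation_thresholds(self):
        assert stress_interpretation(0.04) == "excellent"
        assert stress_interpretation(0.35) == "near-arbitrary"


class TestSimper:
    def test_single_differing_type_contributes_all(self):
        counts = pd.DataFrame(
            {"t1": [5, 5, 0, 0], "t2": [2, 2, 2, 2]},
        )
        groups = np.array(["a", "a", "b", "b"])
        table = simper(counts, groups)
        t1 = table[table["type"] == "t1"].iloc[0]
        assert t1["pct"] == pytest.approx(100.0)

    def test_contributions_sum_to_mean_between_bc(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.integers(0, 20, (10, 15)))
        groups = np.repeat(["a", "b"], 5)
        table = simper(counts, groups)
        total = table["contribution"].sum()
        bcs = [
            bray_curtis(counts.iloc[i], counts.iloc[j])
            for i in range(5)
            for j in range(5, 10)
        ]
        assert total == pytest.approx(np.mean(bcs), abs=1e-9)

    def test_hand_computed_two_by_two(self):
        # groups a: (2,0), (4,0); b: (0,2), (0,0) -> skip zero profile
        counts = pd.DataFrame({"t1": [2, 4, 0], "t2": [0, 0, 2]})
        groups = np.array(["a", "a", "b"])
        table = simper(counts, groups)
        # pairs: (2,0)v(0,2): |2|/4, |2|/4 ; (4,0)v(0,2): 4/6, 2/6
        t1 = (2 / 4 + 4 / 6) / 2
        t2 = (2 / 4 + 2 / 6) / 2
        got = table.set_index("type")["contribution"]
        assert got["t1"] == pytest.approx(t1, abs=1e-12)
        assert got["t2"] == pytest.approx(t2, abs=1e-12)
        assert table.iloc[0]["type"] == "t1"  # ranked first

    def test_seventy_percent_cutoff_marked(self):
        counts = pd.DataFrame(
            {"t1": [10, 10, 0, 0], "t2": [3, 3, 0, 0], "t3": [1, 1, 1, 1]}
        )
        table = simper(counts, np.repeat(["a", "b"], 2))
        assert table[table["rank"] == 1]["in_top"].all()
        assert not table[table["cumulative_pct"] > 99.99]["in_top"].iloc[-1]


class TestLabelInvariance:
    def test_subject_relabeling_preserves_statistics(self):
        d = random_symmetric(10, seed=9)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        perm = np.random.default_rng(1).permutation(10)
        r1 = anosim(d, groups, 49, 0).statistic
        r2 = anosim(d[np.ix_(perm, perm)], groups[perm], 49, 0).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)
        f1 = permanova(d, groups, 49, 0).statistic
        f2 = permanova(d[np.ix_(perm, perm)], groups[perm], 49, 0).statistic
        assert f1 == pytest.approx(f2, abs=1e-9)
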