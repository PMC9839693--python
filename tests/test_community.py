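import itertools

import numpy as np
import pytest
from scipy import stats

from paircohort import fisher_exact_2x2, pam, permanova, select_k
from paircohort.community import rank_cluster_features
from paircohort.diversity import DistanceMatrix, euclidean
from paircohort.tables_io import CountTable


def blobs(rng, centers, n_per, spread=0.2):
    pts = np.vstack([rng.normal(c, spread, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return euclidean(pts), labels


def brute_force_pam_cost(d: np.ndarray, k: int) -> float:
    n = d.shape[0]
    return min(
        d[:, list(m)].min(axis=1).sum() for m in itertools.combinations(range(n), k)
    )


class TestPam:
    def test_two_blobs_recovered(self, rng):
        d, truth = blobs(rng, [(0, 0), (5, 5)], 10)
        res = pam(d, 2)
        grouping = {tuple(sorted(np.flatnonzero(res.labels == c))) for c in (1, 2)}
        expected = {tuple(range(10)), tuple(range(10, 20))}
        assert grouping == expected

    @pytest.mark.parametrize("k", [2, 3])
    def test_swap_reaches_exhaustive_optimum_small_n(self, k):
        """For n <= 7 the BUILD+SWAP local optimum equals the global
        brute-force best medoid subset."""
        for seed in range(8):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(7, 2))
            d = euclidean(pts)
            res = pam(d, k)
            assert res.cost == pytest.approx(brute_force_pam_cost(d.d, k), abs=1e-9)

    def test_k_n_minus_1_cost_is_min_pair_distance(self, rng):
        pts = rng.normal(size=(6, 2))
        d = euclidean(pts)
        res = pam(d, 5)
        # only one non-medoid remains; optimal cost = the smallest distance
        # from any point to another (brute force over medoid subsets)
        assert res.cost == pytest.approx(brute_force_pam_cost(d.d, 5), abs=1e-9)

    def test_cost_matches_label_assignment(self, rng):
        d, _ = blobs(rng, [(0, 0), (4, 4), (0, 6)], 5)
        res = pam(d, 3)
        med_idx = [d.ids.index(m) for m in res.medoids]
        assert res.cost == pytest.approx(d.d[:, med_idx].min(axis=1).sum())
        assert set(res.labels) == {1, 2, 3}

    def test_k_bounds(self, rng):
        d, _ = blobs(rng, [(0, 0)], 4)
        with pytest.raises(ValueError):
            pam(d, 4)
        with pytest.raises(ValueError):
            pam(d, 1)


class TestSelectK:
    def test_planted_two_clusters(self, rng):
        d, _ = blobs(rng, [(0, 0), (6, 6)], 8)
        assert select_k(d, range(2, 6)) == 2

    def test_planted_three_clusters(self, rng):
        d, _ = blobs(rng, [(0, 0), (8, 0), (4, 7)], 8)
        assert select_k(d, range(2, 6)) == 3

    def test_noise_flagged(self, rng):
        d = euclidean(rng.uniform(size=(20, 10)))
        with pytest.warns(UserWarning, match="silhouette"):
            select_k(d, range(2, 5))

    def test_empty_range_errors(self, rng):
        d, _ = blobs(rng, [(0, 0), (3, 3)], 4)
        with pytest.raises(ValueError):
            select_k(d, [])


def fisher_p_enumeration(table) -> float:
    """Brute-force two-sided Fisher p: sum of probabilities of all tables with
    the observed margins that are no more probable than the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, n = a + b, a + b + c + d
    c1 = a + c
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisherExact:
    def test_balanced_table(self):
        res = fisher_exact_2x2([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_perfect_separation_boundary(self):
        res = fisher_exact_2x2([[10, 0], [0, 10]])
        assert np.isinf(res.odds_ratio) or res.odds_ratio > 1e6
        assert np.isinf(res.ci_high)
        assert res.p == pytest.approx(fisher_p_enumeration([[10, 0], [0, 10]]), abs=1e-12)

    def test_p_matches_enumeration_to_1e12(self, rng):
        tables = [[[8, 2], [1, 9]]]
        for _ in range(30):
            t = rng.integers(0, 11, size=(2, 2))
            if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all() and t.sum() <= 40:
                tables.append(t.tolist())
        for t in tables:
            assert fisher_exact_2x2(t).p == pytest.approx(fisher_p_enumeration(t), abs=1e-12)

    def test_ci_brackets_odds_ratio(self):
        res = fisher_exact_2x2([[8, 2], [1, 9]])
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestRankClusterFeatures:
    @staticmethod
    def _table(counts):
        counts = np.asarray(counts)
        return CountTable(
            samples=[f"S{i}" for i in range(counts.shape[0])],
            features=[f"OTU{j}" for j in range(counts.shape[1])],
            counts=counts,
        )

    def test_perfectly_separating_feature_ranked_first(self, rng):
        # marker kept small vs the total so the separation stays confined to
        # its own column after closure to relative abundances
        n = 12
        counts = rng.integers(1000, 2000, size=(n, 6))
        counts[: n // 2, 0] = 30  # feature 0 marks cluster 1
        counts[n // 2 :, 0] = 0
        labels = np.array([1] * (n // 2) + [2] * (n // 2))
        ranked = rank_cluster_features(self._table(counts), labels, n_estimators=100)
        assert ranked[0][0] == "OTU0" and ranked[0][1] > 0
        assert ranked[0][2] == 1  # higher median abundance in cluster 1

    def test_shuffled_labels_give_null_importance(self, rng):
        counts = rng.integers(5, 50, size=(16, 8))
        top = []
        for seed in range(12):
            labels = np.random.default_rng(seed).permutation([1, 2] * 8)
            ranked = rank_cluster_features(self._table(counts), labels, seed=seed, n_estimators=60, n_repeats=3)
            top.append(ranked[0][1])
        # importances hover around zero: mean small, not systematically positive
        assert np.mean(top) < 0.25

    def test_single_cluster_errors(self, rng):
        counts = rng.integers(1, 9, size=(6, 4))
        with pytest.raises(ValueError):
            rank_cluster_features(self._table(counts), [1] * 6)


def permanova_exhaustive_oracle(d2, groups):
    """Exact p over all distinct label arrangements (independent of the
    implementation's internal enumeration)."""
    from paircohort.community import _permanova_f

    f_obs, _ = _permanova_f(d2, np.asarray(groups))
    seen = set()
    hits = 0
    for perm in itertools.permutations(range(len(groups))):
        lab = tuple(np.asarray(groups)[list(perm)])
        if lab in seen:
            continue
        seen.add(lab)
        f, _ = _permanova_f(d2, np.asarray(lab))
        if f >= f_obs - 1e-12:
            hits += 1
    return hits / len(seen), len(seen)


class TestPermanova:
    def test_separated_identical_points(self, rng):
        # two tight groups far apart: only the identity and the mirror
        # arrangement reach F_obs, so the exhaustive p is exactly 2/C(8,4)
        pts = np.vstack([np.zeros((4, 2)), np.full((4, 2), 9.0)])
        d = euclidean(pts + rng.normal(scale=1e-9, size=pts.shape))
        groups = ["a"] * 4 + ["b"] * 4
        res = permanova(d, groups, exhaustive=True)
        assert res.R2 > 0.999
        assert res.p == pytest.approx(2 / 70)
        assert res.df_between == 1

    def test_exhaustive_matches_independent_enumeration_n6(self, rng):
        pts = rng.normal(size=(6, 3))
        pts[3:] += 1.0
        d = euclidean(pts)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(d, groups, exhaustive=True)
        p_exact, n_arrangements = permanova_exhaustive_oracle(d.d**2, groups)
        assert n_arrangements == 20  # 6!/(3!3!)
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_r2_invariant_to_distance_scaling(self, rng):
        pts = rng.normal(size=(10, 3))
        groups = ["a"] * 5 + ["b"] * 5
        d = euclidean(pts)
        d_scaled = DistanceMatrix(d.ids, d.d * 7.5)
        r1 = permanova(d, groups, n_perm=99, seed=1)
        r2 = permanova(d_scaled, groups, n_perm=99, seed=1)
        assert r1.R2 == pytest.approx(r2.R2)
        assert r1.p == r2.p

    def test_null_p_uniformish(self, rng):
        """Random labels on exchangeable data: p roughly uniform (KS check)."""
        ps = []
        for rep in range(60):
            r = np.random.default_rng(rep)
            pts = r.normal(size=(12, 4))
            groups = r.permutation(["a"] * 6 + ["b"] * 6)
            ps.append(permanova(euclidean(pts), groups, n_perm=99, seed=rep).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_group_errors(self, rng):
        d = euclidean(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 5)

    def test_matches_scikit_bio(self, rng):
        """Independent pseudo-F cross-check against scikit-bio's PERMANOVA."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(size=(12, 4))
        pts[6:] += 0.8
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(euclidean(pts), groups, n_perm=99, seed=0)
        ref = skbio_permanova(SkbioDM(euclidean(pts).d), grouping=list(groups), permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)
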