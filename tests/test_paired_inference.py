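import itertools

import numpy as np
import pytest
from scipy import stats

from paircohort import build_pair_graph, fdr_bh, paired_t, permutation_paired_test, welch_t
from paircohort.paired_inference import PairGraph

from conftest import make_metadata


def graph_from(rows, window=90):
    return build_pair_graph(make_metadata(rows), window_days=window)


class TestBuildPairGraph:
    def test_single_pair_within_window(self):
        g = graph_from(
            [("P1", "F1", "patient", "2019-05-07"), ("R1", "F1", "relative", "2019-05-17")]
        )
        assert g.eligible == {"P1": [("R1", 10)]}

    def test_91_days_excluded(self):
        g = graph_from(
            [("P1", "F1", "patient", "2019-01-01"), ("R1", "F1", "relative", "2019-04-02")]
        )
        assert g.patients == [] and g.excluded_patients == ["P1"]

    def test_90_days_still_eligible(self):
        g = graph_from(
            [("P1", "F1", "patient", "2019-01-01"), ("R1", "F1", "relative", "2019-04-01")]
        )
        assert g.eligible["P1"] == [("R1", 90)]

    def test_ambiguous_patient_keeps_all_candidates(self):
        g = graph_from(
            [
                ("P1", "F1", "patient", "2019-06-01"),
                ("R1", "F1", "relative", "2019-06-06"),
                ("R2", "F1", "relative", "2019-08-20"),
            ]
        )
        assert [r for r, _ in g.eligible["P1"]] == ["R1", "R2"]

    def test_cross_family_relatives_not_eligible(self):
        g = graph_from(
            [
                ("P1", "F1", "patient", "2019-06-01"),
                ("R9", "F2", "relative", "2019-06-01"),
            ]
        )
        assert g.excluded_patients == ["P1"]

    def test_shared_relative_flagged(self):
        g = graph_from(
            [
                ("P1", "F1", "patient", "2019-06-01"),
                ("P2", "F1", "patient", "2019-06-02"),
                ("R1", "F1", "relative", "2019-06-05"),
            ]
        )
        assert g.shared_relatives == ["R1"]


class TestPairedT:
    def test_symmetric_differences(self):
        t, df, p, diff, lo, hi = paired_t([1.0, -1.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_closed_form(self):
        d = [1.0, 2.0, 3.0, 4.0]
        t, df, p, diff, lo, hi = paired_t(d)
        sd = np.std(d, ddof=1)
        assert t == pytest.approx(2.5 / (sd / 2))
        assert df == 3
        ref = stats.ttest_1samp(d, 0.0)
        assert p == pytest.approx(ref.pvalue)
        crit = stats.t.ppf(0.975, 3)
        assert (lo, hi) == (pytest.approx(2.5 - crit * sd / 2), pytest.approx(2.5 + crit * sd / 2))

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, _, p, *_ = paired_t([2.0, 2.0, 2.0])
        assert np.isinf(t) and p == 0.0


class TestWelchT:
    def test_identical_groups(self):
        t, df, p, *_ = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        t, df, p, diff, lo, hi = welch_t(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 3 + vb / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(se2)
        df_hand = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        assert t == pytest.approx(t_hand) and df == pytest.approx(df_hand)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_both_groups(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, _, p, *_ = welch_t([0.0, 0.0], [1.0, 1.0])
        assert np.isinf(t) and p == 0.0


class TestFdrBh:
    def test_single_p(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_arithmetic(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_min_q_at_least_min_p(self, rng):
        p = rng.uniform(size=25)
        assert fdr_bh(p).min() >= p.min() - 1e-15

    def test_monotone_in_rank(self, rng):
        p = np.sort(rng.uniform(size=15))
        q = fdr_bh(p)
        assert np.all(np.diff(q) >= -1e-15)


def _unambiguous_graph(n=5):
    rows, vals = [], {}
    rng = np.random.default_rng(7)
    for i in range(n):
        rows.append((f"P{i}", f"F{i}", "patient", "2019-05-07"))
        rows.append((f"R{i}", f"F{i}", "relative", "2019-05-10"))
        vals[f"P{i}"] = float(rng.normal(1.0))
        vals[f"R{i}"] = float(rng.normal())
    return graph_from(rows), vals


class TestPermutationPairedTest:
    def test_unambiguous_equals_closed_form(self):
        """With exactly one eligible relative per patient, the aggregated
        result is the single paired t for any number of permutations."""
        g, vals = _unambiguous_graph()
        d = [vals[f"P{i}"] - vals[f"R{i}"] for i in range(5)]
        t, df, p, diff, lo, hi = paired_t(d)
        for n_perm in (1, 7, 200):
            res = permutation_paired_test(vals, g, n_perm=n_perm, seed=3)
            assert res.mean_t == pytest.approx(t)
            assert res.mean_p == pytest.approx(p)
            assert res.mean_diff == pytest.approx(diff)
            assert (res.mean_ci_low, res.mean_ci_high) == (pytest.approx(lo), pytest.approx(hi))
            assert res.df == 4

    def test_deterministic_given_seed(self):
        g, vals = _ambiguous_graph()
        r1 = permutation_paired_test(vals, g, n_perm=50, seed=11)
        r2 = permutation_paired_test(vals, g, n_perm=50, seed=11)
        assert (r1.mean_t, r1.mean_p, r1.mean_diff) == (r2.mean_t, r2.mean_p, r2.mean_diff)

    def test_mean_ci_brackets_mean_diff(self):
        g, vals = _ambiguous_graph()
        res = permutation_paired_test(vals, g, n_perm=200, seed=0)
        assert res.mean_ci_low <= res.mean_diff <= res.mean_ci_high

    def test_enumeration_oracle_ambiguous(self):
        """Monte-Carlo means converge to the exhaustive-enumeration values
        over all pairing assignments (3 sigma at n_perm = 1e4)."""
        g, vals = _ambiguous_graph()
        stats_by_assignment = _enumerate_assignments(g, vals)
        n_perm = 10_000
        res = permutation_paired_test(vals, g, n_perm=n_perm, seed=5)
        for key in ("t", "p", "diff"):
            arr = np.array([s[key] for s in stats_by_assignment])
            exact = arr.mean()
            sigma = arr.std() / np.sqrt(n_perm)
            got = {"t": res.mean_t, "p": res.mean_p, "diff": res.mean_diff}[key]
            assert abs(got - exact) <= 3 * sigma + 1e-12, key

    def test_invariant_to_input_order(self):
        rows = [
            ("P1", "F1", "patient", "2019-06-01"),
            ("R1a", "F1", "relative", "2019-06-06"),
            ("R1b", "F1", "relative", "2019-06-20"),
            ("P2", "F2", "patient", "2019-06-01"),
            ("R2", "F2", "relative", "2019-06-03"),
            ("P3", "F3", "patient", "2019-06-01"),
            ("R3", "F3", "relative", "2019-06-03"),
        ]
        vals = {"P1": 3.0, "R1a": 1.0, "R1b": 2.0, "P2": 0.5, "R2": 0.1, "P3": 1.5, "R3": 0.9}
        g1 = graph_from(rows)
        g2 = graph_from(rows[::-1])
        r1 = permutation_paired_test(vals, g1, n_perm=64, seed=9)
        r2 = permutation_paired_test(vals, g2, n_perm=64, seed=9)
        assert (r1.mean_t, r1.mean_p) == (r2.mean_t, r2.mean_p)

    def test_missing_endpoint_drops_patient(self):
        g, vals = _unambiguous_graph()
        vals["R0"] = None
        with pytest.warns(UserWarning, match="dropped patient"):
            res = permutation_paired_test(vals, g, n_perm=10, seed=0)
        assert res.n_pairs == 4 and res.df == 3
        assert res.dropped_patients == ["P0"]

    def test_n_perm_validation(self):
        g, vals = _unambiguous_graph()
        with pytest.raises(ValueError):
            permutation_paired_test(vals, g, n_perm=0, seed=0)

    def test_sign_convention_patient_minus_relative(self):
        rows = [
            ("P1", "F1", "patient", "2019-06-01"),
            ("R1", "F1", "relative", "2019-06-02"),
            ("P2", "F2", "patient", "2019-06-01"),
            ("R2", "F2", "relative", "2019-06-02"),
        ]
        vals = {"P1": 1.0, "R1": 2.0, "P2": 1.0, "R2": 2.5}
        res = permutation_paired_test(vals, graph_from(rows), n_perm=5, seed=0)
        assert res.mean_diff < 0  # patient deficit is negative


def _ambiguous_graph():
    rows = [
        ("P1", "F1", "patient", "2019-06-01"),
        ("R1a", "F1", "relative", "2019-06-06"),
        ("R1b", "F1", "relative", "2019-07-20"),
        ("P2", "F2", "patient", "2019-06-01"),
        ("R2a", "F2", "relative", "2019-06-03"),
        ("R2b", "F2", "relative", "2019-06-25"),
        ("R2c", "F2", "relative", "2019-08-01"),
        ("P3", "F3", "patient", "2019-06-01"),
        ("R3", "F3", "relative", "2019-06-03"),
        ("P4", "F4", "patient", "2019-06-01"),
        ("R4", "F4", "relative", "2019-06-08"),
    ]
    rng = np.random.default_rng(21)
    vals = {s: float(rng.normal(0.6 if s.startswith("P") else 0.0)) for s, *_ in [(r[0],) for r in rows]}
    return graph_from(rows), vals


def _enumerate_assignments(g: PairGraph, vals):
    """Exhaustive oracle: paired-t stats for every pairing assignment."""
    patients = sorted(g.patients)
    choices = [sorted(r for r, _ in g.eligible[p]) for p in patients]
    out = []
    for combo in itertools.product(*choices):
        d = [vals[p] - vals[r] for p, r in zip(patients, combo)]
        t, df, p_, diff, lo, hi = paired_t(d)
        out.append({"t": t, "p": p_, "diff": diff})
    return out
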