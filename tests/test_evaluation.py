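import numpy as np
import pytest

from aaeclust.datatypes import SurvivalTable
from aaeclust.errors import ShapeError, ValidationError
from aaeclust.evaluation import (
    clinical_enrichment,
    embed_2d,
    km_curves,
    logrank_test,
    permutation_pvalue,
    residence_matrix,
    similarity_matrix,
    variation_of_information,
)
from aaeclust.synthetic import simulate_clinical


def lifetable_logrank(times, events, labels):
    """Brute-force K-sample log-rank chi-square from first principles.

    Walks the distinct event times, accumulates observed-minus-expected
    per group and the hypergeometric covariance, then forms the quadratic
    form over K-1 groups.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    K = len(groups)
    OE = np.zeros(K)
    V = np.zeros((K, K))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        N = at_risk.sum()
        D = ((times == t) & (events == 1)).sum()
        if N <= 1:
            continue
        for j, gj in enumerate(groups):
            nj = (at_risk & (labels == gj)).sum()
            dj = ((times == t) & (events == 1) & (labels == gj)).sum()
            OE[j] += dj - D * nj / N
            for k, gk in enumerate(groups):
                nk = (at_risk & (labels == gk)).sum()
                same = 1.0 if j == k else 0.0
                V[j, k] += D * (nj / N) * (same - nk / N) * (N - D) / (N - 1)
    sub = slice(0, K - 1)
    return float(OE[sub] @ np.linalg.solve(V[sub, sub], OE[sub]))


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        times = np.array([5.0, 8, 12, 5, 8, 12])
        events = np.array([1, 0, 1, 1, 0, 1])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = logrank_test(times, events, labels)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_lifetable_oracle_on_six_subjects(self):
        times = np.array([3.0, 5.0, 7.0, 2.0, 4.0, 9.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = logrank_test(times, events, labels)
        assert res.chi_square == pytest.approx(
            lifetable_logrank(times, events, labels), abs=1e-9
        )

    def test_matches_lifetable_oracle_on_random_three_group_data(self, rng):
        times = rng.exponential(100, size=60).round(1) + 1
        events = rng.integers(0, 2, 60)
        events[:3] = 1
        labels = rng.integers(0, 3, 60)
        res = logrank_test(times, events, labels)
        assert res.df == 2
        assert res.chi_square == pytest.approx(
            lifetable_logrank(times, events, labels), abs=1e-6
        )

    def test_detects_hazard_ratio_three(self):
        rng = np.random.default_rng(1)
        n = 200
        labels = np.arange(n) % 2
        lam = np.where(labels == 0, 0.003, 0.001)
        T = rng.exponential(1 / lam)
        C = rng.uniform(0, T.max() * 5, n)  # ~10% censoring scale
        times = np.minimum(T, C)
        events = (T <= C).astype(int)
        assert logrank_test(times, events, labels).p_value < 0.01

    def test_argument_errors(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [0, 0], [0, 1])


class TestKmCurves:
    def test_two_event_group_steps(self):
        curves = km_curves([2.0, 5.0], [1, 1], [0, 0])
        t, s = curves[0]
        assert s[0] == 1.0
        assert list(s[np.searchsorted(t, [2.0, 5.0])]) == [0.5, 0.0]

    def test_all_censored_group_is_flat(self):
        curves = km_curves([3.0, 6.0, 2.0], [0, 0, 1], [0, 0, 1])
        _, s = curves[0]
        assert np.all(s == 1.0)

    def test_monotone_nonincreasing_on_random_fixtures(self, rng):
        for _ in range(5):
            times = rng.exponential(50, 40) + 0.1
            events = rng.integers(0, 2, 40)
            labels = rng.integers(0, 3, 40)
            for _, s in km_curves(times, events, labels).values():
                assert np.all(np.diff(s) <= 1e-12)


class TestPermutation:
    def test_r_zero_gives_one(self):
        times = np.array([1.0, 2, 3, 4])
        events = np.ones(4, dtype=int)
        labels = np.array([0, 0, 1, 1])
        assert permutation_pvalue(times, events, labels, R=0) == 1.0

    def test_lower_bound(self, rng):
        times = rng.exponential(10, 20) + 0.1
        events = np.ones(20, dtype=int)
        labels = rng.integers(0, 2, 20)
        p = permutation_pvalue(times, events, labels, R=19, seed=0)
        assert p >= 1 / 20

    def test_fully_separated_groups_reach_floor(self):
        """Strong separation: observed statistic beats all 999 permutations."""
        rng = np.random.default_rng(1)
        labels = np.arange(100) % 2
        times = np.where(labels == 0, rng.exponential(5, 100), rng.exponential(500, 100)) + 0.1
        events = np.ones(100, dtype=int)
        assert permutation_pvalue(times, events, labels, R=999, seed=1) == pytest.approx(1 / 1000)


class TestEnrichment:
    def _table(self, covs, types):
        n = len(covs)
        return SurvivalTable(
            [f"s{i}" for i in range(n)],
            np.ones(n),
            np.ones(n, dtype=int),
            covs,
            types,
        )

    def test_constant_covariate_warns_p_one(self):
        import pandas as pd

        table = self._table(pd.DataFrame({"c": ["x"] * 10}), {"c": "categorical"})
        with pytest.warns(UserWarning, match="constant"):
            report = clinical_enrichment(table, np.arange(10) % 2)
        assert report.tests[0][3] == 1.0
        assert report.n_significant == 0

    def test_perfectly_aligned_binary_covariate(self):
        import pandas as pd

        labels = np.arange(100) % 2
        table = self._table(
            pd.DataFrame({"c": np.where(labels == 0, "a", "b")}), {"c": "categorical"}
        )
        report = clinical_enrichment(table, labels)
        assert report.tests[0][3] < 1e-6
        assert report.n_significant == 1

    def test_planted_and_null_covariates(self):
        import pandas as pd

        labels = np.arange(400) % 4
        covs, types, associated = simulate_clinical(labels, n_associated=3, n_null=4, seed=1)
        table = self._table(covs, types)
        report = clinical_enrichment(table, labels)
        by_name = {name: p for name, _, _, p in report.tests}
        assert all(by_name[a] < 0.05 for a in associated)
        nulls_significant = sum(by_name[f"null_{j}"] < 0.05 for j in range(4))
        assert nulls_significant <= 1

    def test_kruskal_on_continuous(self, rng):
        import pandas as pd

        labels = np.arange(120) % 3
        covs = pd.DataFrame({"age": labels * 10.0 + rng.normal(0, 1, 120)})
        report = clinical_enrichment(self._table(covs, {"age": "continuous"}), labels)
        assert report.tests[0][1] == "kruskal"
        assert report.tests[0][3] < 1e-6


class TestVariationOfInformation:
    def test_identical_partitions(self):
        assert variation_of_information([0, 1, 1, 2], [5, 9, 9, 7]) == 0.0

    def test_cross_partition_hand_value(self):
        # {ab|cd} vs {ac|bd}: I = 0, H = ln 2 each -> VI = 2 ln 2
        assert variation_of_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(
            2 * np.log(2)
        )

    def test_vi_against_single_cluster_is_entropy(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, 30)
            counts = np.bincount(x)
            p = counts[counts > 0] / 30
            h = -(p * np.log(p)).sum()
            assert variation_of_information(x, np.zeros(30)) == pytest.approx(h, abs=1e-12)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(100):
            a, b, c = (rng.integers(0, 4, 25) for _ in range(3))
            ab = variation_of_information(a, b)
            ba = variation_of_information(b, a)
            bc = variation_of_information(b, c)
            ac = variation_of_information(a, c)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert ac <= ab + bc + 1e-9

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            variation_of_information([0, 1], [0, 1, 2])


class TestSimilarityMatrix:
    def test_diagonal_and_affine_invariance(self, rng):
        Z = rng.normal(size=(5, 10))
        Z[3] = 2 * Z[0] + 3
        Z[4] = -(Z[1] - Z[1].mean()) + Z[1].mean()
        C = similarity_matrix(Z)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)
        assert C[0, 3] == pytest.approx(1.0)
        assert C[1, 4] == pytest.approx(-1.0)
        np.testing.assert_allclose(C, C.T, atol=1e-12)

    def test_zero_variance_row_warns_and_zeroes(self, rng):
        Z = rng.normal(size=(4, 6))
        Z[2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            C = similarity_matrix(Z)
        assert np.all(C[2, [0, 1, 3]] == 0.0)
        assert C[2, 2] == 1.0


class TestResidenceMatrix:
    def test_identical_labelings(self):
        res, ua, ub = residence_matrix([0, 0, 1, 1, 2], [0, 0, 1, 1, 2])
        np.testing.assert_allclose(res, 100 * np.eye(3))

    def test_rows_sum_to_hundred(self, rng):
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 3, 50)
        res, *_ = residence_matrix(a, b)
        np.testing.assert_allclose(res.sum(axis=1), 100.0, atol=1e-9)

    def test_hand_counted_example(self):
        res, *_ = residence_matrix([1, 1, 2, 2], [1, 2, 2, 2])
        np.testing.assert_allclose(res, [[50.0, 50.0], [0.0, 100.0]])


class TestEmbed2d:
    def test_shape_and_determinism(self, rng):
        Z = rng.normal(size=(40, 8))
        a = embed_2d(Z, seed=3)
        b = embed_2d(Z, seed=3)
        assert a.shape == (40, 2)
        np.testing.assert_array_equal(a, b)

    def test_planted_clusters_stay_separated(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(1)
        labels = np.arange(60) % 2
        Z = rng.normal(size=(60, 10)) + labels[:, None] * 10.0
        coords = embed_2d(Z, seed=1)
        assert silhouette_score(coords, labels) > 0

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            embed_2d(np.zeros((3, 4)), seed=0)
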