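import itertools
import math

import numpy as np
import pandas as pd
import pytest

import phageome.stats as st
from phageome.io import meta_to_frame
from phageome.simulate import SimConfig, simulate_cohort
from phageome.stats import DistanceMatrix


def random_log_table(rng, n_samples=10, n_features=20):
    return pd.DataFrame(
        rng.standard_normal((n_samples, n_features)),
        index=[f"s{i}" for i in range(n_samples)],
    )


class TestShannon:
    def test_uniform_is_log_k(self):
        assert st.shannon_diversity([0.25] * 4) == pytest.approx(math.log(4))

    def test_single_group_zero(self):
        assert st.shannon_diversity([5.0, 0.0, 0.0]) == 0.0

    def test_hand_computed_value(self):
        assert st.shannon_diversity([0.5, 0.3, 0.2]) == pytest.approx(1.02965, abs=1e-4)

    def test_bounded_by_log_k_iff_uniform(self, rng):
        x = rng.gamma(1.0, 1.0, size=8)
        h = st.shannon_diversity(x)
        assert h <= math.log(8) + 1e-12
        assert h < math.log(8) or np.allclose(x, x[0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            st.shannon_diversity([0.0, 0.0])


class TestLogTransform:
    def test_zero_with_pseudocount(self):
        out = st.log_transform(np.array([[0.0]]), 1e-6)
        assert out[0, 0] == pytest.approx(math.log(1e-6))

    def test_positive_table_plain_log(self):
        out = st.log_transform(np.array([[1.0, math.e]]), 0.0)
        np.testing.assert_allclose(out, [[0.0, 1.0]])

    def test_default_pseudocount_half_min_nonzero(self):
        table = np.array([[0.0, 0.4, 0.6]])
        out = st.log_transform(table)
        assert out[0, 0] == pytest.approx(math.log(0.2))

    def test_order_preserved(self, rng):
        x = rng.random(50)
        out = st.log_transform(x.reshape(1, -1), 1e-6).ravel()
        assert (np.argsort(out) == np.argsort(x)).all()

    def test_zeros_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            st.log_transform(np.array([[0.0, 1.0]]), 0.0)


class TestPearsonDistance:
    def test_identical_profiles_zero(self):
        tab = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3]], index=["a", "b"])
        d = st.pearson_distance(tab)
        assert d.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_two(self):
        tab = pd.DataFrame([[1.0, 2, 3], [3.0, 2, 1]], index=["a", "b"])
        d = st.pearson_distance(tab)
        assert d.d[0, 1] == pytest.approx(2.0)

    def test_matches_direct_correlation_oracle(self, rng):
        tab = random_log_table(rng)
        d = st.pearson_distance(tab)
        for i in range(len(tab)):
            for j in range(len(tab)):
                r = np.corrcoef(tab.iloc[i], tab.iloc[j])[0, 1]
                assert d.d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_sample_named(self):
        tab = pd.DataFrame([[1.0, 1, 1], [1.0, 2, 3]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            st.pearson_distance(tab)

    def test_affine_invariance(self, rng):
        """Positive per-sample affine transforms leave 1 - r unchanged."""
        tab = random_log_table(rng, 6, 15)
        scaled = tab.mul(rng.random(6) * 3 + 0.5, axis=0).add(rng.standard_normal(6), axis=0)
        d1, d2 = st.pearson_distance(tab), st.pearson_distance(scaled)
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-10)


class TestPcoa:
    def test_three_equidistant_points(self):
        d = DistanceMatrix(["a", "b", "c"], 1 - np.eye(3))
        _, eigvals, _ = st.pcoa(d)
        positive = eigvals[eigvals > 1e-10]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1])

    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = DistanceMatrix(list("abcd"), np.abs(x[:, None] - x[None, :]))
        _, eigvals, prop = st.pcoa(d)
        assert prop[0] == pytest.approx(1.0)

    def test_euclidean_distances_reconstructed(self, rng):
        X = rng.standard_normal((12, 4))
        from scipy.spatial.distance import squareform, pdist

        d = DistanceMatrix([f"s{i}" for i in range(12)], squareform(pdist(X)))
        coords, eigvals, _ = st.pcoa(d)
        rec = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(rec, d.d, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            st.pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_matches_reference_ordination(self, rng):
        """Cross-check eigenvalues against scikit-bio's PCoA."""
        import skbio

        tab = random_log_table(rng, 9, 12)
        d = st.pearson_distance(tab)
        _, eigvals, _ = st.pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.d, d.ids))
        np.testing.assert_allclose(
            eigvals[:4], ref.eigvals.to_numpy()[:4], atol=1e-8
        )


class TestPermanova:
    @staticmethod
    def _two_group_dist(rng, n=16, shift=0.0):
        X = rng.standard_normal((n, 10))
        X[n // 2 :] += shift
        tab = pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
        labels = pd.DataFrame(
            {"grp": ["a"] * (n // 2) + ["b"] * (n // 2)}, index=tab.index
        )
        return st.pearson_distance(tab), labels

    def test_perfect_separation(self, rng):
        """Identical within-group, distinct between-group profiles: R2 -> 1."""
        profile_a = rng.standard_normal(10)
        profile_b = -profile_a
        X = np.vstack([profile_a + 0.001 * rng.standard_normal(10) for _ in range(5)]
                      + [profile_b + 0.001 * rng.standard_normal(10) for _ in range(5)])
        tab = pd.DataFrame(X, index=[f"s{i}" for i in range(10)])
        labels = pd.DataFrame({"grp": ["a"] * 5 + ["b"] * 5}, index=tab.index)
        res = st.permanova(st.pearson_distance(tab), labels, n_perm=199, seed=1)
        assert res.loc["grp", "R2"] > 0.95
        assert res.loc["grp", "p"] == pytest.approx(1 / 200)

    def test_statistic_matches_group_sum_oracle(self, rng):
        """One-way F equals the classical within/between decomposition
        computed directly from pairwise distances."""
        d, labels = self._two_group_dist(rng, n=12, shift=0.8)
        res = st.permanova(d, labels, n_perm=99, seed=0)
        n = d.n
        ss_total = (d.d**2).sum() / (2 * n)
        ss_within = 0.0
        for g in ("a", "b"):
            idx = np.where(labels["grp"] == g)[0]
            sub = d.d[np.ix_(idx, idx)]
            ss_within += (sub**2).sum() / (2 * len(idx))
        ss_between = ss_total - ss_within
        f_oracle = (ss_between / 1) / (ss_within / (n - 2))
        assert res.loc["grp", "F"] == pytest.approx(f_oracle, rel=1e-9)
        assert res.loc["grp", "SS"] == pytest.approx(ss_between, rel=1e-9)

    def test_statistic_matches_skbio(self, rng):
        import skbio

        d, labels = self._two_group_dist(rng, n=14, shift=0.5)
        res = st.permanova(d, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.d, d.ids), labels["grp"].to_numpy(), permutations=99
        )
        assert res.loc["grp", "F"] == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_exact_p_by_exhaustive_enumeration(self, rng):
        """Sampled permutation p agrees with full enumeration at n=7."""
        X = rng.standard_normal((7, 6))
        X[4:] += 1.0
        tab = pd.DataFrame(X, index=[f"s{i}" for i in range(7)])
        labels = pd.DataFrame({"grp": list("aaaabbb")}, index=tab.index)
        d = st.pearson_distance(tab)
        res = st.permanova(d, labels, n_perm=999, seed=5)
        # oracle: enumerate all 7! label permutations
        G = st._gower_center(d.d)
        y = (labels["grp"] == "b").to_numpy(dtype=float)
        def f_stat(perm):
            X1 = np.column_stack([np.ones(7), y[list(perm)]])
            H = X1 @ np.linalg.pinv(X1)
            ss_a = np.sum(H * G)  # tr(H0 G) vanishes: G is doubly centred
            ss_r = np.sum((np.eye(7) - H) * G)
            return (ss_a / 1) / (ss_r / 5)
        f_obs = f_stat(range(7))
        count = sum(
            f_stat(perm) >= f_obs - 1e-12
            for perm in itertools.permutations(range(7))
        )
        exact_p = count / math.factorial(7)
        assert res.loc["grp", "p"] == pytest.approx(exact_p, abs=0.05)

    def test_reproducible_under_seed(self, rng):
        d, labels = self._two_group_dist(rng, shift=0.3)
        r1 = st.permanova(d, labels, n_perm=199, seed=42)
        r2 = st.permanova(d, labels, n_perm=199, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_sequential_r2_partitions_total(self, rng):
        vru, meta = simulate_cohort(SimConfig(seed=2, n_infants=16), family="vru")
        md = meta_to_frame(meta)
        d = st.pearson_distance(st.log_transform(vru.family_table()))
        res = st.permanova(d, md[["treatment", "delivery", "age_months"]],
                           n_perm=99, seed=0)
        assert res["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_confounded_factor_rejected(self, rng):
        d, labels = self._two_group_dist(rng)
        labels["grp"] = [f"level{i}" for i in range(d.n)]
        with pytest.raises(ValueError, match="confounded"):
            st.permanova(d, labels, n_perm=99, seed=0)


class TestAbundanceLmm:
    def test_parameter_recovery(self):
        cfg = SimConfig(seed=11, n_infants=40, samples_per_infant=10,
                        effect_sizes={"treatment": 0.8},
                        random_intercept_sd=0.5, residual_sd=0.5)
        y, meta = simulate_cohort(cfg, family="gaussian")
        res = st.fit_abundance_lmm(y, meta_to_frame(meta), ("treatment",))
        est, se, p = res.coefficients["treatment[PE]"]
        assert est == pytest.approx(0.8, abs=0.15)
        assert p < 0.001
        assert res.converged

    def test_zero_random_variance_matches_ols(self):
        """With no infant effect the fixed estimates equal plain OLS."""
        import statsmodels.api as sm

        cfg = SimConfig(seed=21, n_infants=20, samples_per_infant=8,
                        effect_sizes={"treatment": 0.5},
                        random_intercept_sd=0.0, residual_sd=0.4)
        y, meta = simulate_cohort(cfg, family="gaussian")
        md = meta_to_frame(meta)
        res = st.fit_abundance_lmm(y, md, ("treatment",))
        X = st.build_design(md, ("treatment",))
        ols = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        assert res.coefficients["treatment[PE]"][0] == pytest.approx(
            ols.params[1], abs=0.02
        )

    def test_null_effect_small_estimate(self):
        cfg = SimConfig(seed=31, n_infants=40, samples_per_infant=10,
                        random_intercept_sd=0.5, residual_sd=0.5)
        y, meta = simulate_cohort(cfg, family="gaussian")
        res = st.fit_abundance_lmm(y, meta_to_frame(meta), ("treatment",))
        assert abs(res.coefficients["treatment[PE]"][0]) < 0.2


class TestPresenceGlmm:
    def test_parameter_recovery(self):
        cfg = SimConfig(seed=12, n_infants=40, samples_per_infant=10,
                        effect_sizes={"age": 1.0}, random_intercept_sd=0.5)
        y, meta = simulate_cohort(cfg, family="binomial")
        res = st.fit_presence_glmm(y, meta_to_frame(meta))
        est, se, p = res.coefficients["age[12]"]
        assert est == pytest.approx(1.0, abs=0.35)
        assert res.converged

    def test_constant_response_rejected(self):
        cfg = SimConfig(seed=13)
        y, meta = simulate_cohort(cfg, family="binomial")
        y[:] = 1
        with pytest.raises(ValueError, match="constant|classes"):
            st.fit_presence_glmm(y, meta_to_frame(meta))

    def test_screen_applies_bh_within_term(self, rng):
        cfg = SimConfig(seed=14, n_infants=20, samples_per_infant=8)
        vru, meta = simulate_cohort(cfg, family="vru")
        md = meta_to_frame(meta)
        presence = (vru.family_table() > np.quantile(vru.family_table(), 0.5)).astype(int)
        screen = st.screen_presence_glmm(presence, md, ("treatment",))
        if not screen.empty:
            assert (screen["p_bh"] >= screen["p"] - 1e-12).all()
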