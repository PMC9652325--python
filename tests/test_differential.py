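"""The Mahalanobis machinery: distances, weights, MCD, two-pass, FDR, labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from abcompare.differential import (
    DifferentialCompartments,
    MDConfig,
    adjust_pvalues,
    chi2_pvalues,
    classify_transitions,
    mahalanobis,
    pairwise_distances,
    replicate_covariate,
    robust_inverse_covariance,
    two_pass_md,
    weighted_centers,
)
from abcompare.errors import ConfigError, NumericError


def brute_quadratic(dev, sigma_inv):
    return np.array([row @ sigma_inv @ row for row in np.atleast_2d(dev)])


class TestPairwiseDistances:
    def test_two_samples_symmetric(self):
        d, z, w = pairwise_distances(np.array([[1.0, 3.0], [0.0, 0.5]]))
        np.testing.assert_allclose(d[0], [2.0, 2.0])
        np.testing.assert_allclose(d[:, 0], d[:, 1])

    def test_three_sample_hand_oracle(self):
        # scores (0, 1, 2): d = (sqrt5/2, sqrt2/2, sqrt5/2)
        d, _, _ = pairwise_distances(np.array([[0.0, 1.0, 2.0], [0, 0, 0]]))
        np.testing.assert_allclose(
            d[0], [np.sqrt(5) / 2, np.sqrt(2) / 2, np.sqrt(5) / 2]
        )

    def test_mean_distance_bin_gets_half_weight(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=(501, 2))
        d, z, w = pairwise_distances(q)
        i = np.argmin(np.abs(z).max(axis=1))
        assert w[i] == pytest.approx(stats.norm.cdf(z[i].max()), abs=1e-12)
        assert abs(w[i] - 0.5) < 0.05

    def test_degenerate_spread_warns_and_zeroes(self):
        q = np.tile([[0.0, 1.0]], (10, 1))
        with pytest.warns(UserWarning):
            _, z, w = pairwise_distances(q)
        np.testing.assert_allclose(z, 0.0)
        np.testing.assert_allclose(w, 0.5)


class TestWeightedCenters:
    def test_distant_mode_deviation_grows_with_weight(self):
        q = np.array([[2.0, -2.0]])
        dev_hi = q - weighted_centers(q, np.array([0.99]))
        dev_lo = q - weighted_centers(q, np.array([0.2]))
        assert np.linalg.norm(dev_hi) > np.linalg.norm(dev_lo)

    def test_verbatim_full_weight_zero_deviation(self):
        # mu_i = s_i when w = 1, forcing MD = 0
        q = np.array([[3.0, -1.0]])
        mu = weighted_centers(q, np.array([1.0]), mode="verbatim")
        np.testing.assert_allclose(q - mu, 0.0)


class TestRobustCovariance:
    def test_clean_data_matches_classical(self):
        rng = np.random.default_rng(1)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=5000)
        inv_mcd = robust_inverse_covariance(x, MDConfig(random_state=0))
        inv_cls = np.linalg.inv(np.cov(x, rowvar=False))
        np.testing.assert_allclose(inv_mcd, inv_cls, rtol=0.10)

    def test_resists_gross_outliers(self):
        rng = np.random.default_rng(2)
        cov = np.eye(2)
        x = rng.multivariate_normal([0, 0], cov, size=2000)
        x[:200] = rng.normal(20, 1, size=(200, 2))  # 10% gross outliers
        mcd_cov = np.linalg.inv(robust_inverse_covariance(x, MDConfig(random_state=0)))
        cls_cov = np.cov(x, rowvar=False)
        err_mcd = np.linalg.norm(mcd_cov - cov)
        err_cls = np.linalg.norm(cls_cov - cov)
        assert err_mcd < err_cls

    def test_identical_columns_rejected(self):
        x = np.random.default_rng(3).normal(size=(100, 1))
        with pytest.raises(NumericError, match="collinear"):
            robust_inverse_covariance(np.column_stack([x, x]), MDConfig())

    def test_too_few_rows_rejected(self):
        with pytest.raises(NumericError):
            robust_inverse_covariance(np.zeros((8, 2)), MDConfig())


class TestMahalanobis:
    def test_zero_at_center(self):
        sinv = np.eye(3)
        s = np.array([[1.0, 2.0, 3.0]])
        assert mahalanobis(s, s, sinv)[0] == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=(50, 4))
        mu = rng.normal(size=(50, 4))
        a = rng.normal(size=(4, 4))
        sinv = a @ a.T + np.eye(4)
        np.testing.assert_allclose(
            mahalanobis(s, mu, sinv), brute_quadratic(s - mu, sinv), atol=1e-8
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(NumericError):
            mahalanobis(np.array([[np.nan, 1.0]]), np.zeros((1, 2)), np.eye(2))

    def test_affine_invariance(self):
        """MD is invariant under invertible affine recoding of the scores."""
        rng = np.random.default_rng(5)
        s = rng.normal(size=(40, 3))
        mu = rng.normal(size=(40, 3))
        cov = np.cov(rng.normal(size=(500, 3)), rowvar=False)
        a = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        md1 = mahalanobis(s, mu, np.linalg.inv(cov))
        md2 = mahalanobis(s @ a.T, mu @ a.T, np.linalg.inv(a @ cov @ a.T))
        np.testing.assert_allclose(md1, md2, atol=1e-6)


class TestTwoPass:
    def test_chi2_survival_closed_forms(self):
        assert chi2_pvalues(np.array([0.0]), 2)[0] == 1.0
        assert chi2_pvalues(np.array([2.0]), 2)[0] == pytest.approx(np.exp(-1))

    def test_planted_outlier_md_increases_in_pass_two(self):
        """An extreme bin inflates the pass-1 covariance; after its removal
        the refit covariance shrinks and its distance strictly grows."""
        rng = np.random.default_rng(6)
        q = rng.multivariate_normal([0, 0], [[1.0, 0.9], [0.9, 1.0]], size=400)
        q[0] = [6.0, -6.0]
        res = two_pass_md(q, MDConfig(random_state=0))
        assert not res["kept"][0]
        assert res["md"][0] > res["md_pass1"][0]

    def test_pvalues_match_md(self):
        rng = np.random.default_rng(7)
        q = rng.multivariate_normal([0, 0], [[1.0, 0.6], [0.6, 1.0]], size=300)
        res = two_pass_md(q, MDConfig(random_state=0))
        np.testing.assert_allclose(res["p"], stats.chi2.sf(res["md"], 2))


class TestReplicateCovariate:
    def test_all_zero_scores_give_zero(self):
        r = np.zeros((60, 4))
        r += np.random.default_rng(8).normal(size=(60, 4))  # background
        r[0] = 0.0
        md = replicate_covariate(r, ["A", "A", "B", "B"], MDConfig(random_state=0))
        assert md[0] == pytest.approx(0.0, abs=1e-12)

    def test_diag_masking_equals_componentwise_sum(self):
        rng = np.random.default_rng(9)
        r = rng.normal(size=(80, 4))
        samples = ["A", "A", "B", "B"]
        cfg = MDConfig(random_state=0)
        md = replicate_covariate(r, samples, cfg)
        # brute-force evaluation of the diagonal-masked quadratic form
        d = np.empty_like(r)
        for sample in ("A", "B"):
            cols = [j for j, s in enumerate(samples) if s == sample]
            for k, j in enumerate(cols):
                d[:, j] = np.sqrt(((r[:, cols] - r[:, [j]]) ** 2).sum(1)) / (len(cols) - 1)
        z = (d - d.mean(0)) / d.std(0)
        srw = stats.norm.cdf(z.max(1))
        dev = r * srw[:, None]
        sinv = robust_inverse_covariance(r, cfg)
        expected = (dev**2 * np.diag(sinv)).sum(1)
        np.testing.assert_allclose(md, expected, atol=1e-8)

    def test_requires_two_replicates_per_sample(self):
        with pytest.raises(ConfigError):
            replicate_covariate(np.zeros((30, 3)), ["A", "A", "B"], MDConfig())


class TestAdjustPvalues:
    def test_bh_hand_example(self):
        p = np.array([0.01, 0.03, 0.04, 0.5])
        np.testing.assert_allclose(
            adjust_pvalues(p), [0.04, 0.0533333, 0.0533333, 0.5], atol=1e-6
        )

    def test_constant_covariate_equals_plain_bh(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            adjust_pvalues(p, np.ones(200), MDConfig(random_state=0)),
            adjust_pvalues(p),
        )

    def test_informative_covariate_not_fewer_discoveries(self):
        rng = np.random.default_rng(11)
        n = 2000
        covariate = rng.uniform(size=n)
        p = rng.uniform(size=n)
        signal = covariate < 0.2  # signal concentrated in low-covariate stratum
        p[signal] = rng.beta(0.1, 10, size=signal.sum())
        cfg = MDConfig(random_state=0)
        n_weighted = (adjust_pvalues(p, covariate, cfg) < 0.1).sum()
        n_plain = (adjust_pvalues(p) < 0.1).sum()
        assert n_weighted >= n_plain

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=500)
        cov = rng.uniform(size=500)
        adj = adjust_pvalues(p, cov, MDConfig(random_state=0))
        assert (adj >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(NumericError):
            adjust_pvalues(np.array([0.5, 1.5]))


class TestClassifyTransitions:
    @pytest.mark.parametrize(
        "scores,label",
        [
            ((2.0, -1.0), "A->B"),
            ((-1.0, 2.0), "B->A"),
            ((2.0, 0.5), "sA->wA"),
            ((0.5, 2.0), "wA->sA"),
            ((-0.2, -1.5), "wB->sB"),
            ((-1.5, -0.2), "sB->wB"),
            ((0.0, -1.0), "A->B"),  # exact zero counts as A
        ],
    )
    def test_two_sample_labels(self, scores, label):
        assert classify_transitions(np.array([scores]))[0] == label

    def test_multi_sample_label(self):
        lab = classify_transitions(
            np.array([[2.0, 1.0, -3.0]]), ["ESC", "NPC", "CN"]
        )[0]
        assert lab == "AAB(max=CN)"


class TestNullCalibration:
    def test_chi2_uniform_under_known_covariance(self):
        """With the true covariance and center (no MCD, no weighting), the
        quadratic form is chi-square distributed and p-values are uniform."""
        rng = np.random.default_rng(13)
        cov = np.array([[1.0, 0.7], [0.7, 1.5]])
        x = rng.multivariate_normal([0, 0], cov, size=5000)
        md = mahalanobis(x, np.zeros_like(x), np.linalg.inv(cov))
        p = chi2_pvalues(md, 2)
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05


class TestEstimator:
    def test_masked_rows_propagate(self):
        rng = np.random.default_rng(14)
        x = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=200)
        x[5, 0] = np.nan
        est = DifferentialCompartments(random_state=0).fit(x)
        assert np.isnan(est.md_[5]) and est.mask_[5]
        assert np.isfinite(np.delete(est.md_, 5)).all()
        assert not est.significant_[5]

    def test_get_params_round_trip(self):
        est = DifferentialCompartments(fdr_threshold=0.05)
        params = est.get_params()
        assert params["fdr_threshold"] == 0.05
        est.set_params(weight_mode="verbatim")
        assert est.weight_mode == "verbatim"

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_md_nonnegative_and_p_valid(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=120)
        res = two_pass_md(q, MDConfig(random_state=0))
        assert (res["md"] >= 0).all()
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
        assert ((res["w"] > 0) & (res["w"] < 1)).all()
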