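"""Unit tests for detection filtering, adjustment, PC removal, normalization."""

import numpy as np
import pandas as pd
import pytest
from statistics import NormalDist

from statpgx.prep import (
    adjust_known_covariates,
    detect_expressed,
    make_delta,
    rank_normal_transform,
    remove_hidden_factors,
)

from conftest import make_paired_set


class TestDetectExpressed:
    def test_strict_threshold_on_mean_detection_p(self):
        dp = pd.DataFrame(
            {"a": [0.005, 0.04, 0.1], "b": [0.015, 0.06, 0.3]},
            index=["g1", "g2", "g3"],
        )  # means: 0.01, 0.05, 0.2
        assert detect_expressed(dp, 0.05) == {"g1"}

    @pytest.mark.parametrize("fill,expected_n", [(0.0, 3), (1.0, 0)])
    def test_degenerate_extremes(self, fill, expected_n):
        dp = pd.DataFrame(np.full((3, 4), fill), index=["g1", "g2", "g3"])
        assert len(detect_expressed(dp, 0.05)) == expected_n

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            detect_expressed(pd.DataFrame(), 0.05)


class TestAdjustKnownCovariates:
    def test_orthogonal_covariate_leaves_centered_input(self, rng):
        n = 8
        cov_vec = rng.normal(0, 1, n)
        cov_vec -= cov_vec.mean()
        expr = make_paired_set(rng, n_genes=5, n_subjects=n)
        expr.covariates = pd.DataFrame(
            {"x": np.tile(cov_vec, 2)}, index=expr.covariates.index
        )
        # make every gene orthogonal to the covariate within each arm
        for exposure in ("statin", "sham"):
            arm = expr.pairing.index[expr.pairing["exposure"] == exposure]
            Y = expr.intensities[arm].to_numpy()
            Y = Y - np.outer(Y @ cov_vec / (cov_vec @ cov_vec), cov_vec)
            expr.intensities[arm] = Y
        out = adjust_known_covariates(expr)
        for exposure in ("statin", "sham"):
            arm = expr.pairing.index[expr.pairing["exposure"] == exposure]
            Y = expr.intensities[arm].to_numpy()
            centered = Y - Y.mean(axis=1, keepdims=True)
            assert np.allclose(out.intensities[arm].to_numpy(), centered, atol=1e-9)

    def test_batch_shift_removed_exactly(self, rng):
        n = 10
        expr = make_paired_set(rng, n_genes=6, n_subjects=n)
        batch = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        expr.covariates = pd.DataFrame(
            {"batch": np.tile(batch, 2)}, index=expr.covariates.index
        )
        shift_cols = expr.covariates.index[expr.covariates["batch"] == "B"]
        expr.intensities[shift_cols] += 2.0
        out = adjust_known_covariates(expr)
        for exposure in ("statin", "sham"):
            arm = expr.pairing.index[expr.pairing["exposure"] == exposure]
            vals = out.intensities[arm]
            b = expr.covariates.loc[arm, "batch"]
            diff = vals.loc[:, (b == "A").values].mean(axis=1) - vals.loc[
                :, (b == "B").values
            ].mean(axis=1)
            assert np.abs(diff).max() < 1e-9

    def test_constant_covariate_raises_naming_column(self, rng):
        expr = make_paired_set(rng)
        expr.covariates = pd.DataFrame(
            {"age": 50.0, "flat": 1.0}, index=expr.covariates.index
        )
        with pytest.raises(ValueError, match="flat"):
            adjust_known_covariates(expr)

    def test_idempotent(self, rng):
        expr = make_paired_set(rng, n_genes=12, n_subjects=10)
        once = adjust_known_covariates(expr)
        twice = adjust_known_covariates(once)
        assert np.allclose(
            once.intensities.to_numpy(), twice.intensities.to_numpy(), atol=1e-9
        )

    def test_keep_arm_means_preserves_exposure_effect(self, rng):
        delta = np.full((5, 8), 1.5)
        expr = make_paired_set(rng, n_genes=5, n_subjects=8, delta=delta)
        out = adjust_known_covariates(expr, keep_arm_means=True)
        d = make_delta(out, normalize=False).values
        assert np.allclose(d.mean(axis=1), 1.5, atol=1e-9)


class TestRemoveHiddenFactors:
    def test_dominant_factor_removed(self, rng):
        n_g, n_s = 100, 40
        load = rng.normal(0, 2.0, n_g)
        score = rng.normal(0, 1, n_s)
        X = np.outer(load, score) + rng.normal(0, 0.5, (n_g, n_s))
        df = pd.DataFrame(X)
        Xc = X - X.mean(axis=1, keepdims=True)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert s[0] ** 2 / np.sum(s**2) > 0.5  # factor dominates
        out = remove_hidden_factors(df, 0.05).to_numpy()
        # variance fraction carried by the known factor direction collapses
        sc = (score - score.mean()) / np.linalg.norm(score - score.mean())
        frac_after = np.sum((out @ sc) ** 2) / np.sum(out**2)
        assert frac_after < 0.01

    def test_isotropic_noise_passthrough(self, rng):
        X = rng.normal(0, 1, (200, 50))
        Xc = X - X.mean(axis=1, keepdims=True)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert (s**2 / np.sum(s**2) < 0.05).all()  # no PC above threshold
        out = remove_hidden_factors(pd.DataFrame(X), 0.05)
        assert np.allclose(out.to_numpy(), Xc, atol=1e-12)

    def test_threshold_one_is_identity_on_centered(self, rng):
        X = rng.normal(0, 1, (30, 10))
        out = remove_hidden_factors(pd.DataFrame(X), 1.0)
        assert np.allclose(out.to_numpy(), X - X.mean(axis=1, keepdims=True))

    def test_never_increases_gene_variance(self, rng):
        X = rng.normal(0, 1, (50, 20)) + np.outer(rng.normal(0, 1, 50), rng.normal(0, 2, 20))
        before = pd.DataFrame(X)
        after = remove_hidden_factors(before, 0.05)
        v_before = (X - X.mean(axis=1, keepdims=True)).var(axis=1)
        assert (after.to_numpy().var(axis=1) <= v_before + 1e-12).all()


class TestRankNormalTransform:
    def test_median_of_odd_tiefree_vector_is_zero(self):
        out = rank_normal_transform([5.0, 1.0, 9.0, 3.0, 7.0])
        assert out[np.argsort([5.0, 1.0, 9.0, 3.0, 7.0])[2]] == pytest.approx(0.0)

    def test_monotone_map_preserves_order(self, rng):
        x = rng.normal(0, 1, 31)
        out = rank_normal_transform(x)
        assert (np.argsort(out) == np.argsort(x)).all()

    def test_expected_quantiles_n4(self):
        out = rank_normal_transform([10.0, 20.0, 30.0, 40.0])
        nd = NormalDist()  # independent inverse-normal implementation
        expected = [nd.inv_cdf(q) for q in (0.125, 0.375, 0.625, 0.875)]
        assert np.allclose(out, expected, atol=1e-12)

    def test_mean_zero_and_symmetric(self, rng):
        x = rng.normal(3, 2, 41)
        out = rank_normal_transform(x)
        assert abs(out.mean()) < 1e-9
        assert np.allclose(np.sort(out), -np.sort(out)[::-1], atol=1e-9)

    def test_all_tied_raises(self):
        with pytest.raises(ValueError, match="identical"):
            rank_normal_transform([2.0, 2.0, 2.0, 2.0])

    def test_ties_get_average_ranks(self):
        out = rank_normal_transform([1.0, 2.0, 2.0, 3.0])
        assert out[1] == pytest.approx(out[2])


class TestMakeDelta:
    def test_identical_arms_reported_degenerate(self, rng):
        expr = make_paired_set(rng, n_genes=4, n_subjects=5, delta=np.zeros((4, 5)))
        dm = make_delta(expr)
        assert set(dm.degenerate_genes) == {"g0", "g1", "g2", "g3"}
        assert dm.values.empty

    def test_too_few_subjects_raises(self, rng):
        expr = make_paired_set(rng, n_genes=4, n_subjects=2)
        with pytest.raises(ValueError):
            make_delta(expr)

    def test_subject_order_equivariance(self, rng):
        expr = make_paired_set(rng, n_genes=6, n_subjects=6)
        dm = make_delta(expr)
        shuffled_cols = list(expr.intensities.columns)[::-1]
        expr2 = make_paired_set(rng, n_genes=6, n_subjects=6)
        expr2.intensities = expr.intensities[shuffled_cols]
        expr2.detection_p = expr.detection_p[shuffled_cols]
        expr2.pairing = expr.pairing.loc[shuffled_cols]
        expr2.covariates = expr.covariates.loc[shuffled_cols]
        dm2 = make_delta(expr2)
        pd.testing.assert_frame_equal(dm.values, dm2.values)

    def test_raw_delta_is_statin_minus_sham(self, rng):
        delta = rng.normal(0, 1, (5, 6))
        expr = make_paired_set(rng, n_genes=5, n_subjects=6, delta=delta)
        dm = make_delta(expr, normalize=False)
        assert np.allclose(dm.values.to_numpy(), delta, atol=1e-12)
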