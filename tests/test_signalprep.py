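"""Preprocessing: standardization, plateau detection, features, PCA."""

import numpy as np
import pytest

from breathdx.signalprep import (
    build_feature_table,
    detect_end_tidal_plateau,
    extract_features,
    fit_pca,
    project,
    standardize,
)
from breathdx.synthcohort import CHANNELS, BreathRecord


def make_record(voc, co2=None, fs=25.0, label=0, subject="S0", rep=1):
    n = len(voc)
    if co2 is None:
        co2 = np.concatenate([np.linspace(0, 5, n // 4), np.full(n - n // 4, 5.0)])
    channels = {name: np.zeros(n) for name in CHANNELS}
    channels["voc_total"] = np.asarray(voc, dtype=float)
    channels["co2"] = np.asarray(co2, dtype=float)
    return BreathRecord(
        subject_id=subject, age_group="adult", label=label,
        replicate_index=rep, sampling_rate=fs, channels=channels,
    )


class TestStandardize:
    def test_zero_mean_unit_sd_by_definition(self):
        Z = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert abs(Z.mean()) <= 1e-9
        assert Z.std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_maps_to_zeros_with_warning(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            Z = standardize(X)
        np.testing.assert_array_equal(Z[:, 0], 0.0)

    def test_idempotent(self, rng):
        X = rng.normal(size=(20, 4)) * [1, 10, 100, 0.1]
        once = standardize(X)
        np.testing.assert_allclose(standardize(once), once, atol=1e-9)

    def test_preserves_shape_and_order(self, rng):
        X = rng.normal(size=(11, 3))
        Z = standardize(X)
        assert Z.shape == X.shape
        # ordering: the largest raw value per column stays the largest z-score
        assert np.all(np.argmax(Z, axis=0) == np.argmax(X, axis=0))

    def test_empty_and_single_sample_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.empty((0, 3)))
        with pytest.raises(ValueError):
            standardize(np.array([[1.0, 2.0]]))


class TestPlateauDetection:
    def test_square_capnogram_plateau_location_and_level(self):
        x = np.zeros(120)
        x[30:40] = np.linspace(0, 5, 10)
        x[40:81] = 5.0
        x[81:90] = np.linspace(5, 0, 9)
        plateau = detect_end_tidal_plateau(x, min_length=10, slope_tol=0.01)
        assert plateau is not None
        assert plateau.start_index <= 45 and plateau.end_index >= 75
        assert plateau.mean_level == pytest.approx(5.0, abs=0.05)

    def test_pure_ramp_has_no_plateau(self):
        ramp = np.linspace(0, 10, 200)
        assert detect_end_tidal_plateau(ramp, min_length=10, slope_tol=0.01) is None

    def test_min_length_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="min_length"):
            detect_end_tidal_plateau(np.zeros(20), min_length=30)


class TestFeatures:
    def test_gaussian_voc_width_equals_fwhm_in_seconds(self):
        fs = 25.0
        t = np.arange(1000) / fs
        sigma = 2.0
        voc = 2.0 * np.exp(-((t - 20.0) ** 2) / (2 * sigma**2))
        fv = extract_features(make_record(voc, fs=fs), plateau_fraction=0.5)
        fwhm = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert fv.voc_max == pytest.approx(2.0)
        assert fv.voc_plateau_width == pytest.approx(fwhm, rel=0.02)

    def test_all_zero_voc_gives_zero_max_and_width(self):
        fv = extract_features(make_record(np.zeros(200)))
        assert fv.voc_max == 0.0
        assert fv.voc_plateau_width == 0.0

    def test_doubling_voc_doubles_max_but_not_width(self, rng):
        t = np.arange(600) / 25.0
        voc = np.exp(-((t - 10) ** 2) / 8.0)
        f1 = extract_features(make_record(voc))
        f2 = extract_features(make_record(2 * voc))
        assert f2.voc_max == pytest.approx(2 * f1.voc_max)
        assert f2.voc_plateau_width == pytest.approx(f1.voc_plateau_width)

    def test_missing_channel_named_in_error(self):
        rec = make_record(np.ones(100))
        del rec.channels["voc_total"]
        with pytest.raises(ValueError, match="voc_total"):
            extract_features(rec)

    def test_feature_table_aggregates_replicates_by_median(self):
        recs = [
            make_record(np.full(100, v), subject="S1", rep=i + 1, label=1)
            for i, v in enumerate([1.0, 2.0, 50.0])
        ]
        table = build_feature_table(recs)
        assert len(table) == 1
        assert table.loc["S1", "voc_max"] == 2.0  # median, robust to the outlier
        assert table.loc["S1", "label"] == 1


class TestPCA:
    def test_perfectly_correlated_features_need_one_component(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([x, 3 * x])
        pca = fit_pca(standardize(X), variance_target=0.95)
        assert pca.n_components_kept == 1
        assert pca.explained_variance_ratio[0] >= 0.999

    def test_isotropic_data_splits_variance_evenly(self, rng):
        X = rng.normal(size=(2000, 2))
        pca = fit_pca(standardize(X), variance_target=1.0)
        assert np.all(np.abs(pca.explained_variance_ratio - 0.5) < 0.1)

    def test_loadings_orthonormal_and_ratios_sorted(self, rng):
        X = rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6))
        pca = fit_pca(standardize(X), variance_target=1.0)
        gram = pca.loadings @ pca.loadings.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        evr = pca.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_full_reconstruction_reproduces_centered_data(self, rng):
        X = standardize(rng.normal(size=(40, 5)))
        pca = fit_pca(X, variance_target=1.0)
        recon = pca.scores @ pca.loadings + pca.mean
        np.testing.assert_allclose(recon, X, atol=1e-6)

    def test_project_matches_stored_scores_and_centers_mean(self, rng):
        X = standardize(rng.normal(size=(30, 4)))
        pca = fit_pca(X, variance_target=0.99)
        np.testing.assert_allclose(project(pca, X), pca.scores, atol=1e-9)
        np.testing.assert_allclose(project(pca, pca.mean[None, :]), 0.0, atol=1e-9)

    def test_scores_have_zero_mean_per_component(self, rng):
        pca = fit_pca(standardize(rng.normal(size=(60, 5))))
        assert np.all(np.abs(pca.scores.mean(axis=0)) <= 1e-8)

    def test_projection_is_isometric_within_kept_subspace(self, rng):
        X = standardize(rng.normal(size=(25, 3)))
        pca = fit_pca(X, variance_target=1.0)
        # rotate samples within the kept subspace, applied consistently
        theta = 0.7
        R3 = pca.loadings.T @ _rotation(len(pca.loadings), theta) @ pca.loadings
        S1, S2 = project(pca, X), project(pca, (X - pca.mean) @ R3 + pca.mean)
        d1 = np.linalg.norm(S1[:, None] - S1[None], axis=-1)
        d2 = np.linalg.norm(S2[:, None] - S2[None], axis=-1)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_invalid_variance_target_rejected(self, rng):
        with pytest.raises(ValueError, match="variance_target"):
            fit_pca(rng.normal(size=(10, 2)), variance_target=1.5)

    def test_dimension_mismatch_rejected(self, rng):
        pca = fit_pca(standardize(rng.normal(size=(10, 3))))
        with pytest.raises(ValueError, match="feature count"):
            project(pca, np.zeros((2, 5)))


def _rotation(k, theta):
    R = np.eye(k)
    if k >= 2:
        R[0, 0] = R[1, 1] = np.cos(theta)
        R[0, 1], R[1, 0] = -np.sin(theta), np.sin(theta)
    return R


class TestCohortSeparability:
    def test_two_component_scores_separate_classes(self, small_cohort):
        """Class centroids in the leading PCA plane sit more than one pooled
        SD apart on a nonzero-effect cohort."""
        table = build_feature_table(small_cohort)
        y = table["label"].to_numpy()
        X = standardize(table.drop(columns="label").to_numpy())
        pca = fit_pca(X, n_components=2)
        S = pca.scores
        mu1, mu0 = S[y == 1].mean(axis=0), S[y == 0].mean(axis=0)
        pooled_sd = np.sqrt(0.5 * (S[y == 1].var(axis=0) + S[y == 0].var(axis=0))).mean()
        assert np.linalg.norm(mu1 - mu0) > pooled_sd
        # linear separability of >= 80% of subjects along the centroid axis
        axis = (mu1 - mu0) / np.linalg.norm(mu1 - mu0)
        proj = S @ axis
        threshold = (proj[y == 1].mean() + proj[y == 0].mean()) / 2
        correct = ((proj > threshold).astype(int) == y).mean()
        assert correct >= 0.8
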