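import numpy as np
import pytest
from sklearn.base import clone
from sklearn.model_selection import cross_val_score

import pinglab as pl
from pinglab.decoding import MahalanobisRDFDecoder, mahalanobis_rdf, vector_strength


class TestVectorStrength:
    def test_flat_profile_gives_zero(self):
        bins = np.arange(0, 360, 45.0)
        assert vector_strength(np.ones(8), bins) == pytest.approx(0.0)

    def test_planted_cosine_profiles(self):
        # -cos profile (distance grows with angular difference): exactly +0.5
        bins = np.arange(0, 360, 45.0)
        prof = -np.cos(np.deg2rad(bins))
        assert vector_strength(prof, bins) == pytest.approx(0.5, abs=1e-12)
        assert vector_strength(-prof, bins) == pytest.approx(-0.5, abs=1e-12)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="at least 2 bins"):
            vector_strength(np.ones(1), np.array([0.0]))


def _gaussian_classes(rng, n_per, means, cov_chol):
    X, y = [], []
    for ang, mu in means.items():
        pts = rng.standard_normal((n_per, len(mu))) @ cov_chol.T + mu
        X.append(pts)
        y.extend([ang] * n_per)
    return np.vstack(X), np.array(y)


class TestMahalanobisRDF:
    def test_separated_classes_are_closer_to_their_own_mean(self, rng):
        means = {0.0: [4, 0], 45.0: [0, 4], 90.0: [-4, 0], 135.0: [0, -4]}
        X, y = _gaussian_classes(rng, 40, means, np.eye(2))
        prof, bins = mahalanobis_rdf(X, y, n_folds=4, shrinkage=0.1, seed=0)
        own = prof[:, 0]
        others = prof[:, 1:].mean(axis=1)
        assert np.mean(own < others) > 0.95

    def test_permuted_labels_give_flat_profile(self, rng):
        means = {0.0: [4, 0], 45.0: [0, 4], 90.0: [-4, 0], 135.0: [0, -4]}
        X, y = _gaussian_classes(rng, 40, means, np.eye(2))
        yp = rng.permutation(y)
        prof, bins = mahalanobis_rdf(X, yp, n_folds=4, shrinkage=0.1, seed=0)
        vs = vector_strength(prof, bins, axis=1)
        # chance level: mean strength within ~3 SEM of zero
        sem = vs.std(ddof=1) / np.sqrt(len(vs))
        assert abs(vs.mean()) < 3 * sem + 1e-12

    def test_affine_invariance_as_shrinkage_vanishes(self, rng):
        # invertible channel mixing must leave profiles unchanged when the
        # covariance is unregularised (6-channel fixture)
        angles = np.arange(0, 180, 30.0)
        means = {a: rng.standard_normal(6) for a in angles}
        X, y = _gaussian_classes(rng, 32, means, np.linalg.cholesky(
            0.5 * np.eye(6) + 0.1))
        A = rng.standard_normal((6, 6)) + 2 * np.eye(6)
        p1, _ = mahalanobis_rdf(X, y, n_folds=4, shrinkage=0.0, seed=1)
        p2, _ = mahalanobis_rdf(X @ A.T, y, n_folds=4, shrinkage=0.0, seed=1)
        assert np.max(np.abs(p1 - p2)) < 1e-6

    def test_errors_on_small_classes_and_single_label(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="distinct labels"):
            mahalanobis_rdf(X, np.zeros(10))
        y = np.repeat([0.0, 90.0], 5)
        with pytest.raises(ValueError, match="n_folds"):
            mahalanobis_rdf(X, y, n_folds=8)

    def test_two_condition_reduction_uses_own_vs_cross_bins(self, rng):
        means = {0.0: [3, 0], 45.0: [-3, 0]}
        X, y = _gaussian_classes(rng, 24, means, np.eye(2))
        prof, bins = mahalanobis_rdf(X, y, n_folds=4, shrinkage=0.1, seed=0)
        assert np.allclose(bins, [0.0, 180.0])
        # cross-condition distance exceeds own-condition distance
        assert (prof[:, 1] - prof[:, 0]).mean() > 0


class TestDecodeTimecourse:
    def test_tuned_data_decodes_positive_in_waveform_window(self, oriented_epochs):
        dt = pl.decode_timecourse(oriented_epochs, window=(0.15, 0.35),
                                  shrinkage=0.2, seed=0)
        assert dt.strength.mean() > 0.05

    def test_null_data_centered_at_chance(self, null_epochs):
        dt = pl.decode_timecourse(null_epochs, window=(0.15, 0.35),
                                  shrinkage=0.2, seed=0)
        null = pl.shuffle_null(null_epochs, n_shuffles=60, seed=1,
                               window=(0.15, 0.35), shrinkage=0.2)
        lo, hi = np.quantile(null.strengths.mean(axis=1), [0.025, 0.975])
        assert lo < dt.strength.mean() < hi

    def test_strength_nondecreasing_in_tuning_gain(self, small_leadfield):
        from pinglab.synth import NoiseModel
        noise = NoiseModel(0.5, (0.55, 0.7), 0.0)
        means = []
        for gain in [0.0, 0.4, 0.8]:
            e = pl.simulate_oriented_trials(
                96, tuning_gain=gain, noise=noise, lf=small_leadfield,
                duration=0.6, srate=250, seed=11)
            dt = pl.decode_timecourse(e, window=(0.15, 0.35), shrinkage=0.2,
                                      seed=0)
            means.append(dt.strength.mean())
        assert means[0] < means[1] < means[2]

    def test_unknown_channel_raises_with_available_labels(self, oriented_epochs):
        with pytest.raises(KeyError, match="available"):
            pl.decode_timecourse(oriented_epochs, channels=["Oz"])

    def test_shuffle_null_reproducible_and_unbiased(self, oriented_epochs):
        kw = dict(window=(0.15, 0.3), shrinkage=0.2, decimate=4)
        n1 = pl.shuffle_null(oriented_epochs, n_shuffles=20, seed=5, **kw)
        n2 = pl.shuffle_null(oriented_epochs, n_shuffles=20, seed=5, **kw)
        assert np.array_equal(n1.strengths, n2.strengths)
        m = n1.strengths.mean()
        sem = n1.strengths.mean(axis=1).std(ddof=1) / np.sqrt(n1.n_shuffles)
        assert abs(m) < 3 * sem + 1e-12

    def test_alpha_front_end_decodes_amplitude_modulated_tuning(self, small_leadfield):
        # tuned 10 Hz oscillation: voltage phase scrambles the mean pattern
        # little, but alpha power carries the orientation cleanly
        rng = np.random.default_rng(2)
        n, srate, dur = 96, 250.0, 0.8
        t = np.arange(int(dur * srate)) / srate
        oris = (np.arange(n) % 4) * 45.0
        phase = np.deg2rad(2 * oris)
        amps = np.stack([1 + 0.8 * np.cos(phase), 1 + 0.8 * np.sin(phase)], 1)
        carrier = np.sin(2 * np.pi * 10.0 * t)
        env = np.exp(-0.5 * ((t - 0.4) / 0.12) ** 2)
        src = amps[:, :, None] * (carrier * env)[None, None, :]
        data = np.einsum("nst,sc->nct", src, small_leadfield.matrix)
        data += 0.3 * rng.standard_normal(data.shape)
        import pandas as pd
        e = pl.EpochSet(data, srate, 0.0, list(small_leadfield.channel_labels),
                        pd.DataFrame({"orientation": oris}))
        dt = pl.decode_timecourse(e, signal="alpha", window=(0.3, 0.5),
                                  shrinkage=0.2, seed=0)
        assert dt.strength.mean() > 0.05


class TestSklearnEstimator:
    def test_params_clone_and_fitted_attributes(self, rng):
        est = MahalanobisRDFDecoder(shrinkage=0.3)
        assert clone(est).get_params() == {"shrinkage": 0.3}
        X = rng.standard_normal((40, 4))
        y = np.repeat(np.arange(0, 180, 45.0), 10)
        est.fit(X, y)
        assert est.means_.shape == (4, 4)
        assert est.inv_cov_.shape == (4, 4)
        assert est.transform(X).shape == (40, 4)

    def test_cross_val_score_positive_on_tuned_patterns(self, rng):
        angles = np.arange(0, 180, 45.0)
        phase = np.deg2rad(2 * angles)
        mean_map = {a: 3 * np.array([np.cos(p), np.sin(p), 0.0])
                    for a, p in zip(angles, phase)}
        X, y = [], []
        for a in angles:
            X.append(mean_map[a] + rng.standard_normal((30, 3)))
            y.extend([a] * 30)
        X, y = np.vstack(X), np.array(y)
        scores = cross_val_score(MahalanobisRDFDecoder(shrinkage=0.1), X, y, cv=4)
        assert scores.mean() > 0.2
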