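import numpy as np
import pytest

from omfwls.omf import (DetectionMap, fit_classic_mf, omf_filter_vector,
                        rescale_scores, score_classic_mf, score_omf)
from omfwls.osp import build_projector, whitened_projector
from omfwls.synthetic_scene import SceneSpec, generate_scene
from omfwls.pipeline import expand_library, run_on_arrays
from omfwls.band_expansion import expand_bands
from omfwls.raster_io import flatten
from omfwls.whitening import fit_whitening, whiten_pixels


class TestClassicMF:
    def test_unit_gain_constraint_random_models(self, rng):
        """w^T (mu1 - mu0) = 1 holds by construction on 20 random fits."""
        for _ in range(20):
            B = int(rng.integers(2, 9))
            X = rng.normal(size=(B, 200)) * rng.uniform(0.5, 2)
            mu1 = rng.normal(size=B)
            model = fit_classic_mf(X, mu1[None, :])
            assert model.w @ (model.mu1 - model.mu0) == pytest.approx(1.0, abs=1e-8)

    def test_identity_covariance_hand_case(self, rng):
        """Sigma = I, mu0 = 0, mu1 = e1  =>  w = e1."""
        rng_local = np.random.default_rng(7)
        # large iid sample: mean ~0, covariance ~I; exact algebra checked via sigma
        X = rng_local.normal(size=(3, 200_000))
        model = fit_classic_mf(X, np.array([[1.0, 0.0, 0.0]]))
        assert np.allclose(model.w, [1.0, 0.0, 0.0], atol=0.02)

    def test_zero_contrast_rejected(self, rng):
        X = rng.normal(size=(3, 100))
        with pytest.raises(ValueError, match="contrast"):
            fit_classic_mf(X, X.mean(axis=1)[None, :])

    def test_needs_enough_background(self, rng):
        with pytest.raises(ValueError, match="background pixels"):
            fit_classic_mf(rng.normal(size=(4, 4)), np.ones((1, 4)))

    def test_scores_affine_with_anchor_points(self, rng):
        model = fit_classic_mf(rng.normal(size=(4, 500)), rng.normal(size=(2, 4)))
        mid = 0.5 * (model.mu0 + model.mu1)
        X = np.column_stack([model.mu1, model.mu0, mid])
        s = score_classic_mf(model, X).scores
        assert s[0] == pytest.approx(1.0, abs=1e-8)
        assert s[1] == pytest.approx(0.0, abs=1e-10)
        assert s[2] == pytest.approx(0.5, abs=1e-8)


class TestOmfScore:
    def test_filter_is_unit_norm(self, rng):
        d = rng.normal(size=6)
        proj = build_projector(rng.normal(size=(6, 2)))
        for flag in (True, False):
            assert np.linalg.norm(omf_filter_vector(d, proj, flag)) == pytest.approx(1.0)

    def test_degenerate_target_rejected(self):
        proj = build_projector(np.eye(3)[:, :1])
        with pytest.raises(ValueError, match="degenerate"):
            omf_filter_vector(np.array([5.0, 0.0, 0.0]), proj, project_target=True)

    def test_pure_target_scene_scores_target_norm(self, rng):
        """Every pixel = d, no background: the map is constant ||d_white||."""
        X = rng.normal(size=(5, 300))
        m = fit_whitening(X)
        d = rng.uniform(0.2, 1.0, size=5)
        proj, d_white = whitened_projector(m, d, None)
        scores = score_omf(m, d_white, proj, np.tile(d[:, None], 400)).scores
        assert np.allclose(scores, np.linalg.norm(d_white), atol=1e-8)

    def test_orthogonal_pixels_score_zero(self, rng):
        m = fit_whitening(rng.normal(size=(4, 200)))
        d_white = np.array([1.0, 0.0, 0.0, 0.0])
        proj = build_projector(np.empty((4, 0)))
        w = omf_filter_vector(d_white, proj)
        Xw = rng.normal(size=(4, 50))
        Xw[0] = 0.0  # orthogonal to w in whitened coordinates
        assert np.allclose(w @ Xw, 0.0, atol=1e-12)

    @pytest.mark.parametrize("project_target", [False, True])
    def test_brute_force_composition_oracle(self, rng, project_target):
        """score_omf == dot products through the explicit whitening matrix."""
        for _ in range(5):
            X = rng.normal(size=(8, 200)) * rng.uniform(0.5, 2, size=(8, 1))
            m = fit_whitening(X)
            d = rng.uniform(0.1, 1, size=8)
            U = rng.normal(size=(8, 2))
            proj, d_white = whitened_projector(m, d, U)
            got = score_omf(m, d_white, proj, X, project_target).scores

            # oracle: explicit matrices, no shared code path
            span = m.band_maxs - m.band_mins
            W_wh = np.diag(1.0 / np.sqrt(m.eigvals + m.epsilon)) @ m.eigvecs.T
            Xw = W_wh @ ((X - m.band_mins[:, None]) / span[:, None] - m.mean[:, None])
            dw = W_wh @ ((d - m.band_mins) / span - m.mean)
            Uw = W_wh @ ((U - m.band_mins[:, None]) / span[:, None] - m.mean[:, None])
            P = np.eye(8) - Uw @ np.linalg.inv(Uw.T @ Uw) @ Uw.T
            v = P @ dw if project_target else dw
            expected = (v / np.linalg.norm(v)) @ Xw
            assert np.allclose(got, expected, atol=1e-8)

    def test_contrast_positive_and_increasing_with_snr(self):
        """Two-class scenes: target scores exceed background, more so at high SNR.

        SNR is the nir class contrast over the per-band noise sigma (0.02);
        the ladder 5 / 10 / 20 comes from raising the target's nir reflectance.
        """
        contrasts = []
        for nir in (0.11, 0.21, 0.41):  # contrast/sigma = 5, 10, 20
            spectra = {"mangrove": (0.04, 0.06, 0.04, nir),
                       "water": (0.06, 0.05, 0.03, 0.01)}
            spec = SceneSpec(rows=96, cols=96, class_spectra=spectra,
                             noise_sigma=0.02, seed=5)
            cube, truth, lib = generate_scene(spec)
            work = expand_bands(cube)
            X, _ = flatten(work)
            m = fit_whitening(X)
            lib8 = expand_library(lib)
            proj, d_white = whitened_projector(m, lib8.target_mean,
                                               lib8.background_matrix)
            s = score_omf(m, d_white, proj, X).scores
            t = truth.data.ravel()
            pooled = 0.5 * (s[t].std() + s[~t].std())
            contrasts.append((s[t].mean() - s[~t].mean()) / pooled)
        assert contrasts[0] > 0
        assert contrasts[0] < contrasts[1] < contrasts[2]


class TestRescale:
    def test_full_range_scores_unchanged(self):
        s = np.array([[0.0, 0.25], [0.75, 1.0]])
        out = rescale_scores(DetectionMap(s))
        assert np.allclose(out.scores, s)
        assert out.scaling == (0.0, 1.0)

    def test_affine_invariance(self, rng):
        s = rng.normal(size=(6, 6))
        a = rescale_scores(DetectionMap(s)).scores
        b = rescale_scores(DetectionMap(3.7 * s - 12.0)).scores
        assert np.allclose(a, b, atol=1e-12)

    def test_constant_map_goes_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = rescale_scores(DetectionMap(np.full((3, 3), 2.0)))
        assert np.all(out.scores == 0.5)

    def test_nodata_pixels_ignored(self):
        s = np.array([[0.0, 100.0], [1.0, 2.0]])
        valid = np.array([[True, False], [True, True]])
        out = rescale_scores(DetectionMap(s, valid_mask=valid))
        assert out.scores[0, 1] == 0.0  # excluded pixel untouched
        assert out.scores[1, 1] == pytest.approx(1.0)  # max over valid only
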