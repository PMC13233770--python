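"""Elliptic Fourier descriptors and the eigenciona shape spaces."""

import numpy as np
import pytest

from cionakit.bodyplan import default_body_plan
from cionakit.efd import (ContourRejection, amplitude_spectrum,
                          choose_harmonics, contour_from_landmarks,
                          efd_coefficients, fit_shape_space, frame_spectra,
                          normalize_efd, project, reconstruct,
                          reconstruction_error)
from cionakit.synthetic import body_template


def _ellipse(a=2.0, b=1.0, n=360):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([a * np.cos(t), b * np.sin(t)], axis=1)


def _quadrature_oracle(pts, order, M=100_000):
    """Dense arc-length quadrature of the contour Fourier integrals."""
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)
    dt = np.linalg.norm(d, axis=1)
    T = dt.sum()
    tcum = np.concatenate([[0.0], np.cumsum(dt)])
    s = (np.arange(M) + 0.5) * T / M
    seg = np.searchsorted(tcum, s, side="right") - 1
    frac = (s - tcum[seg]) / dt[seg]
    xy = closed[seg] + frac[:, None] * d[seg]
    out = np.zeros((order, 4))
    for n in range(1, order + 1):
        cn = np.cos(2 * np.pi * n * s / T)
        sn = np.sin(2 * np.pi * n * s / T)
        out[n - 1] = [2 / M * np.sum(xy[:, 0] * cn),
                      2 / M * np.sum(xy[:, 0] * sn),
                      2 / M * np.sum(xy[:, 1] * cn),
                      2 / M * np.sum(xy[:, 1] * sn)]
    return out


class TestContour:
    def test_full_frame_accepted(self, plan):
        out = contour_from_landmarks(body_template(), plan)
        assert isinstance(out, np.ndarray) and out.shape == (18, 2)

    def test_nan_landmark_rejected_incomplete(self, plan):
        coords = body_template().copy()
        coords[5] = np.nan
        out = contour_from_landmarks(coords, plan, frame=7)
        assert isinstance(out, ContourRejection)
        assert out.reason == "incomplete" and out.frame == 7

    def test_bowtie_rejected_impossible(self, plan):
        coords = body_template().copy()
        # swap two distant outline points to force a self-intersection
        coords[[1, 10]] = coords[[10, 1]]
        out = contour_from_landmarks(coords, plan)
        assert isinstance(out, ContourRejection)
        assert out.reason == "geometrically impossible"


class TestCoefficients:
    def test_ellipse_first_harmonic(self):
        c = normalize_efd(efd_coefficients(_ellipse(), 5))
        a1, b1, c1, d1 = c[0]
        assert a1 == pytest.approx(1.0)
        assert abs(b1) < 1e-9 and abs(c1) < 1e-9
        assert d1 == pytest.approx(0.5, abs=0.1)  # semi-minor / semi-major
        amps = amplitude_spectrum(efd_coefficients(_ellipse(), 5), 5)
        assert amps[1] / amps[0] < 1e-3  # even harmonics vanish by symmetry

    def test_circle(self):
        circ = _ellipse(3.0, 3.0)
        c = efd_coefficients(circ, 10)
        amps = amplitude_spectrum(c, 10)
        assert amps[0] == pytest.approx(3.0 * np.sqrt(2), rel=1e-3)
        assert np.all(amps[1:] < 1e-3 * amps[0])
        assert reconstruction_error(circ, c) < 0.1

    def test_matches_quadrature_oracle_on_random_18gon(self):
        rng = np.random.default_rng(0)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 18))
        r = 1 + 0.3 * rng.standard_normal(18)
        poly = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        mine = efd_coefficients(poly, 10)
        oracle = _quadrature_oracle(poly, 10)
        assert np.max(np.abs(mine - oracle)) / np.max(np.abs(oracle)) < 1e-6

    def test_zero_perimeter_raises(self):
        with pytest.raises(ValueError):
            efd_coefficients(np.zeros((4, 2)), 5)


@pytest.fixture()
def outline(plan):
    return body_template()[list(plan.body_polygon)]


class TestNormalization:

    def test_scale_invariance(self, outline):
        n1 = normalize_efd(efd_coefficients(outline, 20))
        n2 = normalize_efd(efd_coefficients(outline * 2.0, 20))
        np.testing.assert_allclose(n1, n2, atol=1e-10)

    def test_rotation_invariant_amplitudes(self, outline):
        theta = np.deg2rad(37.0)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        a1 = amplitude_spectrum(normalize_efd(efd_coefficients(outline, 20)), 10)
        a2 = amplitude_spectrum(normalize_efd(
            efd_coefficients(outline @ R.T, 20)), 10)
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_translation_invariant_amplitudes(self, outline):
        a1 = amplitude_spectrum(efd_coefficients(outline, 20), 10)
        a2 = amplitude_spectrum(efd_coefficients(outline + [120, -40], 20), 10)
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_mirror_invariant_amplitudes(self, outline):
        mirrored = outline * [-1, 1]
        a1 = amplitude_spectrum(normalize_efd(efd_coefficients(outline, 20)), 10)
        a2 = amplitude_spectrum(normalize_efd(
            efd_coefficients(mirrored[::-1], 20)), 10)
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_start_vertex_invariant_amplitudes(self, outline):
        a1 = amplitude_spectrum(normalize_efd(efd_coefficients(outline, 20)), 10)
        a2 = amplitude_spectrum(normalize_efd(
            efd_coefficients(np.roll(outline, 5, axis=0), 20)), 10)
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_mirror_correction_sign_convention(self, outline):
        n = normalize_efd(efd_coefficients(outline, 20))
        assert n[0, 0] == pytest.approx(1.0)
        assert n[0, 3] >= 0


class TestHarmonicChoice:
    def test_circle_needs_one(self):
        spectra = amplitude_spectrum(efd_coefficients(_ellipse(2, 2), 30),
                                     30)[None, :]
        assert choose_harmonics(spectra) == 1

    def test_default_cohort_within_ten(self, plan, reference_recording):
        series, _ = reference_recording
        spectra, _, _ = frame_spectra(series.coords[::20], plan, order=30)
        assert choose_harmonics(spectra) <= 10

    def test_full_energy_requires_all(self):
        rng = np.random.default_rng(0)
        spectra = rng.uniform(0.5, 1.0, size=(5, 30))
        assert choose_harmonics(spectra, energy=1.0) == 30


class TestReconstruction:
    def test_template_error_below_one_percent(self, plan):
        outline = body_template()[list(plan.body_polygon)]
        c = efd_coefficients(outline, 30)
        assert reconstruction_error(outline, c, 30) < 1.0

    def test_error_monotone_in_harmonics(self, plan):
        outline = body_template()[list(plan.body_polygon)]
        c = efd_coefficients(outline, 30)
        errs = [reconstruction_error(outline, c, n) for n in range(1, 31)]
        # non-increasing up to Fourier partial-sum ripple (< 0.005% of perimeter)
        assert all(e2 <= e1 + 5e-3 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] < 0.2 * errs[0]

    def test_too_many_harmonics_raises(self):
        c = efd_coefficients(_ellipse(), 5)
        with pytest.raises(ValueError):
            reconstruct(c, 6)


class TestShapeSpace:
    def test_rank_two_data_retains_two(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 8))
        X = rng.standard_normal((2000, 2)) @ basis
        X += 1e-4 * rng.standard_normal(X.shape)
        space = fit_shape_space(X, 0.85)
        assert space.k == 2

    def test_isotropic_gaussian_needs_nine(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20000, 10))
        assert fit_shape_space(X, 0.85).k == 9

    def test_full_reprojection_identity(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((500, 6)) * rng.uniform(0.5, 2, 6)
        space = fit_shape_space(X, 0.85)
        Z = (X - space.mean) / space.scale
        scores = Z @ space.loadings.T
        np.testing.assert_allclose(scores @ space.loadings, Z, atol=1e-8)

    def test_loadings_orthonormal_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((800, 7))
        space = fit_shape_space(X, 0.85)
        gram = space.loadings @ space.loadings.T
        np.testing.assert_allclose(gram, np.eye(7), atol=1e-8)
        assert space.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(space.explained_variance_fraction) <= 1e-12)

    def test_projecting_training_mean_gives_zero(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((300, 5)) + 10
        space = fit_shape_space(X, 0.85)
        scores = project(X.mean(axis=0)[None, :], space)
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)

    def test_component_variance_ordering(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((2000, 6)) * [5, 4, 3, 2, 1, 0.5]
        space = fit_shape_space(X, 0.99)
        scores = project(X, space, n_components=3)
        v = scores.var(axis=0)
        assert v[0] >= v[1] >= v[2]

    def test_feature_mismatch_raises(self):
        rng = np.random.default_rng(6)
        space = fit_shape_space(rng.standard_normal((100, 5)), 0.85)
        with pytest.raises(ValueError):
            project(rng.standard_normal((10, 7)), space)


class TestModeRecovery:
    def test_latent_modes_recovered_in_score_subspace(self, plan):
        """Identifiability cohort: EC scores recover the latent-mode subspace.

        With spectrally orthogonalized latent modes, the leading canonical
        correlations between the five EC score trajectories and the true
        mode-weight trajectories are near 1, and the two dominant modes
        align with individual components.  (Full per-mode alignment is not
        identifiable: PCA recovers the subspace only up to rotation.)
        """
        from scipy.optimize import linear_sum_assignment
        from sklearn.cross_decomposition import CCA
        from cionakit.synthetic import (SynthConfig, orthogonal_mode_fields,
                                        simulate_recording)

        F = orthogonal_mode_fields(plan)
        no_events = {"DPE": {"trunk": 0, "os": 0, "as": 0},
                     "SePE": {"trunk": 0, "os": 0, "as": 0}}
        cfg = SynthConfig(n_frames=9000, seed=7, noise_sd=0.5,
                          custom_mode_fields=F, event_amplitudes=no_events,
                          background_sd=(1.0, 0.7, 0.5, 0.35, 0.25),
                          background_clip=2.2, dropout_rate=0.0)
        series, truth = simulate_recording(cfg)
        spectra, frames, _ = frame_spectra(series.coords, plan, order=30,
                                           n_keep=10)
        space = fit_shape_space(spectra, 0.85)
        scores = project(spectra, space, n_components=5)
        W = truth.mode_weights[frames]

        cca = CCA(n_components=5, max_iter=2000).fit(scores, W)
        U, V = cca.transform(scores, W)
        cc = np.array([abs(np.corrcoef(U[:, i], V[:, i])[0, 1])
                       for i in range(5)])
        assert np.all(cc[:3] >= 0.9)

        C = np.corrcoef(np.hstack([scores, W]).T)[:5, 5:]
        ri, ci = linear_sum_assignment(-np.abs(C))
        matched = np.sort(np.abs(C[ri, ci]))[::-1]
        assert np.all(matched[:2] >= 0.8)
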