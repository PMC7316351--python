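"""Filtering, detection, sCMOS MLE fitting, CRLB, merging, rendering."""

import numpy as np
import pandas as pd
import pytest

from oracles import expected_patch, fisher_fd, weighted_box_mean_loops
from tricolo.localize import (FitResult, compute_crlb, detect_candidates,
                              fit_mle, fit_precision_distribution,
                              merge_blinks, render_image,
                              variance_weighted_box_filter)
from tricolo.simulate import CameraModel, EmissionTrain, render_frames

PIX = 110.0
SIG = 143.0  # PSF sigma in nm


def _render_patch(x_px, y_px, photons, bg, size=7, noise=False, seed=0):
    cam = CameraModel.uniform((size, size), pixel_size_nm=PIX, offset=0.0,
                              gain=1.0, readnoise_var=0.0, n_frames=1)
    tr = [EmissionTrain(0, 1, x_px * PIX, y_px * PIX, np.array([0]), photons)]
    f = render_frames(tr, cam, SIG, background_photons=bg, seed=seed,
                      poisson_noise=noise, read_noise=False)
    return f[0]


class TestBoxFilter:
    def test_uniform_variance_reduces_to_plain_box_mean(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 2, (16, 16))
        var = np.full_like(img, 3.0)
        out = variance_weighted_box_filter(img, var, psf_fwhm_nm=PIX, pixel_size_nm=PIX)
        from scipy import ndimage

        plain = img - ndimage.uniform_filter(img, size=5, mode="reflect")
        np.testing.assert_allclose(out, plain, atol=1e-9)

    def test_constant_image_gives_zero(self):
        img = np.full((12, 12), 7.0)
        var = np.linspace(1, 2, 144).reshape(12, 12)
        out = variance_weighted_box_filter(img, var, PIX, PIX)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(1)
        img = rng.normal(5, 1, (8, 8))
        var = np.where(rng.random((8, 8)) < 0.5, 2.0, 9.0)
        out = variance_weighted_box_filter(img, var, psf_fwhm_nm=PIX * 0.75,
                                           pixel_size_nm=PIX)  # box = 3
        expect = img - weighted_box_mean_loops(img, var, 3)
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_box_larger_than_frame_errors(self):
        with pytest.raises(ValueError):
            variance_weighted_box_filter(np.zeros((5, 5)), np.ones((5, 5)),
                                         psf_fwhm_nm=10 * PIX, pixel_size_nm=PIX)


class TestDetection:
    def test_empty_image_gives_no_candidates(self):
        assert len(detect_candidates(np.zeros((32, 32)))) == 0

    def test_single_bright_emitter_gives_one_candidate(self):
        patch = np.zeros((31, 31))
        patch[10:17, 10:17] = _render_patch(3.5, 3.5, 5000, 0)
        rng = np.random.default_rng(2)
        noisy = patch + rng.normal(0, 0.3, patch.shape)
        cands = detect_candidates(noisy, threshold_sd=4.0)
        assert len(cands) == 1
        assert tuple(cands[0]) == (13, 13)

    def test_high_snr_emitters_recovered(self):
        cam = CameraModel.uniform((64, 64), pixel_size_nm=PIX, offset=100.0,
                                  gain=2.0, readnoise_var=4.0, n_frames=1)
        rng = np.random.default_rng(3)
        pos = [(8 + 12 * i + rng.uniform(-2, 2), 8 + 12 * j + rng.uniform(-2, 2))
               for i in range(5) for j in range(5)]
        trains = [EmissionTrain(k, 1, x * PIX, y * PIX, np.array([0]), 1000.0)
                  for k, (x, y) in enumerate(pos)]
        frames = render_frames(trains, cam, SIG, background_photons=5.0, seed=4)
        q = (frames[0] - 100.0) / 2.0
        filt = variance_weighted_box_filter(q, np.full_like(q, 1.0), 2.355 * SIG, PIX)
        cands = detect_candidates(filt, 4.0)
        found = 0
        for x, y in pos:
            d = np.hypot(cands[:, 1] - x, cands[:, 0] - y)
            found += (d < 2.0).any()
        assert found >= 24  # 25 planted


class TestFullChain:
    def test_recovery_and_false_positive_rate_at_defaults(self):
        # filter + detect + fit recovers >=95% of well-separated 1000-photon
        # emitters with <2% false positives
        from tricolo.localize import localize_stack

        rng = np.random.default_rng(40)
        cam = CameraModel.uniform((64, 64), pixel_size_nm=PIX, offset=100.0,
                                  gain=2.0, readnoise_var=4.0, n_frames=4)
        truth = []
        trains = []
        k = 0
        for f in range(4):
            for i in range(5):
                for j in range(5):
                    x = (8 + 12 * i + rng.uniform(-2, 2)) * PIX
                    y = (8 + 12 * j + rng.uniform(-2, 2)) * PIX
                    truth.append((f, x, y))
                    trains.append(EmissionTrain(k, 1, x, y, np.array([f]), 1000.0))
                    k += 1
        frames = render_frames(trains, cam, SIG, background_photons=5.0, seed=41)
        tab = localize_stack(frames, cam, SIG)
        matched = 0
        false_pos = 0
        for row in tab.itertuples():
            d = min(np.hypot(row.x_nm - x, row.y_nm - y)
                    for f, x, y in truth if f == row.frame)
            if d < 150.0:
                matched += 1
            else:
                false_pos += 1
        found = 0
        for f, x, y in truth:
            sub = tab[tab.frame == f]
            found += bool(len(sub)) and \
                np.hypot(sub.x_nm - x, sub.y_nm - y).min() < 150.0
        assert found / len(truth) >= 0.95
        assert false_pos / max(len(tab), 1) < 0.02


class TestFitMLE:
    def test_symmetric_noise_free_fit_is_exact(self):
        patch = _render_patch(3.5, 3.5, 10_000, 2.0)
        fit = fit_mle(patch, np.zeros((7, 7)), SIG / PIX)
        x, y, n = fit.emitter(0)
        assert abs(x - 3.5) < 1e-3 and abs(y - 3.5) < 1e-3
        assert n == pytest.approx(10_000, rel=1e-3)
        assert fit.background == pytest.approx(2.0, rel=0.05)

    def test_off_center_noise_free_fit(self):
        patch = _render_patch(2.9, 4.2, 5000, 1.0)
        fit = fit_mle(patch, np.zeros((7, 7)), SIG / PIX)
        x, y, _ = fit.emitter(0)
        assert abs(x - 2.9) < 1e-3 and abs(y - 4.2) < 1e-3

    def test_rmse_tracks_crlb(self):
        # 200 noisy single-emitter patches at 1000 photons
        rng = np.random.default_rng(5)
        err, crlb = [], []
        var = np.full((7, 7), 4.0)  # photon-unit read-noise variance
        for i in range(200):
            x0, y0 = 3.5 + rng.uniform(-0.5, 0.5, 2)
            mu = expected_patch([x0, y0, 1000.0, 5.0], 7, SIG / PIX)
            patch = rng.poisson(mu) + rng.normal(0, 2.0, (7, 7))
            fit = fit_mle(patch, var, SIG / PIX)
            if not fit.converged or fit.crlb is None:
                continue
            x, y, _ = fit.emitter(0)
            err.append([(x - x0) * PIX, (y - y0) * PIX])
            crlb.append(fit.crlb[0, :2] * PIX)
        rmse = np.sqrt(np.mean(np.square(err)))
        mean_crlb = np.mean(crlb)
        assert 0.85 <= rmse / mean_crlb <= 1.25

    def test_two_emitter_model_selection(self):
        rng = np.random.default_rng(6)
        mu = (expected_patch([2.0, 3.5, 4000.0, 2.0], 7, SIG / PIX)
              + expected_patch([5.0, 3.5, 4000.0, 0.0], 7, SIG / PIX))
        patch = rng.poisson(mu).astype(float)
        fit = fit_mle(patch, np.zeros((7, 7)), SIG / PIX, max_emitters=2)
        assert fit.k == 2
        xs = sorted([fit.emitter(0)[0], fit.emitter(1)[0]])
        assert abs(xs[0] - 2.0) < 1.0 and abs(xs[1] - 5.0) < 1.0

    def test_single_emitter_not_overfit(self):
        rng = np.random.default_rng(7)
        mu = expected_patch([3.5, 3.5, 2000.0, 5.0], 7, SIG / PIX)
        k2 = sum(fit_mle(rng.poisson(mu).astype(float), np.zeros((7, 7)),
                         SIG / PIX, max_emitters=2).k == 2 for _ in range(20))
        assert k2 <= 2


class TestCRLB:
    def _crlb(self, photons, bg, var_level=0.0):
        params = np.array([3.5, 3.5, photons, bg])
        fit = FitResult(k=1, params=params, log_likelihood=0.0, converged=True)
        var = np.full((7, 7), var_level)
        crlb, singular = compute_crlb(fit, var, SIG / PIX)
        assert not singular
        return crlb[0]

    def test_quarter_photons_double_crlb(self):
        c1 = self._crlb(4000, 0.0)
        c2 = self._crlb(1000, 0.0)
        assert c2[0] / c1[0] == pytest.approx(2.0, rel=0.05)

    def test_matches_finite_difference_fisher(self):
        params = np.array([3.2, 3.8, 1500.0, 8.0])
        fit = FitResult(k=1, params=params, log_likelihood=0.0, converged=True)
        var = np.full((7, 7), 6.0)
        crlb, singular = compute_crlb(fit, var, SIG / PIX)
        assert not singular
        I_fd = fisher_fd(params, 7, SIG / PIX, var)
        crlb_fd = np.sqrt(np.diag(np.linalg.inv(I_fd)))[:3]
        np.testing.assert_allclose(crlb[0], crlb_fd, rtol=0.01)

    def test_pure_poisson_closed_form_limit(self):
        # zero background, zero read noise, fine pixels, wide patch:
        # sigma_x -> sigma/sqrt(N)
        n, size, sigma_px = 1000.0, 15, 2.0
        params = np.array([size / 2, size / 2, n, 0.0])
        fit = FitResult(k=1, params=params, log_likelihood=0.0, converged=True)
        crlb, singular = compute_crlb(fit, np.zeros((size, size)), sigma_px)
        assert not singular
        assert crlb[0, 0] == pytest.approx(sigma_px / np.sqrt(n), rel=0.05)

    def test_crlb_increases_with_background(self):
        cs = [self._crlb(1000, bg)[0] for bg in (0.0, 5.0, 20.0, 80.0)]
        assert np.all(np.diff(cs) > 0)


class TestPrecisionDistribution:
    def test_parameter_recovery(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        x = stats.skewnorm.rvs(4.0, loc=10.0, scale=3.0, size=100_000,
                               random_state=rng)
        m = fit_precision_distribution(x)
        assert m.shape == pytest.approx(4.0, rel=0.05)
        assert m.location == pytest.approx(10.0, rel=0.05)
        assert m.scale == pytest.approx(3.0, rel=0.05)

    def test_symmetric_data_fits_nearly_symmetric_distribution(self):
        # the skew-normal shape is weakly identified at 0 (singular Fisher
        # information), so assert distributional agreement instead of the
        # shape parameter itself
        from scipy import stats

        rng = np.random.default_rng(9)
        x = stats.skewnorm.rvs(0.0, loc=10.0, scale=3.0, size=100_000,
                               random_state=rng)
        m = fit_precision_distribution(x)
        mean_fit = stats.skewnorm.mean(m.shape, m.location, m.scale)
        sd_fit = stats.skewnorm.std(m.shape, m.location, m.scale)
        skew_fit = stats.skewnorm.stats(m.shape, m.location, m.scale,
                                        moments="s")
        assert mean_fit == pytest.approx(10.0, abs=0.05)
        assert sd_fit == pytest.approx(3.0, rel=0.02)
        assert abs(float(skew_fit)) < 0.05

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="50"):
            fit_precision_distribution(np.ones(49) + np.arange(49) * 0.1)

    def test_degenerate_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_precision_distribution(np.full(100, 5.0))


def _loc_table(rows):
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "crlb_x_nm",
                                     "crlb_y_nm"])
    df["channel"] = 1
    df["photons"] = 1000.0
    df["background"] = 1.0
    df["n_merged"] = 1
    return df


class TestMergeBlinks:
    def test_three_consecutive_frames_merge_to_one(self):
        tab = _loc_table([(0, 0.0, 0.0, 10, 10), (1, 5.0, -5.0, 10, 10),
                          (2, -5.0, 5.0, 10, 10)])
        m = merge_blinks(tab)
        assert len(m) == 1
        assert m.n_merged.iloc[0] == 3
        assert m.photons.iloc[0] == 3000.0

    def test_equal_precision_pair_averages(self):
        tab = _loc_table([(0, 0.0, 0.0, 10, 10), (1, 10.0, 0.0, 10, 10)])
        m = merge_blinks(tab)
        assert len(m) == 1
        assert m.x_nm.iloc[0] == pytest.approx(5.0)
        assert m.crlb_x_nm.iloc[0] == pytest.approx(10.0 / np.sqrt(2))

    def test_weighted_mean_uses_inverse_variance(self):
        tab = _loc_table([(0, 0.0, 0.0, 5, 5), (1, 10.0, 0.0, 10, 10)])
        m = merge_blinks(tab)
        # weights 1/25 vs 1/100 -> mean at 2.0
        assert m.x_nm.iloc[0] == pytest.approx(2.0)

    def test_gap_beyond_max_is_not_linked(self):
        tab = _loc_table([(0, 0.0, 0.0, 10, 10), (3, 0.0, 0.0, 10, 10)])
        assert len(merge_blinks(tab, max_gap_frames=1)) == 2
        assert len(merge_blinks(tab, max_gap_frames=3)) == 1

    def test_distant_localizations_not_merged(self):
        tab = _loc_table([(0, 0.0, 0.0, 10, 10), (1, 500.0, 0.0, 10, 10)])
        assert len(merge_blinks(tab)) == 2

    def test_idempotence_and_conservation(self):
        rng = np.random.default_rng(10)
        rows = []
        for e in range(40):
            x, y = rng.uniform(0, 20_000, 2)
            f0 = rng.integers(0, 50)
            for k in range(rng.integers(1, 6)):
                rows.append((f0 + k, x + rng.normal(0, 8), y + rng.normal(0, 8),
                             8.0, 8.0))
        tab = _loc_table(rows)
        m1 = merge_blinks(tab)
        m2 = merge_blinks(m1)
        assert m1.n_merged.sum() == len(tab)
        pd.testing.assert_frame_equal(
            m1.reset_index(drop=True), m2.reset_index(drop=True),
            check_dtype=False)

    def test_channels_merge_independently(self):
        tab = _loc_table([(0, 0.0, 0.0, 10, 10), (1, 0.0, 0.0, 10, 10)])
        tab.loc[1, "channel"] = 2
        assert len(merge_blinks(tab)) == 2


class TestRenderImage:
    def test_single_localization_sums_to_one(self):
        tab = _loc_table([(0, 500.0, 500.0, 10, 10)])
        img, _ = render_image(tab)
        assert img.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_distant_blobs_each_sum_to_one(self):
        tab = _loc_table([(0, 0.0, 0.0, 10, 10), (0, 1000.0, 0.0, 10, 10)])
        img, (x0, y0) = render_image(tab)
        split = int((500.0 - x0) / 10.0)
        assert img[:, :split].sum() == pytest.approx(1.0, rel=0.01)
        assert img[:, split:].sum() == pytest.approx(1.0, rel=0.01)

    def test_empty_table_gives_zero_image(self):
        img, _ = render_image(_loc_table([]))
        assert img.sum() == 0.0
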