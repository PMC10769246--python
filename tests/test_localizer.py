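"""Spot detection, MLE fitting and blink linking."""

import numpy as np
import pandas as pd
import pytest

from flashmap.geometry import BindingSiteSet
from flashmap.localize import (
    detect_candidates,
    fit_spot,
    link_blinks,
    localize_movie,
    precision_formula,
    roi_half_size,
)
from flashmap.simulate import (
    BlinkEvents,
    DriftTrajectory,
    ImagingParams,
    render_movie,
)
from flashmap.tables import LocalizationTable

from .oracles import fine_grid_psf_image

A = 108.0  # pixel size nm
PSF = 130.0  # psf sd nm
SIGMA_PX = PSF / A


def _render_single(x_px, y_px, photons, bg, seed, size=16, n_frames=1):
    params = ImagingParams(
        n_rounds=1, frames_per_round=n_frames, background_photons=bg,
        photons_per_frame=photons, psf_sigma=PSF, pixel_size=A,
    )
    sites = BindingSiteSet(np.array([0]), np.array([x_px * A]), np.array([y_px * A]), ("A",))
    events = BlinkEvents([0], [0], [0], [n_frames], [photons * n_frames])
    stack, sidecar = render_movie(
        events, sites, DriftTrajectory.zero(n_frames), params, (size, size), seed
    )
    return stack, sidecar


class TestDetection:
    def test_constant_frame_has_no_candidates(self):
        assert detect_candidates(np.full((32, 32), 7.0), 5.0, SIGMA_PX) == []

    def test_single_emitter_detected_within_one_pixel(self):
        stack, _ = _render_single(8.4, 7.2, 2000, 5.0, seed=1)
        cands = detect_candidates(stack[0], 5.0, SIGMA_PX)
        assert len(cands) == 1
        r, c = cands[0]
        assert abs(r - 7.2) <= 1.0 and abs(c - 8.4) <= 1.0

    def test_two_emitters_ten_pixels_apart(self):
        params = ImagingParams(
            n_rounds=1, frames_per_round=1, background_photons=5.0,
            photons_per_frame=2000.0, psf_sigma=PSF, pixel_size=A,
        )
        sites = BindingSiteSet(
            np.array([0, 0]), np.array([5 * A, 15 * A]), np.array([10 * A, 10 * A]), ("A",)
        )
        events = BlinkEvents([0, 1], [0, 0], [0, 0], [1, 1], [2000, 2000])
        stack, _ = render_movie(events, sites, DriftTrajectory.zero(1), params, (22, 22), 3)
        assert len(detect_candidates(stack[0], 5.0, SIGMA_PX)) == 2

    def test_translation_equivariance(self):
        stack, _ = _render_single(9.0 + 0.31, 8.0 + 0.47, 3000, 5.0, seed=4, size=24)
        frame = stack[0]
        shifted = np.roll(frame, (2, 3), axis=(0, 1))
        c0 = detect_candidates(frame, 5.0, SIGMA_PX)
        c1 = detect_candidates(shifted, 5.0, SIGMA_PX)
        assert [(r + 2, c + 3) for r, c in c0] == c1


class TestFitting:
    def test_noiseless_emitter_at_pixel_center(self):
        img = fine_grid_psf_image((9, 9), 4.5, 4.5, SIGMA_PX, 5000.0, 2.0)
        fit = fit_spot(img, A, PSF)
        assert fit.converged
        assert abs(fit.x - 4.5) < 0.02 and abs(fit.y - 4.5) < 0.02
        assert abs(fit.photons - 5000.0) / 5000.0 < 0.02
        assert abs(fit.background - 2.0) < 0.1

    @pytest.mark.parametrize("frac", [0.0, 0.25, 0.5])
    def test_subpixel_bias_below_five_hundredths(self, frac):
        # integrated (not sampled) Gaussian model: no pixel-phase bias
        x, y = 4.0 + frac, 4.0 + frac
        img = fine_grid_psf_image((9, 9), x, y, SIGMA_PX, 5000.0, 2.0)
        fit = fit_spot(img, A, PSF)
        assert fit.converged
        assert abs(fit.x - x) < 0.05 and abs(fit.y - y) < 0.05

    def test_all_zero_roi_does_not_converge(self):
        fit = fit_spot(np.zeros((9, 9)), A, PSF)
        assert not fit.converged

    def test_rmse_within_precision_formula(self):
        # scaled-down version of the photon-sweep property
        rng = np.random.default_rng(0)
        n, photons, bg = 200, 1000, 10.0
        m = roi_half_size(PSF, A)
        errs, reported = [], []
        for k in range(n):
            x = 8.0 + rng.uniform(-0.5, 0.5)
            y = 8.0 + rng.uniform(-0.5, 0.5)
            stack, _ = _render_single(x, y, photons, bg, seed=1000 + k)
            roi = stack[0][8 - m : 8 + m + 1, 8 - m : 8 + m + 1].astype(float)
            fit = fit_spot(roi, A, PSF)
            assert fit.converged
            errs.append((8 - m + fit.x - x, 8 - m + fit.y - y))
            reported.append(
                precision_formula(fit.photons, fit.background, fit.sigma * A, A)
            )
        errs = np.asarray(errs) * A
        rmse = np.sqrt(np.mean(errs**2, axis=0))
        assert np.all(rmse <= 1.3 * np.mean(reported))


    @pytest.mark.parametrize("photons", [200, 1000, 5000])
    def test_median_error_tracks_precision_across_photon_sweep(self, photons):
        rng = np.random.default_rng(photons)
        m = roi_half_size(PSF, A)
        errs, reported = [], []
        for k in range(120):
            x = 8.0 + rng.uniform(-0.5, 0.5)
            y = 8.0 + rng.uniform(-0.5, 0.5)
            stack, _ = _render_single(x, y, photons, 10.0, seed=7000 + 10 * photons + k)
            roi = stack[0][8 - m : 8 + m + 1, 8 - m : 8 + m + 1].astype(float)
            fit = fit_spot(roi, A, PSF)
            if not fit.converged:
                continue
            errs.append(np.hypot(8 - m + fit.x - x, (8 - m + fit.y - y)) * A / np.sqrt(2))
            reported.append(
                precision_formula(fit.photons, fit.background, fit.sigma * A, A)
            )
        assert len(errs) > 100
        assert np.median(errs) <= 1.3 * np.median(reported)


class TestLocalizeMovie:
    def test_background_only_stack_yields_empty_table(self):
        params = ImagingParams(n_rounds=1, frames_per_round=100, background_photons=5.0)
        sites = BindingSiteSet(np.empty(0, int), np.empty(0), np.empty(0), ("A",))
        z = np.empty(0, dtype=int)
        stack, sidecar = render_movie(
            BlinkEvents(z, z, z, z, z), sites, DriftTrajectory.zero(100), params, (30, 30), 0
        )
        table = localize_movie(stack, sidecar, threshold_k=5.0)
        # false-positive rate < 1 per 100 frames
        assert len(table) < 1
        assert table.counters["fits_dropped"] == 0

    def test_round_assignment_single_round(self):
        stack, sidecar = _render_single(8.0, 8.0, 2000, 5.0, seed=7, n_frames=5)
        table = localize_movie(stack, sidecar)
        assert len(table) == 5
        assert np.all(table.df["round"] == 0)

    def test_frame_count_mismatch_is_hard_error(self):
        stack, sidecar = _render_single(8.0, 8.0, 2000, 5.0, seed=7, n_frames=5)
        with pytest.raises(ValueError, match="frame"):
            localize_movie(stack[:3], sidecar)

    def test_list_vs_frame_mode_consistency(self):
        """Same ground truth through both fidelity paths: counts agree."""
        rng = np.random.default_rng(12)
        n_sites = 30
        params = ImagingParams(
            n_rounds=1, frames_per_round=300, photons_per_frame=3000.0,
            background_photons=5.0, mean_dark_frames=100.0, mean_bright_frames=2.0,
        )
        field_px = 40
        sites = BindingSiteSet(
            np.zeros(n_sites, int),
            rng.uniform(5 * A, (field_px - 5) * A, n_sites),
            rng.uniform(5 * A, (field_px - 5) * A, n_sites),
            ("A",),
        )
        from flashmap.simulate import events_to_localizations, simulate_rounds

        events = simulate_rounds(sites, params, seed=1)
        drift = DriftTrajectory.zero(300)
        list_table = link_blinks(
            events_to_localizations(events, sites, drift, params, seed=2)
        )
        stack, sidecar = render_movie(events, sites, drift, params, (field_px, field_px), 3)
        frame_table = link_blinks(localize_movie(stack, sidecar))
        assert abs(len(frame_table) - len(list_table)) / len(list_table) < 0.10


class TestLinkBlinks:
    def test_single_event_spanning_three_frames_merges(self):
        df = pd.DataFrame(
            {
                "frame": [10, 11, 12],
                "round": [0, 0, 0],
                "x": [100.0, 101.0, 99.5],
                "y": [50.0, 50.5, 49.5],
                "photons": [500.0, 450.0, 520.0],
                "loc_precision": [6.0, 6.3, 5.9],
            }
        )
        out = link_blinks(LocalizationTable(df=df), max_gap=1, max_dist=50.0)
        assert len(out) == 1
        assert out.df["photons"].iloc[0] == pytest.approx(1470.0)
        assert out.df["n_frames"].iloc[0] == 3

    def test_events_beyond_max_gap_stay_separate(self):
        df = pd.DataFrame(
            {
                "frame": [10, 20],
                "round": [0, 0],
                "x": [100.0, 100.0],
                "y": [50.0, 50.0],
                "photons": [500.0, 500.0],
                "loc_precision": [6.0, 6.0],
            }
        )
        out = link_blinks(LocalizationTable(df=df), max_gap=1, max_dist=50.0)
        assert len(out) == 2

    def test_merged_position_is_inverse_variance_mean(self):
        xs = np.array([100.0, 103.0, 98.0])
        ys = np.array([50.0, 52.0, 47.0])
        prec = np.array([5.0, 10.0, 2.5])
        df = pd.DataFrame(
            {
                "frame": [0, 1, 2],
                "round": [0, 0, 0],
                "x": xs,
                "y": ys,
                "photons": [100.0, 100.0, 100.0],
                "loc_precision": prec,
            }
        )
        out = link_blinks(LocalizationTable(df=df), max_gap=1, max_dist=50.0)
        w = 1.0 / prec**2
        assert out.df["x"].iloc[0] == pytest.approx(np.sum(xs * w) / w.sum())
        assert out.df["y"].iloc[0] == pytest.approx(np.sum(ys * w) / w.sum())
        assert out.df["loc_precision"].iloc[0] == pytest.approx(1.0 / np.sqrt(w.sum()))

    def test_photon_conservation_and_count_monotonicity(self, two_layer_sim):
        table = two_layer_sim["table"]
        linked = link_blinks(table, max_gap=1, max_dist=100.0)
        assert len(linked) <= len(table)
        assert linked.df["photons"].sum() == pytest.approx(table.df["photons"].sum())
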