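import numpy as np
import pandas as pd
import pytest

from patchdyn.detect import (
    CellMask,
    PatchDetector,
    detect_patches_frame,
    enhance_frame,
    enhanced_noise_sd,
    kymograph,
    max_intensity_projection,
    measure_cell_dimensions,
    patch_stats,
    segment_cell,
)
from patchdyn.geometry import CellGeometry
from patchdyn.simulate import SimConfig, simulate_cell_movie

from conftest import paint_rod

PX = 0.064


def _gauss_spot(shape, x0, y0, amp, sigma=1.25):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))


class TestMIP:
    def test_single_frame_identity(self, rng):
        frame = rng.poisson(100, (20, 30)).astype(float)
        assert np.array_equal(max_intensity_projection(frame[None]), frame)

    def test_constant_frames(self):
        stack = np.stack([np.zeros((5, 5)), np.full((5, 5), 5.0)])
        assert np.array_equal(max_intensity_projection(stack), np.full((5, 5), 5.0))

    def test_matches_per_pixel_max_oracle(self, rng):
        stack = rng.normal(size=(12, 16, 16))
        oracle = np.array(
            [[stack[:, i, j].max() for j in range(16)] for i in range(16)]
        )
        assert np.allclose(max_intensity_projection(stack), oracle)

    def test_moving_spot_streak(self):
        frames = [
            100 + _gauss_spot((20, 40), 5 + 2 * t, 10, 200) for t in range(10)
        ]
        mip = max_intensity_projection(np.stack(frames))
        # the streak along the path is brighter than off-path background
        assert mip[10, 5:24].min() > 150


class TestSegmentCell:
    def test_painted_rod_area_recovery(self, rng):
        mask_true = paint_rod(3.0, 0.9)
        img = rng.normal(100, 10, mask_true.shape) + 200.0 * mask_true
        cell = segment_cell(img, PX)
        true_area = mask_true.sum() * PX**2
        assert cell.area_um2 == pytest.approx(true_area, rel=0.05)

    def test_area_arithmetic(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True  # not used for segmentation, just area math
        cm = CellMask(mask=mask, pixel_size_um=PX)
        assert cm.area_um2 == pytest.approx(400 * PX**2)

    def test_uniform_image_raises(self):
        with pytest.raises(ValueError, match="variance"):
            segment_cell(np.full((30, 30), 7.0), PX)

    def test_largest_component_kept(self, rng):
        mask_true = paint_rod(2.5, 0.8)
        img = rng.normal(100, 8, mask_true.shape) + 250.0 * mask_true
        img[2, 2] += 500  # bright speck: separate small component
        cell = segment_cell(img, PX)
        assert not cell.mask[2, 2]


class TestCellDimensions:
    def test_painted_rod_dimensions(self):
        mask = paint_rod(3.0, 0.9)
        length, width = measure_cell_dimensions(mask, PX)
        assert length == pytest.approx(3.0, rel=0.05)
        assert width == pytest.approx(0.9, rel=0.10)

    def test_square_mask_length_equals_width(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:40, 10:40] = True
        length, width = measure_cell_dimensions(mask, PX)
        assert length == pytest.approx(width, rel=0.12)

    @pytest.mark.parametrize("angle", [30, 60])
    def test_rotation_invariance(self, angle):
        from scipy import ndimage as ndi

        mask = paint_rod(3.0, 0.9)
        l0, w0 = measure_cell_dimensions(mask, PX)
        rotated = ndi.rotate(mask.astype(float), angle, order=1, reshape=True) > 0.5
        la, wa = measure_cell_dimensions(rotated, PX)
        assert la == pytest.approx(l0, rel=0.02)
        assert wa == pytest.approx(w0, rel=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            measure_cell_dimensions(np.zeros((5, 5), dtype=bool), PX)


class TestEnhanceFrame:
    def test_constant_frame_maps_to_zero(self):
        out = enhance_frame(np.full((30, 30), 500.0))
        assert np.abs(out).max() < 1e-9 * 500

    def test_impulse_response_equals_kernel(self):
        # direct kernel-construction oracle
        from skimage.filters import gaussian

        imp = np.zeros((41, 41))
        imp[20, 20] = 1.0
        kernel = gaussian(imp, 1.0, preserve_range=True) - gaussian(
            imp, 4.0, preserve_range=True
        )
        assert np.allclose(enhance_frame(imp), kernel)
        assert kernel[20, 20] > 0

    def test_gaussian_spot_maximum_at_centre(self, rng):
        img = 100.0 + _gauss_spot((40, 40), 21.3, 18.7, 300, sigma=2.0)
        out = enhance_frame(img)
        iy, ix = np.unravel_index(out.argmax(), out.shape)
        assert abs(ix - 21.3) <= 0.5 + 1e-9 or abs(ix - 21) <= 1
        assert abs(iy - 18.7) <= 1


class TestDetectPatches:
    def test_single_spot_snr8(self, rng):
        hits, errs = 0, []
        for _ in range(50):
            x0, y0 = 30 + rng.uniform(-1, 1), 14 + rng.uniform(-1, 1)
            img = rng.poisson(100 + _gauss_spot((28, 61), x0, y0, 150)) + rng.normal(
                0, 3, (28, 61)
            )
            det = detect_patches_frame(enhance_frame(img))
            if len(det) >= 1:
                d = np.hypot(det.x_px - x0, det.y_px - y0).min()
                if d < 2:
                    hits += 1
                    errs.append(d)
        assert hits >= 48
        assert np.median(errs) < 0.5

    def test_two_spots_resolved_vs_merged(self, rng):
        img = 100 + _gauss_spot((30, 40), 12, 15, 200) + _gauss_spot((30, 40), 22, 15, 200)
        det = detect_patches_frame(enhance_frame(rng.poisson(img) + 0.0))
        assert len(det) == 2  # 10 px apart: resolved
        img2 = 100 + _gauss_spot((30, 40), 18, 15, 200) + _gauss_spot((30, 40), 20, 15, 200)
        det2 = detect_patches_frame(enhance_frame(rng.poisson(img2) + 0.0))
        assert len(det2) == 1  # 2 px apart: merged (documented behaviour)

    def test_false_positives_on_noise(self, rng):
        n_fp = 0
        n_frames = 300
        for _ in range(n_frames):
            frame = rng.poisson(100, (28, 61)) + rng.normal(0, 3, (28, 61))
            n_fp += len(detect_patches_frame(enhance_frame(frame)))
        assert n_fp / n_frames <= 0.1

    def test_count_invariant_under_offset(self, rng):
        img = rng.poisson(100 + _gauss_spot((28, 40), 20, 14, 150)).astype(float)
        d0 = detect_patches_frame(enhance_frame(img))
        d1 = detect_patches_frame(enhance_frame(img + 500.0))
        assert len(d0) == len(d1)

    def test_empty_result_is_valid(self):
        det = detect_patches_frame(np.zeros((20, 20)))
        assert len(det) == 0


class TestPatchStats:
    @staticmethod
    def _cell(shape=(30, 40)):
        mask = np.zeros(shape, dtype=bool)
        mask[5:25, 5:35] = True
        return CellMask(mask=mask, pixel_size_um=PX)

    def test_density_arithmetic(self):
        # 30 frames x 8 detections, area 4.0 um^2 -> rho = 2.0
        mask = np.zeros((40, 40), dtype=bool)
        n_px = int(round(4.0 / PX**2))
        mask.flat[:n_px] = True
        cell = CellMask(mask=mask, pixel_size_um=PX)
        det = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(30), 8),
                "x_px": np.tile(np.arange(8) * 4 + 2, 30),
                "y_px": np.zeros(240),
            }
        )
        mean_count, rho = patch_stats(det, cell, n_frames=30)
        assert mean_count == pytest.approx(8.0)
        assert rho == pytest.approx(8.0 / cell.area_um2)

    def test_no_detections_zero_density(self):
        cell = self._cell()
        det = pd.DataFrame(columns=["frame", "x_px", "y_px"])
        mean_count, rho = patch_stats(det, cell, n_frames=10)
        assert mean_count == 0 and rho == 0

    def test_outside_mask_discarded(self):
        cell = self._cell()
        det = pd.DataFrame({"frame": [0, 0], "x_px": [10.0, 38.5], "y_px": [10.0, 1.0]})
        mean_count, _ = patch_stats(det, cell, n_frames=1)
        assert mean_count == 1.0

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            patch_stats(pd.DataFrame(columns=["frame", "x_px", "y_px"]), self._cell(), 0)


class TestKymograph:
    def test_static_spot_vertical_ridge(self):
        frames = np.stack([100 + _gauss_spot((20, 40), 20, 10, 200)] * 15)
        kymo = kymograph(frames, (10, 5), (10, 35))
        peaks = kymo.argmax(axis=0)
        assert np.ptp(peaks) == 0

    def test_moving_spot_slope(self):
        frames = np.stack(
            [100 + _gauss_spot((20, 40), 5 + t, 10, 200) for t in range(20)]
        )
        kymo = kymograph(frames, (10, 0), (10, 39))
        peaks = kymo.argmax(axis=0).astype(float)
        slope = np.polyfit(np.arange(20), peaks, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_output_shape(self, rng):
        frames = rng.poisson(100, (7, 30, 30)).astype(float)
        kymo = kymograph(frames, (5, 2), (25, 2))
        assert kymo.shape[1] == 7
        assert kymo.shape[0] == 21  # profile of a 20-px line has 21 samples

    def test_degenerate_line_rejected(self, rng):
        frames = rng.poisson(100, (3, 10, 10)).astype(float)
        with pytest.raises(ValueError):
            kymograph(frames, (5, 5), (5, 5))


class TestPatchDetectorEstimator:
    def test_sklearn_params_roundtrip(self):
        det = PatchDetector(min_threshold_sd=5.0)
        params = det.get_params()
        assert params["min_threshold_sd"] == 5.0
        det.set_params(step_sd=2.0)
        assert det.step_sd == 2.0

    def test_density_invariant_under_intensity_rescale(self, geom):
        movie, _ = simulate_cell_movie(SimConfig(seed=21), geom)
        det = PatchDetector().fit(movie)
        d1 = det.transform(movie)
        from patchdyn.io import Movie

        scaled = Movie(
            pixels=movie.pixels.astype(float) * 3.7,
            pixel_size_um=movie.pixel_size_um,
            frame_interval_s=movie.frame_interval_s,
        )
        det2 = PatchDetector().fit(scaled)
        d2 = det2.transform(scaled)
        _, rho1 = det.density(d1, movie.n_frames)
        _, rho2 = det2.density(d2, movie.n_frames)
        assert rho1 == pytest.approx(rho2, rel=0.02)

    def test_transform_before_fit_raises(self, geom):
        movie, _ = simulate_cell_movie(SimConfig(seed=22), geom)
        with pytest.raises(RuntimeError):
            PatchDetector().transform(movie)

    def test_full_movie_density_recovery(self, geom):
        # membrane-plane population: every spot at the nominal SNR
        rhos = []
        for seed in range(30, 38):
            cfg = SimConfig(seed=seed, frac_directed=0, frac_random=0.5, frac_confined=0.5)
            movie, _ = simulate_cell_movie(cfg, geom)
            det = PatchDetector().fit(movie)
            _, rho = det.density(det.transform(movie), movie.n_frames)
            rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(2.0, rel=0.15)
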