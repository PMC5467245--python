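import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patchdyn.classify import (
    MotionClassifier,
    MotionFit,
    MSDProfile,
    bootstrap_se,
    classify_track,
    classify_tracks,
    compute_msd,
    estimate_D_cdf,
    fit_directed,
    fit_random,
    fit_track,
    frame_fractions,
    summarize_cell,
)
from patchdyn.simulate import (
    simulate_brownian_track,
    simulate_confined_track,
    simulate_directed_track_planar,
)


def brute_force_msd(xy, dt=1.0, max_lag_frac=7.0 / 8.0):
    """Independent double-loop oracle for the time-averaged MSD."""
    n = len(xy)
    max_lag = int(np.floor(max_lag_frac * (n - 1)))
    lags, msd = [], []
    for lag in range(1, max_lag + 1):
        acc = []
        for i in range(n - lag):
            dx = xy[i + lag][0] - xy[i][0]
            dy = xy[i + lag][1] - xy[i][1]
            acc.append(dx * dx + dy * dy)
        lags.append(lag * dt)
        msd.append(sum(acc) / len(acc))
    return np.array(lags), np.array(msd)


class TestComputeMSD:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(5, 40)
            xy = rng.normal(0, 1, (n, 2))
            prof = compute_msd(xy, frame_interval_s=1.0)
            lags, msd = brute_force_msd(xy)
            assert np.allclose(prof.lag_s, lags)
            assert np.max(np.abs(prof.msd_um2 - msd)) < 1e-12

    def test_stationary_track_zero(self):
        prof = compute_msd(np.zeros((10, 2)))
        assert np.allclose(prof.msd_um2, 0.0)

    def test_constant_velocity_closed_form(self):
        t = np.arange(20)
        xy = np.column_stack([0.055 * t, np.zeros(20)])
        prof = compute_msd(xy, frame_interval_s=1.0)
        # msd(4 s) = (0.055*4)^2 = 0.0484 exactly
        assert prof.msd_um2[3] == pytest.approx((0.055 * 4) ** 2, abs=1e-15)
        assert np.allclose(prof.msd_um2, (0.055 * prof.lag_s) ** 2)

    def test_seven_eighths_lag_rule(self):
        # 17 points (16 s duration) -> lags 1..14 only
        prof = compute_msd(np.random.default_rng(0).normal(size=(17, 2)))
        assert prof.lag_s.max() == 14
        assert len(prof.lag_s) == 14

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(np.zeros((1, 2)))


class TestFits:
    @staticmethod
    def _profile(msd, lags=None):
        lags = np.arange(1, len(msd) + 1) if lags is None else lags
        return MSDProfile(lag_s=np.asarray(lags, float), msd_um2=np.asarray(msd, float), n_pairs=np.ones(len(msd), int))

    def test_directed_exact(self):
        t = np.arange(1.0, 11.0)
        nu, r2 = fit_directed(self._profile((0.055 * t) ** 2, t))
        assert nu == pytest.approx(0.055, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_random_exact(self):
        t = np.arange(1.0, 11.0)
        d, r2 = fit_random(self._profile(0.008 * t, t))
        assert d == pytest.approx(0.002, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_model_mismatch_r2_ordering(self):
        t = np.arange(1.0, 16.0)
        quad = self._profile((0.055 * t) ** 2, t)
        lin = self._profile(4 * 0.002 * t, t)
        assert fit_directed(quad)[1] > fit_random(quad)[1]
        assert fit_random(lin)[1] > fit_directed(lin)[1]

    def test_all_zero_profile(self):
        t = np.arange(1.0, 6.0)
        nu, _ = fit_directed(self._profile(np.zeros(5), t))
        d, _ = fit_random(self._profile(np.zeros(5), t))
        assert nu == 0.0 and d == 0.0

    def test_negative_slope_clips_to_zero(self):
        t = np.arange(1.0, 6.0)
        nu, r2 = fit_directed(self._profile(-0.01 * t, t))
        assert nu == 0.0 and r2 <= 1.0

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            fit_directed(self._profile([1.0, 2.0]))


class TestClassifyRule:
    @pytest.mark.parametrize(
        "r2d,r2r,maxmsd,expected",
        [
            (0.99, 0.70, 0.5, "directed"),
            (0.85, 0.92, 0.5, "random"),
            (0.50, 0.50, 0.01, "constrained"),
            (0.50, 0.50, 0.20, "unclassified"),
            (0.80, 0.80, 0.5, "directed"),  # tie at threshold: directed dominates
            (0.79, 0.81, 0.5, "random"),
            (-2.0, -1.0, 0.04, "constrained"),
        ],
    )
    def test_rule_table(self, r2d, r2r, maxmsd, expected):
        fit = MotionFit(nu_um_s=0.05, r2_directed=r2d, d_um2_s=0.002, r2_random=r2r, max_msd_um2=maxmsd)
        assert classify_track(fit) == expected


class TestClassificationRecovery:
    def test_directed_tracks_recovered(self):
        rng = np.random.default_rng(3)
        classes, nus = [], []
        for _ in range(300):
            xy = simulate_directed_track_planar(
                0.055, n=20, heading_rad=rng.uniform(0, 2 * math.pi), loc_noise_um=0.02, seed=rng
            )
            fit = fit_track(xy)
            classes.append(classify_track(fit))
            nus.append(fit.nu_um_s)
        assert np.mean(np.array(classes) == "directed") >= 0.9
        assert np.median(nus) == pytest.approx(0.055, rel=0.10)

    def test_brownian_rarely_directed_majority_random(self):
        rng = np.random.default_rng(4)
        classes = []
        for _ in range(500):
            xy = simulate_brownian_track(0.002, n=26, seed=rng)
            classes.append(classify_track(fit_track(xy)))
        classes = np.array(classes)
        assert np.mean(classes == "directed") <= 0.15
        counts = pd.Series(classes).value_counts()
        assert counts.idxmax() == "random"

    def test_confined_classified_constrained(self):
        rng = np.random.default_rng(5)
        classes = []
        for _ in range(200):
            xy = simulate_confined_track(0.15, 0.002, n=120, seed=rng)
            classes.append(classify_track(fit_track(xy)))
        assert np.mean(np.array(classes) == "constrained") >= 0.8


class TestEstimateDCdf:
    def test_mle_closed_form(self):
        # one long synthetic "track" with known mean squared displacement
        xy = np.zeros((101, 2))
        xy[1::2, 0] = math.sqrt(0.008)  # alternating jumps: mean r^2 = 0.008
        d = estimate_D_cdf([xy], frame_interval_s=1.0)
        assert d == pytest.approx(0.002, rel=1e-12)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(6)
        tracks = [simulate_brownian_track(0.002, n=26, seed=rng) for _ in range(200)]
        assert estimate_D_cdf(tracks) == pytest.approx(0.002, rel=0.15)
        assert estimate_D_cdf(tracks, method="cdf") == pytest.approx(0.002, rel=0.15)

    def test_zero_displacements(self):
        assert estimate_D_cdf([np.zeros((60, 2))]) == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_D_cdf([np.zeros((5, 2))])


def _uniform_tracks_table(class_counts, n_frames=20):
    """Tracks all spanning the same frames, with forced classes."""
    rows, cls_rows = [], []
    tid = 0
    for cls, count in class_counts.items():
        for _ in range(count):
            for f in range(n_frames):
                rows.append({"track_id": tid, "frame": f, "x_um": 0.0, "y_um": 0.0})
            cls_rows.append(
                {
                    "track_id": tid,
                    "n_points": n_frames,
                    "motion_class": cls,
                    "nu_um_s": 0.05,
                    "d_um2_s": 0.002,
                    "r2_directed": 0.9,
                    "r2_random": 0.5,
                    "max_msd_um2": 0.1,
                }
            )
            tid += 1
    return pd.DataFrame(rows), pd.DataFrame(cls_rows)


class TestSummarizeCell:
    def test_fraction_arithmetic(self):
        tracks, classes = _uniform_tracks_table(
            {"directed": 4, "random": 3, "constrained": 2, "unclassified": 1}
        )
        s = summarize_cell(tracks, classes, area_um2=4.0, n_frames=20)
        assert s.theta_d == pytest.approx(0.4)
        assert s.theta_r == pytest.approx(0.3)
        assert s.theta_c == pytest.approx(0.2)
        assert s.theta_u == pytest.approx(0.1)
        assert s.rho_um2 == pytest.approx(10 * 20 / 20 / 4.0)
        assert s.rho_d_um2 == pytest.approx(0.4 * s.rho_um2)
        assert s.rho_d_um2 <= s.rho_um2

    def test_fractions_sum_to_one(self, rng):
        counts = dict(zip(["directed", "random", "constrained", "unclassified"], rng.integers(1, 6, 4)))
        tracks, classes = _uniform_tracks_table(counts)
        s = summarize_cell(tracks, classes, area_um2=2.0, n_frames=20)
        assert s.theta_d + s.theta_r + s.theta_c + s.theta_u == pytest.approx(1.0, abs=1e-9)

    def test_short_tracks_count_as_unclassified(self):
        tracks, classes = _uniform_tracks_table({"directed": 1})
        short = pd.DataFrame(
            {"track_id": [99] * 3, "frame": [0, 1, 2], "x_um": 0.0, "y_um": 0.0}
        )
        tracks = pd.concat([tracks, short], ignore_index=True)
        cls = classify_tracks(tracks)
        fr = frame_fractions(tracks, cls)
        assert fr["unclassified"] > 0

    def test_speed_projection_factor(self):
        tracks, classes = _uniform_tracks_table({"directed": 2})
        s1 = summarize_cell(tracks, classes, area_um2=1.0, n_frames=20)
        s2 = summarize_cell(tracks, classes, area_um2=1.0, n_frames=20, speed_projection_factor=1.2)
        assert s2.nu_um_s == pytest.approx(1.2 * s1.nu_um_s)

    def test_no_frames_rejected(self):
        tracks, classes = _uniform_tracks_table({"random": 2})
        with pytest.raises(ValueError):
            summarize_cell(tracks, classes, area_um2=1.0, n_frames=0)


class TestScaleConsistency:
    @given(st.floats(0.3, 4.0))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_scaling_tracks_scales_estimates(self, c):
        rng = np.random.default_rng(99)
        xy = simulate_brownian_track(0.003, n=30, seed=rng) + simulate_directed_track_planar(
            0.03, n=30, loc_noise_um=0.0
        )
        f1 = fit_track(xy)
        f2 = fit_track(c * xy)
        assert f2.nu_um_s == pytest.approx(c * f1.nu_um_s, rel=1e-9)
        assert f2.d_um2_s == pytest.approx(c * c * f1.d_um2_s, rel=1e-9)
        assert f2.r2_directed == pytest.approx(f1.r2_directed, rel=1e-9)
        assert f2.r2_random == pytest.approx(f1.r2_random, rel=1e-9)


class TestBootstrap:
    def test_constant_statistic_zero_se(self):
        se = bootstrap_se(list(range(10)), lambda v: 1.0, n_boot=100, seed=0)
        assert se == 0.0

    def test_se_of_mean_matches_closed_form(self, rng):
        vals = list(rng.normal(0, 2, 250))
        se = bootstrap_se(vals, lambda v: float(np.mean(v)), n_boot=1000, seed=1)
        expect = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert se == pytest.approx(expect, rel=0.10)

    def test_se_scales_inverse_sqrt_n(self, rng):
        vals = list(rng.normal(0, 1, 800))
        se_small = bootstrap_se(vals[:200], lambda v: float(np.mean(v)), 800, seed=2)
        se_large = bootstrap_se(vals, lambda v: float(np.mean(v)), 800, seed=3)
        assert se_small / se_large == pytest.approx(2.0, rel=0.2)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_se([1.0], np.mean)


class TestMotionClassifierEstimator:
    def test_predict_matches_transform(self, rng):
        rows = []
        for tid in range(5):
            xy = simulate_brownian_track(0.002, n=15, seed=rng)
            for f, (x, y) in enumerate(xy):
                rows.append({"track_id": tid, "frame": f, "x_um": x, "y_um": y})
        tracks = pd.DataFrame(rows)
        clf = MotionClassifier()
        table = clf.fit_transform(tracks)
        assert list(clf.predict(tracks)) == list(table["motion_class"])

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            MotionClassifier(r2_threshold=1.5).fit(pd.DataFrame())

    def test_get_set_params(self):
        clf = MotionClassifier()
        clf.set_params(plateau_um2=0.07)
        assert clf.get_params()["plateau_um2"] == 0.07
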