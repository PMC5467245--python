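"""MSD computation, motion-model fits, track classification and per-cell stats.

Each track of at least five frames gets a time-averaged mean squared
displacement over all overlapping same-lag pairs, for lags up to 7/8 of
the track duration.  Two one-parameter models are fitted through the
origin:

* directed motion, ``MSD(t) = (nu t)^2`` -- least squares on ``t^2``;
* random diffusion, ``MSD(t) = 4 D t`` -- least squares on ``t``.

Class assignment follows the coefficient of determination (computed
about the mean MSD, so it can be negative for bad origin-constrained
fits):

* ``directed``   if R2_directed >= 0.8 and R2_directed >= R2_random;
* ``random``     if R2_random   >= 0.8 and R2_random   >  R2_directed;
* ``constrained`` if both R2 < 0.8 and the maximum MSD < 0.05 um^2
  (a plateauing, trapped trajectory);
* ``unclassified`` otherwise (ambiguous fits with large excursions).

Per-cell statistics weight each detection by frame: every detection
carries its track's class (tracks shorter than five frames count as
unclassified), frame-wise class fractions are averaged over frames, and
bootstrap resampling of whole tracks provides standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "MSDProfile",
    "MotionFit",
    "CellSummary",
    "MotionClassifier",
    "compute_msd",
    "fit_directed",
    "fit_random",
    "classify_track",
    "classify_tracks",
    "estimate_D_cdf",
    "summarize_cell",
    "bootstrap_se",
]

CLASSES = ("directed", "random", "constrained", "unclassified")


@dataclass(frozen=True)
class MSDProfile:
    """Time-averaged MSD of one track.

    ``lag_s`` are multiples of the frame interval, limited to 7/8 of the
    track duration; ``n_pairs`` counts the overlapping displacement pairs
    averaged at each lag.
    """

    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    @property
    def max_msd_um2(self) -> float:
        return float(self.msd_um2.max()) if len(self.msd_um2) else 0.0


@dataclass(frozen=True)
class MotionFit:
    """Directed and random model fits of one MSD profile."""

    nu_um_s: float
    r2_directed: float
    d_um2_s: float
    r2_random: float
    max_msd_um2: float


@dataclass
class CellSummary:
    """Per-cell patch-dynamics statistics.

    Fractions are detection-weighted per frame and then frame-averaged;
    they sum to one by construction.  ``rho_d = theta_d * rho`` is the
    directed patch density, and ``nu_um_s`` averages the fitted speeds
    of directed tracks with at least four steps.
    """

    cell_id: str
    rho_um2: float
    theta_d: float
    theta_r: float
    theta_c: float
    theta_u: float
    rho_d_um2: float
    nu_um_s: float
    d_msd_um2_s: float
    d_cdf_um2_s: float
    n_tracks: int
    mean_patch_count: float
    area_um2: float
    length_um: float = float("nan")
    width_um: float = float("nan")
    tau_s: float = float("nan")
    condition: str = ""
    time_min: float = float("nan")
    se: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "se"}
        for key, val in self.se.items():
            d[f"se_{key}"] = val
        return d


def compute_msd(
    xy: np.ndarray, frame_interval_s: float = 1.0, max_lag_frac: float = 7.0 / 8.0
) -> MSDProfile:
    """Time-averaged MSD over all overlapping same-lag pairs.

    ``msd(n dt) = mean_i |r(i+n) - r(i)|^2`` for lags
    ``n = 1 .. floor(max_lag_frac * (n_points - 1))``.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 2:
        raise ValueError("track must have at least 2 points")
    n = xy.shape[0]
    max_lag = int(np.floor(max_lag_frac * (n - 1)))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    n_pairs = np.empty(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        disp = xy[lag:] - xy[:-lag]
        msd[k] = np.mean(np.sum(disp * disp, axis=1))
        n_pairs[k] = n - lag
    return MSDProfile(lag_s=lags * frame_interval_s, msd_um2=msd, n_pairs=n_pairs)


def _r2(y: np.ndarray, y_hat: np.ndarray, w: np.ndarray) -> float:
    ss_res = float(np.sum(w * (y - y_hat) ** 2))
    mean = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - mean) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def _weights(profile: MSDProfile, weighted: bool) -> np.ndarray:
    if weighted:
        return profile.n_pairs.astype(float)
    return np.ones(len(profile.lag_s))


def fit_directed(profile: MSDProfile, weight_by_pairs: bool = True) -> tuple:
    """Fit ``MSD = (nu t)^2`` through the origin; returns ``(nu, r2)``.

    By default each lag is weighted by its number of overlapping
    displacement pairs: the time-averaged MSD at long lags averages very
    few pairs and its sampling variance grows accordingly, so unweighted
    fits let a handful of noisy long-lag points dictate the curvature.
    A negative fitted slope clips nu to zero (r2 reported for the raw
    fit).
    """
    t, y = profile.lag_s, profile.msd_um2
    if len(t) < 3:
        raise ValueError("need at least 3 lags to fit")
    w = _weights(profile, weight_by_pairs)
    x = t * t
    slope = float(np.sum(w * y * x) / np.sum(w * x * x))
    r2 = _r2(y, slope * x, w)
    nu = float(np.sqrt(slope)) if slope > 0 else 0.0
    return nu, r2


def fit_random(profile: MSDProfile, weight_by_pairs: bool = True) -> tuple:
    """Fit ``MSD = 4 D t`` through the origin; returns ``(D, r2)``.

    Lags are weighted by pair count by default (see :func:`fit_directed`).
    """
    t, y = profile.lag_s, profile.msd_um2
    if len(t) < 3:
        raise ValueError("need at least 3 lags to fit")
    w = _weights(profile, weight_by_pairs)
    slope = float(np.sum(w * y * t) / np.sum(w * t * t))
    r2 = _r2(y, slope * t, w)
    d = slope / 4.0 if slope > 0 else 0.0
    return d, r2


def classify_track(
    fit: MotionFit, r2_threshold: float = 0.8, plateau_um2: float = 0.05
) -> str:
    """Assign one of the four motion classes from the model fits."""
    if fit.r2_directed >= r2_threshold and fit.r2_directed >= fit.r2_random:
        return "directed"
    if fit.r2_random >= r2_threshold and fit.r2_random > fit.r2_directed:
        return "random"
    if (
        fit.r2_directed < r2_threshold
        and fit.r2_random < r2_threshold
        and fit.max_msd_um2 < plateau_um2
    ):
        return "constrained"
    return "unclassified"


def fit_track(
    xy: np.ndarray,
    frame_interval_s: float = 1.0,
    max_lag_frac: float = 7 / 8,
    weight_by_pairs: bool = True,
) -> MotionFit:
    """MSD + both model fits for one trajectory."""
    profile = compute_msd(xy, frame_interval_s, max_lag_frac)
    nu, r2d = fit_directed(profile, weight_by_pairs)
    d, r2r = fit_random(profile, weight_by_pairs)
    return MotionFit(
        nu_um_s=nu,
        r2_directed=r2d,
        d_um2_s=d,
        r2_random=r2r,
        max_msd_um2=profile.max_msd_um2,
    )


def classify_tracks(
    tracks: pd.DataFrame,
    frame_interval_s: float = 1.0,
    r2_threshold: float = 0.8,
    plateau_um2: float = 0.05,
    max_lag_frac: float = 7.0 / 8.0,
    min_points: int = 5,
) -> pd.DataFrame:
    """Classify every track in a linked-detection table.

    Returns one row per track: ``track_id, n_points, motion_class,
    nu_um_s, d_um2_s, r2_directed, r2_random, max_msd_um2``.  Tracks
    shorter than ``min_points`` are labelled unclassified with NaN fits.
    """
    rows = []
    for tid, sub in tracks.sort_values("frame").groupby("track_id"):
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        if len(xy) < min_points:
            rows.append(
                dict(
                    track_id=tid,
                    n_points=len(xy),
                    motion_class="unclassified",
                    nu_um_s=np.nan,
                    d_um2_s=np.nan,
                    r2_directed=np.nan,
                    r2_random=np.nan,
                    max_msd_um2=np.nan,
                )
            )
            continue
        fit = fit_track(xy, frame_interval_s, max_lag_frac)
        rows.append(
            dict(
                track_id=tid,
                n_points=len(xy),
                motion_class=classify_track(fit, r2_threshold, plateau_um2),
                nu_um_s=fit.nu_um_s,
                d_um2_s=fit.d_um2_s,
                r2_directed=fit.r2_directed,
                r2_random=fit.r2_random,
                max_msd_um2=fit.max_msd_um2,
            )
        )
    columns = [
        "track_id",
        "n_points",
        "motion_class",
        "nu_um_s",
        "d_um2_s",
        "r2_directed",
        "r2_random",
        "max_msd_um2",
    ]
    return pd.DataFrame(rows, columns=columns)


def estimate_D_cdf(
    tracks: pd.DataFrame | list,
    frame_interval_s: float = 1.0,
    lag: int = 1,
    min_samples: int = 50,
    method: str = "mle",
) -> float:
    """Diffusion coefficient from the distribution of squared displacements.

    For 2D diffusion the squared displacement at fixed lag is exponential,
    ``P(r^2 <= u) = 1 - exp(-u / (4 D lag dt))``, so the maximum-likelihood
    estimate is ``D = mean(r^2) / (4 lag dt)``.  ``method='cdf'`` instead
    least-squares fits the empirical CDF (cross-check; same estimand).
    """
    if isinstance(tracks, pd.DataFrame):
        arrays = [
            sub.sort_values("frame")[["x_um", "y_um"]].to_numpy(float)
            for _, sub in tracks.groupby("track_id")
        ]
    else:
        arrays = [np.asarray(a, float) for a in tracks]
    sq = []
    for xy in arrays:
        if len(xy) > lag:
            disp = xy[lag:] - xy[:-lag]
            sq.append(np.sum(disp * disp, axis=1))
    if not sq:
        raise ValueError("no displacement samples")
    u = np.concatenate(sq)
    if len(u) < min_samples:
        raise ValueError(f"need >= {min_samples} displacement samples, got {len(u)}")
    scale = 4.0 * lag * frame_interval_s
    d_mle = float(np.mean(u)) / scale
    if method == "mle":
        return d_mle
    if method != "cdf":
        raise ValueError("method must be 'mle' or 'cdf'")
    from scipy.optimize import curve_fit

    u_sorted = np.sort(u)
    ecdf = np.arange(1, len(u) + 1) / len(u)

    def model(x, d):
        return 1.0 - np.exp(-x / (scale * d))

    d0 = max(d_mle, 1e-12)
    popt, _ = curve_fit(model, u_sorted, ecdf, p0=[d0], maxfev=10000)
    return float(popt[0])


def frame_fractions(tracks: pd.DataFrame, classes: pd.DataFrame) -> dict:
    """Detection-weighted, frame-averaged class fractions.

    Each detection carries its track's class; per frame the class shares
    are computed, then averaged over frames that contain detections.
    """
    merged = tracks.merge(
        classes[["track_id", "motion_class"]], on="track_id", how="left"
    )
    merged["motion_class"] = merged["motion_class"].fillna("unclassified")
    shares = (
        merged.groupby("frame")["motion_class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    out = {c: float(shares[c].mean()) if c in shares else 0.0 for c in CLASSES}
    total = sum(out.values())
    if total > 0:  # guard against float drift; exact sums in practice
        out = {k: v / total for k, v in out.items()}
    return out


def summarize_cell(
    tracks: pd.DataFrame,
    classes: pd.DataFrame,
    area_um2: float,
    n_frames: int,
    frame_interval_s: float = 1.0,
    cell_id: str = "cell",
    min_steps_speed: int = 4,
    length_um: float = float("nan"),
    width_um: float = float("nan"),
    tau_s: float = float("nan"),
    condition: str = "",
    time_min: float = float("nan"),
    speed_projection_factor: float = 1.0,
    bootstrap: int = 0,
    seed=None,
) -> CellSummary:
    """Aggregate classified tracks of one cell into a CellSummary.

    ``rho`` is the mean per-frame detection count divided by cell area;
    ``theta`` fractions are frame-averaged instantaneous shares;
    ``nu`` averages directed tracks with at least ``min_steps_speed``
    steps; D comes both from the mean fit of random tracks and from the
    pooled squared-displacement distribution.  With ``bootstrap > 0``,
    track-level resampling provides standard errors for rho_d, nu and
    the fractions.

    ``speed_projection_factor`` corrects the fitted speeds for the
    chord projection of circumferential motion in a TIRF section: the
    apparent speed of a patch at surface angle phi is ``nu cos(phi)``,
    so averaging over the visible band biases nu down by
    ``sin(phi_max)/phi_max``.  Pass ``phi_max / sin(phi_max)`` (from the
    cell diameter and penetration depth) to deproject; the default of 1
    reports the apparent (in-plane) speed.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if area_um2 <= 0:
        raise ValueError("cell area must be positive")
    mean_count = len(tracks) / n_frames
    rho = mean_count / area_um2
    theta = frame_fractions(tracks, classes)
    directed = classes[
        (classes["motion_class"] == "directed")
        & (classes["n_points"] - 1 >= min_steps_speed)
    ]
    nu = (
        float(directed["nu_um_s"].mean()) * speed_projection_factor
        if len(directed)
        else float("nan")
    )
    random_cls = classes[classes["motion_class"] == "random"]
    d_msd = float(random_cls["d_um2_s"].mean()) if len(random_cls) else float("nan")
    if len(random_cls):
        random_tracks = tracks[tracks["track_id"].isin(random_cls["track_id"])]
        try:
            d_cdf = estimate_D_cdf(random_tracks, frame_interval_s)
        except ValueError:
            d_cdf = float("nan")
    else:
        d_cdf = float("nan")
    summary = CellSummary(
        cell_id=cell_id,
        rho_um2=rho,
        theta_d=theta["directed"],
        theta_r=theta["random"],
        theta_c=theta["constrained"],
        theta_u=theta["unclassified"],
        rho_d_um2=theta["directed"] * rho,
        nu_um_s=nu,
        d_msd_um2_s=d_msd,
        d_cdf_um2_s=d_cdf,
        n_tracks=int(tracks["track_id"].nunique()) if len(tracks) else 0,
        mean_patch_count=mean_count,
        area_um2=area_um2,
        length_um=length_um,
        width_um=width_um,
        tau_s=tau_s,
        condition=condition,
        time_min=time_min,
    )
    if bootstrap > 0 and len(classes) >= 2:
        ids = classes["track_id"].to_numpy()
        by_track = dict(tuple(tracks.groupby("track_id")))
        cls_by_track = classes.set_index("track_id")

        def stat(sample_ids):
            t = pd.concat([by_track[i] for i in sample_ids], ignore_index=True)
            c = cls_by_track.loc[list(sample_ids)].reset_index()
            th = frame_fractions(t, c)
            dsub = c[
                (c["motion_class"] == "directed")
                & (c["n_points"] - 1 >= min_steps_speed)
            ]
            return np.array(
                [
                    th["directed"],
                    th["directed"] * len(t) / n_frames / area_um2,
                    float(dsub["nu_um_s"].mean()) * speed_projection_factor
                    if len(dsub)
                    else np.nan,
                ]
            )

        gen = np.random.default_rng(seed)
        draws = np.array(
            [stat(gen.choice(ids, size=len(ids), replace=True)) for _ in range(bootstrap)]
        )
        se = np.nanstd(draws, axis=0, ddof=1)
        summary.se = {"theta_d": float(se[0]), "rho_d_um2": float(se[1]), "nu_um_s": float(se[2])}
    return summary


def bootstrap_se(items, statistic, n_boot: int = 1000, seed=None) -> float:
    """Standard error of ``statistic(items)`` by resampling with replacement.

    ``items`` is a sequence of sampling units (e.g. tracks); the SE is the
    standard deviation of the statistic over ``n_boot`` resamples.
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items to bootstrap")
    gen = np.random.default_rng(seed)
    n = len(items)
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = gen.integers(0, n, size=n)
        values[b] = statistic([items[i] for i in idx])
    return float(values.std(ddof=1))


class MotionClassifier(BaseEstimator):
    """MSD-based motion classifier (scikit-learn estimator).

    ``predict`` maps a linked-detection table to one motion class per
    track; ``transform`` returns the full per-track fit table.

    Parameters mirror the classification rules: R2 acceptance threshold
    (0.8), confinement plateau (0.05 um^2), maximum-lag fraction (7/8)
    and the minimum track length for classification (5 points).
    """

    def __init__(
        self,
        frame_interval_s: float = 1.0,
        r2_threshold: float = 0.8,
        plateau_um2: float = 0.05,
        max_lag_frac: float = 7.0 / 8.0,
        min_points: int = 5,
    ):
        self.frame_interval_s = frame_interval_s
        self.r2_threshold = r2_threshold
        self.plateau_um2 = plateau_um2
        self.max_lag_frac = max_lag_frac
        self.min_points = min_points

    def fit(self, tracks: pd.DataFrame, y=None) -> "MotionClassifier":
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in (0, 1]")
        self.classes_ = np.asarray(CLASSES)
        return self

    def transform(self, tracks: pd.DataFrame) -> pd.DataFrame:
        return classify_tracks(
            tracks,
            frame_interval_s=self.frame_interval_s,
            r2_threshold=self.r2_threshold,
            plateau_um2=self.plateau_um2,
            max_lag_frac=self.max_lag_frac,
            min_points=self.min_points,
        )

    def fit_transform(self, tracks: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(tracks).transform(tracks)

    def predict(self, tracks: pd.DataFrame) -> np.ndarray:
        return self.fit(tracks).transform(tracks)["motion_class"].to_numpy()
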