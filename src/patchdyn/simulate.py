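"""Synthetic MreB-patch trajectories and TIRFM movies with ground truth.

The generator produces the statistical structure the downstream analysis
assumes: a rod-shaped cell carrying a population of near-diffraction-limited
membrane patches split among three motion modes --

* ``directed``: processive circumferential motion around the cell cylinder
  at constant surface speed ``nu`` (~55 nm/s), appearing in the TIRF
  section as a track crossing the cell width whose apparent speed is
  ``nu * cos(phi)``;
* ``random``: free Brownian diffusion in the membrane
  (``D`` ~ 0.001-0.003 um^2/s);
* ``confined``: Brownian steps reflected at a disk boundary of radius
  ``R``, whose time-averaged MSD plateaus near ``R^2``.

Movies are rendered with a Gaussian PSF, evanescent-decay amplitude
(``exp(-z/h)``), Poisson shot noise and additive Gaussian read noise.
Every rendered spot carries a ground-truth record so detection, tracking
and classification can be scored without any external data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry
from .io import Movie

__all__ = [
    "SimConfig",
    "simulate_directed_track",
    "simulate_directed_track_planar",
    "simulate_brownian_track",
    "simulate_confined_track",
    "compose_population",
    "render_movie",
    "simulate_cell_movie",
]

MODES = ("directed", "random", "confined")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated single-cell movie.

    Defaults reproduce the exponential-growth imaging conditions the
    analysis is designed for: ~2 patches per um^2 of projected cell area,
    one third of them directed at 55 nm/s, 1-s frames over 2 minutes,
    64-nm pixels, and signal/background levels giving a peak SNR of ~8.
    """

    frac_directed: float = 1.0 / 3.0
    frac_random: float = 1.0 / 3.0
    frac_confined: float = 1.0 / 3.0
    directed_speed_um_s: float = 0.055
    diffusion_um2_s: float = 0.002
    confinement_radius_um: float = 0.15
    patch_density_um2: float = 2.0
    n_frames: int = 120
    frame_interval_s: float = 1.0
    pixel_size_um: float = 0.064
    psf_sigma_um: float = 0.08
    amplitude: float = 150.0
    background: float = 100.0
    cell_intensity: float = 40.0
    read_noise: float = 3.0
    loc_noise_um: float = 0.02
    margin_um: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_directed, self.frac_random, self.frac_confined)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("mode fractions must lie in [0, 1]")
        if sum(fr) > 1 + 1e-9:
            raise ValueError("mode fractions must sum to at most 1")
        for name in (
            "directed_speed_um_s",
            "patch_density_um2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "diffusion_um2_s",
            "confinement_radius_um",
            "frame_interval_s",
            "pixel_size_um",
            "psf_sigma_um",
        ):
            if getattr(self, name) <= 0 and name != "diffusion_um2_s":
                raise ValueError(f"{name} must be positive")
        if self.diffusion_um2_s < 0:
            raise ValueError("diffusion_um2_s must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def fractions(self) -> tuple:
        return (self.frac_directed, self.frac_random, self.frac_confined)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_directed_track(
    geom: CellGeometry,
    speed_um_s: float,
    start_angle_rad: float = 0.0,
    axial_pos_um: float = 0.0,
    n: int = 120,
    dt: float = 1.0,
    seed=None,
    loc_noise_um: float = 0.0,
) -> pd.DataFrame:
    """Circumferential track on the cell cylinder, projected to the image plane.

    The surface angle advances by ``2 * nu * dt / D_cell`` per frame
    (angular speed ``nu / radius``); the projected lateral coordinate is
    ``y = (D_cell/2) sin(phi)`` and the axial coordinate stays constant.
    Frames whose surface height exceeds the penetration depth are flagged
    invisible.

    Returns a frame-indexed DataFrame with columns
    ``x_um, y_um, z_um, angle_rad, visible``.  ``x`` is axial and ``y``
    lateral, both relative to the cell centre.
    """
    if speed_um_s < 0:
        raise ValueError("speed_um_s must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    half_cyl = geom.cylinder_length_um / 2
    if abs(axial_pos_um) > half_cyl:
        raise ValueError("axial_pos_um must lie within the cylindrical part")
    t = np.arange(n) * dt
    phi = start_angle_rad + 2.0 * speed_um_s * t / geom.diameter_um
    y = geom.radius_um * np.sin(phi)
    z = geom.radius_um * (1.0 - np.cos(phi))
    x = np.full(n, float(axial_pos_um))
    if loc_noise_um > 0:
        gen = _rng(seed)
        x = x + gen.normal(0.0, loc_noise_um, n)
        y = y + gen.normal(0.0, loc_noise_um, n)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "x_um": x,
            "y_um": y,
            "z_um": z,
            "angle_rad": phi,
            "visible": z <= geom.penetration_depth_um,
        }
    )


def simulate_directed_track_planar(
    speed_um_s: float,
    n: int = 20,
    dt: float = 1.0,
    heading_rad: float = 0.0,
    loc_noise_um: float = 0.02,
    seed=None,
) -> np.ndarray:
    """Straight constant-speed 2D track with localisation noise.

    The planar idealisation of directed motion (``MSD = (nu t)^2``),
    used for track-level fixtures where tracking error should be
    separable from detection and projection effects.
    """
    if speed_um_s < 0:
        raise ValueError("speed_um_s must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(n) * dt
    xy = np.column_stack(
        [speed_um_s * t * math.cos(heading_rad), speed_um_s * t * math.sin(heading_rad)]
    )
    if loc_noise_um > 0:
        xy = xy + _rng(seed).normal(0.0, loc_noise_um, xy.shape)
    return xy


def simulate_brownian_track(
    diffusion_um2_s: float,
    n: int = 25,
    dt: float = 1.0,
    seed=None,
    origin=(0.0, 0.0),
) -> np.ndarray:
    """Free 2D Brownian trajectory: Gaussian increments, per-axis variance 2*D*dt.

    Returns an ``(n, 2)`` array of positions in micrometres.
    """
    if diffusion_um2_s < 0:
        raise ValueError("diffusion_um2_s must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    gen = _rng(seed)
    sigma = math.sqrt(2.0 * diffusion_um2_s * dt)
    steps = gen.normal(0.0, sigma, size=(n - 1, 2)) if n > 1 else np.zeros((0, 2))
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return pos + np.asarray(origin, dtype=float)


def _reflect_into_disk(p: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point at a circular boundary (applied iteratively)."""
    for _ in range(16):
        d = p - center
        r = math.hypot(d[0], d[1])
        if r <= radius:
            return p
        p = center + d * (2.0 * radius - r) / r
        if abs(2.0 * radius - r) > radius:
            # pathological step far outside; clamp to the boundary
            d = p - center
            r = math.hypot(d[0], d[1])
            if r > radius:
                p = center + d * (radius / r)
            return p
    return p


def simulate_confined_track(
    radius_um: float,
    diffusion_um2_s: float = 0.002,
    n: int = 120,
    dt: float = 1.0,
    seed=None,
    center=(0.0, 0.0),
) -> np.ndarray:
    """Brownian steps reflected at a disk of radius ``R``.

    The stationary distribution is uniform on the disk, so the long-lag
    MSD plateaus at ``E|r1 - r2|^2 = R^2``.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if diffusion_um2_s < 0:
        raise ValueError("diffusion_um2_s must be >= 0")
    gen = _rng(seed)
    sigma = math.sqrt(2.0 * diffusion_um2_s * dt)
    c = np.asarray(center, dtype=float)
    pos = np.empty((n, 2))
    pos[0] = c
    p = c.copy()
    for i in range(1, n):
        p = _reflect_into_disk(p + gen.normal(0.0, sigma, 2), c, radius_um)
        pos[i] = p
    return pos


def _surface_to_image(geom: CellGeometry, x: np.ndarray, s: np.ndarray):
    """Map unrolled surface coordinates (axial x, arc s) to projected image plane.

    Arc position is taken modulo the circumference; returns projected
    lateral ``y``, height ``z`` and visibility flags.
    """
    r = geom.radius_um
    phi = np.mod(s / r + math.pi, 2 * math.pi) - math.pi  # wrap to (-pi, pi]
    y = r * np.sin(phi)
    z = r * (1.0 - np.cos(phi))
    visible = z <= geom.penetration_depth_um
    return y, z, visible


def expected_patch_count(patch_density_um2: float, area_um2: float) -> float:
    """Expected number of patches in view: density times (visible) area."""
    return patch_density_um2 * area_um2


def compose_population(
    config: SimConfig, geom: CellGeometry, seed=None
) -> pd.DataFrame:
    """Simulate a full patch population on one cell, with ground truth.

    Tracks live on the unrolled cylinder surface (axial position,
    circumferential arc) and are projected into the image plane.  The
    target instantaneous visible patch count is
    ``patch_density_um2 * visible projected area`` (the illuminated
    band, which is also what contour segmentation of the movie
    measures); directed tracks, which spend only ``visible_fraction`` of
    a revolution in the evanescent field, are oversampled by its inverse
    so the per-frame composition matches the configured fractions.

    Returns a long-format DataFrame with one row per track per frame:
    ``track_id, frame, mode, x_um, y_um, z_um, visible,
    true_speed_um_s, true_D_um2_s``.  Coordinates are cell-centred.
    """
    gen = _rng(config.seed if seed is None else seed)
    fr = np.asarray(config.fractions, dtype=float)
    if fr.sum() <= 0:
        raise ValueError("at least one mode fraction must be positive")
    fr = fr / fr.sum()

    def stochastic_round(x: float) -> int:
        base = int(math.floor(x))
        return base + int(gen.random() < (x - base))

    n_target = config.patch_density_um2 * geom.visible_area_um2
    f_vis = geom.visible_fraction
    n_directed = stochastic_round(n_target * fr[0] / f_vis)
    n_random = stochastic_round(n_target * fr[1])
    n_confined = stochastic_round(n_target * fr[2])

    mean_spacing = 1.0 / math.sqrt(max(config.patch_density_um2, 1e-12))
    if mean_spacing < 2.0 * config.psf_sigma_um:
        import warnings

        warnings.warn(
            "patch density so high that mean spacing < 2 PSF sigma; "
            "detection will merge neighbouring spots",
            stacklevel=2,
        )

    n, dt = config.n_frames, config.frame_interval_s
    half_cyl = geom.cylinder_length_um / 2
    r = geom.radius_um
    records = []
    tid = 0

    def axial_start():
        return gen.uniform(-half_cyl, half_cyl)

    for _ in range(n_directed):
        phi0 = gen.uniform(-math.pi, math.pi)
        x = np.full(n, axial_start())
        s = phi0 * r + config.directed_speed_um_s * np.arange(n) * dt
        records.append((tid, "directed", x, s, config.directed_speed_um_s, 0.0))
        tid += 1
    sigma = math.sqrt(2.0 * config.diffusion_um2_s * dt)
    phi_max = geom.max_visible_angle
    arc_max = phi_max * r
    for _ in range(n_random):
        # surface Brownian motion; reflected axially at the cylinder ends and
        # circumferentially at the visibility edge (in steady state the flux
        # of patches diffusing out of view equals the flux diffusing in, so
        # reflection preserves the stationary visible count)
        steps = gen.normal(0.0, sigma, size=(n, 2))
        steps[0] = 0.0
        x = axial_start() + np.cumsum(steps[:, 0])
        x = _reflect_interval(x, -half_cyl, half_cyl)
        s = gen.uniform(-arc_max, arc_max) + np.cumsum(steps[:, 1])
        s = _reflect_interval(s, -arc_max, arc_max)
        records.append((tid, "random", x, s, 0.0, config.diffusion_um2_s))
        tid += 1
    conf_arc = max(arc_max - config.confinement_radius_um, 0.0)
    for _ in range(n_confined):
        c = np.array([axial_start(), gen.uniform(-conf_arc, conf_arc)])
        pos = simulate_confined_track(
            config.confinement_radius_um, config.diffusion_um2_s, n, dt, gen, center=c
        )
        records.append((tid, "confined", pos[:, 0], pos[:, 1], 0.0, config.diffusion_um2_s))
        tid += 1

    frames = np.arange(n)
    parts = []
    for tid_, mode, x, s, nu, d in records:
        y, z, visible = _surface_to_image(geom, np.asarray(x, float), np.asarray(s, float))
        parts.append(
            pd.DataFrame(
                {
                    "track_id": tid_,
                    "frame": frames,
                    "mode": mode,
                    "x_um": x,
                    "y_um": y,
                    "z_um": z,
                    "visible": visible,
                    "true_speed_um_s": nu,
                    "true_D_um2_s": d,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=[
                "track_id",
                "frame",
                "mode",
                "x_um",
                "y_um",
                "z_um",
                "visible",
                "true_speed_um_s",
                "true_D_um2_s",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def _reflect_interval(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a free trajectory into [lo, hi] by reflection at both ends."""
    width = hi - lo
    if width <= 0:
        raise ValueError("empty interval")
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def _cell_body_profile(geom: CellGeometry, shape, pixel_size_um, origin_um):
    """Evanescent-weighted diffuse cell-body brightness (peak-normalised).

    The bottom surface of a spherocylinder lying on the coverslip sits at
    height ``z(x, y) = R - sqrt(R^2 - d^2)`` where ``d`` is the lateral
    distance from the cell axis (including the pole caps), so diffuse
    membrane fluorescence under TIRF decays as ``exp(-z/h)`` from the
    centreline toward the cell edges -- no sharp intensity step.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    x_um = xx * pixel_size_um - origin_um[0]
    y_um = yy * pixel_size_um - origin_um[1]
    half_cyl = geom.cylinder_length_um / 2
    ax = np.clip(x_um, -half_cyl, half_cyl)
    dist = np.hypot(x_um - ax, y_um)
    r = geom.radius_um
    inside = dist < r
    z = np.where(inside, r - np.sqrt(np.clip(r * r - dist * dist, 0.0, None)), np.inf)
    return np.where(inside, np.exp(-z / geom.penetration_depth_um), 0.0)


def render_movie(
    tracks: pd.DataFrame,
    geom: CellGeometry,
    config: SimConfig,
    seed=None,
) -> tuple:
    """Render a population into a noisy TIRFM movie.

    Each visible spot becomes a 2D Gaussian of width ``psf_sigma_um``
    whose amplitude decays as ``exp(-z/h)`` with surface height ``z``
    (evanescent excitation).  A uniform cell-body fluorescence is added
    over the projected footprint so the maximum-intensity projection
    segments like a real TIRF movie, then Poisson shot noise on all
    photon terms and Gaussian read noise are applied and the result is
    quantised to ``uint16``.

    Returns ``(Movie, ground_truth)`` where the ground truth is the input
    table augmented with pixel coordinates ``x_px, y_px`` (0-based pixel
    centres).  An empty track table yields a valid noise-only movie.
    """
    gen = _rng(config.seed + 1 if seed is None else seed)
    px = config.pixel_size_um
    margin = config.margin_um
    w = int(math.ceil((geom.length_um + 2 * margin) / px))
    h = int(math.ceil((geom.diameter_um + 2 * margin) / px))
    # cell centre in image um coordinates
    origin = (geom.length_um / 2 + margin, geom.diameter_um / 2 + margin)

    body = _cell_body_profile(geom, (h, w), px, origin) * config.cell_intensity
    base = config.background + body

    truth = tracks.copy()
    if len(truth):
        truth["x_px"] = (truth["x_um"] + origin[0]) / px
        truth["y_px"] = (truth["y_um"] + origin[1]) / px
    else:
        truth = truth.assign(x_px=pd.Series(dtype=float), y_px=pd.Series(dtype=float))

    sigma_px = config.psf_sigma_um / px
    stack = np.empty((config.n_frames, h, w), dtype=np.uint16)
    yy, xx = np.mgrid[0:h, 0:w]
    by_frame = dict(tuple(truth.groupby("frame"))) if len(truth) else {}
    depth = geom.penetration_depth_um
    for f in range(config.n_frames):
        signal = base.copy()
        sub = by_frame.get(f)
        if sub is not None:
            vis = sub[sub["visible"]]
            for _, row in vis.iterrows():
                amp = config.amplitude * math.exp(-row["z_um"] / depth)
                signal += amp * np.exp(
                    -((xx - row["x_px"]) ** 2 + (yy - row["y_px"]) ** 2)
                    / (2.0 * sigma_px**2)
                )
        frame = gen.poisson(signal) + gen.normal(0.0, config.read_noise, signal.shape)
        stack[f] = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)

    movie = Movie(
        pixels=stack,
        pixel_size_um=px,
        frame_interval_s=config.frame_interval_s,
        metadata={"seed": config.seed, "config": dataclasses.asdict(config)},
    )
    return movie, truth


def simulate_cell_movie(
    config: SimConfig, geom: CellGeometry | None = None
) -> tuple:
    """Convenience wrapper: compose a population and render it.

    Returns ``(Movie, ground_truth)``.  Fully determined by
    ``config.seed`` (identical configs give identical movies).
    """
    if geom is None:
        geom = CellGeometry(length_um=3.0, diameter_um=0.89)
    tracks = compose_population(config, geom, seed=config.seed)
    return render_movie(tracks, geom, config, seed=config.seed + 1)
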