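"""Geometric models linking directed-patch dynamics to sidewall elongation.

If glycan strands are laid down circumferentially, the ``N_d`` directed
patches of a cell moving at speed ``nu`` over one generation time ``tau``
collectively cover ``N_d * nu * tau`` of arc, i.e.

    FT = N_d * nu * tau / (pi * D_cell)

full turns around the cell perimeter.  Dividing the sidewall elongation
per generation by the number of turns gives the axial width of new wall
inserted per turn,

    omega_simple = (L - D_cell) / FT,

and integrating synthesis over an exponential cell cycle refines this to

    omega_refined = ln(2) / (tau * nu * rho_d),

with ``rho_d`` the directed patch density.  Substituting
``N_d = rho_d * pi * D_cell * (L - D_cell)`` into the first expression
makes the two differ by exactly ``ln 2``.

A cross-cell regression of ``L - D_cell`` on FT tests whether omega is a
constant of the organism (slope = omega, as in *B. subtilis*) or varies
with growth condition (as in *E. coli*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import CellGeometry, visible_fraction

__all__ = [
    "GrowthParams",
    "full_turns",
    "band_width_simple",
    "band_width_refined",
    "sidewall_vs_turns_regression",
    "extrapolate_total_patches",
    "upshift_timecourse",
    "growth_rate_from_area",
    "make_growth_population",
]


@dataclass(frozen=True)
class GrowthParams:
    """Per-cell inputs of the elongation model.

    ``n_directed`` (N_d) is the whole-cell count of directed patches;
    ``tau_s`` the generation time (an input, measured by bulk growth,
    never inferred from movies); ``diameter_um`` the cell diameter
    D_cell; ``rho_d_um2`` the directed patch density.
    """

    n_directed: float
    nu_um_s: float
    tau_s: float
    diameter_um: float
    length_um: float
    rho_d_um2: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("nu_um_s", "tau_s", "diameter_um", "length_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_directed < 0:
            raise ValueError("n_directed must be non-negative")
        if self.length_um <= self.diameter_um:
            raise ValueError("length_um must exceed diameter_um")


def full_turns(params: GrowthParams) -> float:
    """Full turns around the perimeter per generation: N_d*nu*tau/(pi*D_cell)."""
    if params.diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return params.n_directed * params.nu_um_s * params.tau_s / (
        math.pi * params.diameter_um
    )


def band_width_simple(length_um: float, diameter_um: float, ft: float) -> float:
    """Inserted band width per turn: omega = (L - D_cell) / FT (um)."""
    if ft <= 0:
        raise ValueError("FT must be positive")
    if length_um <= diameter_um:
        raise ValueError("length must exceed diameter")
    return (length_um - diameter_um) / ft


def band_width_refined(tau_s: float, nu_um_s: float, rho_d_um2: float) -> float:
    """Cell-cycle-integrated band width: omega = ln(2)/(tau * nu * rho_d) (um)."""
    if tau_s <= 0 or nu_um_s <= 0 or rho_d_um2 <= 0:
        raise ValueError("tau, nu and rho_d must all be positive")
    return math.log(2.0) / (tau_s * nu_um_s * rho_d_um2)


def sidewall_vs_turns_regression(sidewall_um, ft) -> tuple:
    """OLS of sidewall length (L - D_cell) on full turns FT.

    Returns ``(slope, intercept, r2)``; the slope, in um per turn, is an
    estimate of omega.  Raises on fewer than 3 cells or degenerate
    (constant-FT) input.
    """
    x = np.asarray(ft, dtype=float)
    y = np.asarray(sidewall_um, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 (sidewall, FT) pairs")
    if np.ptp(x) == 0:
        raise ValueError("FT values are constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def extrapolate_total_patches(
    observed_mean_count: float,
    geom: CellGeometry | None = None,
    diameter_um: float | None = None,
    penetration_depth_um: float = 0.2,
) -> float:
    """Whole-cell patch count from the TIRF-visible count.

    Divides by the visible circumference fraction
    ``f = arccos(1 - 2h/D_cell)/pi`` (capped at 1 when the evanescent
    field spans the cell).  With D_cell = 0.89 um and h = 0.2 um,
    f = 0.314 -- the "bottom third" of the cell.
    """
    if observed_mean_count < 0:
        raise ValueError("observed count must be non-negative")
    if geom is not None:
        diameter_um = geom.diameter_um
        penetration_depth_um = geom.penetration_depth_um
    if diameter_um is None:
        raise ValueError("provide a CellGeometry or a diameter")
    if penetration_depth_um >= diameter_um:
        f = 1.0
    else:
        f = visible_fraction(diameter_um, penetration_depth_um)
    return observed_mean_count / f


def upshift_timecourse(
    summaries: pd.DataFrame,
    statistics: tuple = ("rho_um2", "nu_um_s", "theta_d"),
    time_column: str = "time_min",
    normalize: tuple = (),
    preshift_max_time: float = 0.0,
) -> pd.DataFrame:
    """Aggregate per-cell summaries over an upshift time course.

    Cells are grouped by their time label; each statistic gets a mean and
    SD column.  Statistics named in ``normalize`` are additionally
    divided by their pre-shift mean (time < ``preshift_max_time``),
    matching how directed fractions are reported relative to the poor
    medium baseline.  Missing time points are simply absent rows.
    """
    if len(summaries) == 0:
        raise ValueError("no cell summaries")
    grouped = summaries.groupby(time_column)
    out = {}
    for stat in statistics:
        out[f"{stat}_mean"] = grouped[stat].mean()
        out[f"{stat}_sd"] = grouped[stat].std(ddof=0)
        out[f"{stat}_n"] = grouped[stat].count()
    result = pd.DataFrame(out).reset_index().sort_values(time_column)
    for stat in normalize:
        pre = summaries[summaries[time_column] < preshift_max_time]
        if len(pre) == 0:
            raise ValueError("no pre-shift cells to normalize against")
        baseline = pre[stat].mean()
        result[f"{stat}_norm"] = result[f"{stat}_mean"] / baseline
    return result


def growth_rate_from_area(
    time: np.ndarray, area_um2: np.ndarray, window: int = 3
) -> np.ndarray:
    """Instantaneous exponential growth rate from an area time series.

    The rate at each point is the slope of ``ln(area)`` against time over
    a centred sliding window (truncated at the series ends).  Units are
    the inverse of the time units supplied.
    """
    t = np.asarray(time, dtype=float)
    a = np.asarray(area_um2, dtype=float)
    if len(t) < 3 or len(t) != len(a):
        raise ValueError("need >= 3 (time, area) points")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    if window < 2:
        raise ValueError("window must span at least 2 points")
    log_a = np.log(a)
    half = window // 2
    rates = np.empty(len(t))
    for i in range(len(t)):
        lo = max(0, i - half)
        hi = min(len(t), lo + window)
        lo = max(0, hi - window)
        rates[i] = np.polyfit(t[lo:hi], log_a[lo:hi], 1)[0]
    return rates


DEFAULT_CONDITIONS = (
    {"condition": "poor", "tau_s": 4050.0, "length_mean_um": 2.2, "length_sd_um": 0.25},
    {"condition": "rich", "tau_s": 1350.0, "length_mean_um": 3.8, "length_sd_um": 0.40},
)


def make_growth_population(
    n_cells_per_condition: int = 25,
    omega_um: float | dict = 0.014,
    diameter_um: float = 0.89,
    rho_d_um2: float = 2.0 / 3.0,
    conditions=DEFAULT_CONDITIONS,
    noise: float = 0.10,
    seed=None,
) -> pd.DataFrame:
    """Synthetic cell populations spanning growth conditions.

    Emulates the cross-condition experiment behind the sidewall-vs-turns
    regression: each condition has its own generation time and length
    distribution (rapidly growing cells are roughly twice as long), and
    the directed patch speed scales inversely with the generation time
    (speed proportional to growth rate), keeping ``tau * nu`` constant.

    ``omega_um`` may be a scalar (a constant band width: each cell's
    turn count is ``FT = (L - D_cell)/omega`` and the measured sidewall
    scatters around ``omega * FT`` with relative s.d. ``noise``) or a
    ``{condition: omega}`` mapping (condition-dependent insertion
    capacity, the contrasting regime).  Directed counts are back-solved
    as ``N_d = FT * pi * D_cell / (nu * tau)``.
    """
    gen = np.random.default_rng(seed)
    omegas = (
        {c["condition"]: omega_um for c in conditions}
        if np.isscalar(omega_um)
        else dict(omega_um)
    )
    frames = []
    for cond in conditions:
        name = cond["condition"]
        tau = cond["tau_s"]
        omega = omegas[name]
        # speed tracks growth rate: nu = ln2/(omega * rho_d * tau)
        nu = math.log(2.0) / (omega * rho_d_um2 * tau)
        lengths = np.clip(
            gen.normal(cond["length_mean_um"], cond["length_sd_um"], n_cells_per_condition),
            diameter_um + 0.3,
            None,
        )
        true_sidewall = lengths - diameter_um
        ft = true_sidewall / omega
        sidewall = true_sidewall * (1.0 + noise * gen.standard_normal(len(lengths)))
        n_d = ft * math.pi * diameter_um / (nu * tau)
        frames.append(
            pd.DataFrame(
                {
                    "condition": name,
                    "length_um": diameter_um + sidewall,
                    "diameter_um": diameter_um,
                    "sidewall_um": sidewall,
                    "ft": ft,
                    "n_directed": n_d,
                    "rho_d_um2": n_d / (math.pi * diameter_um * true_sidewall),
                    "nu_um_s": nu,
                    "tau_s": tau,
                    "omega_true_um": omega,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
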