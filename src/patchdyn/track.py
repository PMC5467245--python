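"""Frame-to-frame linking of detections into gap-free tracks.

Linking uses globally optimal bipartite assignment per consecutive frame
pair: candidate links are gated at a maximum displacement (3 px by
default, matching ~1 s frame intervals and <=55 nm/s patch speeds), the
assignment minimises total squared displacement, and non-assignment
(track termination / birth) costs the squared gate radius.  No gap
closing and no merging or splitting: a missed detection terminates a
track and a new one starts when the patch reappears.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

__all__ = ["TrackLinker", "link_detections", "filter_tracks", "track_positions"]

_INF = 1e12


def _assign(prev_xy: np.ndarray, curr_xy: np.ndarray, gate: float) -> list:
    """Gated minimum-cost assignment between two frames.

    Returns a list of ``(i_prev, j_curr)`` matched index pairs.  Uses the
    standard augmented square cost matrix: the top-left block holds
    squared distances (infinite beyond the gate), and diagonal
    birth/death blocks cost ``gate**2`` each.
    """
    m, n = len(prev_xy), len(curr_xy)
    if m == 0 or n == 0:
        return []
    d2 = (
        (prev_xy[:, None, 0] - curr_xy[None, :, 0]) ** 2
        + (prev_xy[:, None, 1] - curr_xy[None, :, 1]) ** 2
    )
    gate2 = gate * gate
    link = np.where(d2 <= gate2, d2, _INF)
    cost = np.full((m + n, m + n), _INF)
    cost[:m, :n] = link
    cost[np.arange(m), n + np.arange(m)] = gate2  # death of previous tracks
    cost[m + np.arange(n), np.arange(n)] = gate2  # birth of new tracks
    cost[m:, n:] = 0.0  # dummy-dummy completions
    rows, cols = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(rows, cols) if i < m and j < n and link[i, j] < _INF]


def link_detections(detections: pd.DataFrame, max_radius_px: float = 3.0) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    Parameters
    ----------
    detections:
        DataFrame with at least ``frame, x_px, y_px`` columns.
    max_radius_px:
        Gate radius: no link may exceed this frame-to-frame displacement.

    Returns
    -------
    DataFrame
        Copy of the input with a ``track_id`` column.  Every detection
        belongs to exactly one track (possibly of length 1); frame
        indices within a track are strictly consecutive.
    """
    det = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    track_id = np.full(len(det), -1, dtype=int)
    if len(det) == 0:
        out = det.copy()
        out["track_id"] = track_id
        return out
    next_id = 0
    prev_idx: list = []  # row indices of detections in the previous frame
    prev_frame = None
    frame_groups = det.groupby("frame", sort=True).indices
    for frame in sorted(frame_groups):
        idx = list(frame_groups[frame])
        if prev_frame is not None and frame == prev_frame + 1 and prev_idx:
            prev_xy = det.loc[prev_idx, ["x_px", "y_px"]].to_numpy(float)
            curr_xy = det.loc[idx, ["x_px", "y_px"]].to_numpy(float)
            for i, j in _assign(prev_xy, curr_xy, max_radius_px):
                track_id[idx[j]] = track_id[prev_idx[i]]
        for j in idx:
            if track_id[j] < 0:
                track_id[j] = next_id
                next_id += 1
        prev_idx, prev_frame = idx, frame
    out = det.copy()
    out["track_id"] = track_id
    return out


def filter_tracks(
    tracks: pd.DataFrame,
    min_points_classify: int = 5,
    min_steps_speed: int = 4,
) -> tuple:
    """Split track ids into classifiable and speed-eligible sets.

    Motion-model classification requires at least five frames; speed
    estimation requires at least four steps (these coincide for the
    defaults).  Shorter tracks remain in the table -- they still count
    towards patch density -- but are labelled unclassifiable downstream.

    Returns ``(classifiable_ids, speed_eligible_ids)`` as sorted arrays.
    """
    if len(tracks) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    sizes = tracks.groupby("track_id").size()
    classifiable = sizes[sizes >= min_points_classify].index.to_numpy()
    speed = sizes[sizes - 1 >= min_steps_speed].index.to_numpy()
    return np.sort(classifiable), np.sort(speed)


def track_positions(tracks: pd.DataFrame, track_id: int, unit: str = "um") -> np.ndarray:
    """Positions of one track as an (n, 2) array, ordered by frame."""
    cols = ["x_um", "y_um"] if unit == "um" else ["x_px", "y_px"]
    sub = tracks[tracks["track_id"] == track_id].sort_values("frame")
    return sub[cols].to_numpy(float)


class TrackLinker(BaseEstimator):
    """Gated nearest-assignment particle linker (scikit-learn transformer).

    Stateless: ``fit`` only validates, ``transform`` appends a
    ``track_id`` column to a detection table.

    Parameters
    ----------
    max_radius_px:
        Maximum frame-to-frame displacement (gate), in pixels.
    """

    def __init__(self, max_radius_px: float = 3.0):
        self.max_radius_px = max_radius_px

    def fit(self, detections: pd.DataFrame, y=None) -> "TrackLinker":
        if self.max_radius_px <= 0:
            raise ValueError("max_radius_px must be positive")
        self.n_detections_ = len(detections)
        return self

    def transform(self, detections: pd.DataFrame) -> pd.DataFrame:
        if self.max_radius_px <= 0:
            raise ValueError("max_radius_px must be positive")
        return link_detections(detections, self.max_radius_px)

    def fit_transform(self, detections: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(detections).transform(detections)
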