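"""Final-model selection from scored trajectories.

The selection rule: pick the trajectory with the highest mean map
cross-correlation, then within it the frame maximizing the *compound score*

    compound = minmax(cc) + minmax(|geometry score|)

where each term is min-max normalized to [0, 1], so the compound score lies
in [0, 2] and rewards frames that fit the map *and* keep good geometry.
Normalization extrema come either from the single trajectory
(``per_trajectory``, the default) or pooled across all trajectories of a
system (``global``). Geometry scores must be negative (statistical-potential
convention: more negative = better); taking the absolute value of a positive
score would silently invert the ordering, so that case is a hard error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoreSeries",
    "SelectionReport",
    "min_max_normalize",
    "compound_scores",
    "select_trajectory",
    "select_frame",
    "select_final_model",
]


@dataclass
class ScoreSeries:
    """Per-frame scores of one refinement trajectory."""

    frame_indices: list[int]
    cc: list[float]
    geometry_scaled: list[float]
    trajectory_id: str = "traj"

    def __post_init__(self) -> None:
        if not (len(self.frame_indices) == len(self.cc) == len(self.geometry_scaled)):
            raise ValueError("score series columns must have equal length")
        if len(self.frame_indices) < 1:
            raise ValueError("score series must contain at least one frame")
        if any(b <= a for a, b in zip(self.frame_indices, self.frame_indices[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def mean_cc(self) -> float:
        return float(np.mean(self.cc))

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "frame": self.frame_indices,
                "cc": self.cc,
                "geometry_scaled": self.geometry_scaled,
                "trajectory_id": self.trajectory_id,
            }
        ).to_csv(path, index=False)


@dataclass
class SelectionReport:
    chosen_trajectory: str
    mean_cc: dict[str, float]
    chosen_frame: int
    compound: list[float]
    normalization_mode: str

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def min_max_normalize(values) -> np.ndarray:
    """(x − min) / (max − min), mapped into [0, 1]; constant input → zeros."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot normalize an empty series")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant series in min-max normalization: returning zeros",
                      stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _extrema(series: ScoreSeries, pool: list[ScoreSeries] | None, mode: str):
    if mode == "per_trajectory" or pool is None:
        cc_all = np.asarray(series.cc)
        geo_all = np.abs(np.asarray(series.geometry_scaled))
    elif mode == "global":
        cc_all = np.concatenate([np.asarray(s.cc) for s in pool])
        geo_all = np.concatenate([np.abs(np.asarray(s.geometry_scaled)) for s in pool])
    else:
        raise ValueError(f"unknown normalization mode: {mode}")
    return (cc_all.min(), cc_all.max()), (geo_all.min(), geo_all.max())


def compound_scores(
    series: ScoreSeries,
    pool: list[ScoreSeries] | None = None,
    mode: str = "per_trajectory",
) -> np.ndarray:
    """Compound score per frame: normalized cc + normalized |geometry|.

    In ``global`` mode the min-max extrema are pooled over ``pool`` (all
    trajectories of the system); in ``per_trajectory`` mode only this
    series' extrema are used.
    """
    geo = np.asarray(series.geometry_scaled, dtype=np.float64)
    if np.any(geo >= 0):
        raise ValueError(
            "geometry scores must be negative (more negative = better); "
            "a non-negative score would invert the |score| ordering"
        )
    (cc_lo, cc_hi), (g_lo, g_hi) = _extrema(series, pool, mode)

    def norm(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if hi == lo:
            warnings.warn("constant series in min-max normalization: using zeros",
                          stacklevel=2)
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    cc_n = norm(np.asarray(series.cc, dtype=np.float64), cc_lo, cc_hi)
    geo_n = norm(np.abs(geo), g_lo, g_hi)
    return cc_n + geo_n


def select_trajectory(all_series: list[ScoreSeries]) -> str:
    """Label of the trajectory with the highest mean cross-correlation.

    Ties break toward the lexicographically smallest label.
    """
    if not all_series:
        raise ValueError("no score series given")
    # max() keeps the first maximal element, so sorting by label first
    # implements the smallest-label tie rule
    best = max(sorted(all_series, key=lambda s: s.trajectory_id),
               key=lambda s: s.mean_cc)
    return best.trajectory_id


def select_frame(
    series: ScoreSeries,
    pool: list[ScoreSeries] | None = None,
    mode: str = "per_trajectory",
) -> int:
    """Frame index maximizing the compound score (earliest frame on ties)."""
    comp = compound_scores(series, pool, mode)
    return int(series.frame_indices[int(np.argmax(comp))])


def select_final_model(
    all_series: list[ScoreSeries],
    mode: str = "per_trajectory",
) -> SelectionReport:
    """Full selection: best-mean-cc trajectory, then best-compound frame."""
    chosen_id = select_trajectory(all_series)
    chosen = next(s for s in all_series if s.trajectory_id == chosen_id)
    pool = all_series if mode == "global" else None
    comp = compound_scores(chosen, pool, mode)
    frame = int(chosen.frame_indices[int(np.argmax(comp))])
    return SelectionReport(
        chosen_trajectory=chosen_id,
        mean_cc={s.trajectory_id: s.mean_cc for s in all_series},
        chosen_frame=frame,
        compound=[float(c) for c in comp],
        normalization_mode=mode,
    )
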