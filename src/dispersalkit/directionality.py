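"""Directionality tests for recapture locations.

The diffusion analysis assumes equal displacement in all directions.  To
test it, recapture locations are projected on the east-west and
north-south transects; per-release mean net displacements are pooled with
weights proportional to the number of beetles captured in each release
(normalized to average 1), a bootstrap over individuals within releases
yields the standard error, and a weighted one-sample Student's t-test
with df = releases - 1 assesses departure from the release point.  Drift
magnitude is reported relative to the dispersal scale, the root mean
square of the recapture distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CaptureRecord, TrapLayout

__all__ = [
    "AXES",
    "project_displacements",
    "weighted_pooled_mean",
    "bootstrap_se",
    "weighted_t_test",
    "dispersal_scale",
    "drift_fraction",
    "DisplacementSummary",
    "NetDisplacementTest",
]

logger = logging.getLogger(__name__)

AXES = ("east_west", "north_south")
_AXIS_COL = {"east_west": "x", "north_south": "y"}


def _capture_points(
    captures: Sequence[CaptureRecord], layout: TrapLayout
) -> pd.DataFrame:
    """One row per captured beetle with trap coordinates (counts expanded)."""
    recs = []
    for cap in captures:
        trap = layout.trap(cap.trap_id)
        for _ in range(cap.n_marked):
            recs.append({"release_id": cap.release_id, "x": trap.x, "y": trap.y})
    return pd.DataFrame(recs, columns=["release_id", "x", "y"])


def project_displacements(
    captures: Sequence[CaptureRecord], layout: TrapLayout
) -> pd.DataFrame:
    """Per-release mean displacement on each axis.

    Returns a frame with release_id, n_captured, mean_x (east-west) and
    mean_y (north-south); records holding several beetles are
    count-weighted.  Releases without captures simply do not appear.
    """
    pts = _capture_points(captures, layout)
    if pts.empty:
        raise ValueError("no captures to project")
    out = (
        pts.groupby("release_id")
        .agg(n_captured=("x", "size"), mean_x=("x", "mean"), mean_y=("y", "mean"))
        .reset_index()
    )
    return out


def weighted_pooled_mean(means: np.ndarray, n_captured: np.ndarray) -> float:
    """Pool per-release means with capture-count weights averaging 1.

    w_i = n_i / mean(n); the normalization cancels in the mean itself but
    fixes the weight scale used by the variance conventions downstream.
    """
    means = np.asarray(means, float)
    n = np.asarray(n_captured, float)
    if len(means) == 0:
        raise ValueError("need at least one release")
    if np.all(n == 0):
        raise ValueError("all weights are zero")
    w = n / n.mean()
    return float(np.sum(w * means) / np.sum(w))


def bootstrap_se(
    captures: Sequence[CaptureRecord],
    layout: TrapLayout,
    axis: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Bootstrap SE of the weighted pooled mean displacement on one axis.

    Individuals are resampled with replacement within each release; per
    replicate the weighted pooled mean is recomputed and the SE is the
    standard deviation of the replicate means.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    col = _AXIS_COL[axis]
    pts = _capture_points(captures, layout)
    groups = [g[col].to_numpy() for _, g in pts.groupby("release_id")]
    for g in groups:
        if len(g) == 1:
            logger.info("release with a single capture contributes zero within-release variance")
    n_per = np.array([len(g) for g in groups], float)
    rng = np.random.default_rng(seed)
    # resampled per-release means, one row per bootstrap replicate
    means = np.empty((n_boot, len(groups)))
    for j, g in enumerate(groups):
        idx = rng.integers(0, len(g), size=(n_boot, len(g)))
        means[:, j] = g[idx].mean(axis=1)
    w = n_per / n_per.mean()
    reps = (means * w).sum(axis=1) / w.sum()
    return float(np.std(reps, ddof=1))


def weighted_t_test(pooled_mean: float, se: float, n_releases: int) -> tuple[float, int, float]:
    """One-sample t-test of the pooled mean against zero; df = releases - 1."""
    df = n_releases - 1
    if se == 0:
        if pooled_mean == 0:
            return 0.0, df, 1.0
        logger.warning("zero SE with nonzero mean displacement; p set to 0")
        return np.inf if pooled_mean > 0 else -np.inf, df, 0.0
    t = pooled_mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, min(p, 1.0)


def dispersal_scale(distances: Sequence[float]) -> float:
    """Root mean square of the recapture distances (m)."""
    d = np.asarray(distances, float)
    if len(d) == 0:
        raise ValueError("need at least one capture")
    return float(np.sqrt(np.mean(d**2)))


def drift_fraction(pooled_mean: float, scale: float) -> float:
    """|net displacement| relative to the dispersal scale."""
    return abs(pooled_mean) / scale


@dataclass
class DisplacementSummary:
    """Net-displacement test result for one axis."""

    axis: str
    per_release: pd.DataFrame  # release_id, mean displacement, n_captured
    pooled_mean: float
    bootstrap_se: float
    t_stat: float
    df: int
    p_value: float
    dispersal_scale: float

    @property
    def drift_fraction(self) -> float:
        return drift_fraction(self.pooled_mean, self.dispersal_scale)

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "pooled_mean_m": float(self.pooled_mean),
            "bootstrap_se_m": float(self.bootstrap_se),
            "t": float(self.t_stat),
            "df": int(self.df),
            "p": float(self.p_value),
            "dispersal_scale_m": float(self.dispersal_scale),
            "drift_fraction": float(self.drift_fraction),
            "per_release": self.per_release.to_dict(orient="records"),
        }

    def summary(self) -> str:
        return (
            f"{self.axis}: net displacement {self.pooled_mean:+.1f} m "
            f"(se {self.bootstrap_se:.1f}), t = {self.t_stat:.2f}, df = {self.df}, "
            f"P = {self.p_value:.3f}; dispersal scale {self.dispersal_scale:.0f} m, "
            f"drift fraction {self.drift_fraction:.1%}"
        )


class NetDisplacementTest:
    """Model object: displacement analysis for one group of releases."""

    def __init__(self, captures: Sequence[CaptureRecord], layout: TrapLayout):
        self.captures = list(captures)
        self.layout = layout

    def fit(self, axis: str, n_boot: int = 2000, seed: int = 0) -> DisplacementSummary:
        if axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        per = project_displacements(self.captures, self.layout)
        col = "mean_x" if axis == "east_west" else "mean_y"
        pooled = weighted_pooled_mean(per[col].to_numpy(), per["n_captured"].to_numpy())
        se = bootstrap_se(self.captures, self.layout, axis, n_boot=n_boot, seed=seed)
        t, df, p = weighted_t_test(pooled, se, len(per))
        pts = _capture_points(self.captures, self.layout)
        scale = dispersal_scale(np.hypot(pts["x"], pts["y"]))
        return DisplacementSummary(
            axis=axis,
            per_release=per[["release_id", col, "n_captured"]].rename(columns={col: "mean_m"}),
            pooled_mean=pooled,
            bootstrap_se=se,
            t_stat=t,
            df=df,
            p_value=p,
            dispersal_scale=scale,
        )

    def fit_both(self, n_boot: int = 2000, seed: int = 0) -> dict[str, DisplacementSummary]:
        return {ax: self.fit(ax, n_boot=n_boot, seed=seed + i) for i, ax in enumerate(AXES)}
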