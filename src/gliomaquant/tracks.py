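"""2D cell-migration track analytics and fluorescence quantification.

Consumes timed trajectories (μm, minutes) as exported point-per-frame by
common nucleus trackers and derives the standard random-migration metrics:

* curvilinear **velocity** — total path length over duration (μm/min);
* **displacement** — straight-line start-to-end distance (μm);
* **directionality** — displacement / path length, 1 for straight-line
  motion, 0 for a closed path;
* **final angle** — direction of the net displacement vector, the quantity
  binned by rose plots.

Also implements corrected total cell fluorescence (CTCF): integrated
density minus cell area times mean background fluorescence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CellTrack",
    "TrackStats",
    "RoseSummary",
    "track_stats",
    "ctcf",
    "measure_fluorescence",
    "rose_summary",
    "condition_report",
    "tracks_to_frame",
    "tracks_from_frame",
    "plot_rose",
]


@dataclass(frozen=True)
class CellTrack:
    """One timed 2D trajectory: times in minutes, coordinates in μm."""

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class TrackStats:
    cell_id: str
    path_length: float  # um
    displacement: float  # um
    duration: float  # min
    velocity: float  # um / min, path_length / duration
    directionality: float  # displacement / path_length, in [0, 1]
    final_angle: float  # radians, atan2 of net displacement


def track_stats(track: CellTrack) -> TrackStats:
    """Derive migration statistics for one track.

    Raises ``ValueError`` for fewer than two samples or non-increasing
    timestamps. Missing frames are fine: steps use the actual Δt.
    """
    if len(track) < 2:
        raise ValueError(f"track {track.cell_id!r}: need >= 2 samples")
    dt = np.diff(track.t)
    if np.any(dt == 0):
        raise ValueError(f"track {track.cell_id!r}: duplicate timestamps")
    if np.any(dt < 0):
        raise ValueError(f"track {track.cell_id!r}: timestamps must increase")

    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    path = float(steps.sum())
    ddx = float(track.x[-1] - track.x[0])
    ddy = float(track.y[-1] - track.y[0])
    disp = float(np.hypot(ddx, ddy))
    duration = float(track.t[-1] - track.t[0])
    return TrackStats(
        cell_id=track.cell_id,
        path_length=path,
        displacement=disp,
        duration=duration,
        velocity=path / duration,
        directionality=disp / path if path > 0 else 0.0,
        final_angle=float(np.arctan2(ddy, ddx)) if disp > 0 else 0.0,
    )


def ctcf(integrated_density: float, area: float, background_mean: float) -> float:
    """Corrected total cell fluorescence.

    ``integrated_density − area · background_mean``; may legitimately come
    out negative for cells dimmer than the local background.
    """
    if area < 0:
        raise ValueError(f"area must be non-negative, got {area}")
    return float(integrated_density) - float(area) * float(background_mean)


def measure_fluorescence(image: np.ndarray, cell_mask: np.ndarray) -> tuple[float, float, float]:
    """Measure (integrated_density, area_px2, background_mean) of one cell.

    Background is the mean of all pixels outside the cell mask, mirroring
    manual background ROI sampling on a uniform field.
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    if cell_mask.all():
        raise ValueError("cell mask covers the whole image; no background left")
    return (
        float(image[cell_mask].sum()),
        float(cell_mask.sum()),
        float(image[~cell_mask].mean()),
    )


@dataclass(frozen=True)
class RoseSummary:
    """Angular histogram of track final angles over [0, 2π)."""

    sector_counts: np.ndarray
    n_zero_displacement: int

    @property
    def n_sectors(self) -> int:
        return int(self.sector_counts.size)


def rose_summary(tracks: Iterable[CellTrack], n_sectors: int = 12) -> RoseSummary:
    """Bin final migration angles into equal sectors.

    Tracks with zero net displacement have no defined angle; they are
    counted separately, so ``sector_counts.sum()`` equals the number of
    tracks that actually moved.
    """
    if n_sectors < 4:
        raise ValueError("n_sectors must be >= 4")
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks supplied")
    counts = np.zeros(n_sectors, dtype=int)
    n_zero = 0
    width = 2.0 * np.pi / n_sectors
    for tr in tracks:
        s = track_stats(tr)
        if s.displacement == 0:
            n_zero += 1
            continue
        counts[int((s.final_angle % (2.0 * np.pi)) / width) % n_sectors] += 1
    return RoseSummary(sector_counts=counts, n_zero_displacement=n_zero)


def stats_frame(tracks: Iterable[CellTrack]) -> pd.DataFrame:
    """Per-track statistics as a tidy DataFrame (one row per cell)."""
    return pd.DataFrame([track_stats(tr).__dict__ for tr in tracks])


def condition_report(
    tracks_by_condition: Mapping[str, Iterable[CellTrack]],
    *,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition mean ± SE of velocity and displacement, plus pairwise
    unpaired t-tests on velocity.

    Conditions with fewer than two tracks are excluded (with a warning); a
    single remaining condition yields an empty pairwise table.
    """
    from .stats import compare_conditions  # local import: avoid cycle

    per_cond: dict[str, pd.DataFrame] = {}
    for cond, trks in tracks_by_condition.items():
        df = stats_frame(trks)
        if len(df) < 2:
            warnings.warn(f"condition {cond!r} has < 2 tracks; excluded")
            continue
        per_cond[cond] = df

    rows = []
    for cond, df in per_cond.items():
        n = len(df)
        rows.append(
            {
                "condition": cond,
                "n_tracks": n,
                "mean_velocity": df["velocity"].mean(),
                "se_velocity": df["velocity"].std(ddof=1) / np.sqrt(n),
                "mean_displacement": df["displacement"].mean(),
                "se_displacement": df["displacement"].std(ddof=1) / np.sqrt(n),
                "mean_directionality": df["directionality"].mean(),
            }
        )
    summary = pd.DataFrame(rows)

    pairs = []
    conds = list(per_cond)
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            cmp = compare_conditions(
                per_cond[a]["velocity"], per_cond[b]["velocity"], equal_var=equal_var
            )
            pairs.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "metric": "velocity",
                    "mean_difference": cmp.mean_difference,
                    "t": cmp.statistic,
                    "df": cmp.df,
                    "p_value": cmp.p_value,
                }
            )
    pairwise = pd.DataFrame(
        pairs,
        columns=[
            "condition_a",
            "condition_b",
            "metric",
            "mean_difference",
            "t",
            "df",
            "p_value",
        ],
    )
    return summary, pairwise


# --------------------------------------------------------------------------
# CSV interchange
# --------------------------------------------------------------------------

def tracks_to_frame(tracks: Iterable[CellTrack]) -> pd.DataFrame:
    """Long-format export: columns cell_id, t_min, x_um, y_um."""
    parts = [
        pd.DataFrame(
            {"cell_id": tr.cell_id, "t_min": tr.t, "x_um": tr.x, "y_um": tr.y}
        )
        for tr in tracks
    ]
    return pd.concat(parts, ignore_index=True)


def tracks_from_frame(df: pd.DataFrame) -> list[CellTrack]:
    """Inverse of :func:`tracks_to_frame`; rows are grouped by cell_id and
    sorted by time."""
    required = {"cell_id", "t_min", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    out = []
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("t_min")
        out.append(
            CellTrack(
                cell_id=str(cid),
                t=g["t_min"].to_numpy(float),
                x=g["x_um"].to_numpy(float),
                y=g["y_um"].to_numpy(float),
            )
        )
    return out


def plot_rose(summary: RoseSummary, ax=None, **bar_kwargs):
    """Polar bar chart of a rose summary (matplotlib imported lazily)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n = summary.n_sectors
    width = 2.0 * np.pi / n
    centers = np.arange(n) * width + width / 2.0
    bar_kwargs.setdefault("edgecolor", "black")
    ax.bar(centers, summary.sector_counts, width=width, **bar_kwargs)
    return ax
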