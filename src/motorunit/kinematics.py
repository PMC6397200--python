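"""Axonal-transport track kinematics.

Single-particle tracks of retrogradely transported cargo (quantum-dot:BDNF,
BDNF-mCherry, GDNF-GFP, MitoTracker-labelled mitochondria) are reduced to the
standard transport statistics: per-step (instantaneous) speeds, average
velocity, stop detection and count, run lengths, time-averaged mean squared
displacement (MSD), net directionality, average-velocity histograms with a
polynomial fit, and pairwise co-transport intervals.

Conventions
-----------
* Tracks are one-dimensional along the axon axis, position in µm. The soma
  lies in the negative direction, so retrograde transport means a negative
  net position increment and anterograde a positive one.
* Frames are sampled on a uniform grid (relative tolerance 1e-6 on the frame
  interval); tracks with dropped frames are rejected rather than
  interpolated, because interpolation would silently alter stop statistics.
* A *stop* is a maximal run of at least ``min_frames`` (default 3)
  consecutive inter-frame steps with speed strictly below
  ``stop_speed_um_s`` (default 0.1 µm/s). A step at exactly the threshold is
  not part of a stop.
* Inclusion filter for analysis: track duration strictly greater than 10
  frames AND average velocity ≥ 0.2 µm/s (inclusive), both configurable.
* Instantaneous velocity V_inst is by default the mean step speed over steps
  *outside* detected stops, which decouples movement speed from pausing;
  ``include_paused_steps=True`` switches to the plain mean over all steps.
* Average velocity V_avg is |net displacement| / elapsed time (not path
  length); a path-length variant is available via ``path_length=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

#: Default stop-detection speed threshold, µm/s.
DEFAULT_STOP_SPEED_UM_S = 0.1
#: Default minimum number of consecutive slow steps that constitute a stop.
DEFAULT_STOP_MIN_FRAMES = 3
#: Inclusion filter: minimum track duration in frames (strict >).
DEFAULT_MIN_DURATION_FRAMES = 10
#: Inclusion filter: minimum average velocity, µm/s (inclusive >=).
DEFAULT_MIN_AVG_VELOCITY_UM_S = 0.2
#: Net displacement below which a track is called stationary, µm.
DEFAULT_DIRECTION_MIN_NET_UM = 1.0

_REL_DT_TOL = 1e-6


@dataclass(frozen=True)
class Track:
    """Per-frame position of one tracked cargo along the axon axis.

    times_s must be strictly increasing and uniformly spaced within a
    relative tolerance of 1e-6 on the frame interval; length >= 2.
    """

    track_id: str
    times_s: np.ndarray
    positions_um: np.ndarray
    channel: str = ""
    condition: str = ""

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.positions_um, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "positions_um", x)
        if t.ndim != 1 or x.ndim != 1 or t.size != x.size:
            raise DataError(
                f"track {self.track_id!r}: times_s and positions_um must be "
                f"1-D arrays of equal length"
            )
        if t.size < 2:
            raise DataError(f"track {self.track_id!r}: needs at least 2 frames")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError(f"track {self.track_id!r}: times must be strictly increasing")
        dt0 = dt[0]
        if np.any(np.abs(dt - dt0) > _REL_DT_TOL * dt0):
            raise DataError(
                f"track {self.track_id!r}: non-uniform frame interval "
                f"(relative tolerance {_REL_DT_TOL:g})"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise DataError(f"track {self.track_id!r}: non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.times_s.size)

    @property
    def frame_interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    @property
    def net_displacement_um(self) -> float:
        return float(self.positions_um[-1] - self.positions_um[0])


@dataclass(frozen=True)
class StopSegment:
    """A maximal run of consecutive slow steps (indices refer to steps)."""

    start_step_index: int
    n_steps: int


@dataclass(frozen=True)
class FrameInterval:
    """A maximal interval of consecutive frames (used for co-transport)."""

    start_frame: int
    n_frames: int


@dataclass
class TrackSummary:
    """All per-track transport statistics; stats are None for excluded tracks."""

    track_id: str
    channel: str = ""
    condition: str = ""
    passed_filter: bool = False
    n_frames: int = 0
    v_inst_um_s: float | None = None
    v_avg_um_s: float | None = None
    stop_count: int | None = None
    run_lengths_um: list[float] = field(default_factory=list)
    msd_um2_by_lag: np.ndarray | None = None
    direction: str | None = None


def step_speeds(track: Track) -> np.ndarray:
    """Per-step speeds |Δx|/Δt in µm/s; length n_frames - 1."""
    dt = track.frame_interval_s
    return np.abs(np.diff(track.positions_um)) / dt


def _runs_of(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True in *mask* with length >= min_len, as (start, len)."""
    out: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                out.append((start, i - start))
            start = None
    if start is not None and len(mask) - start >= min_len:
        out.append((start, len(mask) - start))
    return out


def detect_stops(
    track: Track,
    stop_speed_um_s: float = DEFAULT_STOP_SPEED_UM_S,
    min_frames: int = DEFAULT_STOP_MIN_FRAMES,
) -> list[StopSegment]:
    """Maximal runs of >= min_frames consecutive steps with speed < threshold.

    The inequality is strict: a step at exactly the threshold does not pause.
    """
    if min_frames < 1:
        raise ParameterError("min_frames must be >= 1")
    if stop_speed_um_s < 0:
        raise ParameterError("stop_speed_um_s must be >= 0")
    slow = step_speeds(track) < stop_speed_um_s
    return [StopSegment(s, n) for s, n in _runs_of(slow, min_frames)]


def stop_step_mask(track: Track, stops: Sequence[StopSegment]) -> np.ndarray:
    """Boolean mask over steps: True where the step lies inside a stop."""
    mask = np.zeros(track.n_frames - 1, dtype=bool)
    for seg in stops:
        mask[seg.start_step_index : seg.start_step_index + seg.n_steps] = True
    return mask


def average_velocity(track: Track, path_length: bool = False) -> float:
    """|net displacement| / elapsed time in µm/s.

    With ``path_length=True`` the numerator is the summed absolute step
    displacement instead of the net displacement.
    """
    elapsed = float(track.times_s[-1] - track.times_s[0])
    if elapsed <= 0:
        raise DataError(f"track {track.track_id!r}: zero elapsed time")
    if path_length:
        dist = float(np.sum(np.abs(np.diff(track.positions_um))))
    else:
        dist = abs(track.net_displacement_um)
    return dist / elapsed


def instantaneous_velocity(
    track: Track,
    stops: Sequence[StopSegment] | None = None,
    include_paused_steps: bool = False,
) -> float:
    """Mean step speed, by default over steps outside detected stops.

    Returns 0.0 when every step lies inside a stop (a stationary track).
    """
    speeds = step_speeds(track)
    if include_paused_steps:
        return float(np.mean(speeds))
    if stops is None:
        stops = detect_stops(track)
    mask = stop_step_mask(track, stops)
    if mask.all():
        return 0.0
    return float(np.mean(speeds[~mask]))


def run_lengths(track: Track, stops: Sequence[StopSegment] | None = None) -> list[float]:
    """Absolute net displacement of each maximal stop-free stretch of steps."""
    if stops is None:
        stops = detect_stops(track)
    mask = stop_step_mask(track, stops)
    x = track.positions_um
    out: list[float] = []
    for start, n in _runs_of(~mask, 1):
        out.append(abs(float(x[start + n] - x[start])))
    return out


def track_msd(track: Track, max_lag: int) -> np.ndarray:
    """Time-averaged MSD with overlapping windows for lags 1..max_lag (µm²).

    MSD(k) = mean_i (x_{i+k} - x_i)²; lag 0 is omitted.
    """
    if not 1 <= max_lag < track.n_frames:
        raise ParameterError(
            f"max_lag must be in [1, n_frames-1]; got {max_lag} for "
            f"{track.n_frames} frames"
        )
    x = track.positions_um
    return np.array(
        [float(np.mean((x[k:] - x[:-k]) ** 2)) for k in range(1, max_lag + 1)]
    )


def ensemble_msd(
    tracks: Sequence[Track], max_lag: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-lag mean and SEM of the time-averaged MSD across tracks.

    Each lag k aggregates the tracks with more than k frames. Returns
    (lags_s, mean_msd, sem_msd); SEM is 0 where only one track contributes.
    """
    if not tracks:
        raise DataError("ensemble_msd needs at least one track")
    dt = tracks[0].frame_interval_s
    for t in tracks:
        if abs(t.frame_interval_s - dt) > _REL_DT_TOL * dt:
            raise DataError("tracks have inconsistent frame intervals")
    per_lag: list[list[float]] = [[] for _ in range(max_lag)]
    for t in tracks:
        msd = track_msd(t, min(max_lag, t.n_frames - 1))
        for k, v in enumerate(msd):
            per_lag[k].append(v)
    lags_s = dt * np.arange(1, max_lag + 1)
    mean = np.full(max_lag, np.nan)
    sem = np.full(max_lag, np.nan)
    for k, vals in enumerate(per_lag):
        if not vals:
            continue
        arr = np.asarray(vals)
        mean[k] = arr.mean()
        sem[k] = arr.std(ddof=1) / math.sqrt(arr.size) if arr.size > 1 else 0.0
    return lags_s, mean, sem


def apply_inclusion_filter(
    track: Track,
    min_duration_frames: int = DEFAULT_MIN_DURATION_FRAMES,
    min_avg_velocity_um_s: float = DEFAULT_MIN_AVG_VELOCITY_UM_S,
) -> bool:
    """True iff n_frames > min_duration_frames (strict) and V_avg >= threshold."""
    return (
        track.n_frames > min_duration_frames
        and average_velocity(track) >= min_avg_velocity_um_s
    )


def filter_tracks(tracks: Iterable[Track], **kwargs) -> list[Track]:
    """Tracks passing :func:`apply_inclusion_filter` (idempotent)."""
    return [t for t in tracks if apply_inclusion_filter(t, **kwargs)]


def velocity_distribution(
    tracks: Sequence[Track],
    bin_width_um_s: float,
    poly_degree: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized histogram of per-track average velocities with a polynomial fit.

    Returns (bin_centers, fractions, coefficients); fractions sum to 1 over
    occupied bins, coefficients are in ascending powers. The fit degree is
    clamped to n_bins - 1 when fewer bins than degree + 1 are occupied.
    """
    if len(tracks) == 0:
        raise DataError("velocity_distribution needs at least one track")
    if bin_width_um_s <= 0:
        raise ParameterError("bin_width_um_s must be > 0")
    if poly_degree < 0:
        raise ParameterError("poly_degree must be >= 0")
    v = np.array([average_velocity(t) for t in tracks])
    lo = math.floor(v.min() / bin_width_um_s) * bin_width_um_s
    hi = math.floor(v.max() / bin_width_um_s + 1) * bin_width_um_s
    edges = np.arange(lo, hi + bin_width_um_s / 2, bin_width_um_s)
    counts, edges = np.histogram(v, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    fractions = counts / counts.sum()
    degree = min(poly_degree, len(centers) - 1)
    coeffs = np.polynomial.polynomial.polyfit(centers, fractions, degree)
    return centers, fractions, coeffs


def directionality(
    track: Track, min_net_um: float = DEFAULT_DIRECTION_MIN_NET_UM
) -> str:
    """'retrograde' (net < -min_net_um), 'anterograde' (net > +min_net_um) or 'stationary'."""
    net = track.net_displacement_um
    if net < -min_net_um:
        return "retrograde"
    if net > min_net_um:
        return "anterograde"
    return "stationary"


def detect_cotransport(
    track_a: Track,
    track_b: Track,
    dist_um: float,
    min_frames: int,
) -> list[FrameInterval]:
    """Maximal intervals of >= min_frames consecutive frames with |x_a - x_b| < dist_um.

    Both tracks must share the frame grid (times aligned within tolerance).
    """
    if min_frames < 1:
        raise ParameterError("min_frames must be >= 1")
    if dist_um <= 0:
        raise ParameterError("dist_um must be > 0")
    if track_a.n_frames != track_b.n_frames or np.any(
        np.abs(track_a.times_s - track_b.times_s)
        > _REL_DT_TOL * track_a.frame_interval_s
    ):
        raise DataError(
            f"tracks {track_a.track_id!r} and {track_b.track_id!r} are not on "
            f"the same time grid"
        )
    close = np.abs(track_a.positions_um - track_b.positions_um) < dist_um
    return [FrameInterval(s, n) for s, n in _runs_of(close, min_frames)]


@dataclass
class CohortSummary:
    """Output bundle of :func:`summarize_tracks`."""

    summaries: list[TrackSummary]
    per_track: pd.DataFrame
    per_step: pd.DataFrame
    cohort: pd.DataFrame


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def summarize_tracks(
    tracks: Sequence[Track],
    *,
    stop_speed_um_s: float = DEFAULT_STOP_SPEED_UM_S,
    stop_min_frames: int = DEFAULT_STOP_MIN_FRAMES,
    min_duration_frames: int = DEFAULT_MIN_DURATION_FRAMES,
    min_avg_velocity_um_s: float = DEFAULT_MIN_AVG_VELOCITY_UM_S,
    msd_max_lag: int = 10,
    direction_min_net_um: float = DEFAULT_DIRECTION_MIN_NET_UM,
    include_paused_steps: bool = False,
) -> CohortSummary:
    """Apply the inclusion filter and compute every statistic for passing tracks.

    Emits a tidy per-track table, a per-step record table (the unit behind
    step-count sample sizes), and a per-condition cohort table of
    mean ± SEM for V_inst, V_avg, stop count and run length, plus the
    fraction of retrograde tracks.
    """
    summaries: list[TrackSummary] = []
    step_rows: list[dict] = []
    for t in tracks:
        s = TrackSummary(
            track_id=t.track_id,
            channel=t.channel,
            condition=t.condition,
            n_frames=t.n_frames,
            passed_filter=apply_inclusion_filter(
                t, min_duration_frames, min_avg_velocity_um_s
            ),
        )
        if s.passed_filter:
            stops = detect_stops(t, stop_speed_um_s, stop_min_frames)
            mask = stop_step_mask(t, stops)
            speeds = step_speeds(t)
            s.v_inst_um_s = instantaneous_velocity(
                t, stops, include_paused_steps=include_paused_steps
            )
            s.v_avg_um_s = average_velocity(t)
            s.stop_count = len(stops)
            s.run_lengths_um = run_lengths(t, stops)
            s.msd_um2_by_lag = track_msd(t, min(msd_max_lag, t.n_frames - 1))
            if mask.all():
                s.direction = "stationary"
            else:
                s.direction = directionality(t, direction_min_net_um)
            for i, (sp, in_stop) in enumerate(zip(speeds, mask)):
                step_rows.append(
                    {
                        "track_id": t.track_id,
                        "condition": t.condition,
                        "channel": t.channel,
                        "step_index": i,
                        "speed_um_s": float(sp),
                        "in_stop": bool(in_stop),
                    }
                )
        summaries.append(s)

    per_track = pd.DataFrame(
        [
            {
                "track_id": s.track_id,
                "condition": s.condition,
                "channel": s.channel,
                "n_frames": s.n_frames,
                "passed_filter": s.passed_filter,
                "v_inst_um_s": s.v_inst_um_s,
                "v_avg_um_s": s.v_avg_um_s,
                "stop_count": s.stop_count,
                "n_runs": len(s.run_lengths_um) if s.passed_filter else None,
                "mean_run_length_um": (
                    float(np.mean(s.run_lengths_um))
                    if s.passed_filter and s.run_lengths_um
                    else None
                ),
                "direction": s.direction,
            }
            for s in summaries
        ],
        columns=[
            "track_id",
            "condition",
            "channel",
            "n_frames",
            "passed_filter",
            "v_inst_um_s",
            "v_avg_um_s",
            "stop_count",
            "n_runs",
            "mean_run_length_um",
            "direction",
        ],
    )
    per_step = pd.DataFrame(
        step_rows,
        columns=["track_id", "condition", "channel", "step_index", "speed_um_s", "in_stop"],
    )

    cohort_rows = []
    passing = per_track.loc[per_track["passed_filter"].astype(bool)]
    for cond, grp in passing.groupby("condition", sort=True):
        cohort_rows.append(
            {
                "condition": cond,
                "n_tracks": len(grp),
                "v_inst_mean_um_s": grp["v_inst_um_s"].mean(),
                "v_inst_sem_um_s": _sem(grp["v_inst_um_s"].to_numpy()),
                "v_avg_mean_um_s": grp["v_avg_um_s"].mean(),
                "v_avg_sem_um_s": _sem(grp["v_avg_um_s"].to_numpy()),
                "stop_count_mean": grp["stop_count"].mean(),
                "stop_count_sem": _sem(grp["stop_count"].to_numpy()),
                "run_length_mean_um": passing_mean_run(grp),
                "fraction_retrograde": float((grp["direction"] == "retrograde").mean()),
            }
        )
    cohort = pd.DataFrame(
        cohort_rows,
        columns=[
            "condition",
            "n_tracks",
            "v_inst_mean_um_s",
            "v_inst_sem_um_s",
            "v_avg_mean_um_s",
            "v_avg_sem_um_s",
            "stop_count_mean",
            "stop_count_sem",
            "run_length_mean_um",
            "fraction_retrograde",
        ],
    )
    return CohortSummary(summaries, per_track, per_step, cohort)


def passing_mean_run(per_track_group: pd.DataFrame) -> float | None:
    vals = per_track_group["mean_run_length_um"].dropna()
    if len(vals) == 0:
        return None
    return float(vals.mean())
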