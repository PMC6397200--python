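"""Seeded synthetic cohorts with the statistical structure of each assay.

Every generator draws from a numpy ``Generator`` seeded by the caller;
identical (params, seed) pairs give bit-identical output, and cohort
generators spawn one independent child stream per unit so whole cohorts are
reproducible from a single seed.

What is emulated (and what is not): the generators reproduce the sampling
structure of each readout — run-and-pause cargo motion on a 3-s frame grid,
baseline-plus-burst intensity traces at 30 fps, Bernoulli intactness /
innervation of NMJ colocalization events, binomially thinned motor-neuron
counts over days in co-culture, Poisson aggregate counts per section area,
and truncated-Gaussian fiber diameter populations. They do not render
images, model spot-detection failure, or correlate units.

Axial convention: tracks are one-dimensional along the axon axis with the
soma toward negative positions, so retrograde transport means a negative
net increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._rng import as_rng, spawn_seeds
from .contraction import IntensityTrace
from .errors import ParameterError
from .kinematics import Track
from .morphology import NMJEvent
from .survival import ExplantSeries


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ParameterError(message)


@dataclass(frozen=True)
class TransportParams:
    """Run-and-pause cargo motion parameters.

    The frame grid (3 s interval, 100 frames) matches 5-minute movies
    acquired at 20 frames per minute. Speed and pause magnitudes are free
    parameters — the assay reports only relative group differences — with
    defaults chosen as typical dynein-driven cargo kinematics: runs near
    0.8 µm/s with geometric pause dwell times of a few frames.
    """

    frame_interval_s: float = 3.0
    n_frames: int = 100
    run_speed_mean_um_s: float = 0.8
    run_speed_sd_um_s: float = 0.2
    pause_entry_prob: float = 0.05
    pause_exit_prob: float = 0.3
    retrograde_fraction: float = 0.9
    noise_sd_um: float = 0.02

    def __post_init__(self):
        _require(self.frame_interval_s > 0, "frame_interval_s must be > 0")
        _require(self.n_frames >= 2, "n_frames must be >= 2")
        _require(self.run_speed_mean_um_s >= 0, "run_speed_mean_um_s must be >= 0")
        _require(self.run_speed_sd_um_s >= 0, "run_speed_sd_um_s must be >= 0")
        for name in ("pause_entry_prob", "pause_exit_prob", "retrograde_fraction"):
            _require(0 <= getattr(self, name) <= 1, f"{name} must be in [0, 1]")
        _require(self.noise_sd_um >= 0, "noise_sd_um must be >= 0")


@dataclass(frozen=True)
class ContractionParams:
    """Baseline-plus-burst intensity trace parameters (30 fps, 1000 frames)."""

    fps: float = 30.0
    n_frames: int = 1000
    fraction_contracting: float = 0.74
    burst_rate_hz: float = 0.25
    burst_amplitude_rel: float = 0.5
    burst_duration_frames: int = 5
    noise_sd_rel: float = 0.02

    def __post_init__(self):
        _require(self.fps > 0, "fps must be > 0")
        _require(self.n_frames >= 10, "n_frames must be >= 10")
        _require(0 <= self.fraction_contracting <= 1,
                 "fraction_contracting must be in [0, 1]")
        _require(self.burst_rate_hz >= 0, "burst_rate_hz must be >= 0")
        _require(self.burst_duration_frames >= 1,
                 "burst_duration_frames must be >= 1")
        _require(self.noise_sd_rel >= 0, "noise_sd_rel must be >= 0")
        _require(
            self.burst_amplitude_rel > self.noise_sd_rel,
            "burst_amplitude_rel must exceed noise_sd_rel "
            "(ground truth undetectable otherwise)",
        )


@dataclass(frozen=True)
class SurvivalParams:
    """Per-explant death kinetics over the co-culture observation days."""

    initial_count: int = 40
    observation_days: tuple[int, ...] = (7, 10, 12, 14, 16)
    surviving_fraction_by_day: tuple[float, ...] = (1.0, 0.95, 0.85, 0.68, 0.5)
    count_noise: bool = True

    def __post_init__(self):
        _require(self.initial_count >= 1, "initial_count must be >= 1")
        days = tuple(self.observation_days)
        fr = tuple(float(f) for f in self.surviving_fraction_by_day)
        object.__setattr__(self, "observation_days", days)
        object.__setattr__(self, "surviving_fraction_by_day", fr)
        _require(len(days) == len(fr) and len(days) >= 1,
                 "observation_days and surviving_fraction_by_day must match")
        _require(all(b > a for a, b in zip(days, days[1:])),
                 "observation_days must be increasing")
        _require(fr[0] == 1.0, "surviving_fraction_by_day must start at 1.0")
        _require(all(0 <= f <= 1 for f in fr),
                 "surviving_fraction_by_day must be in [0, 1]")
        _require(all(b <= a for a, b in zip(fr, fr[1:])),
                 "surviving_fraction_by_day must be non-increasing")


def simulate_track(
    params: TransportParams,
    seed,
    *,
    track_id: str = "track0",
    channel: str = "QdotBDNF",
    condition: str = "",
    initial_state: str | None = None,
) -> Track:
    """One run-and-pause track with per-frame Bernoulli state switching.

    In "run" frames the position advances by direction x speed x Δt with a
    per-step Gaussian speed (clipped at 0); in "pause" frames it does not
    advance. Gaussian localization noise is added per frame on top of the
    true position. Direction is fixed per track: negative (retrograde) with
    probability ``retrograde_fraction``. ``initial_state`` forces "run" or
    "pause"; by default it is drawn from the stationary distribution of the
    two-state chain.
    """
    if initial_state not in (None, "run", "pause"):
        raise ParameterError("initial_state must be None, 'run' or 'pause'")
    rng = as_rng(seed)
    p_in, p_out = params.pause_entry_prob, params.pause_exit_prob
    direction = -1.0 if rng.random() < params.retrograde_fraction else 1.0
    if initial_state is None:
        p_pause = p_in / (p_in + p_out) if (p_in + p_out) > 0 else 0.0
        paused = rng.random() < p_pause
    else:
        paused = initial_state == "pause"
    n_steps = params.n_frames - 1
    running = np.empty(n_steps, dtype=bool)
    switch = rng.random(n_steps)
    for i in range(n_steps):
        running[i] = not paused
        if paused:
            paused = not (switch[i] < p_out)
        else:
            paused = switch[i] < p_in
    speeds = rng.normal(params.run_speed_mean_um_s, params.run_speed_sd_um_s, n_steps)
    np.clip(speeds, 0.0, None, out=speeds)
    increments = np.where(running, direction * speeds * params.frame_interval_s, 0.0)
    true_x = np.concatenate([[0.0], np.cumsum(increments)])
    if params.noise_sd_um > 0:
        observed = true_x + rng.normal(0.0, params.noise_sd_um, params.n_frames)
    else:
        observed = true_x
    times = params.frame_interval_s * np.arange(params.n_frames)
    return Track(track_id, times, observed, channel=channel, condition=condition)


def simulate_chamber_tracks(
    params: TransportParams,
    n_tracks: int,
    seed,
    *,
    condition: str = "",
    channel: str = "QdotBDNF",
) -> list[Track]:
    """n_tracks independent tracks from per-track child streams."""
    if n_tracks < 1:
        raise ParameterError("n_tracks must be >= 1")
    return [
        simulate_track(
            params, child, track_id=f"track{i:04d}", channel=channel, condition=condition
        )
        for i, child in enumerate(spawn_seeds(seed, n_tracks))
    ]


def _place_bursts(
    rng: np.random.Generator, n_bursts: int, n_frames: int, duration: int
) -> np.ndarray:
    """Non-overlapping burst start frames separated by >= 2 quiet frames."""
    if n_bursts == 0:
        return np.empty(0, dtype=int)
    for _ in range(200):
        starts = np.sort(rng.integers(0, n_frames - duration + 1, size=n_bursts))
        if n_bursts == 1 or np.all(np.diff(starts) >= duration + 2):
            return starts
    # Dense regime: fall back to an evenly spaced deterministic layout.
    spacing = max(duration + 2, (n_frames - duration) // max(n_bursts, 1))
    return np.arange(n_bursts) * spacing % max(n_frames - duration, 1)


def simulate_intensity_traces(
    params: ContractionParams,
    n_fibers: int,
    seed,
    *,
    chamber_id: str = "chamber0",
    condition: str = "",
) -> tuple[list[IntensityTrace], list[bool]]:
    """Intensity traces with ground-truth contractor labels.

    Non-contractors are baseline 1.0 plus Gaussian noise; contractors add a
    Poisson number of rectangular bursts (rate x movie duration expected
    events) of the configured amplitude and duration.
    """
    if n_fibers < 1:
        raise ParameterError("n_fibers must be >= 1")
    traces: list[IntensityTrace] = []
    labels: list[bool] = []
    duration_s = params.n_frames / params.fps
    for i, child in enumerate(spawn_seeds(seed, n_fibers)):
        rng = as_rng(child)
        contracting = bool(rng.random() < params.fraction_contracting)
        values = np.ones(params.n_frames)
        if params.noise_sd_rel > 0:
            values += rng.normal(0.0, params.noise_sd_rel, params.n_frames)
        if contracting:
            n_bursts = int(rng.poisson(params.burst_rate_hz * duration_s))
            starts = _place_bursts(
                rng, n_bursts, params.n_frames, params.burst_duration_frames
            )
            for s in starts:
                values[s : s + params.burst_duration_frames] += params.burst_amplitude_rel
        traces.append(
            IntensityTrace(
                fiber_id=f"{chamber_id}-fiber{i:04d}",
                fps=params.fps,
                values=values,
                chamber_id=chamber_id,
                condition=condition,
            )
        )
        labels.append(contracting)
    return traces, labels


def simulate_nmj_events(
    p: float,
    n_events: int,
    seed,
    *,
    unit_id: str = "unit0",
    condition: str = "",
    assay: str = "invitro",
) -> list[NMJEvent]:
    """Independent Bernoulli NMJ colocalization events.

    ``assay="invitro"``: every event is a pre/post colocalization and *p* is
    the probability its axon is intact (degenerated otherwise).
    ``assay="invivo"``: every event is a postsynaptic (BTX) site and *p* is
    the probability the presynaptic marker is present (innervation).
    """
    _require(0 <= p <= 1, "p must be in [0, 1]")
    _require(n_events >= 1, "n_events must be >= 1")
    if assay not in ("invitro", "invivo"):
        raise ParameterError("assay must be 'invitro' or 'invivo'")
    rng = as_rng(seed)
    hits = rng.random(n_events) < p
    events = []
    for i, hit in enumerate(hits):
        if assay == "invitro":
            pre, post, intact = True, True, bool(hit)
        else:
            pre, post, intact = bool(hit), True, bool(hit)
        events.append(
            NMJEvent(
                event_id=f"{unit_id}-e{i:04d}",
                unit_id=unit_id,
                pre_present=pre,
                post_present=post,
                axon_intact=intact,
                condition=condition,
            )
        )
    return events


def simulate_explant_counts(
    params: SurvivalParams,
    seed,
    *,
    explant_id: str = "explant0",
    condition: str = "",
) -> ExplantSeries:
    """Motor-neuron counts over days by sequential binomial thinning.

    With ``count_noise`` the count at each day is Binomial(previous count,
    fraction ratio), which keeps counts non-increasing and the marginal mean
    at initial_count x fraction(day). Without noise, counts are the exact
    rounded expectations.
    """
    fr = params.surviving_fraction_by_day
    counts = [params.initial_count]
    if params.count_noise:
        rng = as_rng(seed)
        for prev_f, f in zip(fr, fr[1:]):
            ratio = f / prev_f if prev_f > 0 else 0.0
            counts.append(int(rng.binomial(counts[-1], ratio)))
    else:
        counts = [int(round(params.initial_count * f)) for f in fr]
    return ExplantSeries(
        explant_id=explant_id,
        condition=condition,
        days=params.observation_days,
        counts=tuple(counts),
    )


def simulate_aggregate_counts(
    density_per_mm2: float, areas_mm2: Sequence[float], seed
) -> np.ndarray:
    """Independent Poisson(density x area) aggregate counts per section."""
    _require(density_per_mm2 >= 0, "density_per_mm2 must be >= 0")
    areas = np.asarray(areas_mm2, dtype=float)
    _require(bool(np.all(areas > 0)), "areas_mm2 must be > 0")
    rng = as_rng(seed)
    return rng.poisson(density_per_mm2 * areas)


def simulate_fiber_diameters(
    mean_um: float, sd_um: float, n: int, seed
) -> np.ndarray:
    """Gaussian fiber diameters truncated at 0 µm."""
    _require(mean_um > 0, "mean_um must be > 0")
    _require(sd_um >= 0, "sd_um must be >= 0")
    _require(n >= 1, "n must be >= 1")
    if sd_um == 0:
        return np.full(n, float(mean_um))
    rng = as_rng(seed)
    a = (0.0 - mean_um) / sd_um
    return stats.truncnorm.rvs(a, np.inf, loc=mean_um, scale=sd_um, size=n,
                               random_state=rng)
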