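"""Parameter-recovery experiments on synthetic cohorts.

Each function simulates a named condition preset at its study cohort size
across several replicate seeds, runs the corresponding analysis pipeline
with default settings, and returns the recovered group-level mean with its
SEM — the closed loop (generate -> analyze -> recover) that validates every
stage against the group observable the preset pins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import spawn_seeds
from .contraction import analyze_traces
from .morphology import (
    SectionCount,
    aggregate_density,
    fiber_diameter_summary,
    healthy_nmj_fraction,
    innervation_percent,
)
from .presets import get_preset
from .survival import percent_surviving
from .synthetic import (
    simulate_aggregate_counts,
    simulate_explant_counts,
    simulate_fiber_diameters,
    simulate_intensity_traces,
    simulate_nmj_events,
)


@dataclass(frozen=True)
class RecoveryResult:
    """A recovered group mean with its uncertainty and sample size."""

    value: float
    sem: float
    n: int

    def within(self, target: float, n_sem: float = 3.0) -> bool:
        return abs(self.value - target) <= n_sem * max(self.sem, 1e-12)


def _mean_sem(values: Sequence[float]) -> RecoveryResult:
    arr = np.asarray(values, dtype=float)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return RecoveryResult(float(arr.mean()), sem, int(arr.size))


def default_seeds(seed: int, n: int = 10) -> list[int]:
    """Derive n replicate integer seeds (< 2**31) from one master seed."""
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in spawn_seeds(seed, n)]


def recover_percent_contracting(
    preset_name: str,
    seeds: Sequence[int],
    n_chambers: int = 40,
    n_fibers: int = 30,
) -> RecoveryResult:
    """Simulate contraction chambers, call fibers, recover the mean chamber %.

    The RecoveryResult pools per-chamber percentages over chambers and seeds;
    n counts fibers analyzed.
    """
    params = get_preset("contraction", preset_name).build_params()
    chamber_percents: list[float] = []
    n_total = 0
    for seed in seeds:
        for i, child in enumerate(spawn_seeds(seed, n_chambers)):
            traces, _ = simulate_intensity_traces(
                params, n_fibers, child, chamber_id=f"s{seed}c{i:02d}"
            )
            _, percents = analyze_traces(traces)
            chamber_percents.extend(percents.to_list())
            n_total += n_fibers
    res = _mean_sem(chamber_percents)
    return RecoveryResult(res.value, res.sem, n_total)


def recover_healthy_nmj_percent(
    preset_name: str = "WT_cocult",
    seeds: Sequence[int] = (),
    n_units: int = 30,
    n_events: int = 50,
) -> RecoveryResult:
    """Recover the mean per-chamber healthy-NMJ percentage in vitro."""
    p = get_preset("nmj_invitro", preset_name).build_params()["p_intact"]
    unit_percents: list[float] = []
    n_total = 0
    for seed in seeds:
        events = []
        for i, child in enumerate(spawn_seeds(seed, n_units)):
            events.extend(
                simulate_nmj_events(
                    p, n_events, child, unit_id=f"s{seed}u{i:02d}", assay="invitro"
                )
            )
        unit_percents.extend(healthy_nmj_fraction(events).to_list())
        n_total += n_units * n_events
    res = _mean_sem(unit_percents)
    return RecoveryResult(res.value, res.sem, n_total)


def recover_day16_loss_percent(
    preset_name: str = "SOD1_cocult",
    seeds: Sequence[int] = (),
    n_explants: int = 200,
) -> RecoveryResult:
    """Recover mean motor-neuron loss (100 - % surviving) at the final day."""
    params = get_preset("survival", preset_name).build_params()
    losses: list[float] = []
    for seed in seeds:
        for i, child in enumerate(spawn_seeds(seed, n_explants)):
            series = simulate_explant_counts(
                params, child, explant_id=f"s{seed}e{i:03d}"
            )
            losses.append(100.0 - percent_surviving(series)[-1])
    res = _mean_sem(losses)
    return RecoveryResult(res.value, res.sem, len(losses) * params.initial_count)


def recover_invivo_nmj_loss_percent(
    disease_preset: str,
    seeds: Sequence[int] = (),
    n_muscles: int = 5,
    n_events: int = 100,
    reference_preset: str = "WT_vehicle",
) -> RecoveryResult:
    """Recover % NMJ loss vs the wild-type reference for an in vivo preset.

    Loss per disease muscle = 100 x (1 - innervation% / reference mean),
    pooled over muscles and seeds.
    """
    p_ref = get_preset("nmj_invivo", reference_preset).build_params()["p_innervated"]
    p_dis = get_preset("nmj_invivo", disease_preset).build_params()["p_innervated"]
    losses: list[float] = []
    n_total = 0
    for seed in seeds:
        children = spawn_seeds(seed, 2 * n_muscles)
        ref_events, dis_events = [], []
        for i in range(n_muscles):
            ref_events.extend(
                simulate_nmj_events(
                    p_ref, n_events, children[i], unit_id=f"ref{i}", assay="invivo"
                )
            )
            dis_events.extend(
                simulate_nmj_events(
                    p_dis, n_events, children[n_muscles + i],
                    unit_id=f"dis{i}", assay="invivo",
                )
            )
        ref_mean = float(innervation_percent(ref_events).mean())
        for pct in innervation_percent(dis_events):
            losses.append(100.0 * (1.0 - pct / ref_mean))
        n_total += 2 * n_muscles * n_events
    res = _mean_sem(losses)
    return RecoveryResult(res.value, res.sem, n_total)


def recover_aggregate_reduction_percent(
    seeds: Sequence[int] = (),
    n_sections: int = 50,
    vehicle_preset: str = "SOD1_vehicle",
    treated_preset: str = "SOD1_prido30",
) -> RecoveryResult:
    """Recover the % reduction in aggregate density (treated vs vehicle).

    Sections are 1 mm² gray-matter fields; one percent-change estimate per
    seed, summarized over seeds (SEM is the Monte-Carlo uncertainty).
    """
    dens_v = get_preset("aggregates", vehicle_preset).build_params()["density_per_mm2"]
    dens_t = get_preset("aggregates", treated_preset).build_params()["density_per_mm2"]
    areas = np.ones(n_sections)
    changes: list[float] = []
    for seed in seeds:
        child_v, child_t = spawn_seeds(seed, 2)
        counts_v = simulate_aggregate_counts(dens_v, areas, child_v)
        counts_t = simulate_aggregate_counts(dens_t, areas, child_t)
        sections = [
            SectionCount(f"v{i}", "gray", 1.0, int(c), vehicle_preset)
            for i, c in enumerate(counts_v)
        ] + [
            SectionCount(f"t{i}", "gray", 1.0, int(c), treated_preset)
            for i, c in enumerate(counts_t)
        ]
        result = aggregate_density(sections, reference_group=vehicle_preset)
        changes.append(
            float(result.percent_change["percent_change_vs_reference"].iloc[0])
        )
    res = _mean_sem(changes)
    return RecoveryResult(res.value, res.sem, len(seeds) * 2 * n_sections)


def recover_fiber_diameter_difference_um(
    seeds: Sequence[int] = (),
    n_fibers: int = 500,
    vehicle_preset: str = "SOD1_vehicle",
    treated_preset: str = "SOD1_prido30",
) -> RecoveryResult:
    """Recover the treated-minus-vehicle mean fiber-diameter difference (µm)."""
    pv = get_preset("fibers", vehicle_preset).build_params()
    pt = get_preset("fibers", treated_preset).build_params()
    diffs: list[float] = []
    for seed in seeds:
        child_v, child_t = spawn_seeds(seed, 2)
        groups = {
            vehicle_preset: simulate_fiber_diameters(
                pv["mean_um"], pv["sd_um"], n_fibers, child_v
            ),
            treated_preset: simulate_fiber_diameters(
                pt["mean_um"], pt["sd_um"], n_fibers, child_t
            ),
        }
        result = fiber_diameter_summary(groups)
        diffs.append(float(result.differences["mean_difference_um"].iloc[0]))
    res = _mean_sem(diffs)
    return RecoveryResult(res.value, res.sem, len(seeds) * 2 * n_fibers)
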