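"""NMJ, aggregate and muscle-fiber morphology scoring.

Covers four endpoint quantifications:

* in vitro NMJ health — the percentage of pre/post colocalization events
  whose presynaptic axon is intact, per microfluidic chamber;
* in vivo innervation — the percentage of postsynaptic (AChR/BTX) sites with
  a presynaptic marker present, per muscle;
* mutant-SOD1 aggregate density — NSC500-positive puncta per mm² of spinal
  cord section, by group and gray/white compartment, with percent change
  against a reference group;
* muscle-fiber diameter summaries with pairwise group mean differences.

Group summaries pool at the section/NMJ level by default; per-animal pooling
is available where an animal identifier is supplied.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import as_rng
from .errors import DataError, ParameterError


@dataclass(frozen=True)
class NMJEvent:
    """One pre/postsynaptic colocalization site."""

    event_id: str
    unit_id: str
    pre_present: bool
    post_present: bool
    axon_intact: bool
    condition: str = ""

    @property
    def colocalized(self) -> bool:
        return self.pre_present and self.post_present


@dataclass(frozen=True)
class SectionCount:
    """Aggregate count on one spinal-cord section compartment."""

    section_id: str
    compartment: str  # "gray" or "white"
    area_mm2: float
    n_aggregates: int
    group: str
    animal_id: str | None = None

    def __post_init__(self):
        if self.area_mm2 <= 0:
            raise ParameterError(f"section {self.section_id!r}: area_mm2 must be > 0")
        if self.n_aggregates < 0:
            raise ParameterError(
                f"section {self.section_id!r}: n_aggregates must be >= 0"
            )


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def healthy_nmj_fraction(events: Sequence[NMJEvent]) -> pd.Series:
    """Per-unit percentage of colocalized events with an intact axon.

    Non-colocalized events are ignored entirely; units with zero colocalized
    events are excluded with a warning.
    """
    per_unit: dict[str, list[bool]] = {}
    units_seen: set[str] = set()
    for e in events:
        units_seen.add(e.unit_id)
        if e.colocalized:
            per_unit.setdefault(e.unit_id, []).append(e.axon_intact)
    for unit in units_seen - set(per_unit):
        warnings.warn(f"unit {unit!r} has no colocalized events; excluded",
                      stacklevel=2)
    out = {
        unit: 100.0 * sum(flags) / len(flags)
        for unit, flags in sorted(per_unit.items())
    }
    return pd.Series(out, dtype=float, name="percent_healthy_nmj")


def innervation_percent(events: Sequence[NMJEvent]) -> pd.Series:
    """Per-unit percentage of postsynaptic sites with the presynaptic marker.

    Units with zero postsynaptic sites are excluded with a warning.
    """
    per_unit: dict[str, list[bool]] = {}
    units_seen: set[str] = set()
    for e in events:
        units_seen.add(e.unit_id)
        if e.post_present:
            per_unit.setdefault(e.unit_id, []).append(e.pre_present)
    for unit in units_seen - set(per_unit):
        warnings.warn(f"unit {unit!r} has no postsynaptic sites; excluded",
                      stacklevel=2)
    out = {
        unit: 100.0 * sum(flags) / len(flags)
        for unit, flags in sorted(per_unit.items())
    }
    return pd.Series(out, dtype=float, name="percent_innervated")


@dataclass
class AggregateDensityResult:
    """Per-(group, compartment) density summary plus percent change vs reference."""

    summary: pd.DataFrame
    percent_change: pd.DataFrame
    reference_group: str


def aggregate_density(
    sections: Sequence[SectionCount],
    reference_group: str,
    by: str = "section",
) -> AggregateDensityResult:
    """Aggregates-per-mm² density per group and compartment, with SEM.

    ``by="animal"`` first averages section densities within each animal and
    then summarizes over animals (requires animal_id on every section).
    Percent change is 100 * (1 - group / reference) per compartment.
    """
    if by not in ("section", "animal"):
        raise ParameterError("by must be 'section' or 'animal'")
    if not sections:
        raise DataError("no sections supplied")
    rows = [
        {
            "group": s.group,
            "compartment": s.compartment,
            "animal_id": s.animal_id,
            "density": s.n_aggregates / s.area_mm2,
        }
        for s in sections
    ]
    df = pd.DataFrame(rows)
    if reference_group not in set(df["group"]):
        raise ParameterError(f"reference group {reference_group!r} not present")
    if by == "animal":
        if df["animal_id"].isna().any():
            raise DataError("per-animal pooling requires animal_id on every section")
        df = (
            df.groupby(["group", "compartment", "animal_id"], as_index=False)["density"]
            .mean()
        )
    summary = (
        df.groupby(["group", "compartment"])["density"]
        .agg(
            mean_density_per_mm2="mean",
            sem_density_per_mm2=lambda v: _sem(v.to_numpy()),
            n="size",
        )
        .reset_index()
    )
    ref = summary[summary["group"] == reference_group].set_index("compartment")[
        "mean_density_per_mm2"
    ]
    change_rows = []
    for _, row in summary.iterrows():
        if row["group"] == reference_group:
            continue
        ref_mean = ref.get(row["compartment"])
        if ref_mean is None or ref_mean == 0:
            continue
        change_rows.append(
            {
                "group": row["group"],
                "compartment": row["compartment"],
                "percent_change_vs_reference": 100.0
                * (1.0 - row["mean_density_per_mm2"] / ref_mean),
            }
        )
    percent_change = pd.DataFrame(
        change_rows, columns=["group", "compartment", "percent_change_vs_reference"]
    )
    return AggregateDensityResult(summary, percent_change, reference_group)


@dataclass
class FiberDiameterResult:
    summary: pd.DataFrame
    differences: pd.DataFrame


def fiber_diameter_summary(
    diameters_by_group: Mapping[str, Sequence[float]],
) -> FiberDiameterResult:
    """Mean, SD, SEM, n per group and pairwise mean differences.

    The difference table lists, for each ordered pair in mapping order,
    mean(second) - mean(first).
    """
    if not diameters_by_group:
        raise DataError("no groups supplied")
    rows = []
    means: dict[str, float] = {}
    for group, vals in diameters_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise DataError(f"group {group!r} has no diameters")
        means[group] = float(arr.mean())
        rows.append(
            {
                "group": group,
                "n": int(arr.size),
                "mean_um": float(arr.mean()),
                "sd_um": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "sem_um": _sem(arr),
            }
        )
    summary = pd.DataFrame(rows, columns=["group", "n", "mean_um", "sd_um", "sem_um"])
    diff_rows = [
        {
            "group_a": a,
            "group_b": b,
            "mean_difference_um": means[b] - means[a],
        }
        for a, b in itertools.combinations(diameters_by_group.keys(), 2)
    ]
    differences = pd.DataFrame(
        diff_rows, columns=["group_a", "group_b", "mean_difference_um"]
    )
    return FiberDiameterResult(summary, differences)


def blind_labels(labels: Sequence[str], seed) -> tuple[list[str], dict[str, str]]:
    """Replace group labels with opaque codes for blinded scoring.

    Returns the coded label sequence and a decoder mapping code -> original.
    Scoring coded data and back-mapping yields numbers identical to scoring
    the originals (label equivariance).
    """
    rng = as_rng(seed)
    unique = sorted(set(labels))
    codes = [f"G{i:03d}" for i in range(len(unique))]
    rng.shuffle(codes)
    encoder = dict(zip(unique, codes))
    decoder = {c: u for u, c in encoder.items()}
    return [encoder[l] for l in labels], decoder
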