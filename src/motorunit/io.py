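"""CSV/JSON interchange, schema validation and run manifests.

All interchange is plain UTF-8 CSV with a required header, 0-based frame
indices, seconds and µm as the only time/length units. Readers validate
strictly and raise :class:`~motorunit.errors.SchemaError` (missing columns)
or :class:`~motorunit.errors.DataError` (duplicate frames, frame gaps, ...)
with the offending track/fiber named. Writers emit deterministic column
order, floats at 6 significant digits and "\\n" newlines, so re-running a
deterministic stage reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contraction import IntensityTrace
from .errors import DataError, SchemaError
from .kinematics import Track
from .morphology import NMJEvent, SectionCount
from .survival import ExplantSeries

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "channel", "condition"]
TRACE_COLUMNS = ["fiber_id", "chamber_id", "condition", "frame", "intensity"]
EVENT_COLUMNS = [
    "event_id", "unit_id", "condition", "pre_present", "post_present", "axon_intact",
]
SECTION_COLUMNS = ["section_id", "group", "compartment", "area_mm2", "n_aggregates"]
DIAMETER_COLUMNS = ["group", "diameter_um"]
COUNT_COLUMNS = ["explant_id", "condition", "day", "count"]


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               1: True, 0: False, True: True, False: False}
    out = series.map(lambda v: mapping.get(str(v).strip().lower() if isinstance(v, str) else v))
    if out.isna().any():
        raise DataError(f"column {series.name!r}: values must be boolean (0/1/true/false)")
    return out.astype(bool)


def read_tracks(path) -> list[Track]:
    """Read a track table; rows may arrive in any order.

    Schema: track_id, frame, t_s, x_um[, y_um], channel, condition. An
    optional second coordinate column (y_um) is accepted and ignored. Frames
    within a track must be consecutive (gaps are rejected, not interpolated).
    """
    df = _read_csv(path, TRACK_COLUMNS)
    if df.duplicated(subset=["track_id", "frame"]).any():
        dupes = df[df.duplicated(subset=["track_id", "frame"])]["track_id"].unique()
        raise DataError(f"duplicate (track_id, frame) rows for tracks {sorted(map(str, dupes))}")
    tracks: list[Track] = []
    for track_id, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise DataError(f"track {track_id!r}: non-consecutive frames (gap)")
        tracks.append(
            Track(
                track_id=str(track_id),
                times_s=grp["t_s"].to_numpy(dtype=float),
                positions_um=grp["x_um"].to_numpy(dtype=float),
                channel=str(grp["channel"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
            )
        )
    return tracks


def write_tracks(tracks: Sequence[Track], path) -> None:
    rows = []
    for t in tracks:
        for i in range(t.n_frames):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": i,
                    "t_s": t.times_s[i],
                    "x_um": t.positions_um[i],
                    "channel": t.channel,
                    "condition": t.condition,
                }
            )
    write_table(pd.DataFrame(rows, columns=TRACK_COLUMNS), path)


def read_traces(path, fps: float = 30.0) -> list[IntensityTrace]:
    """Read intensity traces; an optional fps column overrides the argument."""
    df = _read_csv(path, TRACE_COLUMNS)
    traces = []
    for fiber_id, grp in df.groupby("fiber_id", sort=True):
        grp = grp.sort_values("frame")
        fiber_fps = float(grp["fps"].iloc[0]) if "fps" in grp.columns else fps
        traces.append(
            IntensityTrace(
                fiber_id=str(fiber_id),
                fps=fiber_fps,
                values=grp["intensity"].to_numpy(dtype=float),
                chamber_id=str(grp["chamber_id"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
            )
        )
    return traces


def write_traces(traces: Sequence[IntensityTrace], path) -> None:
    rows = []
    for t in traces:
        for i, v in enumerate(t.values):
            rows.append(
                {
                    "fiber_id": t.fiber_id,
                    "chamber_id": t.chamber_id,
                    "condition": t.condition,
                    "frame": i,
                    "intensity": v,
                }
            )
    write_table(pd.DataFrame(rows, columns=TRACE_COLUMNS), path)


def read_nmj_events(path) -> list[NMJEvent]:
    df = _read_csv(path, EVENT_COLUMNS)
    return [
        NMJEvent(
            event_id=str(r.event_id),
            unit_id=str(r.unit_id),
            pre_present=bool(r.pre_present),
            post_present=bool(r.post_present),
            axon_intact=bool(r.axon_intact),
            condition=str(r.condition),
        )
        for r in df.assign(
            pre_present=_as_bool(df["pre_present"]),
            post_present=_as_bool(df["post_present"]),
            axon_intact=_as_bool(df["axon_intact"]),
        ).itertuples()
    ]


def write_nmj_events(events: Sequence[NMJEvent], path) -> None:
    rows = [
        {
            "event_id": e.event_id,
            "unit_id": e.unit_id,
            "condition": e.condition,
            "pre_present": int(e.pre_present),
            "post_present": int(e.post_present),
            "axon_intact": int(e.axon_intact),
        }
        for e in events
    ]
    write_table(pd.DataFrame(rows, columns=EVENT_COLUMNS), path)


def read_sections(path) -> list[SectionCount]:
    df = _read_csv(path, SECTION_COLUMNS)
    return [
        SectionCount(
            section_id=str(r.section_id),
            compartment=str(r.compartment),
            area_mm2=float(r.area_mm2),
            n_aggregates=int(r.n_aggregates),
            group=str(r.group),
            animal_id=str(r.animal_id) if "animal_id" in df.columns else None,
        )
        for r in df.itertuples()
    ]


def write_sections(sections: Sequence[SectionCount], path) -> None:
    rows = [
        {
            "section_id": s.section_id,
            "group": s.group,
            "compartment": s.compartment,
            "area_mm2": s.area_mm2,
            "n_aggregates": s.n_aggregates,
        }
        for s in sections
    ]
    write_table(pd.DataFrame(rows, columns=SECTION_COLUMNS), path)


def read_diameters(path) -> dict[str, np.ndarray]:
    df = _read_csv(path, DIAMETER_COLUMNS)
    return {
        str(g): grp["diameter_um"].to_numpy(dtype=float)
        for g, grp in df.groupby("group", sort=True)
    }


def write_diameters(diameters_by_group: Mapping[str, Sequence[float]], path) -> None:
    rows = [
        {"group": g, "diameter_um": float(d)}
        for g, vals in diameters_by_group.items()
        for d in vals
    ]
    write_table(pd.DataFrame(rows, columns=DIAMETER_COLUMNS), path)


def read_explant_counts(path) -> list[ExplantSeries]:
    df = _read_csv(path, COUNT_COLUMNS)
    series = []
    for explant_id, grp in df.groupby("explant_id", sort=True):
        grp = grp.sort_values("day")
        series.append(
            ExplantSeries(
                explant_id=str(explant_id),
                condition=str(grp["condition"].iloc[0]),
                days=tuple(int(d) for d in grp["day"]),
                counts=tuple(int(c) for c in grp["count"]),
            )
        )
    return series


def write_explant_counts(series_list: Sequence[ExplantSeries], path) -> None:
    rows = [
        {"explant_id": s.explant_id, "condition": s.condition, "day": d, "count": c}
        for s in series_list
        for d, c in zip(s.days, s.counts)
    ]
    write_table(pd.DataFrame(rows, columns=COUNT_COLUMNS), path)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write one CSV deterministically (6 significant digits, \\n, UTF-8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n",
              encoding="utf-8")
    return path


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write every named table as <name>.csv under out_dir; returns the paths."""
    out_dir = Path(out_dir)
    return [write_table(df, out_dir / f"{name}.csv") for name, df in tables.items()]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one CLI/pipeline run."""

    command: str
    config: dict
    seed: int | None
    input_hashes: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""
    tool_version: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_manifest(
    out_dir,
    command: str,
    config: dict,
    seed: int | None,
    inputs: Sequence[str | Path] = (),
    outputs: Sequence[str | Path] = (),
) -> Path:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config=config,
        seed=seed,
        input_hashes={str(p): sha256_file(p) for p in inputs},
        outputs=[str(p) for p in outputs],
        timestamp=datetime.now(timezone.utc).isoformat(),
        tool_version=__version__,
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json() + "\n", encoding="utf-8")
    return path
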