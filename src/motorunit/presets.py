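"""Named condition presets calibrated to group-level assay observables.

A preset pins the group-level quantity each assay reports (the fraction of
contracting fibers, the intact-NMJ probability, the day-16 surviving
fraction, relative aggregate density, fiber-diameter offsets). Magnitudes
the assays only compare relatively — absolute cargo speeds, pause rates,
aggregate density scale, absolute fiber diameters — are free parameters and
documented as such in the methods note.

Preset names are unique within an assay; presets are addressed as
``(assay, name)``. Presets round-trip through YAML/JSON config files; files
with unknown parameter keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError
from .synthetic import ContractionParams, SurvivalParams, TransportParams

ASSAYS = (
    "transport",
    "contraction",
    "nmj_invitro",
    "nmj_invivo",
    "survival",
    "aggregates",
    "fibers",
)

# Allowed parameter keys for the assays whose params are plain mappings.
_PLAIN_KEYS = {
    "nmj_invitro": {"p_intact"},
    "nmj_invivo": {"p_innervated"},
    "aggregates": {"density_per_mm2"},
    "fibers": {"mean_um", "sd_um"},
}
_DATACLASS_PARAMS = {
    "transport": TransportParams,
    "contraction": ContractionParams,
    "survival": SurvivalParams,
}


@dataclass(frozen=True)
class ConditionPreset:
    """A named, assay-specific parameter bundle."""

    name: str
    assay: str
    params: dict

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ParameterError(f"unknown assay {self.assay!r}")
        _validate_param_keys(self.assay, self.params)

    def build_params(self):
        """Materialize the parameter bundle.

        Returns the assay's parameter dataclass for transport, contraction
        and survival, and a plain dict for the Bernoulli/Poisson/Gaussian
        assays.
        """
        cls = _DATACLASS_PARAMS.get(self.assay)
        if cls is not None:
            return cls(**_tupleized(self.params))
        return dict(self.params)

    def to_dict(self) -> dict:
        return {"name": self.name, "assay": self.assay, "params": dict(self.params)}


def _tupleized(params: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in params.items()}


def _validate_param_keys(assay: str, params: dict) -> None:
    cls = _DATACLASS_PARAMS.get(assay)
    if cls is not None:
        allowed = {f.name for f in dataclasses.fields(cls)}
    else:
        allowed = _PLAIN_KEYS[assay]
    unknown = set(params) - allowed
    if unknown:
        raise ParameterError(
            f"unknown parameter keys for assay {assay!r}: {sorted(unknown)}"
        )


def _p(name: str, assay: str, **params) -> ConditionPreset:
    return ConditionPreset(name=name, assay=assay, params=params)


_PRESET_LIST = [
    # -- axonal transport (free kinematic magnitudes; disease slows runs and
    #    pauses more often, the direction of the group difference reported) --
    _p("WT", "transport"),
    _p(
        "SOD1",
        "transport",
        run_speed_mean_um_s=0.55,
        pause_entry_prob=0.10,
    ),
    # -- contraction: pinned contracting fractions --
    _p("WT_cocult", "contraction", fraction_contracting=0.74),
    _p("no_MN", "contraction", fraction_contracting=0.10),
    # -- in vitro NMJ intactness --
    _p("WT_cocult", "nmj_invitro", p_intact=0.75),
    # -- in vivo innervation: fully innervated WT reference, 60%/20% loss --
    _p("WT_vehicle", "nmj_invivo", p_innervated=1.0),
    _p("SOD1_vehicle", "nmj_invivo", p_innervated=0.40),
    _p("SOD1_prido30", "nmj_invivo", p_innervated=0.80),
    # -- explant survival: 50% loss at day 16 in disease co-culture --
    _p("SOD1_cocult", "survival"),
    _p(
        "WT_cocult",
        "survival",
        surviving_fraction_by_day=(1.0, 0.98, 0.96, 0.94, 0.92),
    ),
    # -- aggregates: free density scale, treated = half of vehicle --
    _p("WT_vehicle", "aggregates", density_per_mm2=1.0),
    _p("SOD1_vehicle", "aggregates", density_per_mm2=20.0),
    _p("SOD1_prido30", "aggregates", density_per_mm2=10.0),
    # -- fiber diameters: free absolute scale, common SD, +4 µm with
    #    treatment in disease (+5 µm in WT) --
    _p("WT_vehicle", "fibers", mean_um=38.0, sd_um=6.0),
    _p("WT_prido30", "fibers", mean_um=43.0, sd_um=6.0),
    _p("SOD1_vehicle", "fibers", mean_um=30.0, sd_um=6.0),
    _p("SOD1_prido30", "fibers", mean_um=34.0, sd_um=6.0),
]

PRESETS: dict[tuple[str, str], ConditionPreset] = {
    (p.assay, p.name): p for p in _PRESET_LIST
}
assert len(PRESETS) == len(_PRESET_LIST), "preset names must be unique per assay"


def get_preset(assay: str, name: str) -> ConditionPreset:
    """Look up a shipped preset by (assay, name)."""
    try:
        return PRESETS[(assay, name)]
    except KeyError:
        available = sorted(n for a, n in PRESETS if a == assay)
        raise ParameterError(
            f"no preset {name!r} for assay {assay!r}; available: {available}"
        ) from None


def list_presets(assay: str | None = None) -> list[ConditionPreset]:
    return [p for p in _PRESET_LIST if assay is None or p.assay == assay]


def load_preset_file(path) -> ConditionPreset:
    """Load a preset from a YAML or JSON file; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"preset file {path} must contain a mapping")
    unknown = set(data) - {"name", "assay", "params"}
    if unknown:
        raise ParameterError(f"unknown top-level keys in {path}: {sorted(unknown)}")
    missing = {"name", "assay"} - set(data)
    if missing:
        raise ParameterError(f"preset file {path} missing keys: {sorted(missing)}")
    return ConditionPreset(
        name=data["name"], assay=data["assay"], params=dict(data.get("params", {}))
    )


def dump_preset_file(preset: ConditionPreset, path) -> None:
    """Write a preset as YAML (or JSON when the path ends in .json)."""
    path = Path(path)
    data = preset.to_dict()
    data["params"] = {
        k: list(v) if isinstance(v, tuple) else v for k, v in data["params"].items()
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
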