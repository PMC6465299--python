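"""Preset loading: assay-readout targets -> calibrated kinetic parameters.

The shipped YAML stores, for each (construct, condition), the assay readouts
the preset must reproduce plus measurement-layer settings (temperature factor,
relative mRNA level, PM expression as percent of WT, vesicular-pH mixtures per
chase time). Rate constants are derived at load time by
:func:`hergqc.calibrate.calibrate_preset` and cached.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .calibrate import CalibrationTargets, calibrate_preset
from .params import KineticParams, ParameterError, PHMixtureSpec

__all__ = ["Preset", "PresetLibrary", "load_presets", "default_preset_path"]


@dataclass(frozen=True)
class Preset:
    construct: str
    condition: str
    targets: CalibrationTargets
    cg_decay_rate: float
    temp_factor: float
    mrna_level: float
    pm_pct_of_wt: float
    ph_mixtures: dict  # chase_time_h -> PHMixtureSpec

    @property
    def key(self) -> tuple[str, str]:
        return (self.construct, self.condition)


class PresetLibrary:
    """All presets from one YAML file, with lazy calibration."""

    def __init__(self, presets: dict[tuple[str, str], Preset], sha256: str):
        self._presets = presets
        self.sha256 = sha256
        self._params_cache: dict[tuple[str, str], KineticParams] = {}

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._presets)

    def constructs(self) -> list[str]:
        return sorted({c for c, _ in self._presets})

    def get(self, construct: str, condition: str = "untreated") -> Preset:
        try:
            return self._presets[(construct, condition)]
        except KeyError:
            raise ParameterError(
                f"no preset for construct {construct!r}, condition {condition!r}; "
                f"available: {self.keys()}"
            ) from None

    def params(self, construct: str, condition: str = "untreated") -> KineticParams:
        """Calibrated kinetic parameters for a preset (cached)."""
        key = (construct, condition)
        if key not in self._params_cache:
            p = self.get(construct, condition)
            name = construct if condition == "untreated" else f"{construct}+{condition}"
            self._params_cache[key] = calibrate_preset(
                p.targets,
                fixed={"cg_decay_rate": p.cg_decay_rate},
                construct_name=name,
                temp_factor=p.temp_factor,
                mrna_level=p.mrna_level,
            )
        return self._params_cache[key]

    def mixture(
        self, construct: str, condition: str = "untreated", chase_time_h: float = 3.0
    ) -> PHMixtureSpec:
        p = self.get(construct, condition)
        try:
            return p.ph_mixtures[float(chase_time_h)]
        except KeyError:
            raise ParameterError(
                f"no pH mixture at chase time {chase_time_h} h for {construct}/{condition}; "
                f"available: {sorted(p.ph_mixtures)}"
            ) from None


def default_preset_path() -> Path:
    return Path(resources.files("hergqc").joinpath("data/presets.yaml"))


def _parse(raw: dict, sha256: str) -> PresetLibrary:
    defaults = raw.get("defaults", {})
    default_k = float(defaults.get("cg_decay_rate_per_h", 0.8))
    presets: dict[tuple[str, str], Preset] = {}
    for block in raw["presets"]:
        t = block["targets"]
        mixtures = {
            float(m["chase_time_h"]): PHMixtureSpec(
                tuple((c["weight"], c["mean"], c["sd"]) for c in m["components"])
            )
            for m in block.get("ph_mixtures", [])
        }
        preset = Preset(
            construct=str(block["construct"]),
            condition=str(block.get("condition", "untreated")),
            targets=CalibrationTargets(
                maturation_pct=float(t["maturation_pct"]),
                pct_internalized_5min=float(t["pct_internalized_5min"]),
                recycling_pct_10min=float(t["recycling_pct_10min"]),
                surface_half_life_h=float(t["surface_half_life_h"]),
            ),
            cg_decay_rate=float(block.get("cg_decay_rate_per_h", default_k)),
            temp_factor=float(block.get("temp_factor", 1.0)),
            mrna_level=float(block.get("mrna_level", 1.0)),
            pm_pct_of_wt=float(block.get("pm_pct_of_wt", 100.0)),
            ph_mixtures=mixtures,
        )
        if preset.key in presets:
            raise ParameterError(f"duplicate preset block for {preset.key}")
        presets[preset.key] = preset
    if not presets:
        raise ParameterError("preset file defines no presets")
    return PresetLibrary(presets, sha256)


@lru_cache(maxsize=8)
def _load_cached(path_str: str) -> PresetLibrary:
    data = Path(path_str).read_bytes()
    return _parse(yaml.safe_load(data), hashlib.sha256(data).hexdigest())


def load_presets(path: str | Path | None = None) -> PresetLibrary:
    """Load (and cache) a preset library; defaults to the shipped YAML."""
    path = Path(path) if path is not None else default_preset_path()
    return _load_cached(str(path.resolve()))
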