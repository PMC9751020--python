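"""YAML run configuration.

Numeric keys carry their unit in the name (``dx_mm``, ``window_us``,
``amplitude_kpa``) to keep the mm/m and kPa/Pa conversions at one single
boundary.  An empty file yields all defaults; unknown keys are rejected;
validation collects every violation before raising.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

from tfusim.acoustic_solver import SolverConfig
from tfusim.coupling_pipeline import MultiscaleConfig, ROISpec
from tfusim.errors import ConfigError
from tfusim.head_model import HeadGeometryConfig, MediumProperties
from tfusim.sonophore_neuron import BLSParams, RSNeuronParams


def default_config_dict() -> Dict[str, Any]:
    """The full default configuration tree (paper-printed sweeps)."""
    return {
        "seed": 0,
        "geometry": {
            "grid_nx": 561,
            "grid_ny": 561,
            "dx_mm": 0.5,
            "brain_outer_radius_mm": 85.0,
            "skull_mm": [5.4, 7.6, 10.5],
            "standoff_mm": 40.0,
            "aperture_mm": 64.0,
            "roc_mm": 63.2,
            "apex_margin_mm": 15.0,
            "frequency_khz": 250.0,
            "amplitude_kpa": 100.0,
            "points_per_wavelength": 4.0,
        },
        "media": {
            "water": {"sound_speed": 1481.0, "density": 998.0, "alpha0": 0.002},
            "skull": {"sound_speed": 2820.0, "density": 1732.0, "alpha0": 7.75},
            "brain": {"sound_speed": 1500.0, "density": 1000.0, "alpha0": 0.8},
        },
        "solver": {
            "cfl": 0.5,
            "pml_px": 20,
            "absorption_exponent": 1.0,
            "window_us": 500.0,
            "duty_cycles": [0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
        },
        "neuron": {
            "bls": {},  # SI-unit overrides of any BLSParams field
            "rs": {},  # SI-unit overrides of any RSNeuronParams field
        },
        "roi": {
            "y_rows_mm": [-10.19, -5.56, -0.92],
            "n_columns": 5,
            "column_spacing_mm": 5.0,
            "mirror": False,
        },
        "protocol": {
            "prf_hz": 500.0,
            "duration_ms": 100.0,
            "table_pa_step_kpa": 10.0,
            "sonic_dt_us": 1.0,
            "spike_threshold_mv": 0.0,
            "spike_refractory_ms": 1.0,
        },
        "output": {
            "out_dir": "results",
            "safety_threshold_w_cm2": 3.0,
        },
    }


def _merge(defaults: Dict[str, Any], user: Dict[str, Any], path: str, errors: List[str]):
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            errors.append(f"unknown key {here}")
            continue
        if isinstance(defaults[key], dict) and key not in ("bls", "rs"):
            if not isinstance(value, dict):
                errors.append(f"{here} must be a mapping")
                continue
            out[key] = _merge(defaults[key], value, here, errors)
        else:
            out[key] = value
    return out


def _validate(tree: Dict[str, Any], errors: List[str]) -> None:
    geo = tree["geometry"]
    for key in ("dx_mm", "brain_outer_radius_mm", "standoff_mm", "aperture_mm",
                "roc_mm", "frequency_khz", "points_per_wavelength"):
        if not isinstance(geo[key], (int, float)) or geo[key] <= 0:
            errors.append(f"geometry.{key} must be a positive number")
    if geo["amplitude_kpa"] < 0:
        errors.append("geometry.amplitude_kpa must be non-negative")
    for key in ("grid_nx", "grid_ny"):
        if not isinstance(geo[key], int) or geo[key] < 4:
            errors.append(f"geometry.{key} must be an integer >= 4")
    skulls = geo["skull_mm"] if isinstance(geo["skull_mm"], list) else [geo["skull_mm"]]
    for s in skulls:
        if s < 0:
            errors.append("geometry.skull_mm entries must be >= 0")
    # dx must resolve the configured points-per-wavelength in the slowest medium
    if not errors:
        c_min = min(m["sound_speed"] for m in tree["media"].values())
        dx_max_mm = c_min / (geo["frequency_khz"] * 1e3 * geo["points_per_wavelength"]) * 1e3
        if geo["dx_mm"] > dx_max_mm * (1 + 1e-9):
            errors.append(
                f"geometry.dx_mm={geo['dx_mm']} exceeds the {dx_max_mm:.3f} mm bound "
                "from points_per_wavelength"
            )
    for name, props in tree["media"].items():
        for key in ("sound_speed", "density"):
            if props[key] <= 0:
                errors.append(f"media.{name}.{key} must be positive")
        if props["alpha0"] < 0:
            errors.append(f"media.{name}.alpha0 must be >= 0")
    sol = tree["solver"]
    if not 0 < sol["cfl"] <= 0.7:
        errors.append("solver.cfl must be in (0, 0.7]")
    if sol["window_us"] <= 0:
        errors.append("solver.window_us must be positive")
    for dc in sol["duty_cycles"]:
        if not 0 < dc <= 1:
            errors.append("solver.duty_cycles entries must be in (0, 1]")
    pro = tree["protocol"]
    if pro["prf_hz"] <= 0 or pro["duration_ms"] <= 0:
        errors.append("protocol.prf_hz and protocol.duration_ms must be positive")
    roi = tree["roi"]
    if roi["n_columns"] * len(roi["y_rows_mm"]) != 15:
        errors.append("roi must define 15 sample positions (n_columns x y_rows_mm)")


@dataclass
class RunConfig:
    """Validated configuration tree with typed accessors."""

    tree: Dict[str, Any]

    # -- serialisation ------------------------------------------------------

    def dump(self) -> str:
        return yaml.safe_dump(self.tree, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(self.tree, sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()

    @property
    def seed(self) -> int:
        return int(self.tree["seed"])

    # -- typed accessors ----------------------------------------------------

    def geometry(self, skull_mm: Optional[float] = None) -> HeadGeometryConfig:
        g = self.tree["geometry"]
        skull = skull_mm if skull_mm is not None else self.skull_list_mm()[0]
        return HeadGeometryConfig(
            grid_nx=g["grid_nx"],
            grid_ny=g["grid_ny"],
            dx=g["dx_mm"] * 1e-3,
            brain_outer_radius=g["brain_outer_radius_mm"] * 1e-3,
            skull_thickness=skull * 1e-3,
            standoff=g["standoff_mm"] * 1e-3,
            transducer_aperture=g["aperture_mm"] * 1e-3,
            transducer_roc=g["roc_mm"] * 1e-3,
            apex_margin=g["apex_margin_mm"] * 1e-3,
            source_frequency=g["frequency_khz"] * 1e3,
            source_amplitude=g["amplitude_kpa"] * 1e3,
            points_per_wavelength=g["points_per_wavelength"],
        )

    def skull_list_mm(self) -> List[float]:
        s = self.tree["geometry"]["skull_mm"]
        return list(s) if isinstance(s, list) else [s]

    def duty_cycles(self) -> List[float]:
        return list(self.tree["solver"]["duty_cycles"])

    def media(self) -> Dict[str, MediumProperties]:
        return {
            name: MediumProperties(**props) for name, props in self.tree["media"].items()
        }

    def solver(self) -> SolverConfig:
        s = self.tree["solver"]
        return SolverConfig(
            cfl=s["cfl"],
            boundary_layer_thickness=s["pml_px"],
            absorption_exponent=s["absorption_exponent"],
        )

    def window(self) -> float:
        return self.tree["solver"]["window_us"] * 1e-6

    def bls(self) -> BLSParams:
        return BLSParams(**self.tree["neuron"]["bls"])

    def rs_neuron(self) -> RSNeuronParams:
        return RSNeuronParams(**self.tree["neuron"]["rs"])

    def roi(self) -> ROISpec:
        r = self.tree["roi"]
        return ROISpec(
            y_rows=tuple(v * 1e-3 for v in r["y_rows_mm"]),
            n_columns=r["n_columns"],
            column_spacing=r["column_spacing_mm"] * 1e-3,
            mirror=r["mirror"],
        )

    def multiscale(
        self,
        skull_mm: Optional[List[float]] = None,
        duty_cycles: Optional[List[float]] = None,
    ) -> MultiscaleConfig:
        pro = self.tree["protocol"]
        skulls = skull_mm if skull_mm is not None else self.skull_list_mm()
        dcs = duty_cycles if duty_cycles is not None else self.duty_cycles()
        return MultiscaleConfig(
            geometry=self.geometry(skulls[0]),
            media=self.media(),
            solver=self.solver(),
            roi=self.roi(),
            bls=self.bls(),
            neuron=self.rs_neuron(),
            skull_thicknesses=tuple(s * 1e-3 for s in skulls),
            duty_cycles=tuple(dcs),
            window=self.window(),
            prf=pro["prf_hz"],
            protocol_duration=pro["duration_ms"] * 1e-3,
            table_pa_step=pro["table_pa_step_kpa"] * 1e3,
            sonic_dt=pro["sonic_dt_us"] * 1e-6,
            spike_threshold=pro["spike_threshold_mv"] * 1e-3,
            spike_refractory=pro["spike_refractory_ms"] * 1e-3,
        )

    def out_dir(self) -> Path:
        return Path(self.tree["output"]["out_dir"])

    def safety_threshold(self) -> float:
        """Safety bound in W/m^2."""
        return self.tree["output"]["safety_threshold_w_cm2"] * 1e4


def load_config(path: Optional[str] = None) -> RunConfig:
    """Parse, merge over defaults and validate; empty file = defaults."""
    user: Dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {path}")
        text = p.read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        user = loaded

    errors: List[str] = []
    tree = _merge(default_config_dict(), user, "", errors)
    if not errors:
        _validate(tree, errors)
    if errors:
        raise ConfigError(errors)
    return RunConfig(tree=tree)
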