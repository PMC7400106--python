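"""Run configuration: defaults, presets, and YAML/JSON round-tripping.

The bundled ``flowcell_preset`` encodes the operating point of the
reference PDMS flow-cell assay this package targets: a 0.8 x 1.6 cm
rectangular channel of length 25.42 cm observed at mid-channel, citrate
buffer at 30 degC (rho = 993.37 kg/m^3, mu = 6.94e-4 kg/(m*s)), an
E. coli suspension at 7.6e13 cells/m^3 with diffusion coefficient
4.0e-13 m^2/s and equivalent cell radius 4.5e-7 m, and six flow rates
(1-10 mL/s) with CFD-derived wall shear rates of 7.5-100.8 1/s.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .detect import DetectionParams
from .errors import ParameterError
from .simulate import ShadowModel, SimulationConfig
from .transport import (
    CellMorphology,
    ChannelGeometry,
    FlowCondition,
    FluidProperties,
    make_condition,
)

__all__ = [
    "ConditionSpec",
    "BlockingParams",
    "RunConfig",
    "flowcell_preset",
    "load_config",
    "save_config",
]

_ML_PER_M3 = 1.0e6


@dataclass(frozen=True)
class ConditionSpec:
    """One flow condition as written in a config file (reporting units)."""

    Q_mL_per_s: float
    shear_rate_per_s: float | None = None
    tau_w_Pa: float | None = None

    def to_condition(self, geom: ChannelGeometry, fluid: FluidProperties) -> FlowCondition:
        if not self.Q_mL_per_s > 0:
            raise ParameterError(f"Q_mL_per_s must be > 0 (got {self.Q_mL_per_s})")
        return make_condition(
            self.Q_mL_per_s / _ML_PER_M3,
            geom,
            fluid,
            shear_rate=self.shear_rate_per_s,
            wall_shear_stress=self.tau_w_Pa,
        )


@dataclass(frozen=True)
class BlockingParams:
    """Pair-correlation and anisotropy-test settings."""

    r_max_px: int = 50
    pixel_scale_um: float = 0.61
    mode: str = "unordered"
    theta_deg: float = 30.0
    r_s_px: float = 34.0
    flow_direction: tuple[float, float] = (1.0, 0.0)
    n_permutations: int = 999


@dataclass
class RunConfig:
    """Everything needed for one end-to-end pipeline run.

    ``mode`` selects the input source: "simulate" (synthetic data),
    "images" (a directory of frames), or "coordinates" (a CSV of detected
    positions).
    """

    mode: str = "simulate"
    geometry: ChannelGeometry = field(
        default_factory=lambda: ChannelGeometry(0.016, 0.008, 0.2542, 0.1271)
    )
    fluid: FluidProperties = field(
        default_factory=lambda: FluidProperties(993.37, 6.94e-4, 4.0e-13, 7.6e13)
    )
    cell: CellMorphology = field(default_factory=lambda: CellMorphology(equivalent_radius=4.5e-7))
    conditions: list[ConditionSpec] = field(default_factory=lambda: [ConditionSpec(1.0)])
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    blocking: BlockingParams = field(default_factory=BlockingParams)
    seed: int = 0
    input_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "images", "coordinates"):
            raise ParameterError("mode must be 'simulate', 'images' or 'coordinates'")
        if self.mode in ("images", "coordinates") and not self.input_path:
            raise ParameterError(f"mode '{self.mode}' requires input_path")


#: CFD-derived wall shear rates (1/s) for the six preset flow rates (mL/s).
PRESET_FLOW_RATES_ML_S = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
PRESET_SHEAR_RATES_S = (7.5, 15.0, 33.7, 51.6, 80.3, 100.8)


def flowcell_preset(seed: int = 0) -> RunConfig:
    """The reference six-flow-rate PDMS flow-cell configuration."""
    conditions = [
        ConditionSpec(Q_mL_per_s=q, shear_rate_per_s=g)
        for q, g in zip(PRESET_FLOW_RATES_ML_S, PRESET_SHEAR_RATES_S)
    ]
    return RunConfig(mode="simulate", conditions=conditions, seed=seed)


# ---------------------------------------------------------------------------
# serialization


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_dict(cfg)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    kwargs: dict[str, Any] = {}
    if "geometry" in d:
        kwargs["geometry"] = ChannelGeometry(**d["geometry"])
    if "fluid" in d:
        kwargs["fluid"] = FluidProperties(**d["fluid"])
    if "cell" in d:
        kwargs["cell"] = CellMorphology(**d["cell"])
    if "conditions" in d:
        kwargs["conditions"] = [ConditionSpec(**c) for c in d["conditions"]]
    if "simulation" in d:
        sim = dict(d["simulation"])
        if "shadow" in sim:
            sim["shadow"] = ShadowModel(**sim["shadow"])
        kwargs["simulation"] = SimulationConfig(**sim)
    if "detection" in d:
        kwargs["detection"] = DetectionParams(**d["detection"])
    if "blocking" in d:
        blk = dict(d["blocking"])
        if "flow_direction" in blk:
            blk["flow_direction"] = tuple(blk["flow_direction"])
        kwargs["blocking"] = BlockingParams(**blk)
    for key in ("mode", "seed", "input_path"):
        if key in d:
            kwargs[key] = d[key]
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig to YAML or JSON (by extension)."""
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
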