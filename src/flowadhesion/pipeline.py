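"""End-to-end orchestration: simulate/load -> detect -> kinetics -> blocking.

``run_pipeline`` executes the stages in dependency order for every flow
condition in the config, writes machine-readable CSV/JSON outputs with fixed
float formatting (6 significant digits, so reruns with the same seed are
byte-identical), and returns a manifest listing every file written.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blocking import FieldPoints, flow_axis_depletion_index, pair_correlation_map, permutation_test
from .config import RunConfig, config_to_dict
from .detect import DetectionParams, ImageFrame, detect_sequence
from .errors import ParameterError
from .kinetics import AdhesionTimeSeries, fit_two_phase
from .simulate import scenario_from_transport, simulate_adhesion
from .transport import transport_estimate, transport_table

__all__ = ["RunManifest", "run_pipeline"]

logger = logging.getLogger("flowadhesion")

_FLOAT_FMT = "%.6g"


@dataclass
class RunManifest:
    """Record of one pipeline run: config echo, outputs, stage timings."""

    config: dict
    version: str
    outputs: dict[str, list[str]] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def add(self, stage: str, path: Path) -> None:
        self.outputs.setdefault(stage, []).append(str(path))

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "outputs": self.outputs,
                "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
            },
            indent=2,
            sort_keys=True,
        )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _series_from_sim(sim, condition_label: str) -> AdhesionTimeSeries:
    return AdhesionTimeSeries(
        times_s=sim.frame_times,
        densities=sim.densities_cells_cm2().astype(float),
        condition=condition_label,
    )


def _fields_from_sim(sim, pixel_scale_um: float) -> FieldPoints:
    last = sim.frames[-1]
    return FieldPoints(
        x_px=last[:, 0] / pixel_scale_um,
        y_px=last[:, 1] / pixel_scale_um,
        width_px=sim.config.field_width_um / pixel_scale_um,
        height_px=sim.config.field_height_um / pixel_scale_um,
        attach_times_s=last[:, 2],
    )


def _load_coordinate_fields(path: Path, blocking_cfg) -> list[FieldPoints]:
    df = pd.read_csv(path)
    for col in ("x_px", "y_px"):
        if col not in df.columns:
            raise ParameterError(f"coordinates CSV must have a '{col}' column")
    width = df["x_px"].max() + 1 if "width_px" not in df.columns else df["width_px"].iloc[0]
    height = df["y_px"].max() + 1 if "height_px" not in df.columns else df["height_px"].iloc[0]
    groups = df.groupby("field") if "field" in df.columns else [(0, df)]
    fields = []
    for _, g in groups:
        fields.append(
            FieldPoints(
                x_px=g["x_px"].to_numpy(float),
                y_px=g["y_px"].to_numpy(float),
                width_px=float(width),
                height_px=float(height),
                attach_times_s=g["time_s"].to_numpy(float) if "time_s" in g.columns else None,
            )
        )
    return fields


def _blocking_outputs(fields, cfg: RunConfig, label: str, out: Path, manifest: RunManifest, rng):
    blk = cfg.blocking
    mode = blk.mode
    if mode == "time_ordered" and any(f.attach_times_s is None for f in fields):
        logger.warning("blocking[%s]: no attach times available, falling back to unordered", label)
        mode = "unordered"
    pcmap = pair_correlation_map(fields, r_max=blk.r_max_px, mode=mode)
    map_path = out / f"paircorr_{label}.csv"
    np.savetxt(map_path, pcmap.density, delimiter=",", fmt=_FLOAT_FMT)
    manifest.add("blocking", map_path)
    sidecar = {
        "r_max_px": pcmap.r_max,
        "mode": pcmap.mode,
        "n_pairs": pcmap.n_pairs,
        "normalization": "bins sum to 1 over the disc",
        "max_bin": float(pcmap.density.max()),
        "depletion_index": None,
        "permutation_p": None,
        "n_permutations": 0,
        "low_pair_caveat": True,
    }
    try:
        aniso = flow_axis_depletion_index(
            pcmap, theta_deg=blk.theta_deg, r_s=blk.r_s_px, flow_direction=blk.flow_direction
        )
        perm = permutation_test(
            fields,
            r_max=blk.r_max_px,
            mode=mode,
            theta_deg=blk.theta_deg,
            r_s=blk.r_s_px,
            flow_direction=blk.flow_direction,
            n_permutations=blk.n_permutations,
            seed=rng,
        )
        sidecar.update(
            depletion_index=aniso.index,
            permutation_p=perm.p_value,
            n_permutations=perm.n_permutations,
            low_pair_caveat=perm.low_pair_caveat,
        )
    except ParameterError as exc:
        # too few adhered cells for a directional statistic; keep the map
        logger.warning("blocking[%s]: anisotropy test skipped: %s", label, exc)
    side_path = out / f"paircorr_{label}.json"
    side_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    manifest.add("blocking", side_path)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> RunManifest:
    """Run every stage of the analysis for the configured input mode.

    Outputs per run: ``transport.csv`` (one row per flow condition),
    ``series_<label>.csv`` and ``fits.csv`` (kinetics), one
    ``paircorr_<label>.csv``/``.json`` pair per condition, and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config_to_dict(cfg), version=__version__)
    rng = np.random.default_rng(cfg.seed)

    # --- transport -------------------------------------------------------
    t0 = time.perf_counter()
    conditions = [c.to_condition(cfg.geometry, cfg.fluid) for c in cfg.conditions]
    table = transport_table(conditions, cfg.fluid, cfg.cell, cfg.geometry)
    _write_csv(table, out / "transport.csv")
    manifest.add("transport", out / "transport.csv")
    manifest.stage_seconds["transport"] = time.perf_counter() - t0

    labels = [f"{c.Q_mL_per_s:g}mLs" for c in cfg.conditions]

    fits_rows = []
    t0 = time.perf_counter()
    if cfg.mode == "simulate":
        for label, spec, cond in zip(labels, cfg.conditions, conditions):
            est = transport_estimate(cond, cfg.fluid, cfg.cell, cfg.geometry)
            sim_cfg = scenario_from_transport(cond, est, base=cfg.simulation)
            child_seed = int(rng.integers(0, 2**31 - 1))
            sim_cfg = type(sim_cfg)(**{**sim_cfg.__dict__, "rng_seed": child_seed})
            sim = simulate_adhesion(sim_cfg)
            series = _series_from_sim(sim, label)
            _write_csv(
                pd.DataFrame({"time_s": series.times_s, "cells_per_cm2": series.densities}),
                out / f"series_{label}.csv",
            )
            manifest.add("simulate", out / f"series_{label}.csv")
            try:
                fit = fit_two_phase(series)
                fits_rows.append(
                    {
                        "condition": label,
                        "t_b_min": fit.breakpoint_s / 60.0,
                        "s1_cells_cm2_min": fit.slope1,
                        "s2_cells_cm2_min": fit.slope2,
                        "reduction_pct": fit.reduction_pct,
                        "R2_1": fit.r2_1,
                        "R2_2": fit.r2_2,
                    }
                )
            except ParameterError as exc:
                logger.warning("kinetics[%s]: %s", label, exc)
            fields = [_fields_from_sim(sim, cfg.blocking.pixel_scale_um)]
            _blocking_outputs(fields, cfg, label, out, manifest, rng)
    elif cfg.mode == "images":
        frames = _load_image_frames(Path(cfg.input_path), cfg)
        series = detect_sequence(frames, cfg.detection)
        _write_csv(
            pd.DataFrame({"time_s": series.times_s, "cells_per_cm2": series.densities}),
            out / "series_images.csv",
        )
        manifest.add("detect", out / "series_images.csv")
        fit = fit_two_phase(series)
        fits_rows.append(
            {
                "condition": "images",
                "t_b_min": fit.breakpoint_s / 60.0,
                "s1_cells_cm2_min": fit.slope1,
                "s2_cells_cm2_min": fit.slope2,
                "reduction_pct": fit.reduction_pct,
                "R2_1": fit.r2_1,
                "R2_2": fit.r2_2,
            }
        )
        from .detect import find_maxima

        last = find_maxima(frames[-1], cfg.detection)
        fields = [
            FieldPoints(
                x_px=last.coordinates[:, 0].astype(float),
                y_px=last.coordinates[:, 1].astype(float),
                width_px=frames[-1].pixels.shape[1],
                height_px=frames[-1].pixels.shape[0],
            )
        ]
        _blocking_outputs(fields, cfg, "images", out, manifest, rng)
    else:  # coordinates
        fields = _load_coordinate_fields(Path(cfg.input_path), cfg.blocking)
        _blocking_outputs(fields, cfg, "coords", out, manifest, rng)
    manifest.stage_seconds["analysis"] = time.perf_counter() - t0

    if fits_rows:
        _write_csv(pd.DataFrame(fits_rows), out / "fits.csv")
        manifest.add("kinetics", out / "fits.csv")

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _load_image_frames(path: Path, cfg: RunConfig) -> list[ImageFrame]:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
    if not files:
        raise ParameterError(f"no TIFF/PNG frames found in {path}")
    interval = cfg.simulation.frame_interval_s
    frames = []
    for i, f in enumerate(files):
        px = iio.imread(f)
        if px.ndim == 3:
            px = px[..., 0]
        frames.append(
            ImageFrame(px, pixel_scale_um=cfg.blocking.pixel_scale_um, timestamp_s=(i + 1) * interval)
        )
    return frames
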