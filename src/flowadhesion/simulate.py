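"""Stochastic simulator of initial bacterial adhesion under flow.

Adhesion is modelled as a marked point process on a rectangular field of
view: cells arrive as a homogeneous Poisson process in time (rate set by the
deposition flux times the field area), land at uniformly random positions,
and stick unless the landing spot violates a hard-core exclusion around an
already adhered cell or falls inside an optional "hydrodynamic shadow" — a
rectangular footprint downstream (+x, the flow direction) of each adhered
cell in which deposition is suppressed by the near-wall flow around the
obstacle.  Rejected arrivals are lost (swept away by convection), not
re-queued.  Adhered cells may detach independently with first-order
(exponential) kinetics at rate ``k_det``.

This random-sequential-adsorption-style model is the synthetic stand-in for
flow-cell microscopy experiments: it produces per-frame coordinate lists, a
ground-truth event log, and (via :func:`render_field`) brightfield-like
image frames for exercising the detection code.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .transport import FlowCondition, TransportEstimate

__all__ = [
    "ShadowModel",
    "SimulationConfig",
    "AdhesionEvent",
    "SimulatedField",
    "simulate_adhesion",
    "scenario_from_transport",
    "uniform_hard_core_field",
    "render_field",
]

#: um^2 per cm^2 — converts areal rates quoted per cm^2 to the field scale.
_UM2_PER_CM2 = 1.0e8


@dataclass(frozen=True)
class ShadowModel:
    """Rectangular downstream exclusion footprint behind each adhered cell.

    The blocked region of a cell at (xc, yc) is
    ``xc <= x <= xc + length_um`` and ``|y - yc| <= halfwidth_um``
    (flow along +x).  Disabled by default.
    """

    enabled: bool = False
    length_um: float = 21.0
    halfwidth_um: float = 1.5

    def __post_init__(self) -> None:
        if self.length_um < 0 or self.halfwidth_um < 0:
            raise ParameterError("shadow dimensions must be >= 0")

    def area_multiple(self, cell_radius_um: float) -> float:
        """Blocked area as a multiple of the cell cross-sectional area."""
        if not cell_radius_um > 0:
            raise ParameterError("cell_radius_um must be > 0")
        return (self.length_um * 2.0 * self.halfwidth_um) / (math.pi * cell_radius_um**2)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated adhesion run.

    Defaults follow the flow-cell assay protocol this simulator emulates:
    30 min observation with one frame every 60 s, imaged at 0.61 um/pixel,
    and an arrival rate of order the Smoluchowski-Levich flux at the lowest
    flow rate (~80 cells/(cm^2*s)).
    """

    field_width_um: float = 400.0
    field_height_um: float = 400.0
    pixel_scale_um: float = 0.61
    arrival_rate: float = 80.0  # cells/(cm^2*s)
    detachment_rate: float = 0.0  # 1/s
    hard_core_radius_um: float = 1.0
    shadow: ShadowModel = field(default_factory=ShadowModel)
    duration_s: float = 1800.0
    frame_interval_s: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.field_width_um > 0 or not self.field_height_um > 0:
            raise ParameterError("field dimensions must be > 0")
        if not self.pixel_scale_um > 0:
            raise ParameterError("pixel_scale_um must be > 0")
        if self.arrival_rate < 0:
            raise ParameterError("arrival_rate must be >= 0")
        if self.detachment_rate < 0:
            raise ParameterError("detachment_rate must be >= 0")
        if self.hard_core_radius_um < 0:
            raise ParameterError("hard_core_radius_um must be >= 0")
        if not self.frame_interval_s > 0:
            raise ParameterError("frame_interval_s must be > 0")
        if self.duration_s < self.frame_interval_s:
            raise ParameterError("duration_s must be >= frame_interval_s")

    @property
    def field_area_cm2(self) -> float:
        return self.field_width_um * self.field_height_um / _UM2_PER_CM2


@dataclass(frozen=True)
class AdhesionEvent:
    """One attach or detach event in the ground-truth log."""

    cell_id: int
    event: str  # "attach" | "detach"
    time_s: float
    x_um: float
    y_um: float


@dataclass
class SimulatedField:
    """Output of one simulation run.

    ``frames[i]`` holds the cells adhered at ``frame_times[i]`` as an
    (n, 3) array of columns (x_um, y_um, attach_time_s).
    """

    config: SimulationConfig
    frame_times: np.ndarray
    frames: list[np.ndarray]
    events: list[AdhesionEvent]
    n_arrivals: int
    n_rejected: int

    def counts(self) -> np.ndarray:
        return np.array([len(f) for f in self.frames])

    def densities_cells_cm2(self) -> np.ndarray:
        return self.counts() / self.config.field_area_cm2


def _min_sq_dist(x: float, y: float, xs: np.ndarray, ys: np.ndarray) -> float:
    if xs.size == 0:
        return np.inf
    return float(np.min((xs - x) ** 2 + (ys - y) ** 2))


def _in_any_shadow(x: float, y: float, xs: np.ndarray, ys: np.ndarray, shadow: ShadowModel) -> bool:
    if xs.size == 0:
        return False
    dx = x - xs
    dy = np.abs(y - ys)
    return bool(np.any((dx >= 0.0) & (dx <= shadow.length_um) & (dy <= shadow.halfwidth_um)))


def simulate_adhesion(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedField:
    """Run one adhesion/detachment simulation.

    Arrivals form a homogeneous Poisson process at ``arrival_rate`` times the
    field area; each arrival lands uniformly and is rejected if it falls
    within ``2*hard_core_radius_um`` of an adhered cell or inside any shadow
    footprint.  Each adhered cell carries an independent exponential
    detachment clock at ``detachment_rate``.  With ``rng=None`` the run is
    fully determined by ``config.rng_seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    rate_per_s = config.arrival_rate * config.field_area_cm2
    n_arrivals = int(rng.poisson(rate_per_s * config.duration_s))
    arrival_times = np.sort(rng.uniform(0.0, config.duration_s, size=n_arrivals))
    arrival_x = rng.uniform(0.0, config.field_width_um, size=n_arrivals)
    arrival_y = rng.uniform(0.0, config.field_height_um, size=n_arrivals)

    min_dist_sq = (2.0 * config.hard_core_radius_um) ** 2

    # active adhered cells, parallel arrays
    act_x: list[float] = []
    act_y: list[float] = []
    act_attach: list[float] = []
    act_detach: list[float] = []
    act_id: list[int] = []

    events: list[AdhesionEvent] = []
    settled: list[tuple[int, float, float, float, float]] = []  # id, x, y, attach, detach
    n_rejected = 0
    next_id = 0

    for t, x, y in zip(arrival_times, arrival_x, arrival_y):
        # retire cells whose detachment clock has expired
        if act_detach and config.detachment_rate > 0:
            keep = [i for i, td in enumerate(act_detach) if td > t]
            if len(keep) < len(act_detach):
                for i in range(len(act_detach)):
                    if act_detach[i] <= t:
                        settled.append((act_id[i], act_x[i], act_y[i], act_attach[i], act_detach[i]))
                act_x = [act_x[i] for i in keep]
                act_y = [act_y[i] for i in keep]
                act_attach = [act_attach[i] for i in keep]
                act_detach = [act_detach[i] for i in keep]
                act_id = [act_id[i] for i in keep]

        xs = np.asarray(act_x)
        ys = np.asarray(act_y)
        if _min_sq_dist(x, y, xs, ys) < min_dist_sq:
            n_rejected += 1
            continue
        if config.shadow.enabled and _in_any_shadow(x, y, xs, ys, config.shadow):
            n_rejected += 1
            continue

        if config.detachment_rate > 0:
            t_detach = t + rng.exponential(1.0 / config.detachment_rate)
        else:
            t_detach = np.inf
        act_x.append(x)
        act_y.append(y)
        act_attach.append(t)
        act_detach.append(t_detach)
        act_id.append(next_id)
        events.append(AdhesionEvent(next_id, "attach", t, x, y))
        next_id += 1

    for i in range(len(act_id)):
        settled.append((act_id[i], act_x[i], act_y[i], act_attach[i], act_detach[i]))
    settled.sort(key=lambda c: c[0])
    for cid, x, y, ta, td in settled:
        if td <= config.duration_s:
            events.append(AdhesionEvent(cid, "detach", td, x, y))
    events.sort(key=lambda e: (e.time_s, e.cell_id))

    if n_arrivals > 0 and n_rejected / n_arrivals > 0.5:
        warnings.warn(
            f"jamming regime: {n_rejected}/{n_arrivals} arrivals rejected "
            "(exclusion/shadow area comparable to the field)",
            stacklevel=2,
        )

    n_frames = int(math.floor(config.duration_s / config.frame_interval_s))
    frame_times = config.frame_interval_s * np.arange(1, n_frames + 1)
    frames = []
    for t in frame_times:
        rows = [
            (x, y, ta)
            for _, x, y, ta, td in settled
            if ta <= t < td
        ]
        frames.append(np.array(rows, dtype=float).reshape(-1, 3))

    return SimulatedField(
        config=config,
        frame_times=frame_times,
        frames=frames,
        events=events,
        n_arrivals=n_arrivals,
        n_rejected=n_rejected,
    )


#: Reference drag used to scale detachment; on the order of the drag at the
#: lowest flow rate of the assay. Arbitrary: no measured detachment kinetics
#: exist to calibrate it.
DEFAULT_DRAG_REFERENCE_N = 3.4e-14
DEFAULT_DETACHMENT_SCALE = 1.0e-3  # 1/s at drag == reference


def scenario_from_transport(
    condition: FlowCondition,
    transport: TransportEstimate,
    base: SimulationConfig | None = None,
    detachment_scale: float = DEFAULT_DETACHMENT_SCALE,
    drag_reference: float = DEFAULT_DRAG_REFERENCE_N,
) -> SimulationConfig:
    """Bind a flow condition's transport estimate to a simulation config.

    The arrival rate is set to the Smoluchowski-Levich flux and the
    detachment rate scales linearly with the drag force:
    ``k_det = detachment_scale * drag / drag_reference``.  The scale and
    reference are tunable model choices, not measured quantities.
    """
    if not drag_reference > 0:
        raise ParameterError("drag_reference must be > 0")
    if detachment_scale < 0:
        raise ParameterError("detachment_scale must be >= 0")
    base = base if base is not None else SimulationConfig()
    return replace(
        base,
        arrival_rate=transport.sl_flux,
        detachment_rate=detachment_scale * transport.drag_force / drag_reference,
    )


def uniform_hard_core_field(
    n_cells: int,
    width_um: float,
    height_um: float,
    min_distance_um: float,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> np.ndarray:
    """Sequentially place ``n_cells`` uniform points with a hard-core distance.

    Random sequential adsorption by dart throwing with a grid-based
    neighbour check; returns an (n, 2) array of (x_um, y_um).  Raises if the
    requested density cannot be reached within ``max_attempts`` proposals
    (default ``50 * n_cells``).
    """
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    if not width_um > 0 or not height_um > 0:
        raise ParameterError("field dimensions must be > 0")
    if min_distance_um < 0:
        raise ParameterError("min_distance_um must be >= 0")
    if max_attempts is None:
        max_attempts = max(1000, 50 * n_cells)

    cell = max(min_distance_um, 1e-9)
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    pts = np.empty((n_cells, 2))
    placed = 0
    attempts = 0
    d2 = min_distance_um**2
    while placed < n_cells:
        if attempts >= max_attempts:
            raise ParameterError(
                f"could not place {n_cells} points at min distance {min_distance_um} "
                f"in {width_um}x{height_um} um after {attempts} attempts (jamming)"
            )
        attempts += 1
        x = rng.uniform(0.0, width_um)
        y = rng.uniform(0.0, height_um)
        gi, gj = int(x / cell), int(y / cell)
        ok = True
        for ii in range(gi - 1, gi + 2):
            for jj in range(gj - 1, gj + 2):
                for px, py in grid.get((ii, jj), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        grid.setdefault((gi, gj), []).append((x, y))
        pts[placed] = (x, y)
        placed += 1
    return pts


def render_field(
    positions_um: np.ndarray,
    field_width_um: float,
    field_height_um: float,
    pixel_scale_um: float = 0.61,
    psf_sigma_um: float = 0.8,
    amplitude: float = 120.0,
    background: float = 200.0,
    noise_sd: float = 8.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render adhered-cell positions as a brightfield-like 8-bit frame.

    Each cell is a dark Gaussian blob of standard deviation ``psf_sigma_um``
    and depth ``amplitude`` below a light ``background``; Gaussian read noise
    of standard deviation ``noise_sd`` is added and the result clipped to
    [0, 255].  Returns a (rows, cols) uint8 array with x along columns.
    """
    if not pixel_scale_um > 0:
        raise ParameterError("pixel_scale_um must be > 0")
    if not psf_sigma_um > 0:
        raise ParameterError("psf_sigma_um must be > 0")
    positions_um = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    if positions_um.size and (
        positions_um[:, 0].min() < 0
        or positions_um[:, 1].min() < 0
        or positions_um[:, 0].max() > field_width_um
        or positions_um[:, 1].max() > field_height_um
    ):
        raise ParameterError("positions must lie inside the field")

    n_cols = int(round(field_width_um / pixel_scale_um))
    n_rows = int(round(field_height_um / pixel_scale_um))
    img = np.full((n_rows, n_cols), float(background))

    sigma_px = psf_sigma_um / pixel_scale_um
    half = max(1, int(math.ceil(4.0 * sigma_px)))
    for x_um, y_um in positions_um:
        cx = x_um / pixel_scale_um
        cy = y_um / pixel_scale_um
        c0, c1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
        r0, r1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
        c0c, c1c = max(c0, 0), min(c1, n_cols)
        r0c, r1c = max(r0, 0), min(r1, n_rows)
        if c0c >= c1c or r0c >= r1c:
            continue
        cols = np.arange(c0c, c1c)
        rows = np.arange(r0c, r1c)
        gx = np.exp(-((cols - cx) ** 2) / (2.0 * sigma_px**2))
        gy = np.exp(-((rows - cy) ** 2) / (2.0 * sigma_px**2))
        img[r0c:r1c, c0c:c1c] -= amplitude * np.outer(gy, gx)

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
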