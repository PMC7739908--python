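"""Ground-truth-known synthetic inputs for every analysis stage.

No raw data from the original assay is public, so the test surface of this
package rests on generators that emulate the *statistical structure* of the
three input kinds the pipeline consumes:

* **cell snapshot series** mimicking cell-resolved blood-flow output:
  an RBC core with a prescribed near-wall depleted layer of width
  ``delta_star``, platelets enriched by a factor ``f`` in the first 5 um
  next to each wall (margination; ``f = 2`` for whole blood, ``f = 1`` for
  platelet-rich plasma) beyond a thin platelet-free sliver, optional extra
  platelet bands at 1/4 and 3/4 channel height, all advected by a supplied
  flow field with diffusive jitter;
* **mass-balance traces** rising at ``rho * Q`` and rolling off smoothly to
  a plateau at the programmed occlusion time, with evaporation drift,
  balance noise and a paired evaporation-only reference trace;
* **image stacks** of the top view with a Gaussian clot growing at a
  programmed position: brighter than background in WB, darker in PRP, with
  the stenotic-corner annotation emitted alongside at exact coordinates.

Margination is prescribed statistically, not simulated mechanistically:
these generators exist to exercise estimators against known ground truth,
not to model cell mechanics.  Cross-channel (y) positions are therefore
held stationary by default — jitter acts in the periodic x and z
directions — so the prescribed wall-layer structure is exactly the
stationary distribution of the series.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cell_field_analysis import CellSnapshotSeries, DEFAULT_CELL_VOLUMES, PLATELET_DIAMETER
from .errors import SpecError, ValidationError
from .flow_solver import FlowField
from .geometry import ChamberGeometry, build_van_rooij_geometry
from .occlusion_analysis import CornerAnnotation, ImageStack, MassTrace


# ---------------------------------------------------------------------------
# Cell snapshots


@dataclass(frozen=True)
class MarginationSpec:
    """Statistical recipe for marginated cell positions.

    ``cfl_width`` is the near-wall RBC-free layer (m); ``enhancement`` the
    platelet density factor in the first ``band_width`` beyond a
    ``platelet_free_sliver`` at each wall (2 for whole blood, 1 for PRP);
    ``core_haematocrit`` the RBC volume fraction of the core.  Counts
    default to the reference cell-resolved run (10703 RBCs, 952 platelets
    in the 572 x 130 x 50 um slab).
    """

    cfl_width: float = 5e-6
    enhancement: float = 2.0
    core_haematocrit: float = 0.33
    n_rbc: int = 10703
    n_plt: int = 952
    platelet_free_sliver: float = 0.5e-6
    band_width: float = 5e-6
    quarter_band_amplitude: float = 0.0
    quarter_band_sigma: float = 6.5e-6
    seed: int = 0

    def validate(self, channel_height: float) -> "MarginationSpec":
        if not 0 <= self.cfl_width < channel_height / 2:
            raise SpecError("cfl_width must lie in [0, H/2)")
        if self.enhancement < 1.0:
            raise SpecError("enhancement factor must be >= 1")
        if not 0.0 < self.core_haematocrit < 0.6:
            raise SpecError("core_haematocrit must lie in (0, 0.6)")
        if self.n_rbc < 0 or self.n_plt < 0:
            raise SpecError("cell counts must be non-negative")
        return self

    @classmethod
    def whole_blood(cls, **kw) -> "MarginationSpec":
        return cls(**kw)

    @classmethod
    def prp(cls, **kw) -> "MarginationSpec":
        kw.setdefault("enhancement", 1.0)
        kw.setdefault("n_rbc", 0)
        kw.setdefault("n_plt", 941)
        return cls(**kw)


def _platelet_weight(spec: MarginationSpec, H: float, y: np.ndarray) -> np.ndarray:
    s0 = spec.platelet_free_sliver
    w = np.ones_like(y)
    w[(y < s0) | (y > H - s0)] = 0.0
    band = ((y >= s0) & (y < s0 + spec.band_width)) | (
        (y > H - s0 - spec.band_width) & (y <= H - s0)
    )
    w[band] *= spec.enhancement
    if spec.quarter_band_amplitude > 0:
        for yc in (H / 4, 3 * H / 4):
            w += spec.quarter_band_amplitude * np.exp(
                -0.5 * ((y - yc) / spec.quarter_band_sigma) ** 2
            ) * (w > 0)
    return w


def _rbc_weight(spec: MarginationSpec, H: float, y: np.ndarray) -> np.ndarray:
    w = np.ones_like(y)
    w[(y < spec.cfl_width) | (y > H - spec.cfl_width)] = 0.0
    return w


def _sample_density(
    rng: np.random.Generator, weight: np.ndarray, grid: np.ndarray, n: int
) -> np.ndarray:
    total = np.trapezoid(weight, grid)
    if n > 0 and total <= 0:
        raise SpecError("requested cells but the position density is identically zero")
    if n == 0:
        return np.empty(0)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (weight[1:] + weight[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def synth_cell_snapshots(
    spec: MarginationSpec,
    flow: FlowField,
    duration: float = 0.30,
    dt_snap: float = 5e-3,
    diffusivity: float = 1e-12,
    y_diffusivity: float = 0.0,
) -> CellSnapshotSeries:
    """Generate a labelled snapshot series with prescribed margination structure.

    Positions are drawn from the spec's cross-channel densities (rejected
    against the solid mask so no cell starts inside the stenotic bump),
    then advected by the local flow velocity between snapshots with
    Gaussian jitter of the given diffusivities (x/z periodic; y clamped to
    the lumen).  ``y_diffusivity`` defaults to zero so the prescribed
    margination profile is stationary.

    Requires a converged flow field and ``duration >= 2 * dt_snap``.
    """
    if not flow.converged:
        raise ValidationError("flow field must be converged")
    if duration < 2 * dt_snap:
        raise ValidationError("duration must cover at least two snapshot intervals")
    mask = flow.mask
    dx = mask.dx
    H = mask.ny * dx
    L = mask.nx * dx
    W = flow.width
    spec.validate(H)
    rng = np.random.default_rng(spec.seed)

    grid = np.linspace(0.0, H, 8192)
    n_tot = spec.n_rbc + spec.n_plt
    kinds = np.array(["RBC"] * spec.n_rbc + ["PLT"] * spec.n_plt)

    # rejection-sample against the rasterized lumen so nothing starts in solid
    ys = np.empty(n_tot)
    xs = np.empty(n_tot)
    todo = np.arange(n_tot)
    weights = {
        "RBC": _rbc_weight(spec, H, grid),
        "PLT": _platelet_weight(spec, H, grid),
    }
    for _ in range(200):
        if len(todo) == 0:
            break
        for kind in ("RBC", "PLT"):
            sub = todo[kinds[todo] == kind]
            if len(sub) == 0:
                continue
            ys[sub] = _sample_density(rng, weights[kind], grid, len(sub))
            xs[sub] = rng.random(len(sub)) * L
        ii = np.clip((xs[todo] / dx).astype(int), 0, mask.nx - 1)
        jj = np.clip((ys[todo] / dx).astype(int), 0, mask.ny - 1)
        todo = todo[~mask.fluid[ii, jj]]
    if len(todo):
        raise SpecError(
            "could not place all cells in the fluid domain; counts infeasible "
            "for this geometry"
        )
    zs = rng.random(n_tot) * W

    uc = flow.u_center()
    vc = flow.v_center()
    times = np.arange(0.0, duration + 0.5 * dt_snap, dt_snap)
    sig_xz = math.sqrt(2.0 * diffusivity * dt_snap)
    sig_y = math.sqrt(2.0 * y_diffusivity * dt_snap)

    def sample_center(field: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        fx = x / dx - 0.5
        fy = np.clip(y / dx - 0.5, 0.0, field.shape[1] - 1.0)
        i0 = np.floor(fx).astype(int)
        j0 = np.floor(fy).astype(int)
        j0 = np.minimum(j0, field.shape[1] - 2)
        ax, ay = fx - i0, fy - j0
        i0 %= field.shape[0]
        i1 = (i0 + 1) % field.shape[0]
        return (
            field[i0, j0] * (1 - ax) * (1 - ay)
            + field[i1, j0] * ax * (1 - ay)
            + field[i0, j0 + 1] * (1 - ax) * ay
            + field[i1, j0 + 1] * ax * ay
        )

    y_lo_col = np.zeros(mask.nx)
    y_hi_col = np.full(mask.nx, H)
    for i in range(mask.nx):
        col = np.nonzero(mask.fluid[i])[0]
        if len(col):
            y_lo_col[i] = col[0] * dx
            y_hi_col[i] = (col[-1] + 1) * dx

    rows = []
    ids = np.arange(n_tot)
    x, y, z = xs.copy(), ys.copy(), zs.copy()
    eps = 1e-9
    for t in times:
        rows.append(
            pd.DataFrame({"t": t, "id": ids, "type": kinds, "x": x, "y": y, "z": z})
        )
        u = sample_center(uc, x, y)
        v = sample_center(vc, x, y)
        x = (x + u * dt_snap + rng.normal(0.0, sig_xz, n_tot)) % L
        y = y + v * dt_snap
        if sig_y > 0:
            y = y + rng.normal(0.0, sig_y, n_tot)
        z = (z + rng.normal(0.0, sig_xz, n_tot)) % W
        ic = np.clip((x / dx).astype(int), 0, mask.nx - 1)
        y = np.clip(y, y_lo_col[ic] + eps, y_hi_col[ic] - eps)

    vol = dict(DEFAULT_CELL_VOLUMES)
    return CellSnapshotSeries(
        frame=pd.concat(rows, ignore_index=True),
        domain=(L, H, W),
        cell_volumes=vol,
        platelet_diameter=PLATELET_DIAMETER,
    )


# ---------------------------------------------------------------------------
# Experiments (mass traces and image stacks)


@dataclass(frozen=True)
class ExperimentSpec:
    """Programmed ground truth for one synthetic occlusion experiment.

    ``clot_center`` is measured downstream from the upstream corner of the
    stenotic throat, matching how occlusion distances are reported.
    Mass in kg, times in s, flow in m^3/s.
    """

    geometry: ChamberGeometry = field(default_factory=build_van_rooij_geometry)
    flow_rate: float = 2.4e-9
    occlusion_time: float = 60.0
    ramp_duration: float = 0.5
    clot_center: float = 85e-6
    clot_sigma_x: float = 20e-6
    clot_sigma_z: float = 100e-6
    clot_amplitude: float = 0.4
    modality: str = "WB"
    image_noise: float = 0.005  # per-pixel sigma, fraction of dynamic range
    balance_noise: float = 2e-7  # electronic noise, ~0.2 of the 1 mg balance resolution
    evaporation_rate: float = -2e-8
    frame_rate: float = 2.0
    balance_rate: float = 1.0
    pixel_size: float = 2e-6
    record_duration: float | None = None
    density: float = 1025.0
    seed: int = 0

    @property
    def duration(self) -> float:
        return (
            self.record_duration
            if self.record_duration is not None
            else self.occlusion_time + 10.0
        )

    def validate(self) -> "ExperimentSpec":
        if self.occlusion_time <= 0 or self.occlusion_time > self.duration:
            raise SpecError("occlusion_time must fall within the recording")
        if self.modality not in ("WB", "PRP"):
            raise SpecError("modality must be 'WB' or 'PRP'")
        for name in ("flow_rate", "frame_rate", "balance_rate", "pixel_size"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        x_abs = self.geometry.x_throat_start + self.clot_center
        if not 0.0 <= x_abs <= self.geometry.domain_length:
            raise SpecError("clot_center falls outside the imaged span")
        return self


def _cumulative_volume(spec: ExperimentSpec, t: np.ndarray) -> np.ndarray:
    """Outflow volume under a flow that ramps linearly to zero at occlusion."""
    q, t_occ, tau = spec.flow_rate, spec.occlusion_time, spec.ramp_duration
    tau = min(tau, t_occ)
    v_tot = q * (t_occ - tau / 2.0)
    s = np.clip(t_occ - t, 0.0, None)
    ramp_deficit = q * s**2 / (2.0 * tau) if tau > 0 else 0.0
    v = np.where(t <= t_occ - tau, q * t, v_tot - ramp_deficit)
    return np.where(t >= t_occ, v_tot, v)


def synth_mass_trace(spec: ExperimentSpec) -> MassTrace:
    """Mass-balance trace with programmed flow, occlusion, evaporation and noise.

    Returns a MassTrace whose ``reference`` carries the paired
    evaporation-only record (same drift and independent noise).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 0.5 / spec.balance_rate, 1.0 / spec.balance_rate)
    mass = (
        spec.density * _cumulative_volume(spec, t)
        + spec.evaporation_rate * t
        + rng.normal(0.0, spec.balance_noise, len(t))
    )
    ref = (
        0.05  # arbitrary initial dish mass (kg); only differences matter
        + spec.evaporation_rate * t
        + rng.normal(0.0, spec.balance_noise, len(t))
    )
    return MassTrace(times=t, mass=mass, reference=ref, density=spec.density)


def synth_image_stack(
    spec: ExperimentSpec, margin_px: int = 10
) -> tuple[ImageStack, CornerAnnotation]:
    """Top-view time-lapse with a Gaussian clot growing to occlusion.

    The frame covers the full chamber length (x, columns) and width plus a
    PDMS margin (z, rows).  The clot amplitude rises linearly to its final
    value at the occlusion time; whole blood adds intensity, PRP subtracts.
    Stenosis borders are drawn as dark ticks in the margin rows, outside
    the annotated channel span.  Returns the stack and the corner
    annotation at exact pixel coordinates.
    """
    spec.validate()
    g = spec.geometry
    rng = np.random.default_rng(spec.seed + 1)
    px = spec.pixel_size
    n_x = int(round(g.domain_length / px))
    n_zchan = int(round(g.channel_width / px))
    n_z = n_zchan + 2 * margin_px
    z0, z1 = margin_px, margin_px + n_zchan - 1
    times = np.arange(0.0, spec.duration + 0.5 / spec.frame_rate, 1.0 / spec.frame_rate)

    xcols = (np.arange(n_x) + 0.5) * px
    zrows = np.arange(n_z)
    x_clot = g.x_throat_start + spec.clot_center
    z_clot_rows = 0.5 * (z0 + z1)
    gauss_x = np.exp(-0.5 * ((xcols - x_clot) / spec.clot_sigma_x) ** 2)
    gauss_z = np.exp(
        -0.5 * (((zrows - z_clot_rows) * px) / spec.clot_sigma_z) ** 2
    )
    clot_shape = gauss_z[:, None] * gauss_x[None, :]
    sign = 1.0 if spec.modality == "WB" else -1.0

    base = np.full((n_z, n_x), 0.3, dtype=np.float64)
    base[z0 : z1 + 1, :] = 0.5
    # stenosis border ticks in the PDMS margin (outside the channel span)
    for xb in (g.x_throat_start, g.x_throat_end):
        col = int(round(xb / px))
        if 0 <= col < n_x:
            base[max(z0 - 4, 0) : z0, col] = 0.1
            base[z1 + 1 : min(z1 + 5, n_z), col] = 0.1

    chan = slice(z0, z1 + 1)
    frames = np.empty((len(times), n_z, n_x), dtype=np.float32)
    for k, t in enumerate(times):
        amp = spec.clot_amplitude * min(t / spec.occlusion_time, 1.0)
        frame = base.copy()
        frame[chan, :] += sign * amp * clot_shape[chan, :]
        if spec.image_noise > 0:
            frame += rng.normal(0.0, spec.image_noise, frame.shape)
        frames[k] = frame

    # pixel coordinate p denotes the centre of pixel p, so a physical
    # position X maps to coordinate X/px - 0.5
    corners = CornerAnnotation(
        corners=np.array(
            [
                [g.x_throat_start / px - 0.5, z0],
                [g.x_throat_start / px - 0.5, z1],
                [g.x_throat_end / px - 0.5, z0],
                [g.x_throat_end / px - 0.5, z1],
            ]
        )
    )
    stack = ImageStack(
        frames=frames, times=times, pixel_size=px, modality=spec.modality
    )
    return stack, corners
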