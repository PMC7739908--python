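"""Steady incompressible Newtonian flow in the rasterized chamber.

The flow in the microfluidic chamber is slot-like (width >> height) and slow
(channel Reynolds number ~ 4, throat Reynolds number of the same order), so
the solver computes the steady two-dimensional (x, y) Stokes flow on the
side-view mask, driven by a uniform flow-wise body force with periodic
boundaries in x — the same driving used by the cell-resolved simulations the
chamber was designed for.  The channel width W enters as a scale factor when
converting between the 2-D flux ``int u_x dy`` and the volumetric flow rate
``Q = W * int u_x dy``.

Discretization: marker-and-cell (MAC) staggered finite differences.
``u`` lives on vertical cell faces, ``v`` on horizontal faces, pressure at
cell centres.  No-slip walls coincide with cell boundaries; the tangential
ghost value across a wall is the reflection ``u_ghost = -u``, which keeps
the scheme second order up to the wall.  The discrete saddle-point system
(momentum + continuity, one pressure pinned) is solved directly with
SuperLU, so the discrete divergence and the momentum residual are at
machine precision and the per-station flux is conserved exactly.

Because Stokes flow is linear in the forcing, the body force that matches a
target flow rate is found by a single proportional rescaling of the
unit-force solution (the iterative rescaling degenerates to one step).

Shear is evaluated where the MAC layout makes it natural: the xy-component
``gamma_xy = du_x/dy + du_y/dx`` is formed at grid nodes (cell corners) by
centred differences, which at wall nodes reduces to the one-sided
second-order wall-shear formula.  The other components of the rate-of-strain
tensor are negligible in this slot-like geometry and are not formed.
"""
from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError, StateError, ValidationError
from .geometry import ChamberGeometry, SolidMask, wall_offset_samples

# ---------------------------------------------------------------------------
# Fluids


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian fluid constants: density rho (kg/m^3), kinematic viscosity nu (m^2/s)."""

    density: float
    kinematic_viscosity: float

    def __post_init__(self):
        if self.density <= 0:
            raise ValidationError("density must be positive")
        if self.kinematic_viscosity <= 0:
            raise ValidationError("kinematic_viscosity must be positive")

    @property
    def dynamic_viscosity(self) -> float:
        """mu = rho * nu (Pa s)."""
        return self.density * self.kinematic_viscosity


#: Platelet-rich plasma treated as plasma: rho = 1025 kg/m^3, nu = 1.1e-6 m^2/s.
PRP = FluidSpec(density=1025.0, kinematic_viscosity=1.1e-6)
#: Whole blood as an effective Newtonian continuum: rho = 1060 kg/m^3, nu = 3.3e-6 m^2/s.
WB_CONTINUUM = FluidSpec(density=1060.0, kinematic_viscosity=3.3e-6)

FLUIDS = {"prp": PRP, "wb-continuum": WB_CONTINUUM}


# ---------------------------------------------------------------------------
# Flow field container


@dataclass
class FlowField:
    """Steady MAC velocity field on the side-view grid.

    ``u[i, j]`` is the x-velocity on the vertical face at
    (i dx, (j + 1/2) dx) — periodic in i; ``v[i, j]`` the y-velocity on the
    horizontal face at ((i + 1/2) dx, j dx), j = 0..ny.  ``body_force`` is
    the uniform flow-wise force density (N/m^3) that drives the flow.
    """

    mask: SolidMask
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    body_force: float
    width: float
    residual: float
    converged: bool = True

    @property
    def dx(self) -> float:
        return self.mask.dx

    def station_flux(self) -> np.ndarray:
        """Volumetric flow rate through each x-station (m^3/s)."""
        return self.u.sum(axis=1) * self.dx * self.width

    @property
    def flow_rate(self) -> float:
        return float(self.station_flux().mean())

    def u_center(self) -> np.ndarray:
        """x-velocity interpolated to cell centres (walls enter as zero faces)."""
        return 0.5 * (self.u + np.roll(self.u, -1, axis=0))

    def v_center(self) -> np.ndarray:
        return 0.5 * (self.v[:, :-1] + self.v[:, 1:])

    def to_hdf5(self, path: str, group: str = "/") -> None:
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in ("u", "v", "p"):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=getattr(self, name))
            g.attrs["dx"] = self.dx
            g.attrs["body_force"] = self.body_force
            g.attrs["width"] = self.width
            g.attrs["residual"] = self.residual
        self.mask.to_hdf5(path, group)


def _face_activity(fluid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Active (unknown) u and v faces: faces between two fluid cells.

    Faces touching a solid cell or the y-domain boundary carry zero
    velocity (no-slip / no-penetration) and are eliminated.
    """
    nx, ny = fluid.shape
    u_act = fluid & np.roll(fluid, 1, axis=0)
    v_act = np.zeros((nx, ny + 1), dtype=bool)
    v_act[:, 1:ny] = fluid[:, 1:] & fluid[:, :-1]
    return u_act, v_act


def solve_flow(
    mask: SolidMask,
    fluid: FluidSpec,
    Q_target: float,
    width: float | None = None,
    tol: float = 1e-8,
) -> FlowField:
    """Solve body-force-driven steady Stokes flow matched to a target flow rate.

    Parameters
    ----------
    mask
        Rasterized side-view lumen (x-periodic).
    fluid
        Newtonian fluid constants.
    Q_target
        Volumetric flow rate to match (m^3/s), referred to the full
        channel width ``width``.
    width
        Channel width W (m) used to scale between the 2-D flux and Q.
        Default 480 um (the experimental chamber width).
    tol
        Acceptable relative momentum/continuity residual of the discrete
        solution (direct solve: machine precision in practice).
    """
    if width is None:
        width = 480e-6
    if Q_target < 0:
        raise ValidationError("Q_target must be non-negative")
    flu = mask.fluid
    nx, ny = flu.shape
    if not flu.any():
        raise ValidationError("mask contains no fluid cells")
    dx = mask.dx
    mu = fluid.dynamic_viscosity

    if Q_target == 0.0:
        return FlowField(
            mask=mask,
            u=np.zeros((nx, ny)),
            v=np.zeros((nx, ny + 1)),
            p=np.zeros((nx, ny)),
            body_force=0.0,
            width=width,
            residual=0.0,
        )

    u_act, v_act = _face_activity(flu)
    n_u = int(u_act.sum())
    n_v = int(v_act.sum())
    n_p = int(flu.sum())
    iu = np.full((nx, ny), -1, dtype=np.int64)
    iu[u_act] = np.arange(n_u)
    iv = np.full((nx, ny + 1), -1, dtype=np.int64)
    iv[v_act] = n_u + np.arange(n_v)
    ip = np.full((nx, ny), -1, dtype=np.int64)
    ip[flu] = n_u + n_v + np.arange(n_p)
    n_tot = n_u + n_v + n_p

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    b = np.zeros(n_tot)
    f_unit = 1.0  # unit body force density (N/m^3); rescaled afterwards
    # nondimensionalized assembly: momentum rows scaled by dx^2/mu and the
    # pressure unknown by dx/mu, so the matrix is independent of the fluid
    # (better conditioned, and equal-Q solves of different fluids coincide)
    c_visc = 1.0
    c_grad = 1.0
    b_scale = dx**2 / mu

    # --- u-momentum: mu lap(u) - dp/dx + f = 0 on active u faces ----------
    ui, uj = np.nonzero(u_act)
    r_u = iu[ui, uj]
    center = np.full(n_u, -4.0)
    for di in (-1, 1):
        nb = iu[(ui + di) % nx, uj]
        ok = nb >= 0
        add(r_u[ok], nb[ok], np.full(ok.sum(), c_visc))
        # inactive x-neighbour: wall plane passes through that face, u = 0
    for dj in (-1, 1):
        jn = uj + dj
        inside = (jn >= 0) & (jn < ny)
        nb = np.where(inside, iu[ui, np.clip(jn, 0, ny - 1)], -1)
        ok = nb >= 0
        add(r_u[ok], nb[ok], np.full(ok.sum(), c_visc))
        # wall across the node: ghost reflection u_ghost = -u
        center[~ok] -= 1.0
    add(r_u, r_u, center * c_visc)
    add(r_u, ip[ui, uj], np.full(n_u, -c_grad))
    add(r_u, ip[(ui - 1) % nx, uj], np.full(n_u, c_grad))
    b[r_u] = -f_unit * b_scale

    # --- v-momentum: mu lap(v) - dp/dy = 0 on active v faces --------------
    vi, vj = np.nonzero(v_act)
    r_v = iv[vi, vj]
    center = np.full(n_v, -4.0)
    for dj in (-1, 1):
        jn = vj + dj
        inside = (jn >= 0) & (jn <= ny)
        nb = np.where(inside, iv[vi, np.clip(jn, 0, ny)], -1)
        ok = nb >= 0
        add(r_v[ok], nb[ok], np.full(ok.sum(), c_visc))
        # inactive y-neighbour: wall at that face, v = 0 there
    for di in (-1, 1):
        nb = iv[(vi + di) % nx, vj]
        ok = nb >= 0
        add(r_v[ok], nb[ok], np.full(ok.sum(), c_visc))
        center[~ok] -= 1.0  # vertical wall through the node: reflection
    add(r_v, r_v, center * c_visc)
    add(r_v, ip[vi, vj], np.full(n_v, -c_grad))
    add(r_v, ip[vi, vj - 1], np.full(n_v, c_grad))

    # --- continuity on fluid cells ----------------------------------------
    ci, cj = np.nonzero(flu)
    r_c = ip[ci, cj]
    pin = r_c[0]  # one pressure pinned: continuity rows sum to zero
    for sign, idx in (
        (1.0, iu[(ci + 1) % nx, cj]),
        (-1.0, iu[ci, cj]),
        (1.0, iv[ci, cj + 1]),
        (-1.0, iv[ci, cj]),
    ):
        ok = (idx >= 0) & (r_c != pin)
        add(r_c[ok], idx[ok], np.full(ok.sum(), sign))
    add(np.array([pin]), np.array([pin]), np.array([1.0]))

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_tot, n_tot),
    ).tocsc()
    try:
        x = spla.spsolve(A, b)
    except Exception as exc:  # pragma: no cover - SuperLU failure path
        raise SolverError(f"direct Stokes solve failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("direct Stokes solve returned non-finite values")

    res = A @ x - b
    scale_ref = max(float(np.abs(b).max()), 1e-300)
    residual = float(np.abs(res).max()) / scale_ref

    u = np.zeros((nx, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    u[u_act] = x[:n_u]
    v[v_act] = x[n_u : n_u + n_v]
    p[flu] = x[n_u + n_v :] * mu / dx  # undo the pressure scaling

    q_unit = float((u.sum(axis=1) * dx * width).mean())
    if q_unit == 0.0:
        raise SolverError("unit-force solve produced zero flux", residuals=[residual])
    scale = Q_target / q_unit
    ff = FlowField(
        mask=mask,
        u=u * scale,
        v=v * scale,
        p=p * scale,
        body_force=f_unit * scale,
        width=width,
        residual=residual,
        converged=residual < max(tol, 1e-6),
    )
    q = ff.station_flux()
    if abs(ff.flow_rate - Q_target) > 5e-3 * Q_target or (
        q.max() - q.min()
    ) > 1e-3 * abs(Q_target):
        raise SolverError(
            "flow-rate matching failed: achieved "
            f"{ff.flow_rate:.6g} vs target {Q_target:.6g}",
            residuals=[residual],
        )
    return ff


# ---------------------------------------------------------------------------
# Shear fields


def shear_fields(flow: FlowField, fluid: FluidSpec) -> tuple[np.ndarray, np.ndarray]:
    """xy shear-rate and shear-stress fields at grid nodes.

    Returns ``(gamma_xy, tau_xy)`` of shape (nx, ny + 1): node (i, j) sits
    at (i dx, j dx), periodic in i.  ``gamma_xy = du_x/dy + du_y/dx`` by
    centred differences; across a wall the ghost reflection gives the
    one-sided second-order wall value.  ``tau_xy = mu * gamma_xy``.
    """
    if not flow.converged:
        raise StateError("shear fields requested on an unconverged flow field")
    flu = flow.mask.fluid
    nx, ny = flu.shape
    dx = flow.dx
    u_act, v_act = _face_activity(flu)

    # du/dy at node (i, j): faces u[i, j] (above) and u[i, j-1] (below)
    above_ok = np.zeros((nx, ny + 1), dtype=bool)
    above_ok[:, :ny] = u_act
    below_ok = np.zeros((nx, ny + 1), dtype=bool)
    below_ok[:, 1:] = u_act
    ua = np.zeros((nx, ny + 1))
    ua[:, :ny] = flow.u
    ub = np.zeros((nx, ny + 1))
    ub[:, 1:] = flow.u
    du = np.where(
        above_ok & below_ok,
        (ua - ub) / dx,
        np.where(above_ok, 2.0 * ua / dx, np.where(below_ok, -2.0 * ub / dx, 0.0)),
    )

    # dv/dx at node (i, j): faces v[i-1, j] (left) and v[i, j] (right)
    right_ok = v_act
    left_ok = np.roll(v_act, 1, axis=0)
    vr = flow.v
    vl = np.roll(flow.v, 1, axis=0)
    dv = np.where(
        right_ok & left_ok,
        (vr - vl) / dx,
        np.where(right_ok, 2.0 * vr / dx, np.where(left_ok, -2.0 * vl / dx, 0.0)),
    )

    gamma = du + dv
    tau = fluid.dynamic_viscosity * gamma
    return gamma, tau


def sample_node_field(field: np.ndarray, dx: float, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a node-based (nx, ny+1) field, periodic in x."""
    nx = field.shape[0]
    x = points[:, 0] / dx
    y = np.clip(points[:, 1] / dx, 0.0, field.shape[1] - 1.0)
    i0 = np.floor(x).astype(int)
    j0 = np.floor(y).astype(int)
    j0 = np.minimum(j0, field.shape[1] - 2)
    fx = x - i0
    fy = y - j0
    i0 %= nx
    i1 = (i0 + 1) % nx
    return (
        field[i0, j0] * (1 - fx) * (1 - fy)
        + field[i1, j0] * fx * (1 - fy)
        + field[i0, j0 + 1] * (1 - fx) * fy
        + field[i1, j0 + 1] * fx * fy
    )


@dataclass
class WallProfile:
    """Near-wall shear profile sampled a fixed offset from one wall.

    ``corner_flag`` marks samples adjacent to the ramp corners, where the
    xy-component carries sharp gradients that may be artefacts of taking a
    single tensor component near a non-planar wall; they are reported, not
    suppressed.
    """

    x: np.ndarray
    y: np.ndarray
    gamma_dot: np.ndarray
    tau: np.ndarray
    wall: str
    offset: float
    corner_flag: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "gamma_dot": self.gamma_dot,
                "tau": self.tau,
                "flag": self.corner_flag.astype(int),
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def sample_at(self, x: float) -> tuple[float, float]:
        """(gamma_dot, tau) at flow-wise position x by linear interpolation."""
        return (
            float(np.interp(x, self.x, self.gamma_dot)),
            float(np.interp(x, self.x, self.tau)),
        )


def wall_profile(
    flow: FlowField,
    fluid: FluidSpec,
    geometry: ChamberGeometry,
    wall: str,
    offset: float = 1e-6,
    spacing: float | None = None,
) -> WallProfile:
    """Shear rate/stress along a wall-offset curve (default 1 um from the wall)."""
    samples = wall_offset_samples(geometry, wall, offset, spacing or flow.dx)
    gamma, tau = shear_fields(flow, fluid)
    gd = sample_node_field(gamma, flow.dx, samples)
    tv = sample_node_field(tau, flow.dx, samples)
    corners = np.array(
        [
            geometry.x_contraction_start,
            geometry.x_throat_start,
            geometry.x_throat_end,
            geometry.x_expansion_end,
        ]
    )
    stenotic = wall == geometry.stenotic_wall
    if stenotic and geometry.bump_height > 0:
        flag = (
            np.abs(samples[:, 0:1] - corners[None, :]) < 2.0 * flow.dx
        ).any(axis=1)
    else:
        flag = np.zeros(len(samples), dtype=bool)
    return WallProfile(
        x=samples[:, 0],
        y=samples[:, 1],
        gamma_dot=gd,
        tau=tv,
        wall=wall,
        offset=offset,
        corner_flag=flag,
    )


def reynolds_number(
    Q: float,
    geometry: ChamberGeometry,
    fluid: FluidSpec,
    characteristic: str = "channel_height",
) -> float:
    """Channel Reynolds number Re = U H / nu with U = Q / (W H).

    The mean-velocity/height choice makes H cancel: Re = Q / (W nu), with W
    the full chamber width.  ``characteristic`` = "throat_height" evaluates
    the same expression in the throat (identical by cancellation; kept for
    API symmetry).
    """
    if Q <= 0:
        raise ValidationError("Q must be positive")
    if characteristic not in ("channel_height", "throat_height"):
        raise ValidationError("characteristic must be channel_height or throat_height")
    return Q / (geometry.channel_width * fluid.kinematic_viscosity)
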