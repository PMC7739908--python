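"""Parametric stenotic flow-chamber geometry.

The chamber is a shallow rectangular microchannel: height ``H`` across the
channel (y), width ``W`` across the imaging direction (z, with W >> H) and
length ``L`` along the flow (x).  One wall — by convention the moulded PDMS
wall at y = H; the bonded glass coverslip at y = 0 stays flat — carries a
single trapezoidal bump that locally reduces the lumen height by the
stenosis severity ``s``: the throat height is ``hs = (1 - s) * H``.  The
bump is described by a contraction ramp, a flat throat of length ``Ls`` and
an expansion ramp; the ramp angle ``theta`` is measured between the ramp
face and the wall plane, so an 80 degree ramp is nearly vertical with a
horizontal run of ``(H - hs) / tan(theta)``.

Everything here is side-view (x, y) geometry in SI units.  The width enters
only as a scale factor downstream (the chamber is slot-like, w >> h, and
the z direction is treated as homogeneous).

The module provides

* :func:`build_van_rooij_geometry` — the default chamber presets
  (design, as-built and periodic-slab simulation widths),
* :func:`rasterize` — a centre-sampled boolean fluid/solid mask on a
  square grid, the input the flow solver consumes,
* :func:`wall_offset_samples` — sample curves displaced a fixed distance
  from either wall along the inward normal, used for near-wall shear
  profiles.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import h5py
import numpy as np
import yaml

from .errors import OffsetError, ResolutionError, ValidationError

#: Flow-wise extent of the reference simulation domain (m): 200 um of
#: straight channel on either side of the stenotic feature.
DESIGN_TOTAL_LENGTH = 572e-6


@dataclass(frozen=True)
class ChamberGeometry:
    """Parametric side-view description of a stenotic flow chamber.

    All lengths in metres, the ramp angle in degrees from the wall plane.
    ``stenotic_wall`` names the wall carrying the bump ("pdms", the y = H
    side, or "glass", y = 0).
    """

    channel_height: float = 130e-6
    channel_width: float = 480e-6
    stenosis_severity: float = 0.5
    ramp_angle: float = 80.0
    throat_length: float = 150e-6
    upstream_length: float = 200e-6
    downstream_length: float = 200e-6
    stenotic_wall: str = "pdms"

    # -- derived quantities -------------------------------------------------

    @property
    def throat_height(self) -> float:
        """Lumen height hs = (1 - s) * H in the throat (m)."""
        return (1.0 - self.stenosis_severity) * self.channel_height

    @property
    def bump_height(self) -> float:
        return self.channel_height - self.throat_height

    @property
    def ramp_run(self) -> float:
        """Horizontal extent of one ramp, (H - hs) / tan(theta)."""
        if self.ramp_angle >= 90.0:
            return 0.0
        return self.bump_height / math.tan(math.radians(self.ramp_angle))

    @property
    def domain_length(self) -> float:
        return (
            self.upstream_length
            + 2.0 * self.ramp_run
            + self.throat_length
            + self.downstream_length
        )

    @property
    def x_contraction_start(self) -> float:
        return self.upstream_length

    @property
    def x_throat_start(self) -> float:
        """Upstream end of the flat throat (the upstream stenotic corner)."""
        return self.upstream_length + self.ramp_run

    @property
    def x_throat_end(self) -> float:
        return self.x_throat_start + self.throat_length

    @property
    def x_expansion_end(self) -> float:
        return self.x_throat_end + self.ramp_run

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ChamberGeometry":
        """Check all geometric invariants; raise ValidationError naming the field."""
        for name in (
            "channel_height",
            "channel_width",
            "throat_length",
            "upstream_length",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.downstream_length < 0:
            raise ValidationError("downstream_length must be non-negative")
        if not 0.0 < self.stenosis_severity < 1.0:
            raise ValidationError(
                "stenosis_severity must lie strictly in (0, 1), got "
                f"{self.stenosis_severity}"
            )
        if not 0.0 < self.ramp_angle <= 90.0:
            raise ValidationError("ramp_angle must lie in (0, 90] degrees")
        if self.throat_height <= 0:
            raise ValidationError("throat_height (1 - s) * H must be positive")
        if self.stenotic_wall not in ("pdms", "glass"):
            raise ValidationError("stenotic_wall must be 'pdms' or 'glass'")
        return self

    # -- lumen envelope -----------------------------------------------------

    def bump_profile(self, x: np.ndarray) -> np.ndarray:
        """Bump height above the stenotic wall plane at flow-wise position x."""
        x = np.asarray(x, dtype=float)
        x0, x1 = self.x_contraction_start, self.x_throat_start
        x2, x3 = self.x_throat_end, self.x_expansion_end
        h = np.zeros_like(x)
        if self.bump_height == 0.0:
            return h
        run = self.ramp_run
        if run > 0:
            up = (x > x0) & (x < x1)
            h[up] = (x[up] - x0) / run * self.bump_height
            down = (x > x2) & (x < x3)
            h[down] = (x3 - x[down]) / run * self.bump_height
        flat = (x >= x1) & (x <= x2)
        h[flat] = self.bump_height
        return h

    def lumen(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper lumen bounds (y_lo(x), y_hi(x))."""
        bump = self.bump_profile(x)
        H = self.channel_height
        if self.stenotic_wall == "pdms":
            return np.zeros_like(bump), H - bump
        return bump, np.full_like(bump, H)

    def analytic_fluid_area(self) -> float:
        """Side-view fluid area of the lumen polygon (m^2).

        Rectangle minus the trapezoidal bump: the bump area is
        (Ls + run) * (H - hs) since each triangular ramp contributes
        run * (H - hs) / 2.
        """
        return self.channel_height * self.domain_length - self.bump_height * (
            self.throat_length + self.ramp_run
        )

    # -- straight-channel factory (oracle geometry) ------------------------

    @classmethod
    def straight(
        cls,
        channel_height: float = 130e-6,
        channel_width: float = 480e-6,
        length: float = DESIGN_TOTAL_LENGTH,
    ) -> "ChamberGeometry":
        """Bump-free rectangular channel.

        Degenerate (s = 0) on purpose: it is the closed-form plane-Poiseuille
        reference every solver test leans on, so it bypasses the stenosis
        validation that :func:`build_van_rooij_geometry` enforces.
        """
        return cls(
            channel_height=channel_height,
            channel_width=channel_width,
            stenosis_severity=0.0,
            ramp_angle=90.0,
            throat_length=0.0,
            upstream_length=length,
            downstream_length=0.0,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str) -> None:
        """Write the parameter set as YAML (or JSON if the path ends .json)."""
        d = self.to_dict()
        if str(path).endswith(".json"):
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        else:
            with open(path, "w") as fh:
                yaml.safe_dump(d, fh)

    @classmethod
    def load(cls, path: str) -> "ChamberGeometry":
        with open(path) as fh:
            if str(path).endswith(".json"):
                d = json.load(fh)
            else:
                d = yaml.safe_load(fh)
        return cls(**d)


#: Recognized presets for :func:`build_van_rooij_geometry`.
_PRESETS = {
    # Nominal design values of the moulded chamber.
    "design": dict(channel_height=130e-6, stenosis_severity=0.5, channel_width=480e-6),
    # Confocal height measurements of the machined mould: channel 131 um,
    # throat 65.7 um, i.e. s = 1 - 65.7/131 (~49.85%, rounds to 50%).
    "as-built": dict(
        channel_height=131e-6,
        stenosis_severity=1.0 - 65.7 / 131.0,
        channel_width=480e-6,
    ),
    # Periodic-slab computational domain: same side view, 50 um of width
    # with z-periodicity standing in for the full 480 um.
    "simulation": dict(channel_height=130e-6, stenosis_severity=0.5, channel_width=50e-6),
}


def build_van_rooij_geometry(
    overrides: dict | None = None, preset: str = "design"
) -> ChamberGeometry:
    """Construct the stenotic reference chamber.

    Defaults: H = 130 um, 50% stenosis, 80 degree ramps, 150 um flat throat,
    200 um of straight channel upstream, W = 480 um (experimental width).
    Unless ``downstream_length`` is overridden, the downstream straight
    section absorbs the ramp-run residual so the total domain length is
    exactly ``DESIGN_TOTAL_LENGTH`` (572 um).

    Parameters
    ----------
    overrides
        Mapping of ChamberGeometry field names to replacement values.
        Unrecognized keys raise :class:`ValidationError`.
    preset
        "design" (default), "as-built" (measured mould heights) or
        "simulation" (50 um periodic-slab width).
    """
    if preset not in _PRESETS:
        raise ValidationError(
            f"unknown preset {preset!r}; expected one of {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[preset])
    overrides = dict(overrides or {})
    recognized = set(ChamberGeometry.__dataclass_fields__)
    unknown = set(overrides) - recognized
    if unknown:
        raise ValidationError(f"unrecognized geometry keys: {sorted(unknown)}")
    params.update(overrides)
    geom = ChamberGeometry(**params)
    if "downstream_length" not in overrides:
        downstream = DESIGN_TOTAL_LENGTH - (
            geom.upstream_length + 2.0 * geom.ramp_run + geom.throat_length
        )
        if downstream <= 0:
            raise ValidationError(
                "downstream_length: stenotic feature does not fit in the "
                f"{DESIGN_TOTAL_LENGTH * 1e6:.0f} um domain; pass "
                "downstream_length explicitly"
            )
        geom = replace(geom, downstream_length=downstream)
    return geom.validate()


# ---------------------------------------------------------------------------
# Rasterization


@dataclass
class SolidMask:
    """Centre-sampled boolean occupancy of the side-view lumen.

    ``fluid[i, j]`` is True when the centre of cell (i, j) — at
    ``origin + ((i + 0.5) dx, (j + 0.5) dx)`` — lies strictly inside the
    fluid polygon.  x is flow-wise (axis 0), y cross-channel (axis 1).
    """

    fluid: np.ndarray
    dx: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def nx(self) -> int:
        return self.fluid.shape[0]

    @property
    def ny(self) -> int:
        return self.fluid.shape[1]

    @property
    def fluid_area(self) -> float:
        return float(self.fluid.sum()) * self.dx**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.arange(self.nx) + 0.5) * self.dx
        y = self.origin[1] + (np.arange(self.ny) + 0.5) * self.dx
        return x, y

    def to_hdf5(self, path: str, group: str = "/") -> None:
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            if "fluid" in g:
                del g["fluid"]
            ds = g.create_dataset("fluid", data=self.fluid.astype(np.uint8))
            ds.attrs["dx"] = self.dx
            ds.attrs["origin"] = self.origin

    @classmethod
    def from_hdf5(cls, path: str, group: str = "/") -> "SolidMask":
        with h5py.File(path, "r") as fh:
            ds = fh[group]["fluid"]
            return cls(
                fluid=ds[...].astype(bool),
                dx=float(ds.attrs["dx"]),
                origin=tuple(ds.attrs["origin"]),
            )


def rasterize(geometry: ChamberGeometry, dx: float) -> SolidMask:
    """Rasterize the side-view lumen on a square grid of spacing ``dx``.

    Requires at least 8 cells across the throat (``dx <= hs / 8``); a cell
    is fluid iff its centre lies inside the lumen polygon (half-open,
    centre-sampled).
    """
    if dx <= 0:
        raise ValidationError("dx must be positive")
    hs = geometry.throat_height
    if dx > hs / 8.0:
        raise ResolutionError(
            f"dx = {dx:.3g} m too coarse: need dx <= hs/8 = {hs / 8:.3g} m "
            "(>= 8 cells across the throat)"
        )
    L, H = geometry.domain_length, geometry.channel_height
    nx = int(round(L / dx))
    ny = int(round(H / dx))
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx
    y_lo, y_hi = geometry.lumen(xc)
    fluid = (yc[None, :] > y_lo[:, None]) & (yc[None, :] < y_hi[:, None])
    return SolidMask(fluid=fluid, dx=dx)


# ---------------------------------------------------------------------------
# Wall-offset sampling


def _wall_polyline(geometry: ChamberGeometry) -> np.ndarray:
    """Vertices of the stenotic wall contour, walked in +x, bump at y = H."""
    g = geometry
    H, hs = g.channel_height, g.throat_height
    pts = [(0.0, H)]
    if g.bump_height > 0:
        pts += [
            (g.x_contraction_start, H),
            (g.x_throat_start, hs),
            (g.x_throat_end, hs),
            (g.x_expansion_end, H),
        ]
    pts.append((g.domain_length, H))
    # collapse duplicate vertices (zero-run ramps, zero upstream length)
    out = [pts[0]]
    for p in pts[1:]:
        if not np.allclose(p, out[-1]):
            out.append(p)
    return np.array(out)


def _offset_polyline(vertices: np.ndarray, offset: float) -> np.ndarray:
    """Displace a wall polyline by ``offset`` along the inward (fluid-side) normal.

    The fluid sits below the contour (smaller y).  Corners are mitred by
    intersecting consecutive offset segment lines.
    """
    d = np.diff(vertices, axis=0)
    lengths = np.linalg.norm(d, axis=1)
    t = d / lengths[:, None]
    # inward normal of a top wall walked in +x: rotate tangent by -90 deg
    normals = np.column_stack([t[:, 1], -t[:, 0]])
    starts = vertices[:-1] + offset * normals
    out = [starts[0]]
    for k in range(1, len(starts)):
        # intersect line k-1 (through starts[k-1], dir t[k-1]) with line k
        p, q = starts[k - 1], starts[k]
        A = np.column_stack([t[k - 1], -t[k]])
        det = np.linalg.det(A)
        if abs(det) < 1e-12:  # collinear segments
            out.append(q)
            continue
        s = np.linalg.solve(A, q - p)
        out.append(p + s[0] * t[k - 1])
    out.append(vertices[-1] + offset * normals[-1])
    return np.array(out)


def wall_offset_samples(
    geometry: ChamberGeometry,
    wall: str,
    offset: float,
    spacing: float = 1e-6,
) -> np.ndarray:
    """Sample points displaced ``offset`` from a wall along its inward normal.

    Returns an (n, 2) array of (x, y) positions ordered in increasing arc
    length (strictly increasing x on the flat wall).  The flat wall yields a
    straight line; the stenotic wall contour follows the ramps and throat.

    Raises :class:`OffsetError` when ``offset >= hs / 2``, i.e. when the
    offset curve would reach the throat mid-plane.
    """
    if wall not in ("glass", "pdms"):
        raise ValidationError("wall must be 'glass' or 'pdms'")
    if offset < 0:
        raise OffsetError("offset must be non-negative")
    if offset >= geometry.throat_height / 2.0:
        raise OffsetError(
            f"offset {offset:.3g} m >= half throat height "
            f"{geometry.throat_height / 2.0:.3g} m"
        )
    flat_wall_y0 = geometry.stenotic_wall == "pdms"  # glass flat at y = 0
    is_flat = (wall == "glass") == flat_wall_y0
    L, H = geometry.domain_length, geometry.channel_height
    if is_flat:
        n = max(2, int(round(L / spacing)) + 1)
        x = np.linspace(0.0, L, n)
        y_wall = 0.0 if flat_wall_y0 else H
        y = np.full_like(x, y_wall + offset if flat_wall_y0 else y_wall - offset)
        return np.column_stack([x, y])
    poly = _offset_polyline(_wall_polyline(geometry), offset)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(round(arc[-1] / spacing)) + 1)
    s = np.linspace(0.0, arc[-1], n)
    x = np.interp(s, arc, poly[:, 0])
    y = np.interp(s, arc, poly[:, 1])
    if not flat_wall_y0:
        # bump on the glass (y = 0) wall: mirror the contour
        y = H - y
    pts = np.column_stack([x, y])
    return pts
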