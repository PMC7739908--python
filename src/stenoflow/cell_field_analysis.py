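"""Cell-transport metrics from labelled cell-position snapshot series.

Input is the kind of output a cell-resolved blood-flow simulation dumps at
regular intervals: timestamped 3-D positions of every red blood cell (RBC)
and platelet (PLT).  From those snapshots this module derives the
transport quantities that matter for near-wall platelet capture:

* **flux maps** — time-averaged cell-presence counts per (x, y) bin per
  second, with the width direction (z) collapsed;
* **residence-time maps** — the time a platelet needs to translocate its
  own diameter (2 um), a proxy for the time available to form a bond;
* **RBC volume-fraction maps** and the **cell-depleted layer (CFL)**
  thickness, operationally the near-wall layer holding only 1% of the
  RBC volume fraction.

Flux counts cell-presence events per snapshot (the same cell seen in a bin
on consecutive snapshots counts each time) and divides by the window
duration.  Trajectories are unwrapped across the x-periodic boundary by
minimum-image displacement before any distance is accumulated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    TrajectoryError,
    ValidationError,
    WindowError,
)

#: Platelet diameter (m) used for residence times.
PLATELET_DIAMETER = 2e-6
#: Default cell volumes (m^3): literature values for human RBC and platelet.
DEFAULT_CELL_VOLUMES = {"RBC": 90e-18, "PLT": 6e-18}


@dataclass
class CellSnapshotSeries:
    """Timestamped, labelled cell positions.

    ``frame`` holds one row per cell per snapshot with columns
    ``t, id, type, x, y, z`` (SI units; ``type`` in {"RBC", "PLT"}).
    ``domain`` is the (Lx, H, W) bounding box; x and z are periodic.
    """

    frame: pd.DataFrame
    domain: tuple[float, float, float]
    cell_volumes: dict = field(default_factory=lambda: dict(DEFAULT_CELL_VOLUMES))
    platelet_diameter: float = PLATELET_DIAMETER

    def __post_init__(self):
        required = {"t", "id", "type", "x", "y", "z"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"snapshot frame missing columns {sorted(missing)}")
        times = self.times
        if len(times) < 1:
            raise ValidationError("snapshot series is empty")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("snapshot times must be strictly increasing")
        dts = np.diff(times)
        if len(dts) > 1 and (dts.max() - dts.min()) > 0.01 * dts.mean():
            raise ValidationError("snapshot interval must be constant within 1%")
        Lx, H, W = self.domain
        pos = self.frame[["x", "y", "z"]].to_numpy()
        lo = np.array([0.0, 0.0, 0.0]) - 1e-12
        hi = np.array([Lx, H, W]) + 1e-12
        if np.any(pos < lo) or np.any(pos > hi):
            raise ValidationError("cell positions fall outside the domain bounds")

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.frame["t"].to_numpy())

    @property
    def dt_snap(self) -> float:
        t = self.times
        if len(t) < 2:
            raise ValidationError("need >= 2 snapshots for a snapshot interval")
        return float(np.diff(t).mean())

    def in_window(self, window: tuple[float, float]) -> pd.DataFrame:
        t0, t1 = window
        if t1 <= t0:
            raise WindowError("window end must exceed window start")
        sel = self.frame[(self.frame["t"] >= t0) & (self.frame["t"] <= t1)]
        if len(np.unique(sel["t"])) < 2:
            raise WindowError("window contains fewer than 2 snapshots")
        return sel

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, domain: tuple[float, float, float], **kw):
        return cls(frame=pd.read_csv(path), domain=domain, **kw)

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["domain"] = self.domain
            fh.attrs["platelet_diameter"] = self.platelet_diameter
            for name, vol in self.cell_volumes.items():
                fh.attrs[f"volume_{name}"] = vol
            for k, t in enumerate(self.times):
                snap = self.frame[self.frame["t"] == t]
                g = fh.create_group(f"snapshot_{k:05d}")
                g.attrs["t"] = t
                g.create_dataset("id", data=snap["id"].to_numpy(np.int64))
                g.create_dataset(
                    "type",
                    data=np.array(snap["type"], dtype="S3"),
                )
                g.create_dataset("pos", data=snap[["x", "y", "z"]].to_numpy())

    @classmethod
    def from_hdf5(cls, path: str) -> "CellSnapshotSeries":
        rows = []
        with h5py.File(path, "r") as fh:
            domain = tuple(fh.attrs["domain"])
            d_p = float(fh.attrs.get("platelet_diameter", PLATELET_DIAMETER))
            volumes = {
                k[len("volume_") :]: float(v)
                for k, v in fh.attrs.items()
                if k.startswith("volume_")
            } or dict(DEFAULT_CELL_VOLUMES)
            for name in sorted(fh):
                g = fh[name]
                pos = g["pos"][...]
                rows.append(
                    pd.DataFrame(
                        {
                            "t": g.attrs["t"],
                            "id": g["id"][...],
                            "type": [s.decode() for s in g["type"][...]],
                            "x": pos[:, 0],
                            "y": pos[:, 1],
                            "z": pos[:, 2],
                        }
                    )
                )
        return cls(
            frame=pd.concat(rows, ignore_index=True),
            domain=domain,
            cell_volumes=volumes,
            platelet_diameter=d_p,
        )


@dataclass
class BinnedFieldMap:
    """2-D (x, y) field on rectangular bins, z collapsed.

    ``kind`` is one of "flux" (1/s), "residence" (s) or "volume_fraction"
    (dimensionless).  ``values`` may hold NaN for undefined (never-visited)
    bins; ``censored`` counts right-censored residence visits per bin.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    kind: str
    window: tuple[float, float]
    censored: np.ndarray | None = None

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_hdf5(self, path: str, group: str = "/") -> None:
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in ("x_edges", "y_edges", "values"):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=getattr(self, name))
            if self.censored is not None:
                if "censored" in g:
                    del g["censored"]
                g.create_dataset("censored", data=self.censored)
            g.attrs["kind"] = self.kind
            g.attrs["window"] = self.window

    def to_csv(self, path: str) -> None:
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        pd.DataFrame(
            {"x": xc.ravel(), "y": yc.ravel(), "value": self.values.ravel()}
        ).to_csv(path, index=False)


def _bin_edges(series: CellSnapshotSeries, bins) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a bin specification: a scalar bin size (m) or (x_edges, y_edges)."""
    Lx, H, _ = series.domain
    if np.isscalar(bins):
        b = float(bins)
        if b <= 0:
            raise ValidationError("bin size must be positive")
        return (
            np.arange(0.0, Lx + 0.5 * b, b),
            np.arange(0.0, H + 0.5 * b, b),
        )
    x_edges, y_edges = bins
    return np.asarray(x_edges, float), np.asarray(y_edges, float)


def flux_map(
    series: CellSnapshotSeries,
    cell_type: str,
    bins=2e-6,
    window: tuple[float, float] | None = None,
) -> BinnedFieldMap:
    """Cell-presence flux: per-bin presence counts over a window / duration.

    ``value(bin) = sum over snapshots of count(cell_type in bin) / (t1 - t0)``
    with positions projected over z.  Units 1/s.
    """
    if window is None:
        t = series.times
        window = (float(t[0]), float(t[-1]))
    sel = series.in_window(window)
    sel = sel[sel["type"] == cell_type]
    x_edges, y_edges = _bin_edges(series, bins)
    counts, _, _ = np.histogram2d(
        sel["x"].to_numpy(), sel["y"].to_numpy(), bins=(x_edges, y_edges)
    )
    duration = window[1] - window[0]
    return BinnedFieldMap(
        x_edges=x_edges,
        y_edges=y_edges,
        values=counts / duration,
        kind="flux",
        window=window,
    )


def _unwrap_min_image(dx: np.ndarray, period: float) -> np.ndarray:
    return dx - period * np.round(dx / period)


def residence_time_map(
    series: CellSnapshotSeries,
    bins=2e-6,
    window: tuple[float, float] | None = None,
    diameter: float | None = None,
    cell_type: str = "PLT",
) -> BinnedFieldMap:
    """Mean translocation time per bin: time to travel one platelet diameter.

    For every platelet and every snapshot ("visit") in the window, the
    residence is the first time lag at which the cumulative path length
    (x unwrapped by minimum image) reaches the platelet diameter, linearly
    interpolated between snapshots.  The residence is assigned to the bin
    of the position at visit start; visits whose trajectory never covers
    one diameter before the window (or the trajectory) ends are censored
    at the remaining window length and counted in ``censored``.
    Bin value = mean over visits; never-visited bins are NaN.
    """
    d = diameter if diameter is not None else series.platelet_diameter
    if window is None:
        t = series.times
        window = (float(t[0]), float(t[-1]))
    sel = series.in_window(window)
    sel = sel[sel["type"] == cell_type]
    if sel.duplicated(subset=["t", "id"]).any():
        raise TrajectoryError("duplicate cell id within a snapshot")
    x_edges, y_edges = _bin_edges(series, bins)
    Lx = series.domain[0]
    t_end = window[1]

    sums = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    nvis = np.zeros_like(sums)
    ncens = np.zeros_like(sums)

    n_linked = 0
    for _, traj in sel.groupby("id", sort=False):
        traj = traj.sort_values("t")
        t = traj["t"].to_numpy(float)
        if len(t) < 2:
            continue
        n_linked += 1
        pos = traj[["x", "y", "z"]].to_numpy(float)
        step = np.diff(pos, axis=0)
        step[:, 0] = _unwrap_min_image(step[:, 0], Lx)
        cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(step, axis=1))])
        # the last snapshot of a trajectory has no forward data and is not a visit
        n_vis = len(t) - 1
        targets = cum[:n_vis] + d
        idx = np.searchsorted(cum, targets)  # first k with cum[k] >= cum[j] + d
        res = np.empty(n_vis)
        cens = idx >= len(cum)
        ok = ~cens
        k = idx[ok]
        j = np.nonzero(ok)[0]
        seg = cum[k] - cum[k - 1]
        frac = np.where(seg > 0, (targets[j] - cum[k - 1]) / seg, 0.0)
        res[ok] = t[k - 1] + frac * (t[k] - t[k - 1]) - t[j]
        res[cens] = t_end - t[:n_vis][cens]
        pos = pos[:n_vis]
        ix = np.clip(np.searchsorted(x_edges, pos[:, 0], side="right") - 1, 0, sums.shape[0] - 1)
        iy = np.clip(np.searchsorted(y_edges, pos[:, 1], side="right") - 1, 0, sums.shape[1] - 1)
        np.add.at(sums, (ix, iy), res)
        np.add.at(nvis, (ix, iy), 1.0)
        np.add.at(ncens, (ix, iy), cens.astype(float))
    if n_linked == 0:
        raise TrajectoryError(
            "no cell id appears in >= 2 snapshots; trajectories unlinkable"
        )
    with np.errstate(invalid="ignore"):
        values = np.where(nvis > 0, sums / np.maximum(nvis, 1), np.nan)
    return BinnedFieldMap(
        x_edges=x_edges,
        y_edges=y_edges,
        values=values,
        kind="residence",
        window=window,
        censored=ncens,
    )


def rbc_volume_fraction(
    series: CellSnapshotSeries,
    bins=2e-6,
    window: tuple[float, float] | None = None,
) -> BinnedFieldMap:
    """Per-bin RBC volume fraction: mean RBC count * V_RBC / bin volume.

    The bin volume uses the full domain width as z extent (maps are
    z-collapsed).  Values are clipped to [0, 1].
    """
    if "RBC" not in series.cell_volumes:
        raise ConfigurationError("cell_volumes must provide an 'RBC' entry")
    v_rbc = series.cell_volumes["RBC"]
    if window is None:
        t = series.times
        window = (float(t[0]), float(t[-1]))
    sel = series.in_window(window)
    n_snap = len(np.unique(sel["t"]))
    sel = sel[sel["type"] == "RBC"]
    x_edges, y_edges = _bin_edges(series, bins)
    counts, _, _ = np.histogram2d(
        sel["x"].to_numpy(), sel["y"].to_numpy(), bins=(x_edges, y_edges)
    )
    bin_vol = (
        np.diff(x_edges)[:, None] * np.diff(y_edges)[None, :] * series.domain[2]
    )
    phi = np.clip(counts / n_snap * v_rbc / bin_vol, 0.0, 1.0)
    return BinnedFieldMap(
        x_edges=x_edges,
        y_edges=y_edges,
        values=phi,
        kind="volume_fraction",
        window=window,
    )


@dataclass
class CFLProfile:
    """Cell-depleted-layer thickness along the channel for one wall."""

    x: np.ndarray
    delta: np.ndarray
    flagged: np.ndarray
    wall: str
    threshold_mode: str
    threshold: float

    @property
    def mean_thickness(self) -> float:
        return float(np.mean(self.delta[~self.flagged])) if (~self.flagged).any() else float(
            np.mean(self.delta)
        )


def cfl_thickness(
    phi: BinnedFieldMap,
    wall: str,
    threshold_mode: str = "relative",
    c: float = 0.01,
    lumen: np.ndarray | None = None,
) -> CFLProfile:
    """Cell-depleted-layer thickness: distance from the wall to 1% RBC volume fraction.

    Per x-column, the thickness ``delta`` is the wall distance at which the
    volume fraction first exceeds ``c * phi_ref``, with ``phi_ref`` the
    column maximum in "relative" mode (1% of the local core fraction, the
    default reading) or 1 in "absolute" mode.  The crossing is linearly
    interpolated between the bracketing bin centres and capped at the local
    lumen half-height.  All-empty columns return the cap, flagged.

    ``lumen`` optionally gives per-column (y_lo, y_hi) lumen bounds,
    shape (nx, 2); otherwise the full map extent is used.
    """
    if phi.kind != "volume_fraction":
        raise ValidationError("cfl_thickness requires a volume_fraction map")
    if wall not in ("glass", "pdms"):
        raise ValidationError("wall must be 'glass' or 'pdms'")
    if threshold_mode not in ("relative", "absolute"):
        raise ValidationError("threshold_mode must be 'relative' or 'absolute'")
    yc = phi.y_centers
    nx = phi.values.shape[0]
    if lumen is None:
        lumen = np.tile(
            np.array([phi.y_edges[0], phi.y_edges[-1]]), (nx, 1)
        )
    delta = np.zeros(nx)
    flagged = np.zeros(nx, dtype=bool)
    for i in range(nx):
        y_lo, y_hi = lumen[i]
        half = 0.5 * (y_hi - y_lo)
        col_sel = (yc >= y_lo) & (yc <= y_hi)
        col = phi.values[i, col_sel]
        yy = yc[col_sel]
        if wall == "pdms":
            # scan from the top wall downwards: distances from y_hi
            col = col[::-1]
            dist = y_hi - yy[::-1]
            wall_y = y_hi
        else:
            dist = yy - y_lo
        phi_ref = float(col.max()) if threshold_mode == "relative" else 1.0
        thr = c * phi_ref
        if phi_ref <= 0 or not (col > thr).any():
            delta[i] = half
            flagged[i] = True
            continue
        j = int(np.argmax(col > thr))
        if j == 0:
            delta[i] = 0.0
        else:
            d0, d1 = dist[j - 1], dist[j]
            f0, f1 = col[j - 1], col[j]
            delta[i] = d0 + (thr - f0) / (f1 - f0) * (d1 - d0)
        delta[i] = min(delta[i], half)
    return CFLProfile(
        x=phi.x_centers,
        delta=delta,
        flagged=flagged,
        wall=wall,
        threshold_mode=threshold_mode,
        threshold=c,
    )
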