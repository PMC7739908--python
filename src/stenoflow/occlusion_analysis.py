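"""Experimental occlusion pipeline: mass-balance metering and image profiling.

The *in vitro* assay drives blood through the stenotic chamber under a
constant hydrostatic head while (i) a mass balance records the cumulative
outflow mass and (ii) a bright-field camera images the channel from the top
(x flow-wise, z across the width) at about 2 Hz.  A second balance holding
a dish of the same mixture records evaporation alone.  This module turns
those two records into the assay's primary read-outs:

* the evaporation-corrected **flow rate** (slope of mass vs. time / density),
* the **occlusion time** — when the corrected mass stops rising; if the
  trace plateaus at its maximum, the centre of the plateau is taken,
* the **occlusion location** — at the occlusion frame, pixel intensities
  are averaged over the channel width, min–max normalized, aligned on the
  upstream corner of the stenotic throat, and the distance from that corner
  to the intensity peak is reported.  In whole blood a clot is brighter
  than the background; in platelet-rich plasma it is darker, so PRP
  profiles are inverted before comparison with WB.

Corner annotation replaces the interactive click step with a JSON file of
ordered (x, z) pixel pairs: 4 corners for a chamber whose contraction and
expansion are effectively single lines in the top view, 8 when contraction
and expansion areas have distinct start and end edges.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    AlignmentError,
    AnnotationError,
    DegenerateProfileError,
    ValidationError,
    WindowError,
)

#: Default balance resolution (kg); the plateau tolerance defaults to twice this.
BALANCE_RESOLUTION = 1e-6


# ---------------------------------------------------------------------------
# Mass traces


@dataclass
class MassTrace:
    """Cumulative outflow mass record, optionally with an evaporation reference."""

    times: np.ndarray
    mass: np.ndarray
    reference: np.ndarray | None = None
    reference_times: np.ndarray | None = None
    density: float = 1025.0
    corrected: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.mass = np.asarray(self.mass, float)
        if self.times.ndim != 1 or self.times.shape != self.mass.shape:
            raise ValidationError("times and mass must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, float)
            if self.reference_times is None:
                self.reference_times = self.times.copy()
            else:
                self.reference_times = np.asarray(self.reference_times, float)

    @classmethod
    def from_csv(cls, path: str, density: float = 1025.0) -> "MassTrace":
        df = pd.read_csv(path)
        ref = df["ref_mass"].to_numpy() if "ref_mass" in df.columns else None
        return cls(
            times=df["t"].to_numpy(),
            mass=df["mass"].to_numpy(),
            reference=ref,
            density=density,
        )

    def to_csv(self, path: str) -> None:
        d = {"t": self.times, "mass": self.mass}
        if self.reference is not None and len(self.reference) == len(self.times):
            d["ref_mass"] = self.reference
        pd.DataFrame(d).to_csv(path, index=False)


def correct_evaporation(
    trace: MassTrace, reference: MassTrace | None = None
) -> MassTrace:
    """Subtract the evaporation reference (re-zeroed at its first sample).

    The reference trace is linearly resampled onto the trace's time grid;
    corrected mass = mass - (reference - reference[0]).
    """
    if reference is not None:
        ref_t, ref_m = reference.times, reference.mass
    elif trace.reference is not None:
        ref_t, ref_m = trace.reference_times, trace.reference
    else:
        return MassTrace(
            times=trace.times,
            mass=trace.mass.copy(),
            density=trace.density,
            corrected=True,
        )
    if ref_t[-1] < trace.times[0] or ref_t[0] > trace.times[-1]:
        raise AlignmentError("reference trace does not overlap the mass trace in time")
    ref = np.interp(trace.times, ref_t, ref_m)
    return MassTrace(
        times=trace.times,
        mass=trace.mass - (ref - ref[0]),
        density=trace.density,
        corrected=True,
    )


def flow_rate(trace: MassTrace, window: tuple[float, float]) -> float:
    """Volumetric flow rate (m^3/s): least-squares mass slope over a window / density.

    The window must lie in the pre-occlusion regime and contain at least 5
    samples.  Multiply by 1e9 for ul/s.
    """
    t0, t1 = window
    sel = (trace.times >= t0) & (trace.times <= t1)
    if sel.sum() < 5:
        raise WindowError("flow-rate window must contain at least 5 samples")
    t = trace.times[sel]
    m = trace.mass[sel]
    slope = np.polyfit(t, m, 1)[0]
    return float(slope / trace.density)


@dataclass
class OcclusionTime:
    """Detected occlusion time with provenance flags."""

    time: float
    frame_index: int | None = None
    censored: bool = False
    plateau: tuple[float, float] | None = None


def occlusion_time(
    trace: MassTrace,
    tolerance: float | None = None,
    frame_times: np.ndarray | None = None,
) -> OcclusionTime:
    """Occlusion time from the corrected mass trace.

    The plateau is the maximal contiguous run of samples within
    ``tolerance`` of the global maximum (default tolerance: twice the
    balance resolution).  A plateau bounded inside the record returns its
    temporal centre; a plateau running into the last sample returns its
    start (the plateau's end was not observed).  A trace still rising at
    the last sample — the run at the maximum shorter than 3 samples and
    touching the end — is flagged right-censored.
    """
    eps = 2.0 * BALANCE_RESOLUTION if tolerance is None else float(tolerance)
    m = trace.mass
    t = trace.times
    high = m >= m.max() - eps
    imax = int(np.argmax(m))
    # contiguous run of `high` containing the argmax
    lo = imax
    while lo > 0 and high[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(m) - 1 and high[hi + 1]:
        hi += 1
    plateau = (float(t[lo]), float(t[hi]))
    if hi == len(m) - 1:
        if hi - lo + 1 < 3:
            result = OcclusionTime(time=float(t[-1]), censored=True, plateau=plateau)
        else:
            # occluded, recording stopped during the plateau
            result = OcclusionTime(time=float(t[lo]), plateau=plateau)
    else:
        result = OcclusionTime(time=0.5 * (t[lo] + t[hi]), plateau=plateau)
    if frame_times is not None:
        ft = np.asarray(frame_times, float)
        result.frame_index = int(np.argmin(np.abs(ft - result.time)))
    return result


# ---------------------------------------------------------------------------
# Images


@dataclass
class ImageStack:
    """Grey-scale top-view time-lapse: frames[k][z_row, x_col].

    x (columns) is the flow direction, z (rows) the channel width.
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size: float
    modality: str

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, float)
        if self.frames.ndim not in (3, 4):
            raise ValidationError("frames must be (n, nz, nx[, channels])")
        if len(self.times) != self.frames.shape[0]:
            raise ValidationError("one timestamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("frame timestamps must be strictly increasing")
        if self.modality not in ("WB", "PRP"):
            raise ValidationError("modality must be 'WB' or 'PRP'")

    def to_tiff(self, path: str) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "times": self.times.tolist(),
                    "pixel_size": self.pixel_size,
                    "modality": self.modality,
                },
                fh,
            )

    @classmethod
    def from_tiff(cls, path: str) -> "ImageStack":
        frames = tifffile.imread(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(
            frames=frames,
            times=np.asarray(meta["times"]),
            pixel_size=float(meta["pixel_size"]),
            modality=meta["modality"],
        )


@dataclass
class CornerAnnotation:
    """Stenotic-region corner pixels: 4 (single-line contraction) or 8 corners.

    Corners are (x_px, z_px) pairs.  Derived quantities: the x pixel of the
    contraction start/end and expansion start/end (averaged over the two z
    sides) and the alignment reference — the upstream corner of the
    stenotic throat, i.e. the downstream (right) border of the contraction
    area.
    """

    corners: np.ndarray

    def __post_init__(self):
        self.corners = np.asarray(self.corners, float)
        if self.corners.shape not in ((4, 2), (8, 2)):
            raise AnnotationError("expected 4 or 8 (x, z) corner pairs")

    def _x_clusters(self) -> np.ndarray:
        xs = np.sort(self.corners[:, 0])
        return xs.reshape(-1, 2).mean(axis=1)  # pairs of z-sides share an x

    @property
    def contraction_start_x(self) -> float:
        return float(self._x_clusters()[0])

    @property
    def contraction_end_x(self) -> float:
        c = self._x_clusters()
        return float(c[0] if len(c) == 2 else c[1])

    @property
    def expansion_start_x(self) -> float:
        c = self._x_clusters()
        return float(c[1] if len(c) == 2 else c[2])

    @property
    def expansion_end_x(self) -> float:
        return float(self._x_clusters()[-1])

    @property
    def reference_x(self) -> float:
        """Alignment reference: upstream corner of the stenotic throat."""
        return self.contraction_end_x

    @property
    def z_span(self) -> tuple[int, int]:
        z = self.corners[:, 1]
        return int(round(z.min())), int(round(z.max()))

    def validate_against(self, frame_shape: tuple[int, int]) -> None:
        nz, nx = frame_shape[:2]
        x, z = self.corners[:, 0], self.corners[:, 1]
        if (x < 0).any() or (x > nx - 1).any() or (z < 0).any() or (z > nz - 1).any():
            raise AnnotationError("corner coordinates fall outside the frame")
        if self.contraction_end_x >= self.expansion_start_x:
            raise AnnotationError("contraction must lie upstream of expansion")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"corners": self.corners.tolist()}, fh)

    @classmethod
    def from_json(cls, path: str) -> "CornerAnnotation":
        with open(path) as fh:
            return cls(corners=np.asarray(json.load(fh)["corners"]))


@dataclass
class IntensityProfile:
    """Width-averaged, normalized, corner-aligned intensity curve I(x)."""

    x: np.ndarray
    intensity: np.ndarray
    modality: str
    inverted: bool
    degenerate: bool = False


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        # unweighted channel mean (monochrome camera in the real assay;
        # only synthetic RGB fixtures ever hit this branch)
        return img.mean(axis=2)
    return np.asarray(img, float)


def intensity_profile(
    stack: ImageStack,
    frame_index: int,
    corners: CornerAnnotation,
    modality: str | None = None,
    invert_before_normalize: bool = True,
    pixel_size: float | None = None,
) -> IntensityProfile:
    """Width-averaged normalized intensity of one frame, aligned on the throat corner.

    Pixel columns are averaged over the annotated channel width (z span),
    PRP intensities are inverted (darker clot -> positive peak) and the
    curve is min–max normalized to [0, 1].  x = 0 at the upstream stenotic
    corner, increasing downstream, in metres.  A contrast-free frame yields
    a zero profile flagged degenerate.
    """
    if not 0 <= frame_index < stack.frames.shape[0]:
        raise ValidationError("frame_index outside the stack")
    modality = modality or stack.modality
    img = _to_grayscale(stack.frames[frame_index])
    corners.validate_against(img.shape)
    z0, z1 = corners.z_span
    profile = img[z0 : z1 + 1, :].mean(axis=0)
    inverted = modality == "PRP"
    if inverted and invert_before_normalize:
        profile = -profile
    rng = profile.max() - profile.min()
    scale = max(abs(profile.max()), abs(profile.min()), 1.0)
    if rng < 1e-9 * scale:
        norm = np.zeros_like(profile)
        degenerate = True
    else:
        norm = (profile - profile.min()) / rng
        degenerate = False
    if inverted and not invert_before_normalize and not degenerate:
        norm = 1.0 - norm
    px = pixel_size or stack.pixel_size
    x = (np.arange(img.shape[1]) - corners.reference_x) * px
    return IntensityProfile(
        x=x, intensity=norm, modality=modality, inverted=inverted, degenerate=degenerate
    )


@dataclass
class PeakLocation:
    """Occlusion distance: upstream throat corner to the intensity maximum."""

    distance: float
    index: int
    tie: bool

    def __float__(self) -> float:
        return self.distance


def occlusion_distance(profile: IntensityProfile) -> PeakLocation:
    """Distance from the upstream stenotic corner to the intensity peak (m).

    Ties at the maximum report the first (most upstream) location, flagged.
    """
    if profile.degenerate:
        raise DegenerateProfileError(
            "profile has no contrast; occlusion distance undefined"
        )
    imax = int(np.argmax(profile.intensity))
    tie = int(np.sum(profile.intensity == profile.intensity[imax])) > 1
    return PeakLocation(distance=float(profile.x[imax]), index=imax, tie=tie)


def aggregate_profiles(
    profiles: list[IntensityProfile],
    grid: np.ndarray | None = None,
    y_shift: bool = False,
) -> tuple[IntensityProfile, list[IntensityProfile]]:
    """Pointwise mean of aligned profiles on a common x grid.

    Profiles are linearly interpolated onto the intersection of their x
    supports (or onto ``grid``).  ``y_shift`` removes each profile's mean
    first, for cross-modality shape comparison.  Returns the mean profile
    and the per-experiment curves on the common grid.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    lo = max(p.x.min() for p in profiles)
    hi = min(p.x.max() for p in profiles)
    if hi <= lo:
        raise AlignmentError("profiles have disjoint x supports")
    if grid is None:
        step = float(np.median(np.diff(profiles[0].x)))
        grid = np.arange(lo, hi + 0.5 * step, step)
    else:
        grid = np.asarray(grid, float)
        if grid.min() < lo or grid.max() > hi:
            raise AlignmentError("requested grid exceeds the common support")
    curves = []
    for p in profiles:
        y = np.interp(grid, p.x, p.intensity)
        if y_shift:
            y = y - y.mean()
        curves.append(
            IntensityProfile(
                x=grid, intensity=y, modality=p.modality, inverted=p.inverted
            )
        )
    mean = np.mean([c.intensity for c in curves], axis=0)
    mean_profile = IntensityProfile(
        x=grid,
        intensity=mean,
        modality=profiles[0].modality if len({p.modality for p in profiles}) == 1 else "mixed",
        inverted=any(p.inverted for p in profiles),
    )
    return mean_profile, curves


@dataclass
class OcclusionResult:
    """End-to-end result: when the channel occluded and where the clot sat."""

    occlusion: OcclusionTime
    distance: PeakLocation
    profile: IntensityProfile

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "occlusion_time_s": self.occlusion.time,
                    "frame_index": self.occlusion.frame_index,
                    "censored": self.occlusion.censored,
                    "distance_m": self.distance.distance,
                    "tie": self.distance.tie,
                },
                fh,
                indent=2,
            )


def analyze_occlusion(
    stack: ImageStack,
    trace: MassTrace,
    corners: CornerAnnotation,
    reference: MassTrace | None = None,
    tolerance: float | None = None,
) -> OcclusionResult:
    """Full pipeline: correct evaporation, find the occlusion frame, locate the clot."""
    corrected = trace if trace.corrected else correct_evaporation(trace, reference)
    occ = occlusion_time(corrected, tolerance=tolerance, frame_times=stack.times)
    prof = intensity_profile(stack, occ.frame_index, corners)
    dist = occlusion_distance(prof)
    return OcclusionResult(occlusion=occ, distance=dist, profile=prof)
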