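# Methods

This note documents the models, numerical choices and limitations behind
`stenoflow`, in the order a dataset flows through the package.

## Chamber geometry

The chamber is treated as a slot (width W ≫ height H) whose side view is a
rectangle of height H and length L with one trapezoidal bump on the moulded
(PDMS) wall; the glass coverslip wall is flat.  Parameters, all SI:

| parameter | symbol | default | meaning |
|---|---|---|---|
| `channel_height` | H | 130 µm | lumen height (y) |
| `channel_width` | W | 480 µm | lumen width (z); 50 µm in the periodic-slab preset |
| `stenosis_severity` | s | 0.5 | fractional lumen-height reduction; throat height h_s = (1−s)H |
| `ramp_angle` | θ | 80° | angle between ramp face and wall plane (near-vertical) |
| `throat_length` | L_s | 150 µm | flat-top length, excluding ramps |
| `upstream_length` | — | 200 µm | straight channel before the contraction |
| `downstream_length` | — | ≈199.1 µm | straight channel after the expansion |

The ramp angle is wall-referenced, so each ramp has a horizontal run of
(H−h_s)/tan θ ≈ 11.46 µm at the defaults.  Two readings of the printed
chamber dimensions are geometrically possible (throat length including or
excluding the ramps; wall- or axis-referenced angle); we adopt
flat-top-only and wall-referenced, and let the downstream straight section
absorb the residual so the default domain is exactly 572 µm long.  The
builder exposes three presets: `design` (nominal mould dimensions),
`as-built` (confocal measurements of the machined mould: H = 131 µm,
h_s = 65.7 µm, i.e. s ≈ 49.85%, which rounds to the nominal 50%), and
`simulation` (a 50 µm-wide z-periodic slab, usable because w ≫ h makes the
side-view flow z-homogeneous).

Rasterization is centre-sampled on a square grid: a cell is fluid iff its
centre lies strictly inside the lumen polygon.  This is first-order in the
cell size for the slanted ramps — the rasterized area converges to the
shoelace-formula polygon area as Δx → 0 and agrees within 2% at
Δx = 0.5 µm — and exact for straight channels.  The rasterizer refuses
grids coarser than h_s/8 (fewer than 8 cells across the throat).

Wall-offset curves displace the wall polyline along its inward normal with
mitred corners, so the 1 µm shear-sampling curve follows the ramps and
throat on the stenotic side and is the straight line y = 1 µm on the glass
side.  Offsets of h_s/2 or more would cross the throat mid-plane and are
rejected.

## Flow model

Flow in these chambers is slow and viscous: at Q ≈ 2 × 10⁻⁹ m³/s the
channel Reynolds number Re = Q/(Wν) is about 4 and the regime is
quasi-Stokes.  The solver therefore computes steady 2-D Stokes flow on the
side-view mask (the width enters only as the scale factor between the 2-D
flux and Q), driven by a uniform flow-wise body force with x-periodic
boundaries — the same driving the cell-resolved simulations of this
chamber use.  Neglecting inertia discards a weak up/downstream asymmetry of
order Re; the solution is mirror-symmetric about the throat midplane, which
the tests verify to 2%.

Discretization is a marker-and-cell (MAC) staggered grid: u on vertical
faces, v on horizontal faces, p at cell centres, default Δx = 0.5 µm
(tests and the acceptance computation use 1–2 µm, which already reproduces
the plane-Poiseuille wall shear to better than 0.1%).  Walls coincide with
cell boundaries; the tangential ghost value across a wall is the
reflection u_ghost = −u (second order at the wall).  The assembly is
nondimensionalized (momentum rows scaled by Δx²/µ, pressure by Δx/µ) so
the matrix is independent of the fluid; one pressure is pinned because the
continuity rows are linearly dependent under periodicity.  The saddle
system is solved directly with SuperLU, giving machine-precision discrete
divergence — the per-station flux spread is ~10⁻⁵ relative, far inside the
0.1% mass-conservation contract.  Because Stokes flow is linear in the
forcing, matching a target Q needs exactly one proportional rescaling of
the unit-force solution rather than an iteration.

Fluids are Newtonian constants: plasma/PRP ρ = 1025 kg/m³,
ν = 1.1 × 10⁻⁶ m²/s; whole blood as an effective continuum
ρ = 1060 kg/m³, ν = 3.3 × 10⁻⁶ m²/s.  At equal Q the two solves produce
identical shear-rate fields and stresses scaled by µ_WB/µ_PRP — a
consequence of Stokes linearity that the tests assert exactly.  Shear
thinning, pulsatility and any feedback of a growing clot on the flow are
out of scope.

Shear is formed where the MAC layout makes it natural: γ̇ₓᵧ = ∂u/∂y + ∂v/∂x
at grid nodes by centred differences, reducing to the one-sided
second-order wall formula at wall nodes; τₓᵧ = µγ̇ₓᵧ by construction.  Only
the xy-component is formed — in a slot-like geometry the other components
are negligible, except within a few cells of the ramp corners where the
single-component values spike; those samples are flagged in wall profiles,
not suppressed, since they may be artefacts of the component choice.
Wall profiles bilinearly interpolate the node fields onto the offset
curves.

`reynolds_number` uses mean velocity Q/(WH) and characteristic length H,
which cancels to Re = Q/(Wν) — the only combination that reproduces the
reference value ≈4 at the printed conditions.

## Cell-transport metrics

Input is a snapshot series: every Δt_snap (default 5 ms) the positions of
all cells, labelled RBC/PLT with persistent ids.  All maps are 2-D (x, y)
with z collapsed, default 2 µm bins.

* **Flux** counts cell *presences* per bin per snapshot and divides by the
  window duration (units 1/s): a stationary platelet seen 60 times in
  0.30 s contributes 200 /s to its bin.  Summed over bins and multiplied
  by the window, the map returns the total presence count exactly.
* **Residence time** is the time a platelet needs to translocate its own
  diameter (2 µm).  "Distance travelled" is path length — the cumulative
  sum of inter-snapshot step magnitudes, with x-steps unwrapped by
  minimum image across the periodic boundary — and the crossing of the
  2 µm threshold is linearly interpolated between snapshots.  Each
  snapshot a platelet appears in opens a visit assigned to the bin of its
  position at that moment; a trajectory's final snapshot opens no visit.
  Visits that never cover one diameter before the window ends carry the
  remaining window length and are counted separately as censored (a 0.3 s
  window necessarily censors platelets trapped in the recirculation
  zones).  The bin value is the mean over visits.
* **RBC volume fraction** is mean RBC count per bin × V_RBC / bin volume,
  using the full domain width as z-extent and clipping to [0, 1].  Cell
  volumes default to literature values V_RBC = 90 µm³, V_PLT = 6 µm³ and
  are configurable.
* **Cell-depleted layer (CFL)**: per x-column, the distance from the wall
  at which the volume fraction first exceeds c·φ_ref, with c = 1% and
  φ_ref the column maximum ("relative" mode, the default) or 1
  ("absolute" mode) — the 1%-of-volume-fraction rule is ambiguous between
  the two, so both are exposed.  The crossing is interpolated between bin
  centres and capped at the local lumen half-height; empty columns return
  the cap, flagged.  With a sharp depletion edge and a 1% threshold the
  estimate lands near the foot of the edge, i.e. systematically up to one
  bin below the true width; the recovery contract is therefore "within
  one bin width", and holds for prescribed widths of 3, 5 and 8 µm at
  2 µm bins.

## Occlusion pipeline

**Mass balance.**  The corrected trace is mass − (reference − reference₀),
with the evaporation reference linearly resampled onto the trace's time
grid.  Flow rate is the least-squares slope over a pre-occlusion window
(≥5 samples) divided by the fluid density.  Occlusion is detected on the
corrected trace: the plateau is the contiguous run of samples within ε of
the global maximum (ε defaults to twice the 1 mg balance resolution; the
original protocol states neither ε nor the resolution).  A plateau bounded
inside the record returns its temporal centre; a plateau running into the
last sample returns its start, since its end was never observed; a trace
still rising at its last sample (a shorter-than-3-sample run at the
maximum touching the end) is flagged right-censored.  The detected time
maps to the nearest camera frame.

**Images.**  The occlusion frame's pixel columns are averaged over the
annotated channel width, giving I(x).  PRP clots are darker than
background where WB clots are brighter, so PRP profiles are inverted
(default: invert first, then min–max normalize; the reverse order is
exposed, and for min–max normalization the two orders coincide).  Profiles
are normalized per experiment over the annotated span only and aligned so
x = 0 at the upstream corner of the stenotic throat (the downstream border
of the contraction); the occlusion distance is the x of the global
intensity maximum, first index on ties (flagged).  A contrast-free frame
yields a flagged degenerate profile and no distance.  The interactive
corner-clicking step of the original protocol becomes a JSON annotation of
4 (single-line contraction) or 8 ordered (x, z) pixel pairs; pixel
coordinates denote pixel centres, and the metre scale comes from the
sidecar pixel size or from the annotated corner spacing against the known
throat length.  `aggregate_profiles` interpolates aligned profiles onto
their common support and averages pointwise, with an optional per-profile
mean shift for cross-modality shape comparison.

## Synthetic data

The generators prescribe the *statistics* the estimators must recover;
they do not simulate cell mechanics.

**Cell snapshots.**  RBC y-positions are drawn from a density that is zero
within δ* of each wall and uniform in the core; platelet y-positions from
a piecewise density: zero in a 0.5 µm platelet-free sliver at each wall
(a platelet-free plasma layer appears in both WB and PRP), an enhancement
factor f in the next 5 µm (f = 2 for WB margination, 1 for PRP), uniform
elsewhere, plus optional Gaussian bands at ¼ and ¾ height mimicking the
volume-exclusion bands seen in cell-resolved runs.  x and z are uniform
and periodic; counts default to the reference cell-resolved run (10 703
RBCs, 952 platelets; 941 platelets in the PRP preset).  Positions are
advected by the supplied flow field with Gaussian jitter in x and z
(D = 10⁻¹² m²/s by default); y is held stationary — y-jitter is opt-in —
so the prescribed margination and depletion profiles are exactly the
series' stationary distributions rather than decaying transients.  With
equal platelet counts forced into differently normalized densities, the
measured WB/PRP wall-band flux ratio is f·Z_PRP/Z_WB ≈ 1.87 rather than
exactly f; the recovery contract (2 ± 15%) accounts for this.

**Mass traces.**  mass(t) = ρ·V(t) + r_evap·t + noise, where the
programmed flow holds Q until a short linear ramp (default 0.5 s) brings
it to zero at the occlusion time, after which V plateaus; the paired
reference carries the same drift with independent noise.  Balance noise
defaults to 2 × 10⁻⁷ kg — electronic noise a factor ~5 below the 1 mg
display resolution, which keeps the plateau-start sample identifiable to
± one sample under the ε = 2 mg plateau rule.  At noise equal to the full
resolution the plateau run fragments and no detector honouring the raw
plateau definition can do better.

**Image stacks.**  Frames at 2 Hz cover the chamber length and width plus
a PDMS margin; a separable-Gaussian clot (σ_x = 20 µm, σ_z = 100 µm) grows
linearly in amplitude (to 0.4 of dynamic range) until the occlusion time,
added for WB and subtracted for PRP over a 0.5 background.  Stenosis
border ticks are drawn in the margin rows *outside* the annotated channel
span, so width-averaged profiles contain channel signal only — this makes
WB and PRP renderings of the same clot yield identical profiles after
inversion (min–max normalization maps I to 1−I under a sign flip when the
background is affine).  Per-pixel noise defaults to 0.005 of dynamic
range: averaging ~240 channel rows leaves a column noise of ~3 × 10⁻⁴,
against adjacent-column peak contrast of ~10⁻³ after z-averaging the
clot — the raw-argmax peak rule then localizes to ± one pixel with ≥3σ
margin, which a 1% noise floor would not give.  Corner annotations are
emitted at exact (half-pixel-corrected) coordinates.

All generators are deterministic per seed (bit-identical reruns) and every
snapshot carries exactly N_RBC + N_PLT records.

## What passing tests do and do not show

The synthetic inputs share the real data's structure (marginated wall
bands, depleted layers, plateauing mass traces, modality-dependent clot
contrast) but none of its physics: no cell deformation or lift, no
shear-dependent margination dynamics, no clot growth feedback, no uneven
illumination or drift in the images.  Green tests therefore certify the
*estimators* — that each pipeline stage recovers what its input encodes,
at known noise — not that the generators' defaults reproduce any
particular laboratory's numbers.  Quantities that require the original
cell-resolved cluster runs or raw experiment images (absolute flux levels,
shear fluctuation bands, continuum-vs-cellular gaps, measured occlusion
distances) are treated as context, not as oracles.

## Problem sizes used

Routine tests solve at Δx = 2 µm (≈19 000 cells, under a second each);
shear-bound checks and the acceptance computation use Δx = 1 µm (≈64 000
fluid cells, ~10 s).  Statistical recovery tests run 10⁴ platelets over
0.3 s of snapshots, where the sampling error of the wall-band flux ratio
is a few percent; the 952-platelet study-scale count carries ~15% ratio
noise and is used where only determinism or bookkeeping is under test.
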