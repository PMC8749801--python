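# Methods

## What is being modelled

A proton minibeam arc plan is an ordered set of equally spaced, equally
weighted treatment fields, each delivering a spread-out Bragg peak
through a multi-slit collimator, rotated about the axis perpendicular to
the slits (the *modulation axis*, `x`).  Because every field's rigid
transform is a rotation about `x`, the modulation coordinate of any
point is invariant across fields: the peak/valley combs of all arrays
co-align, which is the mechanism that preserves spatial fractionation
over the arc.  The package evaluates the dose and dose-averaged LET of
such plans on a synthetic water head phantom and computes the standard
plan-comparison metrics of spatially fractionated radiotherapy.

Coordinate conventions: millimetre world units, origin at the isocenter
(phantom center); `z` is the beam axis at gantry angle 0 (beam travels
along −z, entering from the +z surface); positive gantry angles rotate
counterclockwise in the y–z plane looking down +x.

## Phantom

A homogeneous water sphere (default radius 80 mm, a head-like size) in
air, with a spherical PTV (20 or 30 mm diameter) at its center and
"normal tissue" defined as body minus PTV.  Relative stopping power is
stored on a voxel grid (default 0.1 mm along the modulation axis, 1 mm
elsewhere) so heterogeneous phantoms can be introduced later; the
analytic sphere surface is used for exact skin-entry calculations.  The
grid is exported as NIfTI.  Grids coarser than 0.5 mm along `x` are
refused — they cannot represent the 400 μm slit pattern — but profiles
and PVDR are always computed by analytic point sampling, never from a
scored grid.

The phantom deliberately omits anatomy: skull, air cavities, and the
off-center tumor positions of real patients.  Findings here are
geometric/dosimetric statements about arc composition, not predictions
for a specific anatomy.

## Beam model

All depth quantities are water-equivalent depths; upstream material only
shifts the depth origin.

* **Range–energy**: Bragg–Kleeman `R = αE^p` with α = 0.022 mm·MeV⁻ᵖ,
  p = 1.77 (fits measured proton ranges in water to ~1 % over
  70–235 MeV; R(100 MeV) = 76.3 mm).  The inverse is closed-form; both
  directions refuse energies beyond the 235 MeV cyclotron bound.
* **Bragg curve**: continuous-slowing-down stopping power
  `S(E) = E^(1−p)/(pα)` evaluated along the residual range, multiplied
  by a linear nuclear-removal fluence factor (0.0012/mm), then
  Gaussian-smeared with σ combining range straggling
  (0.012·R^0.935, cm units) and the beamline momentum spread.  The
  default fractional energy spread (0.005) puts the distal 80–20 %
  falloff at 3.4 mm for 150 MeV, inside the 2–4 mm design window.
  Resulting peak-to-entrance ratios are 4–5 for pristine peaks.
* **LET_d**: `dose` and `dose × LET` are smeared with the same kernel
  and their ratio taken, which preserves the sharp LET rise at the
  distal edge.  The track LET is the same stopping-power expression,
  floored at the 0.5 MeV value (~44 keV/μm) where the power law
  diverges.  Entrance LET_d at 150 MeV is 0.54 keV/μm, matching the
  stopping power there.
* **Lateral spread**: Fermi–Eyges transport of a Highland-type
  scattering power `T = (E_s/pv)²/X₀` with X₀ = 360.8 mm.  The single
  calibration constant E_s = 12.5 MeV is chosen so σ at the end of range
  is ≈ 2.1–2.3 % of the range across therapeutic energies (the standard
  rule of thumb); the package verifies its own table against direct
  quadrature.  On top of the MCS growth, beamlets carry an initial spot
  size (0.3 mm) and divergence (3.5 mrad ≈ slit width / collimator
  thickness, the angular acceptance of a 400 μm slit in a 65 mm block).
* **Nuclear halo**: a configurable fraction (default 0.10) of each
  contribution is carried by a second Gaussian 3× wider than the
  primary, standing in for the large-angle secondary halo that fills
  valleys at depth.
* **Range shifter**: 30 mm PMMA modelled as 34.8 mm water (WET factor
  1.16) added to every ray's depth bookkeeping; straggling accumulated
  in the shifter is inherited by using the machine-energy curve shifted,
  while lateral growth in tissue restarts from the post-shifter energy
  (the collimator re-defines the spatial distribution downstream of the
  shifter).
* **SOBP**: energy layers spaced 2 mm in range from the distal to the
  proximal PTV surface, weighted by non-negative least squares against a
  unit plateau between the proximal and distal layers' *peak positions*.
  Achieved ripple ≈ 1 %; construction refuses configurations whose
  ripple exceeds 3 %.  Every field of a plan uses the same layer stack —
  legitimate here because the phantom is spherically symmetric about the
  isocenter.

## Collimator and field footprint

The collimator is reduced to its entrance fluence pattern: a comb of
400 μm top-hats on the slit pitch, convolved with a single effective
penumbra σ (0.2 mm) that absorbs collimator scatter, slit-edge effects
and the 50 mm air gap.  Brass transport is not modelled.

The treatment planning system's per-angle field-area optimisation is
replaced by a fixed rule: slits whose centers project within
`PTV radius + margin` of the isocenter are open (margin 2 mm → 7 slits
for the 20 mm PTV at 4 mm pitch, 9 slits for the 30 mm PTV), and the
scan envelope across the slits is `PTV diameter + 2·margin` wide.  This
rule reproduces the field-size dependence of the overlap behaviour
(larger targets → wider slabs → overlap at shallower depths).

## Dose engine

Dose is a sum over fields and energy layers evaluated directly at query
points; there is no rotated-grid resampling.  Valley dose arises only
from Gaussian lateral spread plus the configurable halo — no
neutron/room background — so absolute normal-tissue PVDR magnitudes are
regression-tracked rather than treated as patient-equivalent.  Points
outside the body receive zero dose (air transport ignored).  An optional
stochastic mode multiplies scored voxels by seeded Poisson-like noise
(relative σ ∝ 1/√dose, 2 % at the grid maximum) purely to exercise the
statistical-uncertainty diagnostic, which stays below 3 % by
construction.

## Metrics conventions

* Every plan is normalized to mean PTV dose 1 before comparison; PVDR
  and LET_d are ratios and unaffected.
* PVDR uses the central peak over the mean of its two adjacent valleys,
  with extrema located nearest slit centers / midpoints; flat (broad
  field) profiles have PVDR 1 by convention.
* Dose reduction is `100·(A−B)/A` per depth with the single-array plan
  as reference A; "averaged along the proton range" means the unweighted
  mean from the skin to the proximal PTV surface; the peak line is the
  central slit axis, the valley line the adjacent mid-valley line.
* Mean LET_d is dose-weighted over the structure (an arithmetic variant
  is one flag away).
* Integral doses are reported normalized so each plan's PTV integral
  dose is 1.

## Problem sizes

Default study runs use analytic sampling: PTV normalization on a
(0.5, 1, 1) mm point lattice (~8300 points), lateral profiles at
0.02 mm pitch, depth curves at 0.5 mm pitch, and volume statistics on a
(1, 2, 2) mm scoring grid (finer along the modulation axis in the
acceptance/property suites where the comb must not alias).  A full
three-plan case completes in about two minutes on one CPU.

## Known limitations and observed deviations

The engine reproduces the geometric findings quantitatively at shallow
depth (the 1 − 1/N entrance reduction is exact to <2 %) and the target
homogenization closely (PVDR 1.06–1.27 across the PTV depth span; mean
LET_d in the PTV 3.3 keV/μm).  Two systematic deviations from the
patient-CT Monte Carlo study are known and expected:

1. **Near-target reduction.**  With uniform field weights and a hard
   24 mm scan envelope, fields beyond ~±60° only partially cover points
   a few millimetres proximal to the PTV, so the arc's dose reduction
   there reads ~20 % rather than the published ~5 %.  The decay of the
   reduction toward the PTV is monotone, as published.  A spot-map
   optimizer (out of scope) would both flatten the PTV edge dose and
   effectively widen the per-angle field area, moving this value down.
2. **Angular-separation slope and broad-field integral dose.**  The same
   sharp-envelope surrogate makes the overlap-onset response slightly
   steeper than measured (≈10.6 pp per 5° of separation vs ≈7), and the
   equal-weight broad-field (PAT) variant deposits ~15 % less
   normal-tissue integral dose per unit PTV dose than the minibeam plans
   (published gap ≈6 %, within MC uncertainty); the minibeam pair itself
   agrees to 0.2 %.  Both trace to the absence of per-angle field-area
   and spot-weight optimisation, which is a declared non-goal.

The c-t-c invariance of the dose reduction holds within 3 percentage
points on the peak lines over the full normal-tissue depth range; valley
lines drift to 3.7 pp in the final few millimetres before the PTV, where
valley filling is strongly pitch-dependent in this engine.
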