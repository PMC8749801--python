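# pmbat — analytic dosimetry for proton minibeam arc therapy

Proton minibeam radiation therapy (pMBRT) delivers dose through an array
of sub-millimetre planar beams (400 μm slits, 2–4 mm apart), producing a
comb of high-dose *peaks* and low-dose *valleys* that normal tissue
tolerates far better than a uniform field.  Proton arc therapy (PAT)
spreads the entrance dose of many broad fields over a gantry arc.
**pMBAT** combines the two: minibeam arrays delivered from many arc
angles, with the gantry rotating about the axis *perpendicular to the
slits* so that the peak/valley combs of all fields co-align and the
spatial fractionation survives the arc.

This package is a desk-scale toolkit for studying that combination. It
provides:

* a synthetic water-equivalent head phantom (80 mm sphere, spherical
  PTV at its center) standing in for a patient CT,
* an analytic proton pencil-beam model bounded by a 235 MeV cyclotron —
  Bragg–Kleeman range–energy `R = αE^p`, straggled Bragg curves,
  Fermi–Eyges lateral spread, dose-averaged LET, SOBP construction by
  non-negative least squares,
* the multi-slit collimator (15 slits, 400 μm × 5.6 cm, c-t-c 4/2.8/2 mm,
  30 mm PMMA range shifter) as a blurred transmission comb,
* an on-demand dose/LET engine: for a field at gantry angle θ,
  `D(p) = Σ_layers w·B(t) · X(x; σ(t)) · Y(y; σ(t))`, where `t` is the
  water-equivalent depth along the ray, `X` the slit comb convolved with
  the lateral spread, `Y` the scan envelope — evaluable at arbitrary
  points, so the 0.4 mm beam structure is never grid-limited,
* plan metrics: peak-to-valley dose ratio (PVDR, central-peak over
  adjacent-valley convention), peak/valley depth-dose, percent dose
  reduction between plans, DVH, integral dose, dose-weighted mean LET_d,
  and a statistical-uncertainty diagnostic for stochastic grids,
* a registry of the twelve study plan configurations (number of arrays,
  angular separation, c-t-c distance, PTV size) and a CLI to run them.

All plan comparisons are made after normalizing each plan to the same
mean PTV dose.

## Worked example

```python
import numpy as np
from pmbat import (DoseSampler, build_case_plans, depth_dose_curve,
                   dose_reduction, lateral_profile, make_head_phantom,
                   normalize_to_ptv_mean, ptv_sample_points, pvdr)

phantom = make_head_phantom()                    # 80 mm water sphere
spec, ptv, plans = build_case_plans(1)           # 13 arrays / 15° / 4 mm / 20 mm PTV
pts = ptv_sample_points(ptv)
samplers = {name: normalize_to_ptv_mean(DoseSampler(plan, phantom), pts)
            for name, plan in plans.items()}

red = dose_reduction(depth_dose_curve(samplers["pmbrt"], "peak"),
                     depth_dose_curve(samplers["pmbat"], "peak"))
print(f"peak-line reduction at 5 mm: {red.at(5.0):.1f} %")
print(f"max PVDR inside the PTV: "
      f"{max(pvdr(lateral_profile(samplers['pmbat'], d)) for d in np.arange(70, 91)):.3f}")
```

prints

```
peak-line reduction at 5 mm: 92.3 %
max PVDR inside the PTV: 1.272
```

Reading: spreading the single array over thirteen arc angles cuts the
shallow normal-tissue dose by 92 % (the geometric limit is
1 − 1/13 ≈ 92.3 % wherever the field slabs do not yet overlap), while
inside the target the minibeam pattern has washed out to a
quasi-homogeneous dose — PVDR falls from 1.27 at the proximal PTV
surface to 1.06 at its distal surface.

The same study is available from the shell:

```bash
pmbat run case 1 --outdir out/case1        # tables + manifest
pmbat run sweep separation --outdir out    # cases 5-7, reduction curves
```

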