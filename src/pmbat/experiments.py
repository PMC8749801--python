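"""End-to-end study runs: one case, or one parameter sweep.

``run_case`` builds the pMBAT, single-array pMBRT and PAT variants of a
study case on the synthetic head phantom, normalizes every plan to mean
PTV dose 1, and computes the full metrics bundle.  ``run_sweep``
reproduces the four parameter sweeps (number of arrays, angular
separation, c-t-c distance, PTV size) as dose-reduction-vs-depth tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beam import BeamModelParams, DEFAULT_PARAMS
from .engine import (
    DoseSampler,
    add_stochastic_noise,
    normalize_to_ptv_mean,
    ptv_sample_points,
)
from .geometry import build_case_plans, case_registry
from .grids import GridSpec
from .metrics import (
    MetricsBundle,
    depth_dose_curve,
    dose_reduction,
    dvh,
    global_uncertainty,
    integral_dose,
    lateral_profile,
    mean_letd,
    pvdr,
)
from .phantom import make_head_phantom, make_ptv

log = logging.getLogger("pmbat")

__all__ = ["RunManifest", "run_case", "run_sweep", "SWEEPS"]

#: the four parameter sweeps and the cases they compare
SWEEPS = {
    "arrays": (1, 2, 3, 4),
    "separation": (5, 6, 7),
    "ctc": (8, 9, 10),
    "ptv": (11, 12),
}


@dataclass
class RunManifest:
    """Everything needed to reproduce one run bit-exactly."""

    cases: tuple
    phantom_radius: float
    beam_params: dict
    seed: int | None
    engine_mode: str
    grid_spacing: tuple
    outdir: str | None
    version: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _normalized_samplers(case_number, phantom, params):
    spec, ptv, plans = build_case_plans(case_number, phantom, params)
    pts = ptv_sample_points(ptv)
    samplers = {
        name: normalize_to_ptv_mean(DoseSampler(plan, phantom, params), pts)
        for name, plan in plans.items()
    }
    return spec, ptv, samplers


def _body_grid_spec(phantom, spacing):
    return GridSpec.centered_cube(phantom.radius, spacing)


def _structure_masks(phantom, ptv, spec):
    pts = spec.voxel_centers()
    body = phantom.contains(pts).reshape(spec.dims)
    inptv = ptv.contains(pts).reshape(spec.dims)
    return body & inptv, body & ~inptv


def run_case(
    case_number: int,
    phantom_radius: float = 80.0,
    params: BeamModelParams = DEFAULT_PARAMS,
    outdir=None,
    seed: int | None = None,
    stochastic: bool = False,
    noise_level: float = 0.02,
    grid_spacing=(1.0, 2.0, 2.0),
    with_volumes: bool = False,
    pvdr_depth_step: float = 1.0,
) -> MetricsBundle:
    """Run one study case end to end and return its metrics bundle.

    All three plan variants are normalized to mean PTV dose 1 before any
    comparison.  ``grid_spacing`` controls the scoring grid used for
    DVH, integral-dose and LET volume statistics (profiles and depth
    curves are sampled analytically and do not depend on it).
    """
    t0 = time.time()
    phantom = make_head_phantom(radius=phantom_radius)
    spec, ptv, samplers = _normalized_samplers(case_number, phantom, params)
    log.info("case %d: plans built and normalized (%.1fs)", case_number, time.time() - t0)

    # PVDR vs depth (pMBAT and single-array pMBRT), through the PTV span
    skin_to_iso = phantom.radius
    rows = []
    depths = np.arange(5.0, skin_to_iso + ptv.radius + 1e-9, pvdr_depth_step)
    for name in ("pmbat", "pmbrt"):
        for d in depths:
            prof = lateral_profile(samplers[name], d)
            region = "ptv" if abs(d - skin_to_iso) <= ptv.radius else "normal"
            rows.append(
                {"plan": name, "depth_mm": d, "pvdr": pvdr(prof), "region": region}
            )
    pvdr_table = pd.DataFrame(rows)
    log.info("case %d: PVDR table done (%.1fs)", case_number, time.time() - t0)

    # peak/valley depth-dose curves and reductions vs single-array pMBRT
    curves = {}
    for name, s in samplers.items():
        for line in ("peak", "valley"):
            curves[(name, line)] = depth_dose_curve(s, line=line)
    depth_frames = []
    for (name, line), c in curves.items():
        depth_frames.append(
            pd.DataFrame(
                {"plan": name, "line": line, "depth_mm": c.depths, "dose": c.values}
            )
        )
    red_frames = []
    for line in ("peak", "valley"):
        red = dose_reduction(curves[("pmbrt", line)], curves[("pmbat", line)])
        red_frames.append(
            pd.DataFrame(
                {
                    "comparison": "pmbat_vs_pmbrt",
                    "line": line,
                    "depth_mm": red.depths,
                    "reduction_pct": red.values,
                }
            )
        )
    log.info("case %d: depth curves done (%.1fs)", case_number, time.time() - t0)

    # volume statistics on a scoring grid
    gspec = _body_grid_spec(phantom, grid_spacing)
    ptv_mask, nt_mask = _structure_masks(phantom, ptv, gspec)
    dvh_rows, integrals, lets = [], {}, {}
    uncertainty = None
    rng = np.random.default_rng(seed)
    for name, s in samplers.items():
        grid = s.score_grid(gspec)
        if stochastic:
            realizations = [
                add_stochastic_noise(grid, rng, noise_level) for _ in range(3)
            ]
            if name == "pmbat":
                uncertainty = global_uncertainty(realizations)
            grid = realizations[0]
        ptv_int = integral_dose(grid, ptv_mask)
        integrals[name] = {
            "ptv": 1.0,
            "normal_tissue": integral_dose(grid, nt_mask) / ptv_int,
        }
        for sname, mask in (("ptv", ptv_mask), ("normal_tissue", nt_mask)):
            curve = dvh(grid, mask, structure=sname)
            dvh_rows.append(
                pd.DataFrame(
                    {
                        "plan": name,
                        "structure": sname,
                        "dose": curve.thresholds,
                        "volume_fraction": curve.volume_fraction,
                    }
                )
            )
        if name in ("pmbat", "pmbrt", "pat"):
            let_grid = s.score_grid(gspec, quantity="letd")
            lets[name] = {
                sname: mean_letd(grid.values, let_grid.values, mask)
                for sname, mask in (("ptv", ptv_mask), ("normal_tissue", nt_mask))
            }
        if with_volumes and outdir is not None:
            voldir = Path(outdir) / "volumes"
            voldir.mkdir(parents=True, exist_ok=True)
            grid.to_nifti(voldir / f"{name}_dose.nii.gz")
        log.info("case %d: %s volume metrics done (%.1fs)", case_number, name, time.time() - t0)

    bundle = MetricsBundle(
        case_number=case_number,
        pvdr_vs_depth=pvdr_table,
        depth_curves=pd.concat(depth_frames, ignore_index=True),
        reduction_curves=pd.concat(red_frames, ignore_index=True),
        dvh_table=pd.concat(dvh_rows, ignore_index=True),
        integral_doses=integrals,
        mean_letd_values=lets,
        global_uncertainty_value=uncertainty,
    )
    if outdir is not None:
        outdir = Path(outdir)
        tabledir = outdir / "tables"
        bundle.write(tabledir)
        RunManifest(
            cases=(case_number,),
            phantom_radius=phantom_radius,
            beam_params=asdict(params),
            seed=seed,
            engine_mode="stochastic" if stochastic else "deterministic",
            grid_spacing=tuple(grid_spacing),
            outdir=str(outdir),
            version=__version__,
        ).write(outdir / "manifest.json")
    return bundle


def reduction_curves_for_case(
    case_number: int,
    phantom_radius: float = 80.0,
    params: BeamModelParams = DEFAULT_PARAMS,
    pitch: float = 0.5,
):
    """Peak- and valley-line reduction curves of one case vs single-array.

    Cheaper than :func:`run_case` (no volume scoring); used by the
    sweeps.  Returns ``{(line): DepthCurve}`` plus the case spec.
    """
    phantom = make_head_phantom(radius=phantom_radius)
    spec, ptv, samplers = _normalized_samplers(case_number, phantom, params)
    out = {}
    for line in ("peak", "valley"):
        ref = depth_dose_curve(samplers["pmbrt"], line=line, pitch=pitch)
        cmp_ = depth_dose_curve(samplers["pmbat"], line=line, pitch=pitch)
        out[line] = dose_reduction(ref, cmp_)
    return spec, ptv, out


def run_sweep(
    parameter: str,
    phantom_radius: float = 80.0,
    params: BeamModelParams = DEFAULT_PARAMS,
    outdir=None,
) -> pd.DataFrame:
    """Dose-reduction-vs-depth curves for one of the four parameter sweeps.

    Returns a long-format table with one curve per swept case and line
    (peak / valley).
    """
    if parameter not in SWEEPS:
        raise ValueError(
            f"unknown sweep {parameter!r}; valid sweeps: {sorted(SWEEPS)}"
        )
    frames = []
    for case_number in SWEEPS[parameter]:
        spec, ptv, curves = reduction_curves_for_case(
            case_number, phantom_radius, params
        )
        for line, curve in curves.items():
            frames.append(
                pd.DataFrame(
                    {
                        "sweep": parameter,
                        "case": case_number,
                        "n_arrays": spec.n_arrays,
                        "angular_separation_deg": spec.angular_separation,
                        "ctc_mm": spec.ctc,
                        "ptv_diameter_mm": spec.ptv_diameter,
                        "line": line,
                        "depth_mm": curve.depths,
                        "reduction_pct": curve.values,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"sweep_{parameter}.csv", index=False)
    return table


def range_averaged_reduction(curve, proximal_depth: float) -> float:
    """Unweighted mean of a reduction curve from the skin to ``proximal_depth``.

    Operationalizes "averaged along the proton range" for the
    angular-separation sweep: the average runs from the surface to the
    proximal PTV surface.
    """
    sel = (curve.depths >= 0) & (curve.depths <= proximal_depth)
    vals = curve.values[sel]
    return float(np.nanmean(vals))
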