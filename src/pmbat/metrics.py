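"""Dosimetric figures of merit for spatially fractionated arc plans.

Implements lateral peak/valley profiles, PVDR (central-peak over
adjacent-valley convention), peak/valley depth-dose lines, dose
reduction between plans, cumulative DVH, integral dose, dose-weighted
mean LET_d and the statistical-uncertainty diagnostic for stochastic
scoring grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import DoseSampler
from .grids import VoxelGrid

__all__ = [
    "LateralProfile",
    "DepthCurve",
    "DVHCurve",
    "MetricsBundle",
    "lateral_profile",
    "pvdr",
    "depth_dose_curve",
    "dose_reduction",
    "dvh",
    "dvh_spread",
    "integral_dose",
    "mean_letd",
    "global_uncertainty",
]

#: relative modulation below which a profile counts as flat (PVDR = 1)
FLAT_TOLERANCE = 1e-3


@dataclass
class LateralProfile:
    """Dose samples along the modulation axis at one depth."""

    positions: np.ndarray
    dose: np.ndarray
    depth: float
    peak_positions: np.ndarray
    peak_doses: np.ndarray
    valley_positions: np.ndarray
    valley_doses: np.ndarray

    @property
    def is_flat(self) -> bool:
        top = self.dose.max()
        return top <= 0 or (top - self.dose.min()) / top < FLAT_TOLERANCE


def _extremum_near(positions, dose, center, half_window, mode):
    sel = np.abs(positions - center) <= half_window
    if not np.any(sel):
        return None
    idx = np.flatnonzero(sel)
    local = dose[idx]
    j = idx[np.argmax(local) if mode == "max" else np.argmin(local)]
    return positions[j], dose[j]


def lateral_profile(
    sampler: DoseSampler,
    depth: float,
    slit_positions=None,
    y: float = 0.0,
    pitch: float = 0.02,
    span: float | None = None,
) -> LateralProfile:
    """Sample the plan dose across the modulation axis at ``depth`` mm.

    The line runs through ``x`` at world ``(x, y, R - depth)`` — the
    central field's axis at gantry angle 0.  Peaks are located as the
    extrema nearest each slit-center projection, valleys nearest each
    slit midpoint; on a flat (broad-field) profile peaks and valleys
    coincide with the overall dose and PVDR is 1 by convention.
    """
    radius = sampler.phantom.radius
    if not 0 <= depth <= 2 * radius:
        raise ValueError("depth must lie within the phantom")
    if slit_positions is None:
        f0 = sampler.plan.fields[0]
        if f0.collimated:
            slit_positions = (
                np.asarray(f0.slits)
                if f0.slits is not None
                else np.array([0.0])
            )
        else:
            slit_positions = np.array([0.0])
    slit_positions = np.sort(np.asarray(slit_positions, dtype=float))
    if span is None:
        pad = (
            np.diff(slit_positions).mean() if len(slit_positions) > 1 else 4.0
        )
        span = (slit_positions[-1] - slit_positions[0]) / 2.0 + pad
    xs = np.arange(-span, span + pitch / 2, pitch)
    mid = (slit_positions[0] + slit_positions[-1]) / 2.0
    pts = np.column_stack(
        [mid + xs, np.full_like(xs, y), np.full_like(xs, radius - depth)]
    )
    dose = sampler.dose_at(pts)
    positions = mid + xs
    ctc = np.diff(slit_positions).mean() if len(slit_positions) > 1 else 4.0
    peaks_p, peaks_d, valls_p, valls_d = [], [], [], []
    for c in slit_positions:
        got = _extremum_near(positions, dose, c, ctc / 4.0, "max")
        if got:
            peaks_p.append(got[0])
            peaks_d.append(got[1])
    for c in (slit_positions[:-1] + slit_positions[1:]) / 2.0:
        got = _extremum_near(positions, dose, c, ctc / 4.0, "min")
        if got:
            valls_p.append(got[0])
            valls_d.append(got[1])
    return LateralProfile(
        positions=positions,
        dose=dose,
        depth=float(depth),
        peak_positions=np.array(peaks_p),
        peak_doses=np.array(peaks_d),
        valley_positions=np.array(valls_p),
        valley_doses=np.array(valls_d),
    )


def pvdr(profile: LateralProfile) -> float:
    """Peak-to-valley dose ratio at the center of a lateral profile.

    Ratio of the central peak dose to the mean of its two adjacent
    valley doses.  A flat profile has PVDR 1 by convention.
    """
    if profile.is_flat or len(profile.valley_positions) == 0:
        return 1.0
    ic = np.argmin(np.abs(profile.peak_positions))
    c = profile.peak_positions[ic]
    below = profile.valley_doses[profile.valley_positions < c]
    above = profile.valley_doses[profile.valley_positions > c]
    neighbours = [v[-1] if side == "b" else v[0] for side, v in
                  (("b", below), ("a", above)) if len(v)]
    valley = float(np.mean(neighbours))
    if valley <= 0:
        raise ValueError("zero valley dose; PVDR undefined")
    return float(profile.peak_doses[ic] / valley)


@dataclass
class DepthCurve:
    """Values along depth below skin on a stated line."""

    depths: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")

    def at(self, depth) -> np.ndarray:
        return np.interp(depth, self.depths, self.values)


def depth_dose_curve(
    sampler: DoseSampler,
    line: str = "peak",
    x_offset: float | None = None,
    depths=None,
    pitch: float = 0.5,
) -> DepthCurve:
    """Dose vs depth along the central field's peak or valley line.

    ``line="peak"`` follows the central slit axis (x = 0), ``"valley"``
    the adjacent mid-valley line (x = ctc / 2); an explicit ``x_offset``
    overrides both.
    """
    radius = sampler.phantom.radius
    if x_offset is None:
        f0 = sampler.plan.fields[0]
        ctc = f0.collimator.ctc if f0.collimated else 4.0
        if line == "peak":
            x_offset = 0.0
        elif line == "valley":
            x_offset = ctc / 2.0
        else:
            raise ValueError("line must be 'peak' or 'valley'")
    if depths is None:
        depths = np.arange(0.0, radius + pitch / 2, pitch)
    depths = np.asarray(depths, dtype=float)
    pts = np.column_stack(
        [
            np.full_like(depths, x_offset),
            np.zeros_like(depths),
            radius - depths,
        ]
    )
    return DepthCurve(
        depths=depths, values=sampler.dose_at(pts), label=f"{line}@x={x_offset:g}"
    )


def dose_reduction(reference: DepthCurve, comparison: DepthCurve) -> DepthCurve:
    """Percent dose reduction of ``comparison`` relative to ``reference``.

    ``100 * (A - B) / A`` per depth on the reference depth grid
    (comparison linearly resampled); depths where the reference dose is
    zero are masked with NaN.  Both curves are expected to come from
    plans normalized to the same mean PTV dose.
    """
    b = np.interp(reference.depths, comparison.depths, comparison.values)
    a = reference.values
    out = np.full_like(a, np.nan)
    ok = a > 0
    out[ok] = 100.0 * (a[ok] - b[ok]) / a[ok]
    return DepthCurve(
        depths=reference.depths.copy(),
        values=out,
        label=f"reduction[{comparison.label} vs {reference.label}]",
    )


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    thresholds: np.ndarray
    volume_fraction: np.ndarray
    structure: str = ""

    def d_at_volume(self, fraction: float) -> float:
        """Smallest dose received by at least ``fraction`` of the volume."""
        idx = np.flatnonzero(self.volume_fraction >= fraction)
        return float(self.thresholds[idx[-1]]) if len(idx) else 0.0


def dvh(
    dose_grid: VoxelGrid,
    mask: np.ndarray,
    structure: str = "",
    n_bins: int = 512,
) -> DVHCurve:
    """Cumulative volume-fraction-at-or-above-dose curve for one mask."""
    if not np.any(mask):
        raise ValueError("empty structure mask")
    doses = np.sort(np.asarray(dose_grid.values)[mask].ravel())
    top = doses[-1] if doses[-1] > 0 else 1.0
    thresholds = np.linspace(0.0, top, n_bins)
    frac = 1.0 - np.searchsorted(doses, thresholds, side="left") / doses.size
    frac[0] = 1.0
    return DVHCurve(thresholds=thresholds, volume_fraction=frac, structure=structure)


def dvh_spread(curve: DVHCurve) -> float:
    """D5 - D95 dose spread, a steepness measure of a DVH curve."""
    return curve.d_at_volume(0.05) - curve.d_at_volume(0.95)


def integral_dose(dose_grid: VoxelGrid, mask: np.ndarray) -> float:
    """Sum of voxel dose times voxel volume over a mask (unit density)."""
    if not np.any(mask):
        raise ValueError("empty structure mask")
    return float(np.sum(np.asarray(dose_grid.values)[mask]) * dose_grid.voxel_volume)


def mean_letd(
    dose_values: np.ndarray,
    letd_values: np.ndarray,
    mask: np.ndarray | None = None,
    weighting: str = "dose",
) -> float:
    """Mean LET_d over a structure, dose-weighted by default.

    ``weighting="arithmetic"`` averages voxel LET_d without weights (the
    alternative reading of a "mean LET_d" table).
    """
    d = np.asarray(dose_values, dtype=float)
    l = np.asarray(letd_values, dtype=float)
    if mask is not None:
        if not np.any(mask):
            raise ValueError("empty structure mask")
        d, l = d[mask], l[mask]
    if weighting == "dose":
        total = d.sum()
        if total <= 0:
            raise ValueError("zero total dose in structure; mean LET_d undefined")
        return float(np.sum(d * l) / total)
    if weighting == "arithmetic":
        return float(np.mean(l))
    raise ValueError("weighting must be 'dose' or 'arithmetic'")


def global_uncertainty(realizations) -> float:
    """Mean relative statistical uncertainty of the high-dose voxels.

    Given >= 2 independent realizations of a scored grid, computes the
    per-voxel relative standard deviation across the ensemble and
    averages it over voxels whose mean dose exceeds 90 % of the maximum
    mean dose — the usual convergence diagnostic for stochastic dose
    grids.  Identical realizations give exactly 0.
    """
    arrays = [np.asarray(r.values if hasattr(r, "values") else r, dtype=float)
              for r in realizations]
    if len(arrays) < 2:
        raise ValueError("need at least two independent realizations")
    stack = np.stack(arrays)
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    # identical samples are exactly converged (guard float round-off)
    std[stack.max(axis=0) == stack.min(axis=0)] = 0.0
    hot = mean > 0.9 * mean.max()
    if not np.any(hot):
        raise ValueError("no voxels above 90% of the maximum dose")
    return float(np.mean(std[hot] / mean[hot]))


@dataclass
class MetricsBundle:
    """All figures of merit of one study case."""

    case_number: int
    pvdr_vs_depth: pd.DataFrame
    depth_curves: pd.DataFrame
    reduction_curves: pd.DataFrame
    dvh_table: pd.DataFrame | None = None
    integral_doses: dict = field(default_factory=dict)
    mean_letd_values: dict = field(default_factory=dict)
    global_uncertainty_value: float | None = None

    def summary(self) -> dict:
        out = {
            "case": self.case_number,
            "integral_doses": self.integral_doses,
            "mean_letd_kev_um": self.mean_letd_values,
        }
        if self.global_uncertainty_value is not None:
            out["global_uncertainty"] = self.global_uncertainty_value
        if len(self.pvdr_vs_depth):
            ptv_rows = self.pvdr_vs_depth[self.pvdr_vs_depth.region == "ptv"]
            if len(ptv_rows):
                out["max_pvdr_in_ptv"] = float(ptv_rows.pvdr.max())
        return out

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pvdr_vs_depth.to_csv(outdir / "pvdr_vs_depth.csv", index=False)
        self.depth_curves.to_csv(outdir / "depth_dose.csv", index=False)
        self.reduction_curves.to_csv(outdir / "dose_reduction.csv", index=False)
        if self.dvh_table is not None:
            self.dvh_table.to_csv(outdir / "dvh.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=1)
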