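"""Analytic proton pencil-beam physics in water.

The model supplies everything the dose engine needs for a pencil-beam
scanning beamline fed by a 235 MeV cyclotron:

* a Bragg–Kleeman power law ``R = alpha * E**p`` linking beam energy to
  water-equivalent range (alpha = 0.022 mm MeV^-p, p = 1.77, the values
  commonly fitted to measured proton ranges in water),
* a pristine Bragg depth–dose curve built from the continuous-slowing-
  down stopping power ``S(E) = E**(1-p) / (p alpha)`` with a fluence
  attenuation factor for nuclear removals, Gaussian-smeared by range
  straggling plus the beamline momentum spread,
* dose-averaged LET as a function of depth, obtained by smearing both
  ``dose`` and ``dose * LET`` with the same kernel and taking the ratio
  (this keeps the sharp LET rise at the distal edge),
* lateral beam-spread growth from Fermi–Eyges transport of a
  Highland-type scattering power, plus the initial spot size and
  divergence of the collimated beamlets,
* spread-out Bragg peak (SOBP) construction by non-negative least
  squares on a stack of pristine curves.

All depth quantities are water-equivalent depths in mm; upstream
material (the PMMA range shifter) only shifts the depth origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import nnls

__all__ = [
    "BeamModelParams",
    "EnergyLayer",
    "DepthDoseTable",
    "range_from_energy",
    "energy_for_range",
    "bragg_depth_dose",
    "lateral_sigma",
    "lateral_sigma_table",
    "letd_vs_depth",
    "build_sobp",
]

PROTON_MASS_MEV = 938.272
WATER_RADIATION_LENGTH_MM = 360.8


@dataclass(frozen=True)
class BeamModelParams:
    """Tunable parameters of the analytic beam model.

    Attributes
    ----------
    max_energy:
        Cyclotron energy ceiling, MeV.
    range_alpha_mm, range_exponent:
        Bragg–Kleeman coefficients (``R[mm] = alpha * E[MeV]**p``).
    initial_sigma:
        Gaussian beamlet size at the patient surface, mm.  For the slit
        geometry this is the residual spot blur on top of the collimator
        penumbra.
    initial_divergence:
        Angular spread of the beamlets entering the patient, rad.  The
        65 mm-deep slits act as angular collimators, so the transmitted
        divergence is of order slit_width / thickness (~4 mrad).
    scattering_es_mev:
        Effective scattering energy E_s of the Highland-type scattering
        power ``T = (E_s / pv)^2 / X0``.  12.5 MeV reproduces the usual
        sigma(R) ~ 2.1 % of range rule for therapeutic energies.
    nuclear_halo_fraction:
        Fraction of the local dose carried by a broad secondary-particle
        halo (second Gaussian); fills valleys at depth.
    halo_sigma_scale:
        Halo width as a multiple of the primary lateral sigma.
    energy_spread:
        Relative (1-sigma) energy spread of the beamline.
    fluence_loss_per_mm:
        Linear nuclear-removal coefficient of the primary fluence.
    pmma_thickness_mm, pmma_wet_factor:
        Range shifter: physical thickness and water-equivalent-thickness
        ratio; the product is added to every ray's depth bookkeeping.
    depth_step:
        Sampling pitch of the internal depth tables, mm.
    """

    max_energy: float = 235.0
    range_alpha_mm: float = 0.022
    range_exponent: float = 1.77
    initial_sigma: float = 0.3
    initial_divergence: float = 0.0035
    scattering_es_mev: float = 12.5
    nuclear_halo_fraction: float = 0.10
    halo_sigma_scale: float = 3.0
    energy_spread: float = 0.005
    fluence_loss_per_mm: float = 0.0012
    pmma_thickness_mm: float = 30.0
    pmma_wet_factor: float = 1.16
    depth_step: float = 0.1

    def __post_init__(self) -> None:
        if self.max_energy > 235.0:
            raise ValueError("max_energy cannot exceed the 235 MeV cyclotron bound")
        if self.range_alpha_mm <= 0 or self.range_exponent <= 0:
            raise ValueError("range-energy coefficients must be positive")
        if not 0 <= self.nuclear_halo_fraction <= 0.2:
            raise ValueError("nuclear halo fraction must lie in [0, 0.2]")

    @property
    def shifter_wet_mm(self) -> float:
        """Water-equivalent thickness of the PMMA range shifter, mm."""
        return self.pmma_thickness_mm * self.pmma_wet_factor


DEFAULT_PARAMS = BeamModelParams()


@dataclass(frozen=True)
class EnergyLayer:
    """One machine energy with its (dimensionless) fluence weight."""

    energy: float
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("layer weight must be non-negative")


def range_from_energy(energy, params: BeamModelParams = DEFAULT_PARAMS):
    """Water-equivalent range in mm of a proton beam of ``energy`` MeV."""
    e = np.asarray(energy, dtype=float)
    if np.any(e <= 0) or np.any(e > params.max_energy):
        raise ValueError(
            f"energy must lie in (0, {params.max_energy:g}] MeV, got {energy}"
        )
    r = params.range_alpha_mm * e**params.range_exponent
    return float(r) if np.isscalar(energy) else r


def energy_for_range(range_mm, params: BeamModelParams = DEFAULT_PARAMS):
    """Beam energy (MeV) whose water-equivalent range equals ``range_mm``."""
    r = np.asarray(range_mm, dtype=float)
    rmax = params.range_alpha_mm * params.max_energy**params.range_exponent
    if np.any(r <= 0) or np.any(r > rmax):
        raise ValueError(
            f"requested range {range_mm} mm is outside (0, {rmax:.1f}] mm, "
            f"the reach of the {params.max_energy:g} MeV cyclotron"
        )
    e = (r / params.range_alpha_mm) ** (1.0 / params.range_exponent)
    return float(e) if np.isscalar(range_mm) else e


def _stopping_power(energy_mev: np.ndarray, params: BeamModelParams) -> np.ndarray:
    """CSDA stopping power dE/dz in MeV/mm (numerically = keV/um)."""
    p = params.range_exponent
    return energy_mev ** (1.0 - p) / (p * params.range_alpha_mm)


def _residual_energy(residual_range_mm: np.ndarray, params: BeamModelParams) -> np.ndarray:
    return (residual_range_mm / params.range_alpha_mm) ** (1.0 / params.range_exponent)


def range_straggling_sigma(energy: float, params: BeamModelParams = DEFAULT_PARAMS) -> float:
    """Total longitudinal smearing sigma (mm): straggling + energy spread."""
    r = range_from_energy(energy, params)
    # Bortfeld-style straggling parametrisation (0.012 * R^0.935 in cm)
    sigma_straggle = 0.12 * (r / 10.0) ** 0.935
    sigma_espread = params.range_exponent * r * params.energy_spread
    return float(np.hypot(sigma_straggle, sigma_espread))


@dataclass
class DepthDoseTable:
    """Pristine depth-dose and LET_d of one beam energy on a shared grid."""

    energy: float
    range_mm: float
    depth: np.ndarray
    dose: np.ndarray
    letd: np.ndarray

    def dose_at(self, depth_mm) -> np.ndarray:
        return np.interp(depth_mm, self.depth, self.dose, left=self.dose[0], right=0.0)

    def letd_at(self, depth_mm) -> np.ndarray:
        return np.interp(depth_mm, self.depth, self.letd, left=self.letd[0], right=0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"depth_mm": self.depth, "dose": self.dose, "letd_kev_um": self.letd}
        )


# LET is evaluated no lower than this residual energy; below it the
# power-law stopping power diverges unphysically.
_LET_ENERGY_FLOOR_MEV = 0.5


@lru_cache(maxsize=256)
def _bragg_cached(energy: float, params: BeamModelParams) -> DepthDoseTable:
    r = range_from_energy(energy, params)
    sigma = range_straggling_sigma(energy, params)
    h = params.depth_step
    z = np.arange(0.0, r + 6.0 * sigma + 2.0, h)
    t = r - z  # residual range
    inside = t > 0
    d0 = np.zeros_like(z)
    l0 = np.zeros_like(z)
    # evaluate at cell centers to keep the integrable (R - z)^(1/p - 1)
    # singularity finite
    t_eval = np.clip(t[inside], h / 2.0, None)
    e_res = _residual_energy(t_eval, params)
    s = _stopping_power(e_res, params)
    beta = params.fluence_loss_per_mm
    fluence = (1.0 + beta * t_eval) / (1.0 + beta * r)
    d0[inside] = fluence * s
    l0[inside] = _stopping_power(np.clip(e_res, _LET_ENERGY_FLOOR_MEV, None), params)
    sig_pts = sigma / h
    dose = gaussian_filter1d(d0, sig_pts, mode="nearest")
    dose_let = gaussian_filter1d(d0 * l0, sig_pts, mode="nearest")
    letd = np.zeros_like(dose)
    pos = dose > 1e-12 * dose.max()
    letd[pos] = dose_let[pos] / dose[pos]
    return DepthDoseTable(energy=float(energy), range_mm=r, depth=z, dose=dose, letd=letd)


def bragg_depth_dose(
    energy: float, params: BeamModelParams = DEFAULT_PARAMS
) -> DepthDoseTable:
    """Pristine Bragg depth-dose curve (per unit fluence) for one energy.

    The returned table also carries LET_d on the same depth grid so the
    two quantities can never get out of register.
    """
    range_from_energy(energy, params)  # validate bounds
    return _bragg_cached(float(energy), params)


def letd_vs_depth(
    energy: float, params: BeamModelParams = DEFAULT_PARAMS
) -> DepthDoseTable:
    """Dose-averaged LET vs depth; same table as :func:`bragg_depth_dose`."""
    return bragg_depth_dose(energy, params)


def _proton_pv(energy_mev: np.ndarray) -> np.ndarray:
    """Kinematic factor p*v in MeV."""
    m = PROTON_MASS_MEV
    return energy_mev * (energy_mev + 2.0 * m) / (energy_mev + m)


@lru_cache(maxsize=256)
def _sigma_table_cached(energy: float, params: BeamModelParams):
    r = range_from_energy(energy, params)
    h = params.depth_step
    z = np.arange(0.0, r + h, h)
    t = np.clip(r - z, h / 2.0, None)
    e_res = _residual_energy(t, params)
    pv = _proton_pv(e_res)
    scat = (params.scattering_es_mev / pv) ** 2 / WATER_RADIATION_LENGTH_MM
    # Fermi-Eyges: sigma^2(z) = int_0^z (z-u)^2 T(u) du, via cumulative moments
    a0 = np.concatenate([[0.0], np.cumsum((scat[1:] + scat[:-1]) / 2.0) * h])
    m1 = scat * z
    a1 = np.concatenate([[0.0], np.cumsum((m1[1:] + m1[:-1]) / 2.0) * h])
    m2 = scat * z**2
    a2 = np.concatenate([[0.0], np.cumsum((m2[1:] + m2[:-1]) / 2.0) * h])
    var_mcs = z**2 * a0 - 2.0 * z * a1 + a2
    var = (
        params.initial_sigma**2
        + (params.initial_divergence * z) ** 2
        + var_mcs
    )
    return z, np.sqrt(var)


def lateral_sigma_table(energy: float, params: BeamModelParams = DEFAULT_PARAMS):
    """Depth grid and lateral sigma (mm) of a beamlet of ``energy`` MeV."""
    range_from_energy(energy, params)
    return _sigma_table_cached(float(energy), params)


def lateral_sigma(energy: float, depth, params: BeamModelParams = DEFAULT_PARAMS):
    """Lateral Gaussian sigma (mm) at water depth ``depth`` mm.

    Non-decreasing in depth; depths beyond the range are clamped to the
    value at the range (the beam no longer exists there, but callers may
    probe the fringe of the distal falloff).
    """
    z, sig = lateral_sigma_table(energy, params)
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    r = range_from_energy(energy, params)
    out = np.interp(np.minimum(d, r), z, sig, right=sig[-1])
    return float(out) if np.isscalar(depth) else out


def build_sobp(
    proximal_range: float,
    distal_range: float,
    layer_spacing: float = 2.0,
    params: BeamModelParams = DEFAULT_PARAMS,
    flatness_tol: float = 0.03,
) -> list[EnergyLayer]:
    """Select energy layers and weights producing a flat SOBP.

    ``proximal_range`` and ``distal_range`` are water-equivalent depths
    (mm) bounding the flat region.  Weights are fitted by non-negative
    least squares against a unit plateau; the summed curve is required
    to be flat within ``flatness_tol`` over the span.  The weights are
    scaled so the plateau mean is 1 (per unit fluence of the distal
    layer's curve normalisation).
    """
    if proximal_range > distal_range:
        raise ValueError("proximal_range must not exceed distal_range")
    if layer_spacing <= 0:
        raise ValueError("layer_spacing must be positive")
    e_dist = energy_for_range(distal_range, params)  # validates reach
    if proximal_range == distal_range:
        return [EnergyLayer(energy=e_dist, weight=1.0)]
    ranges = np.arange(distal_range, proximal_range - 1e-9, -layer_spacing)
    if proximal_range - ranges[-1] < -0.25 * layer_spacing:
        ranges = np.append(ranges, proximal_range)
    energies = energy_for_range(ranges, params)
    tables = [bragg_depth_dose(float(e), params) for e in energies]
    # the flat region is bounded by the proximal and distal layers' peak
    # positions (a pristine peak sits ~1 straggling sigma short of its range)
    peak_lo = tables[-1].depth[np.argmax(tables[-1].dose)]
    peak_hi = tables[0].depth[np.argmax(tables[0].dose)]
    zfit = np.arange(peak_lo, peak_hi + 1e-9, 0.25)
    design = np.stack([tab.dose_at(zfit) for tab in tables], axis=1)
    scale = design.max()
    weights, _ = nnls(design / scale, np.ones_like(zfit))
    weights /= scale
    combined = design @ (weights * scale) / scale
    plateau = combined.mean()
    ripple = np.max(np.abs(combined - plateau)) / plateau
    if ripple > flatness_tol:
        raise ValueError(
            f"SOBP ripple {100 * ripple:.1f}% exceeds {100 * flatness_tol:.0f}%; "
            f"use a finer layer_spacing than {layer_spacing:g} mm"
        )
    weights = weights / plateau  # plateau -> 1
    return [
        EnergyLayer(energy=float(e), weight=float(w))
        for e, w in zip(energies, weights)
        if w > 0
    ]


def sobp_depth_dose(layers, depth, params: BeamModelParams = DEFAULT_PARAMS):
    """Summed depth-dose of a list of :class:`EnergyLayer` at ``depth`` mm."""
    d = np.zeros_like(np.asarray(depth, dtype=float))
    for layer in layers:
        d = d + layer.weight * bragg_depth_dose(layer.energy, params).dose_at(depth)
    return d
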