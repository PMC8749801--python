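"""Arc plan construction and the study-case registry.

A minibeam arc plan is an ordered set of equally spaced fields rotated
about the modulation axis (x).  Rotating about the axis perpendicular to
the slits is the mechanism that preserves spatial fractionation: the
modulation coordinate of every point is invariant under each field's
rigid transform, so the peak/valley combs of all fields co-align.

Angle convention: gantry angle 0 sends the beam along -z (entering the
phantom from the +z surface); positive angles rotate counterclockwise in
the y-z plane as seen looking down +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .beam import BeamModelParams, DEFAULT_PARAMS, EnergyLayer, build_sobp
from .collimator import MinibeamCollimator, active_slits
from .phantom import Phantom, SphereTarget, make_head_phantom, make_ptv

__all__ = [
    "FieldPlan",
    "ArcPlan",
    "CaseSpec",
    "FieldFrame",
    "make_arc_plan",
    "case_registry",
    "build_case_plans",
    "field_frame",
    "overlap_onset_depth",
    "DEFAULT_FIELD_MARGIN",
]

#: margin (mm) added around the PTV radius when selecting active slits
#: and sizing the scan extent across the slits
DEFAULT_FIELD_MARGIN = 2.0


@dataclass(frozen=True)
class FieldPlan:
    """One treatment field: a minibeam array or a broad (PAT) field."""

    gantry_angle: float
    weight: float
    collimated: bool
    scan_extent_y: float
    collimator: MinibeamCollimator | None = None
    layers: tuple[EnergyLayer, ...] = ()
    slits: tuple[float, ...] | None = None  # active slit centers, mm

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("field weight must be non-negative")
        if self.collimated and self.collimator is None:
            raise ValueError("a collimated field must carry a collimator")


@dataclass(frozen=True)
class FieldFrame:
    """Rigid world <-> field transform: rotation about the modulation axis."""

    angle_deg: float

    @property
    def _cs(self):
        a = np.deg2rad(self.angle_deg)
        return np.cos(a), np.sin(a)

    def world_to_field(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = self._cs
        out = np.empty_like(pts)
        out[:, 0] = pts[:, 0]
        out[:, 1] = c * pts[:, 1] + s * pts[:, 2]
        out[:, 2] = -s * pts[:, 1] + c * pts[:, 2]
        return out

    def field_to_world(self, points: np.ndarray) -> np.ndarray:
        return FieldFrame(-self.angle_deg).world_to_field(points)

    @property
    def beam_direction_world(self) -> np.ndarray:
        c, s = self._cs
        return np.array([0.0, s, -c])


def field_frame(fld: FieldPlan) -> FieldFrame:
    """Transform between world and field coordinates for one field."""
    return FieldFrame(fld.gantry_angle)


@dataclass(frozen=True)
class ArcPlan:
    """Ordered set of equally spaced fields forming (part of) an arc."""

    fields: tuple[FieldPlan, ...]
    angular_separation: float

    def __post_init__(self) -> None:
        angles = np.array([f.gantry_angle for f in self.fields])
        if len(angles) > 1:
            steps = np.diff(angles)
            if not np.allclose(steps, self.angular_separation, atol=1e-9):
                raise ValueError("arc fields must be equally spaced")

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def span(self) -> float:
        return (self.n_fields - 1) * self.angular_separation

    def with_layers(self, layers) -> "ArcPlan":
        layers = tuple(layers)
        return ArcPlan(
            fields=tuple(replace(f, layers=layers) for f in self.fields),
            angular_separation=self.angular_separation,
        )

    def scaled(self, factor: float) -> "ArcPlan":
        return ArcPlan(
            fields=tuple(replace(f, weight=f.weight * factor) for f in self.fields),
            angular_separation=self.angular_separation,
        )


def make_arc_plan(
    n_fields: int,
    angular_separation: float,
    collimator: MinibeamCollimator | None = None,
    arc_center_angle: float = 0.0,
    scan_extent_y: float = 24.0,
    slits=None,
    layers=(),
) -> ArcPlan:
    """Build an arc of ``n_fields`` equally spaced, equally weighted fields.

    Weights sum to 1 so a plan's dose is the average of its fields; a
    single-field arc is identical to one pMBRT array.
    """
    if n_fields < 1:
        raise ValueError("an arc needs at least one field")
    if n_fields > 1 and angular_separation <= 0:
        raise ValueError("angular separation must be positive for multi-field arcs")
    span = (n_fields - 1) * angular_separation
    if span > 360.0:
        raise ValueError(f"arc span {span:g} deg exceeds 360 deg")
    offsets = (np.arange(n_fields) - (n_fields - 1) / 2.0) * angular_separation
    fields = tuple(
        FieldPlan(
            gantry_angle=float(arc_center_angle + off),
            weight=1.0 / n_fields,
            collimated=collimator is not None,
            collimator=collimator,
            scan_extent_y=scan_extent_y,
            slits=None if slits is None else tuple(float(s) for s in slits),
            layers=tuple(layers),
        )
        for off in offsets
    )
    return ArcPlan(fields=fields, angular_separation=float(angular_separation))


@dataclass(frozen=True)
class CaseSpec:
    """One row of the twelve-case study grid."""

    case_number: int
    n_arrays: int
    angular_separation: float
    ctc: float
    ptv_diameter: float


def _load_case_table() -> dict[int, CaseSpec]:
    table = {}
    case_dir = resources.files("pmbat") / "cases"
    for entry in sorted(case_dir.iterdir()):
        if not entry.name.endswith(".yaml"):
            continue
        raw = yaml.safe_load(entry.read_text())
        spec = CaseSpec(
            case_number=int(raw["case"]),
            n_arrays=int(raw["n_arrays"]),
            angular_separation=float(raw["angular_separation_deg"]),
            ctc=float(raw["ctc_mm"]),
            ptv_diameter=float(raw["ptv_diameter_mm"]),
        )
        table[spec.case_number] = spec
    return table


_CASE_TABLE: dict[int, CaseSpec] | None = None


def _case_table() -> dict[int, CaseSpec]:
    global _CASE_TABLE
    if _CASE_TABLE is None:
        _CASE_TABLE = _load_case_table()
    return _CASE_TABLE


def case_registry(
    case_number: int,
    phantom: Phantom | None = None,
    params: BeamModelParams = DEFAULT_PARAMS,
    margin: float = DEFAULT_FIELD_MARGIN,
) -> tuple[CaseSpec, ArcPlan]:
    """Return the case parameters and the fully built pMBAT arc plan.

    The plan carries its collimator, active slits, scan extent and SOBP
    energy layers for the default (or supplied) phantom.
    """
    table = _case_table()
    if case_number not in table:
        raise KeyError(f"unknown case {case_number}; valid cases are 1-12")
    spec = table[case_number]
    if phantom is None:
        phantom = make_head_phantom()
    plan = _build_pmbat_plan(spec, phantom, params, margin)
    return spec, plan


def _target_layers(
    phantom: Phantom, ptv: SphereTarget, params: BeamModelParams
) -> tuple[EnergyLayer, ...]:
    """SOBP covering the PTV depth span, range-shifter WET included."""
    skin_to_iso = phantom.radius
    proximal = params.shifter_wet_mm + skin_to_iso - ptv.radius
    distal = params.shifter_wet_mm + skin_to_iso + ptv.radius
    return tuple(build_sobp(proximal, distal, params=params))


def _build_pmbat_plan(spec, phantom, params, margin) -> ArcPlan:
    ptv = make_ptv(phantom, spec.ptv_diameter)
    coll = MinibeamCollimator(ctc=spec.ctc)
    slits = active_slits(coll, ptv, margin=margin)
    layers = _target_layers(phantom, ptv, params)
    return make_arc_plan(
        n_fields=spec.n_arrays,
        angular_separation=spec.angular_separation,
        collimator=coll,
        scan_extent_y=spec.ptv_diameter + 2 * margin,
        slits=slits,
        layers=layers,
    )


def build_case_plans(
    case_number: int,
    phantom: Phantom | None = None,
    params: BeamModelParams = DEFAULT_PARAMS,
    margin: float = DEFAULT_FIELD_MARGIN,
):
    """pMBAT, single-array pMBRT and PAT variants of one study case.

    Returns ``(spec, ptv, plans)`` where ``plans`` maps
    ``{"pmbat", "pmbrt", "pat"}`` to :class:`ArcPlan`.  The pMBRT
    reference is a single array with the same collimator; the PAT plan
    keeps the arc geometry but removes the collimator (broad fields over
    the same scan footprint).
    """
    if phantom is None:
        phantom = make_head_phantom()
    spec, pmbat = case_registry(case_number, phantom, params, margin)
    ptv = make_ptv(phantom, spec.ptv_diameter)
    coll = pmbat.fields[0].collimator
    slits = pmbat.fields[0].slits
    layers = pmbat.fields[0].layers
    extent = pmbat.fields[0].scan_extent_y
    pmbrt = make_arc_plan(
        1, 0.0, collimator=coll, scan_extent_y=extent, slits=slits, layers=layers
    )
    pat = make_arc_plan(
        spec.n_arrays,
        spec.angular_separation,
        collimator=None,
        scan_extent_y=extent,
        layers=layers,
    )
    return spec, ptv, {"pmbat": pmbat, "pmbrt": pmbrt, "pat": pat}


def overlap_onset_depth(
    plan_halfwidth: float, angular_separation: float, skin_to_iso: float
) -> float:
    """Depth below skin at which two adjacent field slabs begin to overlap.

    Each field irradiates a slab of half-width ``plan_halfwidth`` around
    its central ray; rays of adjacent fields cross at the isocenter.  On
    the central field's axis the neighbour's slab first intrudes at

    ``depth = skin_to_iso - plan_halfwidth / sin(separation)``

    clamped to >= 0 (overlap from the surface onward).
    """
    if not 0 < angular_separation <= 180:
        raise ValueError("angular separation must lie in (0, 180] degrees")
    if plan_halfwidth <= 0:
        raise ValueError("plan half-width must be positive")
    s = np.sin(np.deg2rad(angular_separation))
    if s == 0:
        return 0.0
    return float(max(0.0, skin_to_iso - plan_halfwidth / s))


def plan_to_dict(plan: ArcPlan) -> dict:
    """Serializable description of an arc plan (config round-trip)."""
    f0 = plan.fields[0]
    out = {
        "n_fields": plan.n_fields,
        "angular_separation_deg": plan.angular_separation,
        "arc_center_angle_deg": float(
            np.mean([f.gantry_angle for f in plan.fields])
        ),
        "scan_extent_y_mm": f0.scan_extent_y,
        "collimated": f0.collimated,
        "layers": [
            {"energy_mev": l.energy, "weight": l.weight} for l in f0.layers
        ],
    }
    if f0.collimated:
        c = f0.collimator
        out["collimator"] = {
            "n_slits": c.n_slits,
            "slit_width_mm": c.slit_width,
            "slit_length_mm": c.slit_length,
            "ctc_mm": c.ctc,
            "thickness_mm": c.thickness,
            "air_gap_mm": c.air_gap,
            "penumbra_sigma_mm": c.penumbra_sigma,
        }
        out["active_slits_mm"] = list(f0.slits) if f0.slits is not None else None
    return out


def plan_from_dict(raw: dict) -> ArcPlan:
    coll = None
    if raw.get("collimated"):
        c = raw["collimator"]
        coll = MinibeamCollimator(
            n_slits=c["n_slits"],
            slit_width=c["slit_width_mm"],
            slit_length=c["slit_length_mm"],
            ctc=c["ctc_mm"],
            thickness=c["thickness_mm"],
            air_gap=c["air_gap_mm"],
            penumbra_sigma=c["penumbra_sigma_mm"],
        )
    layers = tuple(
        EnergyLayer(energy=l["energy_mev"], weight=l["weight"])
        for l in raw.get("layers", [])
    )
    return make_arc_plan(
        n_fields=raw["n_fields"],
        angular_separation=raw["angular_separation_deg"],
        collimator=coll,
        arc_center_angle=raw.get("arc_center_angle_deg", 0.0),
        scan_extent_y=raw["scan_extent_y_mm"],
        slits=raw.get("active_slits_mm"),
        layers=layers,
    )
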