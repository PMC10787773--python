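"""Outlet boundary conditions: cardiac-output splits, Murray's-law
resistances and effective-viscosity extruded outlets.

Every non-retinal outlet resistance is designed so that, with systolic
pressure upstream and zero pressure downstream, the region carries its
assigned fraction of systolic cardiac output, shared among the region's
outlets by cube-of-radius (Murray) weighting:

    R_i = P_sys / (Q_sys · split · r_i³ / Σ_j r_j³)

Any designed resistance (Murray or fractal-tree) is then encoded as an
"extruded outlet": a virtual conduit of length twice the outlet diameter
whose effective viscosity μ = R π r⁴ / (8 L) reproduces the resistance with
a zero-pressure distal surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "RegionSplit",
    "SystolicReference",
    "OutletSpec",
    "DEFAULT_REGION_SPLITS",
    "RESIDUAL_REGION",
    "complete_split_table",
    "murray_outlet_resistances",
    "resistance_to_effective_viscosity",
    "make_outlet_spec",
]

#: extrusion length is double the outlet diameter, i.e. 4 radii
EXTRUSION_LENGTH_RADII = 4.0


@dataclass(frozen=True)
class RegionSplit:
    """Fraction of cardiac output assigned to one arterial region."""

    region_name: str
    n_outlets: int
    co_fraction: float | None  # None => residual, to be completed
    paired: bool = False


#: published flow-distribution table; subclavian is the residual of cardiac
#: output and is deliberately left unset here.
DEFAULT_REGION_SPLITS: tuple[RegionSplit, ...] = (
    RegionSplit("celiac", 1, 0.14),
    RegionSplit("cerebral", 32, 0.1278),
    RegionSplit("coronary", 26, 0.05),
    RegionSplit("external_carotid", 2, 0.0945, paired=True),
    RegionSplit("internal_iliac", 2, 0.04, paired=True),
    RegionSplit("external_iliac", 2, 0.09, paired=True),
    RegionSplit("ophthalmic", 2, 0.0068, paired=True),
    RegionSplit("mesenteric", 1, 0.16),
    RegionSplit("renal", 2, 0.23, paired=True),
    RegionSplit("subclavian", 2, None, paired=True),
)

RESIDUAL_REGION = "subclavian"


@dataclass(frozen=True)
class SystolicReference:
    """Systolic pressure/flow operating point used to size outlet resistances."""

    p_sys: float
    q_sys: float

    def __post_init__(self) -> None:
        if self.p_sys <= 0 or self.q_sys <= 0:
            raise ValueError("p_sys and q_sys must be positive")


@dataclass(frozen=True)
class OutletSpec:
    """A terminal boundary: designed resistance and its extruded-outlet form."""

    outlet_id: str
    region: str
    radius: float
    resistance: float
    effective_viscosity: float
    extrusion_length: float


def complete_split_table(
    partial: Sequence[RegionSplit], residual_region: str = RESIDUAL_REGION
) -> list[RegionSplit]:
    """Assign the residual of cardiac output to ``residual_region``.

    Exactly one region must carry ``co_fraction=None``; its fraction becomes
    one minus the sum of the listed fractions. The completed table sums to 1.
    """
    residuals = [s for s in partial if s.co_fraction is None]
    if len(residuals) != 1 or residuals[0].region_name != residual_region:
        raise ValueError(
            f"exactly one region ({residual_region!r}) must have an unset fraction"
        )
    listed = sum(s.co_fraction for s in partial if s.co_fraction is not None)
    if listed >= 1.0:
        raise ValueError(f"listed fractions sum to {listed} >= 1")
    residual = 1.0 - listed
    out = []
    for s in partial:
        if s.co_fraction is None:
            s = RegionSplit(s.region_name, s.n_outlets, residual, s.paired)
        out.append(s)
    return out


def murray_outlet_resistances(
    region: RegionSplit, outlet_radii: Sequence[float], ref: SystolicReference
) -> list[float]:
    """Per-outlet resistances so region flow at (P_sys, 0) is Q_sys·split.

    Flow is shared within the region in proportion to r³.
    """
    if region.co_fraction is None:
        raise ValueError(f"region {region.region_name!r} has no completed fraction")
    if not outlet_radii:
        if region.co_fraction > 0:
            raise ValueError(
                f"region {region.region_name!r} has a nonzero split but no outlets"
            )
        return []
    if len(outlet_radii) != region.n_outlets:
        raise ValueError(
            f"region {region.region_name!r} expects {region.n_outlets} outlets, "
            f"got {len(outlet_radii)} radii"
        )
    if any(r <= 0 for r in outlet_radii):
        raise ValueError("all outlet radii must be positive")
    cubes = [r**3 for r in outlet_radii]
    total = sum(cubes)
    q_region = ref.q_sys * region.co_fraction
    return [ref.p_sys / (q_region * c / total) for c in cubes]


def resistance_to_effective_viscosity(R: float, radius: float, length: float) -> float:
    """μ = R π r⁴ / (8 L): viscosity making a conduit of (r, L) resist R."""
    if R <= 0 or radius <= 0 or length <= 0:
        raise ValueError("R, radius and length must all be positive")
    return R * math.pi * radius**4 / (8.0 * length)


def make_outlet_spec(
    outlet_id: str, region: str, radius: float, R: float
) -> OutletSpec:
    """Package a designed resistance as an extruded outlet (length = 4 r)."""
    if radius <= 0 or R <= 0:
        raise ValueError("radius and R must be positive")
    length = EXTRUSION_LENGTH_RADII * radius
    return OutletSpec(
        outlet_id=outlet_id,
        region=region,
        radius=radius,
        resistance=R,
        effective_viscosity=resistance_to_effective_viscosity(R, radius, length),
        extrusion_length=length,
    )
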