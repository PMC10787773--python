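"""Structured asymmetric fractal trees for retinal arteriole outlets.

Each retinal outlet is terminated by a deterministic bifurcating tree grown
from the outlet radius down to a capillary-scale terminal diameter. The tree
is then collapsed to a single Hagen-Poiseuille equivalent resistance, using
the diameter-dependent FL viscosity for every tree segment (all of which are
below the FL diameter threshold by construction).

Radius scaling follows a power law ``r_p^k = r_d1^k + r_d2^k`` with an
asymmetry index ``γ = r_d2 / r_d1`` in (0, 1]; segment length is
``length_ratio_fn(diameter) · radius``. Default exponents and length ratios
follow the cited structured-tree literature (they are not printed in the
study itself) and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .rheology import RheologyParams, fl_effective_viscosity
from .hagen_poiseuille import poiseuille_resistance

__all__ = [
    "BranchingParams",
    "TreeSegment",
    "default_length_ratio",
    "build_structured_tree",
    "tree_resistance",
    "retinal_outlet_resistances",
]


def default_length_ratio(diameter: float) -> float:
    """Length/radius ratio as a piecewise-constant function of diameter (m).

    Smaller arterioles are relatively longer; the bands and values are
    cited-work defaults, not measured constants.
    """
    d_um = diameter * 1e6
    if d_um < 25.0:
        return 45.0
    if d_um < 75.0:
        return 30.0
    return 20.0


@dataclass(frozen=True)
class BranchingParams:
    """Rules governing structured-tree growth and termination."""

    radius_exponent: float = 2.76
    asymmetry_index: float = 0.64
    length_ratio_fn: Callable[[float], float] = field(
        default=default_length_ratio, repr=False, compare=False
    )
    terminal_diameter: float = 4.0e-6
    terminal_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.terminal_diameter <= 0:
            raise ValueError("terminal_diameter must be positive")
        if not 0.0 < self.asymmetry_index <= 1.0:
            raise ValueError("asymmetry_index must be in (0, 1]")
        if self.radius_exponent <= 0:
            raise ValueError("radius_exponent must be positive")

    def daughter_radii(self, parent_radius: float) -> tuple[float, float]:
        """Radii (r_d1 ≥ r_d2) from the power law and asymmetry index."""
        k = self.radius_exponent
        g = self.asymmetry_index
        r1 = parent_radius * (1.0 + g**k) ** (-1.0 / k)
        return r1, g * r1


@dataclass
class TreeSegment:
    """One cylindrical tree vessel; leaves have no children."""

    radius: float
    length: float
    children: tuple["TreeSegment", "TreeSegment"] | tuple[()] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


def build_structured_tree(
    root_radius: float, bp: BranchingParams, max_depth: int = 60
) -> TreeSegment:
    """Grow the deterministic tree from ``root_radius`` down to termination.

    A segment becomes a leaf when either of its prospective daughters would
    fall below the terminal diameter. ``max_depth`` guards against
    non-contracting parameter choices.
    """
    if root_radius <= 0:
        raise ValueError(f"root radius must be positive, got {root_radius}")

    def grow(radius: float, depth: int) -> TreeSegment:
        if depth > max_depth:
            raise RuntimeError(
                f"structured tree exceeded max_depth={max_depth} at radius "
                f"{radius:.3e} m (radius_exponent={bp.radius_exponent}, "
                f"asymmetry_index={bp.asymmetry_index})"
            )
        length = bp.length_ratio_fn(2.0 * radius) * radius
        r1, r2 = bp.daughter_radii(radius)
        if 2.0 * min(r1, r2) < bp.terminal_diameter:
            return TreeSegment(radius=radius, length=length)
        return TreeSegment(
            radius=radius,
            length=length,
            children=(grow(r1, depth + 1), grow(r2, depth + 1)),
        )

    return grow(root_radius, 0)


def tree_resistance(tree: TreeSegment, params: RheologyParams) -> float:
    """Equivalent resistance of a tree: series own-segment, parallel children.

    Segment viscosity is the FL value at the segment diameter; every tree
    diameter must fall in the FL-only regime (asserted, not assumed). Leaves
    drain to the terminal pressure datum, which contributes no resistance.
    """
    d = 2.0 * tree.radius
    if d > params.d_fl_max:
        raise ValueError(
            f"tree segment diameter {d:.3e} m exceeds the FL-only threshold "
            f"{params.d_fl_max:.3e} m"
        )
    mu = fl_effective_viscosity(d, params)
    r_own = poiseuille_resistance(mu, tree.length, tree.radius)
    if tree.is_leaf:
        return r_own
    r1 = tree_resistance(tree.children[0], params)
    r2 = tree_resistance(tree.children[1], params)
    return r_own + r1 * r2 / (r1 + r2)


def retinal_outlet_resistances(
    outlet_radii: Sequence[float],
    bp: Optional[BranchingParams] = None,
    params: Optional[RheologyParams] = None,
) -> list[float]:
    """Structured-tree resistance for each outlet radius, order preserved."""
    bp = bp if bp is not None else BranchingParams()
    params = params if params is not None else RheologyParams()
    out = []
    for r in outlet_radii:
        if r <= 0:
            raise ValueError(f"outlet radius must be positive, got {r}")
        out.append(tree_resistance(build_structured_tree(r, bp), params))
    return out
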