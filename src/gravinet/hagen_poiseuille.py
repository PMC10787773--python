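"""Hagen-Poiseuille primitives shared across modules."""

from __future__ import annotations

import math

__all__ = ["poiseuille_resistance", "poiseuille_wall_shear_rate"]


def poiseuille_resistance(mu: float, length: float, radius: float) -> float:
    """R = 8 μ L / (π r⁴) for laminar flow in a cylinder (SI units)."""
    if mu <= 0 or length <= 0 or radius <= 0:
        raise ValueError("mu, length and radius must all be positive")
    return 8.0 * mu * length / (math.pi * radius**4)


def poiseuille_wall_shear_rate(flow: float, radius: float) -> float:
    """Wall shear rate γ̇ = 4 |Q| / (π r³) of fully developed pipe flow."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * abs(flow) / (math.pi * radius**3)
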