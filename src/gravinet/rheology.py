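"""Blood viscosity laws for the network model.

Three regimes, selected by conduit diameter:

* below ``d_fl_max`` (default 0.6 mm) — the Fåhraeus-Lindqvist (FL) regime:
  apparent viscosity depends on diameter (and haematocrit), not shear rate;
* above ``d_cy_min`` (default 1.2 mm) — the Carreau-Yasuda (CY) regime:
  shear-thinning viscosity independent of diameter;
* between the two thresholds — a linear blend in diameter of the two laws.

All quantities are SI (metres, Pa·s, s⁻¹). The FL relative-viscosity law is
pluggable; the default is the Pries et al. in-vitro fit, which takes the
diameter in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

__all__ = [
    "RheologyParams",
    "pries_invitro_relative_viscosity",
    "carreau_yasuda_viscosity",
    "fl_effective_viscosity",
    "blended_viscosity",
]


def pries_invitro_relative_viscosity(diameter_um: float, haematocrit: float) -> float:
    """Relative apparent viscosity (vs plasma) of blood in a tube.

    Pries-type in-vitro fit as a function of tube diameter (μm) and discharge
    haematocrit. Returns 1.0 exactly for haematocrit 0.
    """
    d = diameter_um
    if d <= 0:
        raise ValueError(f"diameter must be positive, got {d} um")
    if not 0.0 <= haematocrit < 1.0:
        raise ValueError(f"haematocrit must be in [0, 1), got {haematocrit}")
    if haematocrit == 0.0:
        return 1.0
    # apparent relative viscosity at Hct = 0.45
    mu45 = 220.0 * math.exp(-1.3 * d) + 3.2 - 2.44 * math.exp(-0.06 * d**0.645)
    # shape exponent of the haematocrit dependence
    f = 1.0 / (1.0 + 1e-11 * d**12)
    c = (0.8 + math.exp(-0.075 * d)) * (-1.0 + f) + f
    h = haematocrit
    return 1.0 + (mu45 - 1.0) * ((1.0 - h) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0)


@dataclass(frozen=True)
class RheologyParams:
    """Constants of the blended viscosity model.

    Defaults are the published model constants: Carreau-Yasuda plateaus
    ``eta_inf``/``eta_0``, relaxation time ``lambda_cy``, Yasuda exponent
    ``a_cy``, power index ``n_cy``; haematocrit 0.45 and plasma viscosity
    1.2 mPa·s for the FL law; blood density 1050 kg·m⁻³; and the diameter
    thresholds 0.6 mm / 1.2 mm bounding the blending band.
    """

    eta_inf: float = 0.0035
    eta_0: float = 0.16
    lambda_cy: float = 8.2
    a_cy: float = 0.64
    n_cy: float = 0.2128
    haematocrit: float = 0.45
    mu_plasma: float = 0.0012
    rho: float = 1050.0
    d_fl_max: float = 6.0e-4
    d_cy_min: float = 1.2e-3
    relative_viscosity_law: Callable[[float, float], float] = field(
        default=pries_invitro_relative_viscosity, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.eta_inf < self.eta_0):
            raise ValueError("require 0 < eta_inf < eta_0")
        if self.mu_plasma <= 0 or self.rho <= 0:
            raise ValueError("mu_plasma and rho must be positive")
        if not 0.0 <= self.haematocrit < 1.0:
            raise ValueError("haematocrit must be in [0, 1)")
        if not (0.0 < self.d_fl_max < self.d_cy_min):
            raise ValueError("require 0 < d_fl_max < d_cy_min")


def carreau_yasuda_viscosity(shear_rate: float, params: RheologyParams) -> float:
    """Shear-thinning viscosity η(γ̇) = η∞ + (η0−η∞)[1+(λγ̇)^a]^((n−1)/a)."""
    if shear_rate < 0:
        raise ValueError(f"shear rate must be non-negative, got {shear_rate}")
    p = params
    return p.eta_inf + (p.eta_0 - p.eta_inf) * (
        1.0 + (p.lambda_cy * shear_rate) ** p.a_cy
    ) ** ((p.n_cy - 1.0) / p.a_cy)


def fl_effective_viscosity(diameter: float, params: RheologyParams) -> float:
    """Diameter-dependent apparent viscosity μ_plasma · μ_rel(d, Hct).

    ``diameter`` in metres; the relative-viscosity law receives micrometres.
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter} m")
    mu_rel = params.relative_viscosity_law(diameter * 1e6, params.haematocrit)
    return params.mu_plasma * mu_rel


def blended_viscosity(
    diameter: float, shear_rate: float, params: RheologyParams
) -> float:
    """Viscosity of the three-regime model at conduit diameter and shear rate.

    FL below ``d_fl_max``, CY above ``d_cy_min``, linear interpolation in
    diameter between; continuous at both thresholds.
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter} m")
    if diameter <= params.d_fl_max:
        return fl_effective_viscosity(diameter, params)
    if diameter >= params.d_cy_min:
        return carreau_yasuda_viscosity(shear_rate, params)
    w = (diameter - params.d_fl_max) / (params.d_cy_min - params.d_fl_max)
    return w * carreau_yasuda_viscosity(shear_rate, params) + (
        1.0 - w
    ) * fl_effective_viscosity(diameter, params)
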