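"""Haemodynamic metrics and gravity-vs-microgravity comparison tables.

Flow metrics are extracted from named segments (ICA/VA mass flow, CRA
volumetric flow), wall shear metrics from the Poiseuille surrogate
τ_w = 4 μ Q / (π r³). Percent changes are reported rounded to the nearest
integer, with full precision retained in the underlying values.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_solver import CaseResult, NetworkGraph

__all__ = [
    "MetricRow",
    "waveform_peak_and_average",
    "percent_change",
    "percent_change_rounded",
    "paired_mean",
    "poiseuille_wss",
    "tawss",
    "osi",
    "build_comparison_report",
    "M3S_TO_UL_MIN",
]

#: m³·s⁻¹ → μl·min⁻¹
M3S_TO_UL_MIN = 1e9 * 60.0


@dataclass(frozen=True)
class MetricRow:
    quantity: str
    gravity: float
    microgravity: float
    percent_change: int
    units: str


def waveform_peak_and_average(series) -> tuple[float, float]:
    """(max, time mean) of one uniformly sampled cycle."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    return float(arr.max()), float(arr.mean())


def percent_change(g_value: float, ug_value: float) -> float:
    """Signed percent change from the gravity to the microgravity value."""
    if g_value == 0:
        raise ValueError("zero baseline value")
    return 100.0 * (ug_value - g_value) / g_value


def percent_change_rounded(g_value: float, ug_value: float) -> int:
    """Percent change rounded half-away-from-zero to a whole percent."""
    x = percent_change(g_value, ug_value)
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def paired_mean(left: float, right: float) -> tuple[float, float]:
    """Combine bilateral values: (arithmetic mean, sample SD of the pair)."""
    return (left + right) / 2.0, statistics.stdev([left, right])


def poiseuille_wss(flow, radius: float, viscosity) -> np.ndarray:
    """Wall shear stress series τ_w(t) = 4 μ(t) Q(t) / (π r³)."""
    q = np.asarray(flow, dtype=float)
    mu = np.asarray(viscosity, dtype=float)
    return 4.0 * mu * q / (math.pi * radius**3)


def tawss(tau) -> float:
    """Time-averaged magnitude of wall shear stress over one cycle."""
    arr = np.asarray(tau, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    return float(np.mean(np.abs(arr)))


def osi(tau) -> float:
    """Oscillatory shear index 0.5(1 − |∫τ| / ∫|τ|), in [0, 0.5].

    Identically 0 for the quasi-static solver's unidirectional flows; an
    all-zero series is defined as 0.
    """
    arr = np.asarray(tau, dtype=float)
    denom = float(np.sum(np.abs(arr)))
    if denom == 0.0:
        return 0.0
    return 0.5 * (1.0 - abs(float(np.sum(arr))) / denom)


def _region_tawss(result: CaseResult, net: NetworkGraph, region: str) -> float:
    taus = [
        tawss(result.wall_shear[s.segment_id])
        for s in net.segments
        if s.region == region
    ]
    return float(np.mean(taus))


def build_comparison_report(
    gravity: CaseResult, micro: CaseResult, net: NetworkGraph
) -> pd.DataFrame:
    """Emit the flow/velocity/shear comparison table for the two cases.

    Rows: ICA/VA peak and average mass flow, CRA peak/average volumetric
    flow per side and paired across eyes, CRA mean velocity, and per-region
    TAWSS. Row order is deterministic.
    """
    if set(gravity.segment_flows) != set(micro.segment_flows):
        raise ValueError("case results come from different networks")
    rho = 1050.0
    rows: list[MetricRow] = []

    def add(quantity: str, g: float, ug: float, units: str) -> None:
        rows.append(
            MetricRow(quantity, g, ug, percent_change_rounded(g, ug), units)
        )

    named = set(gravity.segment_flows)
    for sid in ("ICA_L", "ICA_R", "VA_L", "VA_R"):
        if sid not in named:
            continue
        gp, ga = waveform_peak_and_average(gravity.segment_flows[sid] * rho)
        up, ua = waveform_peak_and_average(micro.segment_flows[sid] * rho)
        add(f"{sid} MFR_peak", gp, up, "kg s^-1")
        add(f"{sid} MFR_ave", ga, ua, "kg s^-1")

    cra_sides = [s for s in ("CRA_L", "CRA_R") if s in named]
    cra_vals: dict[str, dict[str, float]] = {"peak": {}, "ave": {}}
    for sid in cra_sides:
        gp, ga = waveform_peak_and_average(
            gravity.segment_flows[sid] * M3S_TO_UL_MIN
        )
        up, ua = waveform_peak_and_average(micro.segment_flows[sid] * M3S_TO_UL_MIN)
        add(f"{sid} Q_peak", gp, up, "ul min^-1")
        add(f"{sid} Q_ave", ga, ua, "ul min^-1")
        cra_vals["peak"][sid] = (gp, up)
        cra_vals["ave"][sid] = (ga, ua)
    if len(cra_sides) == 2:
        for kind in ("peak", "ave"):
            gl, ul = cra_vals[kind]["CRA_L"]
            gr, ur = cra_vals[kind]["CRA_R"]
            add(
                f"CRA Q_{kind} (paired mean)",
                paired_mean(gl, gr)[0],
                paired_mean(ul, ur)[0],
                "ul min^-1",
            )
    # CRA mean velocity surrogate Q/(π r²); the 3D maximal velocity is not claimed
    cra_seg = {s.segment_id: s for s in net.segments if s.segment_id in cra_sides}
    for sid, seg in sorted(cra_seg.items()):
        area = math.pi * seg.radius**2
        gp, ga = waveform_peak_and_average(
            gravity.segment_flows[sid] / area * 100.0
        )
        up, ua = waveform_peak_and_average(micro.segment_flows[sid] / area * 100.0)
        add(f"{sid} V_mean_peak", gp, up, "cm s^-1")
        add(f"{sid} V_mean_ave", ga, ua, "cm s^-1")

    for region in sorted({s.region for s in net.segments if s.region}):
        g = _region_tawss(gravity, net, region)
        ug = _region_tawss(micro, net, region)
        add(f"{region} TAWSS", g, ug, "Pa")

    return pd.DataFrame(
        [
            {
                "quantity": r.quantity,
                "gravity": r.gravity,
                "microgravity": r.microgravity,
                "percent_change": r.percent_change,
                "units": r.units,
            }
            for r in rows
        ]
    )
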