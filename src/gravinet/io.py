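"""Plain-text persistence of networks, outlet tables and waveforms.

Formats (all CSV):

* segments: ``segment_id, from, to, radius_m, length_m, delta_z_m, region``
* outlets: ``outlet_id, region, node, radius_m, resistance_Pa_s_per_m3,
  mu_eff_Pa_s, extrusion_length_m``
* waveform: ``t_s, massflow_kg_s``

Node elevations are reconstructed from the inlet (z = 0 datum) and the
segment elevation gains.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .boundary_conditions import OutletSpec
from .network_solver import NetworkGraph, OutletAttachment, VesselSegment, Waveform

__all__ = [
    "write_network",
    "read_network",
    "write_waveform",
    "read_waveform",
    "outlet_table",
]


def outlet_table(net: NetworkGraph) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outlet_id": o.spec.outlet_id,
                "region": o.spec.region,
                "node": o.node,
                "radius_m": o.spec.radius,
                "resistance_Pa_s_per_m3": o.spec.resistance,
                "mu_eff_Pa_s": o.spec.effective_viscosity,
                "extrusion_length_m": o.spec.extrusion_length,
            }
            for o in net.outlets
        ]
    )


def write_network(net: NetworkGraph, segments_path, outlets_path) -> None:
    seg_df = pd.DataFrame(
        [
            {
                "segment_id": s.segment_id,
                "from": s.from_node,
                "to": s.to_node,
                "radius_m": s.radius,
                "length_m": s.length,
                "delta_z_m": s.delta_z,
                "region": s.region,
            }
            for s in net.segments
        ]
    )
    seg_df.to_csv(segments_path, index=False)
    outlet_table(net).to_csv(outlets_path, index=False)


def _elevations_from_segments(
    segments: list[VesselSegment], inlet_node: str
) -> dict[str, float]:
    z = {inlet_node: 0.0}
    pending = list(segments)
    while pending:
        progressed = False
        rest = []
        for s in pending:
            if s.from_node in z:
                z[s.to_node] = z[s.from_node] + s.delta_z
                progressed = True
            elif s.to_node in z:
                z[s.from_node] = z[s.to_node] - s.delta_z
                progressed = True
            else:
                rest.append(s)
        pending = rest
        if not progressed and pending:
            raise ValueError("segments do not form a connected network")
    return z


def read_network(segments_path, outlets_path, inlet_node: str = "aortic_root") -> NetworkGraph:
    seg_df = pd.read_csv(segments_path, float_precision="round_trip").fillna({"region": ""})
    segments = [
        VesselSegment(
            segment_id=str(r["segment_id"]),
            from_node=str(r["from"]),
            to_node=str(r["to"]),
            radius=float(r["radius_m"]),
            length=float(r["length_m"]),
            delta_z=float(r["delta_z_m"]),
            region=str(r["region"]),
        )
        for _, r in seg_df.iterrows()
    ]
    out_df = pd.read_csv(outlets_path, float_precision="round_trip")
    outlets = tuple(
        OutletAttachment(
            node=str(r["node"]),
            spec=OutletSpec(
                outlet_id=str(r["outlet_id"]),
                region=str(r["region"]),
                radius=float(r["radius_m"]),
                resistance=float(r["resistance_Pa_s_per_m3"]),
                effective_viscosity=float(r["mu_eff_Pa_s"]),
                extrusion_length=float(r["extrusion_length_m"]),
            ),
        )
        for _, r in out_df.iterrows()
    )
    net = NetworkGraph(
        node_elevations=_elevations_from_segments(segments, inlet_node),
        segments=tuple(segments),
        inlet_node=inlet_node,
        outlets=outlets,
    )
    net.validate()
    return net


def write_waveform(wave: Waveform, path) -> None:
    pd.DataFrame({"t_s": wave.time, "massflow_kg_s": wave.massflow}).to_csv(
        path, index=False
    )


def read_waveform(path, rho: float = 1050.0) -> Waveform:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t_s"].to_numpy(dtype=float)
    m = df["massflow_kg_s"].to_numpy(dtype=float)
    dt = t[1] - t[0]
    return Waveform(time=t, massflow=m, period=float(t[-1] + dt), rho=rho)
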