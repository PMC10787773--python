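"""Synthetic stand-in for the heart-to-eye arterial network and inflow.

The study's 3D geometries and inlet waveform are not deposited, so this
module generates a connected arterial tree with the published regional
outlet counts, physiologic radii (aortic root ~centimetre scale down to the
163 μm central retinal artery), upright elevations (eyes above the heart,
iliacs below) and a parametric single-peaked pulsatile inflow waveform.

Retinal (ophthalmic/CRA) outlets are terminated by structured fractal
trees; every other outlet resistance comes from the cardiac-output split
table and Murray's law. Networks are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .boundary_conditions import (
    DEFAULT_REGION_SPLITS,
    OutletSpec,
    RegionSplit,
    SystolicReference,
    complete_split_table,
    make_outlet_spec,
    murray_outlet_resistances,
)
from .fractal_outlets import BranchingParams, retinal_outlet_resistances
from .network_solver import (
    NetworkGraph,
    OutletAttachment,
    VesselSegment,
    Waveform,
)
from .rheology import RheologyParams

__all__ = [
    "GeometrySpec",
    "WaveformSpec",
    "MMHG_TO_PA",
    "generate_network",
    "generate_inflow",
    "perturb_geometry",
]

MMHG_TO_PA = 133.322387415

#: published regional outlet counts
DEFAULT_OUTLET_COUNTS: dict[str, int] = {
    "celiac": 1,
    "cerebral": 32,
    "coronary": 26,
    "external_carotid": 2,
    "internal_iliac": 2,
    "external_iliac": 2,
    "ophthalmic": 2,
    "mesenteric": 1,
    "renal": 2,
    "subclavian": 2,
}


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric pulsatile inflow: raised-cosine systole on a diastolic plateau."""

    heart_rate: float = 60.0  # min^-1
    stroke_volume: float = 70.0e-6  # m^3
    systolic_fraction: float = 0.35
    # mild pulsatility: the purely resistive network transfers the flow
    # pulse 1:1 into pressure, so a physiologic mean perfusion pressure
    # requires a flow peak/mean ratio close to an arterial pressure one
    peak_to_mean: float = 2.0
    rho: float = 1050.0

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def q_sys(self) -> float:
        """Systolic-peak volumetric flow implied by the pulse shape."""
        return self.peak_to_mean * self.stroke_volume / self.period


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters of the synthetic heart-to-eye tree."""

    outlet_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_OUTLET_COUNTS)
    )
    eye_elevation: float = 0.35
    cerebral_elevation: float = 0.40
    iliac_elevation: float = -0.55
    cra_diameter: float = 163.0e-6
    jitter_fraction: float = 0.0
    seed: int = 0
    p_sys: float = 120.0 * MMHG_TO_PA

    def __post_init__(self) -> None:
        for region, n in DEFAULT_OUTLET_COUNTS.items():
            if self.outlet_counts.get(region, 0) < 1:
                raise ValueError(f"region {region!r} needs at least one outlet")
        if not 0.0 <= self.jitter_fraction <= 0.2:
            raise ValueError("jitter_fraction must be in [0, 0.2]")
        if self.cra_diameter <= 0 or self.p_sys <= 0:
            raise ValueError("cra_diameter and p_sys must be positive")


class _Builder:
    def __init__(self) -> None:
        self.z: dict[str, float] = {}
        self.segments: list[VesselSegment] = []
        self.outlet_nodes: dict[str, list[tuple[str, str, float]]] = {}

    def node(self, name: str, z: float) -> str:
        self.z[name] = z
        return name

    def seg(
        self,
        sid: str,
        a: str,
        b: str,
        radius: float,
        length: float,
        region: str = "",
    ) -> None:
        dz = self.z[b] - self.z[a]
        self.segments.append(
            VesselSegment(sid, a, b, radius, max(length, abs(dz)), dz, region)
        )

    def outlet(self, oid: str, region: str, node: str, radius: float) -> None:
        self.outlet_nodes.setdefault(region, []).append((oid, node, radius))


def _build_skeleton(spec: GeometrySpec) -> _Builder:
    b = _Builder()
    nd = b.node
    root = nd("aortic_root", 0.0)
    z_eye = spec.eye_elevation
    z_brain = spec.cerebral_elevation
    z_iliac = spec.iliac_elevation

    # coronaries, straight off the root
    cor_hub = nd("coronary_hub", 0.0)
    b.seg("coronary_trunk", root, cor_hub, 0.002, 0.02, "coronary")
    for i in range(spec.outlet_counts["coronary"]):
        leaf = nd(f"coronary_out_{i}", 0.0)
        b.seg(f"coronary_{i}", cor_hub, leaf, 0.0008, 0.03, "coronary")
        b.outlet(f"coronary_out_{i}", "coronary", leaf, 0.0008)

    arch = nd("aortic_arch", 0.05)
    b.seg("ascending_aorta", root, arch, 0.0125, 0.06, "aorta")

    # head vessels per side; the right side branches via the brachiocephalic
    bc = nd("brachiocephalic", 0.10)
    b.seg("brachiocephalic", arch, bc, 0.007, 0.06, "aorta")
    n_cer_side = spec.outlet_counts["cerebral"] // 2
    for side, origin in (("R", bc), ("L", arch)):
        sub = nd(f"subclavian_node_{side}", 0.12)
        b.seg(f"subclavian_trunk_{side}", origin, sub, 0.005, 0.08, "subclavian")
        sub_leaf = nd(f"subclavian_out_{side}", 0.10)
        b.seg(f"subclavian_{side}", sub, sub_leaf, 0.004, 0.08, "subclavian")
        b.outlet(f"subclavian_out_{side}", "subclavian", sub_leaf, 0.004)

        bif = nd(f"carotid_bif_{side}", 0.28)
        b.seg(f"common_carotid_{side}", origin, bif, 0.0035, 0.25, "carotid")
        ext = nd(f"ext_carotid_out_{side}", 0.32)
        b.seg(f"external_carotid_{side}", bif, ext, 0.002, 0.05, "carotid")
        b.outlet(f"ext_carotid_out_{side}", "external_carotid", ext, 0.002)

        ica_top = nd(f"ica_top_{side}", z_eye + 0.03)
        b.seg(f"ICA_{side}", bif, ica_top, 0.0025, 0.12, "cerebral")
        cow = nd(f"cow_{side}", z_brain)
        b.seg(f"ica_terminal_{side}", ica_top, cow, 0.002, 0.03, "cerebral")
        b.seg(f"VA_{side}", sub, cow, 0.0015, 0.30, "cerebral")

        m1_leaf = nd(f"cerebral_out_{side}_0", z_brain)
        b.seg(f"M1_{side}", cow, m1_leaf, 0.0012, 0.04, "cerebral")
        b.outlet(f"cerebral_out_{side}_0", "cerebral", m1_leaf, 0.0012)
        for i in range(1, n_cer_side):
            leaf = nd(f"cerebral_out_{side}_{i}", z_brain)
            b.seg(f"cerebral_{side}_{i}", cow, leaf, 0.0007, 0.04, "cerebral")
            b.outlet(f"cerebral_out_{side}_{i}", "cerebral", leaf, 0.0007)

        eye = nd(f"eye_{side}", z_eye)
        b.seg(f"ophthalmic_{side}", ica_top, eye, 0.0007, 0.04, "ophthalmic")
        cra_leaf = nd(f"cra_out_{side}", z_eye)
        b.seg(f"CRA_{side}", eye, cra_leaf, spec.cra_diameter / 2, 0.005, "ophthalmic")
        b.outlet(f"cra_out_{side}", "ophthalmic", cra_leaf, spec.cra_diameter / 2)

    # descending aorta and abdominal branches
    thor = nd("thoracic_aorta", -0.10)
    b.seg("descending_aorta", arch, thor, 0.010, 0.18, "aorta")
    abd = nd("abdominal_aorta", -0.20)
    b.seg("abdominal_aorta_seg", thor, abd, 0.009, 0.12, "aorta")
    for region, radius, length, dz in (
        ("celiac", 0.004, 0.03, -0.01),
        ("mesenteric", 0.004, 0.04, -0.02),
    ):
        leaf = nd(f"{region}_out_0", b.z[abd] + dz)
        b.seg(f"{region}_0", abd, leaf, radius, length, region)
        b.outlet(f"{region}_out_0", region, leaf, radius)
    for side in ("L", "R"):
        leaf = nd(f"renal_out_{side}", b.z[abd] - 0.02)
        b.seg(f"renal_{side}", abd, leaf, 0.0035, 0.05, "renal")
        b.outlet(f"renal_out_{side}", "renal", leaf, 0.0035)

    ili = nd("iliac_bifurcation", -0.35)
    b.seg("infrarenal_aorta", abd, ili, 0.0075, 0.16, "aorta")
    for side in ("L", "R"):
        int_leaf = nd(f"int_iliac_out_{side}", -0.45)
        b.seg(f"internal_iliac_{side}", ili, int_leaf, 0.003, 0.12, "internal_iliac")
        b.outlet(f"int_iliac_out_{side}", "internal_iliac", int_leaf, 0.003)
        ext_leaf = nd(f"ext_iliac_out_{side}", z_iliac)
        b.seg(f"external_iliac_{side}", ili, ext_leaf, 0.004, 0.24, "external_iliac")
        b.outlet(f"ext_iliac_out_{side}", "external_iliac", ext_leaf, 0.004)
    return b


def _jitter_radii(
    builder: _Builder, jitter: float, seed: int
) -> tuple[list[VesselSegment], dict[str, list[tuple[str, str, float]]]]:
    """Apply multiplicative radius jitter, then clamp so radii never grow
    towards the periphery along any path."""
    rng = np.random.default_rng(seed)
    segments = list(builder.segments)
    outlets = {r: list(v) for r, v in builder.outlet_nodes.items()}
    if jitter > 0:
        segments = [
            replace(s, radius=s.radius * (1.0 + jitter * rng.uniform(-1, 1)))
            for s in segments
        ]
        outlets = {
            r: [(oid, node, rad * (1.0 + jitter * rng.uniform(-1, 1))) for oid, node, rad in v]
            for r, v in outlets.items()
        }
    # enforce monotone non-increasing radii root -> periphery
    import networkx as nx

    dg = nx.DiGraph()
    seg_by_id = {}
    for s in segments:
        dg.add_edge(s.from_node, s.to_node, sid=s.segment_id)
        seg_by_id[s.segment_id] = s
    for node in nx.topological_sort(dg):
        in_r = [
            seg_by_id[dg.edges[u, node]["sid"]].radius for u in dg.predecessors(node)
        ]
        if not in_r:
            continue
        cap = min(in_r)
        for v in dg.successors(node):
            sid = dg.edges[node, v]["sid"]
            s = seg_by_id[sid]
            if s.radius > cap:
                seg_by_id[sid] = replace(s, radius=cap)
    segments = [seg_by_id[s.segment_id] for s in segments]
    # outlet radii capped by their feeding segment
    leaf_feed = {s.to_node: s.radius for s in segments}
    outlets = {
        r: [(oid, node, min(rad, leaf_feed[node])) for oid, node, rad in v]
        for r, v in outlets.items()
    }
    return segments, outlets


def generate_network(
    spec: GeometrySpec | None = None,
    wave_spec: WaveformSpec | None = None,
    bp: BranchingParams | None = None,
    params: RheologyParams | None = None,
) -> NetworkGraph:
    """Build the synthetic network with all outlet resistances assigned.

    Ophthalmic (CRA) outlets get structured-fractal-tree resistances; every
    other region gets Murray's-law resistances sized at the systolic
    operating point of the (synthetic) inflow waveform.
    """
    spec = spec if spec is not None else GeometrySpec()
    wave_spec = wave_spec if wave_spec is not None else WaveformSpec()
    params = params if params is not None else RheologyParams()
    builder = _build_skeleton(spec)
    segments, outlet_nodes = _jitter_radii(builder, spec.jitter_fraction, spec.seed)

    splits = {
        s.region_name: s for s in complete_split_table(list(DEFAULT_REGION_SPLITS))
    }
    ref = SystolicReference(p_sys=spec.p_sys, q_sys=wave_spec.q_sys)
    attachments: list[OutletAttachment] = []
    for region, rows in sorted(outlet_nodes.items()):
        radii = [rad for _, _, rad in rows]
        if region == "ophthalmic":
            resistances = retinal_outlet_resistances(radii, bp, params)
        else:
            resistances = murray_outlet_resistances(splits[region], radii, ref)
        for (oid, node, rad), R in zip(rows, resistances):
            attachments.append(
                OutletAttachment(node=node, spec=make_outlet_spec(oid, region, rad, R))
            )

    net = NetworkGraph(
        node_elevations=dict(builder.z),
        segments=tuple(segments),
        inlet_node="aortic_root",
        outlets=tuple(attachments),
    )
    net.validate()
    return net


def generate_inflow(spec: WaveformSpec | None = None, dt: float = 0.001) -> Waveform:
    """Sample one period of the parametric pulse; exact stroke volume.

    Shape: raised-cosine systolic pulse of duration ``systolic_fraction × T``
    over a constant diastolic plateau; the plateau level is solved so the
    period integral matches the stroke volume exactly. Requires ``dt`` to
    divide the period; the systolic duration is snapped to the grid.
    """
    spec = spec if spec is not None else WaveformSpec()
    T = spec.period
    n = round(T / dt)
    if n < 4 or abs(n * dt - T) > 1e-9 * T:
        raise ValueError(f"dt={dt} must divide the period {T}")
    ns = round(spec.systolic_fraction * T / dt)
    if ns < 2 or ns >= n:
        raise ValueError("systolic fraction incompatible with dt")
    ts = ns * dt
    m_mean = spec.rho * spec.stroke_volume / T
    m_peak = spec.peak_to_mean * m_mean
    # discrete integral of the raised cosine over [0, ts) is exactly ts/2
    m_dia = (spec.rho * spec.stroke_volume - m_peak * ts / 2.0) / (T - ts / 2.0)
    if m_dia < 0 or m_dia > m_peak:
        raise ValueError(
            f"infeasible pulse: peak_to_mean={spec.peak_to_mean}, "
            f"systolic_fraction={spec.systolic_fraction} give diastolic level "
            f"{m_dia:.3e} outside [0, peak]"
        )
    t = np.arange(n) * dt
    shape = np.where(t < ts, 0.5 * (1.0 - np.cos(2.0 * math.pi * t / ts)), 0.0)
    mass = m_dia + (m_peak - m_dia) * shape
    return Waveform(time=t, massflow=mass, period=T, rho=spec.rho)


def perturb_geometry(net: NetworkGraph, magnitude: float, seed: int) -> NetworkGraph:
    """Jitter segment radii and lengths by ±magnitude (uniform, seeded).

    Outlet specifications are untouched; elevation changes are preserved and
    lengths are kept ≥ |delta_z|. Magnitude 0 returns the network unchanged.
    """
    if not 0.0 <= magnitude <= 0.2:
        raise ValueError("magnitude must be in [0, 0.2]")
    if magnitude == 0.0:
        return net
    rng = np.random.default_rng(seed)
    segments = []
    for s in net.segments:
        r = s.radius * (1.0 + magnitude * rng.uniform(-1, 1))
        length = max(s.length * (1.0 + magnitude * rng.uniform(-1, 1)), abs(s.delta_z))
        segments.append(replace(s, radius=r, length=length))
    return replace(net, segments=tuple(segments))
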