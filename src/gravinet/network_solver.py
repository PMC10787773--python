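"""Quasi-static pulsatile solve of the resistive arterial network.

Each time instant is an independent linear nodal solve in piezometric
pressure P* = P + ρ g z, with a flow source at the aortic-root inlet and
zero physical pressure at each outlet's distal datum (taken at the outlet
node's own elevation, mirroring zero-pressure extruded outlet faces under a
body force). Segment conductances use the blended viscosity evaluated at
the Poiseuille wall shear rate of the segment's own flow, iterated to a
fixed point with under-relaxed Picard iteration.

No inertia or compliance is modelled: the network is memoryless, cycles are
bitwise identical, and the cyclic convergence check passes at cycle 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .boundary_conditions import OutletSpec, resistance_to_effective_viscosity
from .hagen_poiseuille import poiseuille_resistance, poiseuille_wall_shear_rate
from .rheology import RheologyParams, blended_viscosity

__all__ = [
    "VesselSegment",
    "OutletAttachment",
    "NetworkGraph",
    "Waveform",
    "CaseConfig",
    "GRAVITY_CASE",
    "MICROGRAVITY_CASE",
    "InstantSolution",
    "CaseResult",
    "segment_resistance",
    "solve_instant",
    "run_case",
    "apply_microgravity",
]

#: shear-rate floor (s⁻¹) for viscosity evaluation at near-zero flow
SHEAR_RATE_FLOOR = 1e-6


@dataclass(frozen=True)
class VesselSegment:
    """One cylindrical conduit between two named nodes.

    ``delta_z`` is the signed elevation gain to_node − from_node; it must not
    exceed the conduit length.
    """

    segment_id: str
    from_node: str
    to_node: str
    radius: float
    length: float
    delta_z: float = 0.0
    region: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError(f"segment {self.segment_id}: radius and length must be positive")
        if abs(self.delta_z) > self.length * (1 + 1e-12):
            raise ValueError(
                f"segment {self.segment_id}: |delta_z|={abs(self.delta_z)} exceeds length {self.length}"
            )


@dataclass(frozen=True)
class OutletAttachment:
    """An OutletSpec attached at a network node."""

    node: str
    spec: OutletSpec


@dataclass(frozen=True)
class NetworkGraph:
    """Directed tree of segments from one inlet to outlet terminals."""

    node_elevations: dict[str, float]
    segments: tuple[VesselSegment, ...]
    inlet_node: str
    outlets: tuple[OutletAttachment, ...]

    def validate(self) -> None:
        nodes = set(self.node_elevations)
        if self.inlet_node not in nodes:
            raise ValueError("inlet node missing from node list")
        for s in self.segments:
            if s.from_node not in nodes or s.to_node not in nodes:
                raise ValueError(f"segment {s.segment_id} references unknown node")
            dz = self.node_elevations[s.to_node] - self.node_elevations[s.from_node]
            if abs(dz - s.delta_z) > 1e-9 * max(1.0, s.length):
                raise ValueError(
                    f"segment {s.segment_id}: delta_z inconsistent with node elevations"
                )
        # connectivity + leaf/outlet bijection
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((s.from_node, s.to_node) for s in self.segments)
        if nodes and not nx.is_connected(g):
            raise ValueError("network is disconnected")
        if nx.number_of_selfloops(g) or len(self.segments) != len(nodes) - 1:
            dg = nx.DiGraph()
            dg.add_edges_from((s.from_node, s.to_node) for s in self.segments)
            if not nx.is_directed_acyclic_graph(dg):
                raise ValueError("network contains a cycle")
        outlet_nodes = [o.node for o in self.outlets]
        if len(set(outlet_nodes)) != len(outlet_nodes):
            raise ValueError("multiple outlets attached at one node")
        leaves = {n for n in nodes if g.degree(n) == 1 and n != self.inlet_node}
        if leaves != set(outlet_nodes):
            raise ValueError(
                f"leaf nodes {sorted(leaves)} do not match outlet nodes {sorted(set(outlet_nodes))}"
            )

    def replace_outlets(self, outlets: tuple[OutletAttachment, ...]) -> "NetworkGraph":
        return replace(self, outlets=outlets)


@dataclass(frozen=True)
class Waveform:
    """One period of inlet mass flow, uniformly sampled."""

    time: np.ndarray
    massflow: np.ndarray
    period: float
    rho: float = 1050.0

    def __post_init__(self) -> None:
        if len(self.time) != len(self.massflow) or len(self.time) < 2:
            raise ValueError("time and massflow must be equal-length, >= 2 samples")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("waveform sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def volumetric_flow(self) -> np.ndarray:
        return self.massflow / self.rho

    @property
    def stroke_volume(self) -> float:
        """∫Q dt / ρ over one period (periodic rectangle rule, exact)."""
        return float(np.sum(self.massflow) * self.dt / self.rho)

    def scaled(self, factor: float) -> "Waveform":
        return replace(self, massflow=self.massflow * factor)


@dataclass(frozen=True)
class CaseConfig:
    """One gravity case: body force, inflow scaling, resistance overrides."""

    name: str = "gravity"
    g: float = 9.81
    sv_scale: float = 1.0
    region_resistance_multipliers: dict[str, float] = field(default_factory=dict)
    n_cycles: int = 4
    dt: float = 0.001
    cycle_tolerance: float = 0.03

    def __post_init__(self) -> None:
        if self.g < 0 or self.sv_scale <= 0 or self.dt <= 0 or self.n_cycles < 1:
            raise ValueError("invalid case configuration")


GRAVITY_CASE = CaseConfig(name="gravity", g=9.81, sv_scale=1.0)
MICROGRAVITY_CASE = CaseConfig(
    name="microgravity",
    g=0.0,
    sv_scale=1.2,
    region_resistance_multipliers={"external_iliac": 1.93},
)


@dataclass
class InstantSolution:
    node_pressures: dict[str, float]
    segment_flows: dict[str, float]
    segment_viscosities: dict[str, float]
    outlet_flows: dict[str, float]
    picard_iterations: int


@dataclass
class CaseResult:
    """Final-cycle series for one gravity case."""

    case: CaseConfig
    times: np.ndarray
    node_pressures: dict[str, np.ndarray]
    segment_flows: dict[str, np.ndarray]
    segment_viscosities: dict[str, np.ndarray]
    outlet_flows: dict[str, np.ndarray]
    wall_shear: dict[str, np.ndarray]
    cycles_run: int
    cycle_changes: list[float]

    def cycle_average_outlet_flow(self, outlet_id: str) -> float:
        return float(np.mean(self.outlet_flows[outlet_id]))

    def region_outlet_flow(self, net: NetworkGraph, region: str) -> float:
        """Cycle-averaged total flow through all outlets of a region."""
        ids = [o.spec.outlet_id for o in net.outlets if o.spec.region == region]
        if not ids:
            raise ValueError(f"no outlets in region {region!r}")
        return float(sum(np.mean(self.outlet_flows[i]) for i in ids))


def segment_resistance(seg: VesselSegment, mu: float) -> float:
    """Hagen-Poiseuille resistance of the conduit at viscosity ``mu``."""
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    return poiseuille_resistance(mu, seg.length, seg.radius)


class _Assembled:
    """Index maps and constant arrays reused across time steps."""

    def __init__(self, net: NetworkGraph, g: float, params: RheologyParams):
        net.validate()
        self.net = net
        self.params = params
        self.nodes = sorted(net.node_elevations)
        self.idx = {n: i for i, n in enumerate(self.nodes)}
        self.z = np.array([net.node_elevations[n] for n in self.nodes])
        self.segs = net.segments
        self.s_from = np.array([self.idx[s.from_node] for s in self.segs])
        self.s_to = np.array([self.idx[s.to_node] for s in self.segs])
        self.s_radius = np.array([s.radius for s in self.segs])
        self.s_length = np.array([s.length for s in self.segs])
        self.s_geom = math.pi * self.s_radius**4 / (8.0 * self.s_length)
        self.o_node = np.array([self.idx[o.node] for o in net.outlets])
        self.o_cond = np.array([1.0 / o.spec.resistance for o in net.outlets])
        # distal datum: physical P = 0 at the outlet node elevation
        self.o_pstar = params.rho * g * self.z[self.o_node]
        self.inlet = self.idx[net.inlet_node]
        self.rho_g_z = params.rho * g * self.z

    def viscosity(self, flows: np.ndarray) -> np.ndarray:
        mu = np.empty(len(self.segs))
        for k, s in enumerate(self.segs):
            gamma = max(
                poiseuille_wall_shear_rate(flows[k], s.radius), SHEAR_RATE_FLOOR
            )
            mu[k] = blended_viscosity(2.0 * s.radius, gamma, self.params)
        return mu

    def solve_linear(self, mu: np.ndarray, q_in: float) -> tuple[np.ndarray, np.ndarray]:
        """One linear nodal solve at fixed viscosities. Returns (P*, flows)."""
        n = len(self.nodes)
        cond = self.s_geom / mu
        a = np.zeros((n, n))
        b = np.zeros(n)
        np.add.at(a, (self.s_from, self.s_from), cond)
        np.add.at(a, (self.s_to, self.s_to), cond)
        np.add.at(a, (self.s_from, self.s_to), -cond)
        np.add.at(a, (self.s_to, self.s_from), -cond)
        np.add.at(a, (self.o_node, self.o_node), self.o_cond)
        np.add.at(b, self.o_node, self.o_cond * self.o_pstar)
        b[self.inlet] += q_in
        try:
            pstar = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular nodal system: {exc}") from exc
        flows = cond * (pstar[self.s_from] - pstar[self.s_to])
        return pstar, flows


def _solve_fixed_point(
    asm: _Assembled,
    q_in: float,
    mu0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    relax: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Under-relaxed Picard iteration on segment viscosities."""
    if mu0 is None:
        mu = np.array(
            [
                blended_viscosity(2.0 * s.radius, SHEAR_RATE_FLOOR, asm.params)
                for s in asm.segs
            ]
        )
    else:
        mu = mu0.copy()
    pstar = flows = None
    for it in range(1, max_iter + 1):
        pstar, flows = asm.solve_linear(mu, q_in)
        mu_new = asm.viscosity(flows)
        change = float(np.max(np.abs(mu_new - mu) / mu))
        if change < tol:
            # return the viscosities the final linear solve actually used,
            # keeping pressures, flows and viscosities self-consistent
            return pstar, flows, mu, it
        mu = (1.0 - relax) * mu + relax * mu_new
    raise RuntimeError(
        f"viscosity fixed point not converged after {max_iter} iterations "
        f"(last relative change {change:.3e})"
    )


def solve_instant(
    net: NetworkGraph,
    q_in: float,
    g: float,
    params: RheologyParams | None = None,
    mu0: np.ndarray | None = None,
    tol: float = 1e-6,
) -> InstantSolution:
    """Solve the network at one instant of inflow ``q_in`` (m³·s⁻¹)."""
    params = params if params is not None else RheologyParams()
    asm = _Assembled(net, g, params)
    pstar, flows, mu, iters = _solve_fixed_point(asm, q_in, mu0, tol=tol)
    p = pstar - asm.rho_g_z
    outlet_flows = {
        o.spec.outlet_id: float(
            asm.o_cond[k] * (pstar[asm.o_node[k]] - asm.o_pstar[k])
        )
        for k, o in enumerate(net.outlets)
    }
    return InstantSolution(
        node_pressures={n: float(p[i]) for n, i in asm.idx.items()},
        segment_flows={s.segment_id: float(flows[k]) for k, s in enumerate(asm.segs)},
        segment_viscosities={s.segment_id: float(mu[k]) for k, s in enumerate(asm.segs)},
        outlet_flows=outlet_flows,
        picard_iterations=iters,
    )


def _march_one_cycle(
    asm: _Assembled, q_series: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Solve every instant of one cycle; warm-start viscosity step-to-step.

    Each cycle starts from the same cold state so consecutive cycles are
    bitwise identical (the network carries no memory).
    """
    n_t = len(q_series)
    n_seg = len(asm.segs)
    n_node = len(asm.nodes)
    n_out = len(asm.o_node)
    flows = np.empty((n_t, n_seg))
    press = np.empty((n_t, n_node))
    visc = np.empty((n_t, n_seg))
    q_out = np.empty((n_t, n_out))
    mu = None
    for i, q in enumerate(q_series):
        pstar, f, mu, _ = _solve_fixed_point(asm, float(q), mu)
        flows[i] = f
        visc[i] = mu
        press[i] = pstar - asm.rho_g_z
        q_out[i] = asm.o_cond * (pstar[asm.o_node] - asm.o_pstar)
    return press, flows, visc, q_out


def run_case(
    net: NetworkGraph,
    wave: Waveform,
    cc: CaseConfig,
    params: RheologyParams | None = None,
    stop_on_convergence: bool = True,
) -> CaseResult:
    """March the quasi-static solve over cardiac cycles; keep the final one.

    Cycle-averaged outlet flows are compared between consecutive cycles;
    the run stops once every change falls below ``cc.cycle_tolerance``
    (always at cycle 2 for this memoryless solver) or errors out if the
    criterion is still unmet after ``cc.n_cycles``.
    """
    params = params if params is not None else RheologyParams()
    if abs(wave.dt - cc.dt) > 1e-12 * cc.dt:
        raise ValueError(
            f"waveform sampling dt={wave.dt} does not match case dt={cc.dt}"
        )
    asm = _Assembled(net, cc.g, params)
    q_series = wave.volumetric_flow
    cycle_changes: list[float] = []
    prev_avg = None
    result = None
    cycles_run = 0
    for cycle in range(1, cc.n_cycles + 1):
        press, flows, visc, q_out = _march_one_cycle(asm, q_series)
        cycles_run = cycle
        avg = q_out.mean(axis=0)
        result = (press, flows, visc, q_out)
        if prev_avg is not None:
            denom = np.where(np.abs(prev_avg) > 0, np.abs(prev_avg), 1.0)
            change = float(np.max(np.abs(avg - prev_avg) / denom))
            cycle_changes.append(change)
            if change < cc.cycle_tolerance and stop_on_convergence:
                break
        prev_avg = avg
    else:
        if cycle_changes and cycle_changes[-1] >= cc.cycle_tolerance:
            raise RuntimeError(
                f"cyclic convergence not reached after {cc.n_cycles} cycles "
                f"(last change {cycle_changes[-1]:.3e})"
            )
    press, flows, visc, q_out = result
    wall_shear = {}
    for k, s in enumerate(asm.segs):
        wall_shear[s.segment_id] = (
            4.0 * visc[:, k] * flows[:, k] / (math.pi * s.radius**3)
        )
    return CaseResult(
        case=cc,
        times=wave.time.copy(),
        node_pressures={n: press[:, i] for n, i in asm.idx.items()},
        segment_flows={s.segment_id: flows[:, k] for k, s in enumerate(asm.segs)},
        segment_viscosities={s.segment_id: visc[:, k] for k, s in enumerate(asm.segs)},
        outlet_flows={
            o.spec.outlet_id: q_out[:, k] for k, o in enumerate(net.outlets)
        },
        wall_shear=wall_shear,
        cycles_run=cycles_run,
        cycle_changes=cycle_changes,
    )


def apply_microgravity(
    wave: Waveform,
    outlets: tuple[OutletAttachment, ...],
    cc_gravity: CaseConfig,
    cc_micro: CaseConfig = MICROGRAVITY_CASE,
) -> tuple[Waveform, tuple[OutletAttachment, ...], CaseConfig]:
    """Transform gravity-case inputs into the simulated-microgravity case.

    The inflow waveform is vertically scaled so stroke volume rises by the
    configured factor (default 1.2); outlets in regions listed in the
    microgravity resistance multipliers (default: external iliac ×1.93) get
    their resistance scaled with the effective viscosity recomputed; gravity
    is set to the microgravity value (default 0). All other outlets keep
    their Earth-gravity resistances.
    """
    scaled_wave = wave.scaled(cc_micro.sv_scale / cc_gravity.sv_scale)
    multipliers = cc_micro.region_resistance_multipliers
    touched = {region: False for region in multipliers}
    new_outlets = []
    for o in outlets:
        factor = multipliers.get(o.spec.region)
        if factor is None:
            new_outlets.append(o)
            continue
        touched[o.spec.region] = True
        spec = o.spec
        new_r = spec.resistance * factor
        new_spec = replace(
            spec,
            resistance=new_r,
            effective_viscosity=resistance_to_effective_viscosity(
                new_r, spec.radius, spec.extrusion_length
            ),
        )
        new_outlets.append(OutletAttachment(node=o.node, spec=new_spec))
    for region, found in touched.items():
        if not found:
            warnings.warn(
                f"no outlets labelled {region!r}; resistance multiplier not applied",
                stacklevel=2,
            )
    return scaled_wave, tuple(new_outlets), cc_micro
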