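import math
from dataclasses import replace

import numpy as np
import pytest

from gravinet.boundary_conditions import make_outlet_spec
from gravinet.network_solver import (
    GRAVITY_CASE,
    MICROGRAVITY_CASE,
    CaseConfig,
    NetworkGraph,
    OutletAttachment,
    VesselSegment,
    Waveform,
    apply_microgravity,
    run_case,
    segment_resistance,
    solve_instant,
)
from gravinet.rheology import RheologyParams
from gravinet.synthetic_geometry import WaveformSpec, generate_inflow

RHO = 1050.0


def pipe_network(radius=2e-3, length=0.1, dz=0.0, r_out=1e9):
    seg = VesselSegment("pipe", "A", "B", radius, max(length, abs(dz)), dz)
    outlet = OutletAttachment("B", make_outlet_spec("out", "test", radius, r_out))
    return NetworkGraph(
        node_elevations={"A": 0.0, "B": dz},
        segments=(seg,),
        inlet_node="A",
        outlets=(outlet,),
    )


def y_network():
    segs = (
        VesselSegment("trunk", "A", "B", 3e-3, 0.1, 0.0),
        VesselSegment("left", "B", "C1", 2e-3, 0.08, 0.0),
        VesselSegment("right", "B", "C2", 2e-3, 0.08, 0.0),
    )
    outlets = (
        OutletAttachment("C1", make_outlet_spec("o1", "test", 2e-3, 5e8)),
        OutletAttachment("C2", make_outlet_spec("o2", "test", 2e-3, 5e8)),
    )
    return NetworkGraph(
        node_elevations={"A": 0.0, "B": 0.0, "C1": 0.0, "C2": 0.0},
        segments=segs,
        inlet_node="A",
        outlets=outlets,
    )


class TestSegmentResistance:
    def test_direct_formula_oracle(self):
        seg = VesselSegment("s", "a", "b", 1e-3, 0.1, 0.0)
        expected = 8 * 0.0035 * 0.1 / (math.pi * (1e-3) ** 4)
        assert expected == pytest.approx(8.913e8, rel=1e-3)
        assert segment_resistance(seg, 0.0035) == pytest.approx(expected, rel=1e-15)

    def test_halving_radius_multiplies_by_16(self):
        big = VesselSegment("s", "a", "b", 2e-3, 0.1, 0.0)
        small = VesselSegment("s", "a", "b", 1e-3, 0.1, 0.0)
        assert segment_resistance(small, 0.004) == pytest.approx(
            16 * segment_resistance(big, 0.004), rel=1e-15
        )

    def test_linear_in_viscosity(self):
        seg = VesselSegment("s", "a", "b", 1e-3, 0.1, 0.0)
        assert segment_resistance(seg, 0.007) == pytest.approx(
            2 * segment_resistance(seg, 0.0035), rel=1e-15
        )


class TestSolveInstant:
    def test_single_pipe_pressure_drop(self, params):
        net = pipe_network()
        q = 1e-5
        sol = solve_instant(net, q, g=0.0, params=params)
        seg = net.segments[0]
        mu = sol.segment_viscosities["pipe"]
        dp = sol.node_pressures["A"] - sol.node_pressures["B"]
        assert sol.segment_flows["pipe"] == pytest.approx(q, rel=1e-12)
        assert dp == pytest.approx(segment_resistance(seg, mu) * q, rel=1e-9)

    def test_hydrostatic_column(self, params):
        h = 0.3
        net = pipe_network(dz=h, length=0.3)
        sol = solve_instant(net, 0.0, g=9.81, params=params)
        assert sol.segment_flows["pipe"] == pytest.approx(0.0, abs=1e-18)
        dp = sol.node_pressures["A"] - sol.node_pressures["B"]
        assert dp == pytest.approx(1050.0 * 9.81 * h, rel=1e-12)

    def test_symmetric_y_equal_branch_flows(self, params):
        sol = solve_instant(y_network(), 2e-5, g=0.0, params=params)
        assert sol.segment_flows["left"] == pytest.approx(
            sol.segment_flows["right"], rel=1e-12
        )
        assert sol.outlet_flows["o1"] == pytest.approx(1e-5, rel=1e-9)

    def test_fixed_point_independent_of_initial_guess(self, params):
        net = y_network()
        n_seg = len(net.segments)
        sol_a = solve_instant(net, 3e-5, 0.0, params, mu0=None, tol=1e-12)
        sol_b = solve_instant(
            net, 3e-5, 0.0, params, mu0=np.full(n_seg, 0.16), tol=1e-12
        )
        for sid in sol_a.segment_flows:
            assert sol_a.segment_flows[sid] == pytest.approx(
                sol_b.segment_flows[sid], rel=1e-8
            )

    def test_piezometric_equivalence_at_zero_g(self, params):
        h = 0.25
        elevated = pipe_network(dz=h, length=0.3)
        flat = pipe_network(dz=0.0, length=0.3)
        sol_e = solve_instant(elevated, 1e-5, g=0.0, params=params)
        sol_f = solve_instant(flat, 1e-5, g=0.0, params=params)
        assert sol_e.segment_flows["pipe"] == pytest.approx(
            sol_f.segment_flows["pipe"], rel=1e-12
        )
        assert sol_e.node_pressures["A"] == pytest.approx(
            sol_f.node_pressures["A"], rel=1e-12
        )

    def test_disconnected_network_rejected(self):
        seg = VesselSegment("s", "A", "B", 1e-3, 0.1, 0.0)
        out = OutletAttachment("B", make_outlet_spec("o", "x", 1e-3, 1e9))
        net = NetworkGraph(
            node_elevations={"A": 0.0, "B": 0.0, "C": 0.0},
            segments=(seg,),
            inlet_node="A",
            outlets=(out,),
        )
        with pytest.raises(ValueError, match="disconnected"):
            solve_instant(net, 1e-5, 0.0)


class TestNetworkValidation:
    def test_leaf_without_outlet_rejected(self):
        segs = (
            VesselSegment("s1", "A", "B", 1e-3, 0.1, 0.0),
            VesselSegment("s2", "B", "C", 1e-3, 0.1, 0.0),
        )
        net = NetworkGraph(
            node_elevations={"A": 0.0, "B": 0.0, "C": 0.0},
            segments=segs,
            inlet_node="A",
            outlets=(),
        )
        with pytest.raises(ValueError, match="leaf"):
            net.validate()

    def test_inconsistent_elevation_rejected(self):
        seg = VesselSegment("s", "A", "B", 1e-3, 0.1, 0.05)
        net = NetworkGraph(
            node_elevations={"A": 0.0, "B": 0.2},
            segments=(seg,),
            inlet_node="A",
            outlets=(OutletAttachment("B", make_outlet_spec("o", "x", 1e-3, 1e9)),),
        )
        with pytest.raises(ValueError, match="delta_z"):
            net.validate()

    def test_segment_dz_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="delta_z"):
            VesselSegment("s", "A", "B", 1e-3, 0.1, 0.2)


@pytest.fixture(scope="module")
def small_wave():
    return generate_inflow(WaveformSpec(), dt=0.01)


class TestRunCase:
    def test_memoryless_cycles_identical(self, small_wave, params):
        net = y_network()
        cc2 = replace(GRAVITY_CASE, dt=0.01, n_cycles=2)
        cc3 = replace(GRAVITY_CASE, dt=0.01, n_cycles=3)
        r2 = run_case(net, small_wave, cc2, params, stop_on_convergence=False)
        r3 = run_case(net, small_wave, cc3, params, stop_on_convergence=False)
        for oid in r2.outlet_flows:
            np.testing.assert_allclose(
                r2.outlet_flows[oid], r3.outlet_flows[oid], rtol=1e-12
            )
        assert max(r3.cycle_changes) == 0.0

    def test_total_outlet_volume_equals_stroke_volume(self, small_wave, params):
        net = y_network()
        cc = replace(GRAVITY_CASE, dt=0.01)
        res = run_case(net, small_wave, cc, params)
        dt = small_wave.dt
        vol_out = sum(np.sum(q) * dt for q in res.outlet_flows.values())
        assert vol_out == pytest.approx(small_wave.stroke_volume, rel=1e-9)

    def test_dt_mismatch_rejected(self, small_wave, params):
        with pytest.raises(ValueError, match="dt"):
            run_case(y_network(), small_wave, replace(GRAVITY_CASE, dt=0.001), params)

    def test_unreachable_tolerance_errors(self, small_wave, params):
        cc = replace(GRAVITY_CASE, dt=0.01, n_cycles=2, cycle_tolerance=0.0)
        with pytest.raises(RuntimeError, match="convergence"):
            run_case(y_network(), small_wave, cc, params)

    def test_wall_shear_matches_poiseuille(self, small_wave, params):
        net = y_network()
        cc = replace(GRAVITY_CASE, dt=0.01)
        res = run_case(net, small_wave, cc, params)
        seg = net.segments[0]
        expected = (
            4.0
            * res.segment_viscosities["trunk"]
            * res.segment_flows["trunk"]
            / (math.pi * seg.radius**3)
        )
        np.testing.assert_allclose(res.wall_shear["trunk"], expected, rtol=1e-12)


class TestMassConservation:
    def test_every_node_every_instant(self, default_network, gravity_result, coarse_wave):
        net = default_network
        res = gravity_result
        q_in = coarse_wave.volumetric_flow
        scale = float(np.max(np.abs(q_in)))
        balance = {n: np.zeros_like(q_in) for n in net.node_elevations}
        for s in net.segments:
            balance[s.from_node] -= res.segment_flows[s.segment_id]
            balance[s.to_node] += res.segment_flows[s.segment_id]
        for o in net.outlets:
            balance[o.node] -= res.outlet_flows[o.spec.outlet_id]
        balance[net.inlet_node] += q_in
        worst = max(float(np.max(np.abs(v))) for v in balance.values())
        assert worst <= 1e-9 * scale


class TestApplyMicrogravity:
    def _outlets(self):
        return (
            OutletAttachment("n1", make_outlet_spec("ei", "external_iliac", 4e-3, 1e8)),
            OutletAttachment("n2", make_outlet_spec("re", "renal", 3e-3, 2e8)),
        )

    def test_stroke_volume_ratio_exactly_1_2(self):
        wave = generate_inflow(WaveformSpec(), dt=0.01)
        scaled, _, cc = apply_microgravity(wave, self._outlets(), GRAVITY_CASE)
        assert scaled.stroke_volume / wave.stroke_volume == pytest.approx(
            1.2, rel=1e-15
        )
        assert cc.g == 0.0

    def test_external_iliac_resistance_ratio_exactly_1_93(self):
        wave = generate_inflow(WaveformSpec(), dt=0.01)
        _, outlets, _ = apply_microgravity(wave, self._outlets(), GRAVITY_CASE)
        by_id = {o.spec.outlet_id: o.spec for o in outlets}
        assert by_id["ei"].resistance / 1e8 == pytest.approx(1.93, rel=1e-15)
        assert by_id["re"].resistance / 2e8 == pytest.approx(1.0, rel=1e-15)

    def test_effective_viscosity_recomputed(self):
        wave = generate_inflow(WaveformSpec(), dt=0.01)
        _, outlets, _ = apply_microgravity(wave, self._outlets(), GRAVITY_CASE)
        spec = {o.spec.outlet_id: o.spec for o in outlets}["ei"]
        back = 8 * spec.effective_viscosity * spec.extrusion_length / (
            math.pi * spec.radius**4
        )
        assert back == pytest.approx(spec.resistance, rel=1e-12)

    def test_missing_region_warns_and_noop(self):
        wave = generate_inflow(WaveformSpec(), dt=0.01)
        outlets = (
            OutletAttachment("n2", make_outlet_spec("re", "renal", 3e-3, 2e8)),
        )
        with pytest.warns(UserWarning, match="external_iliac"):
            _, out, _ = apply_microgravity(wave, outlets, GRAVITY_CASE)
        assert out[0].spec.resistance == 2e8


class TestGravityDirectionality:
    def test_cra_flow_increases_and_iliac_fraction_decreases(
        self, default_network, gravity_result, microgravity_result, microgravity_setup
    ):
        net_u, _, _ = microgravity_setup
        g, ug = gravity_result, microgravity_result
        cra_g = g.region_outlet_flow(default_network, "ophthalmic")
        cra_u = ug.region_outlet_flow(net_u, "ophthalmic")
        assert cra_u > cra_g
        tot_g = sum(np.mean(q) for q in g.outlet_flows.values())
        tot_u = sum(np.mean(q) for q in ug.outlet_flows.values())
        ei_g = g.region_outlet_flow(default_network, "external_iliac") / tot_g
        ei_u = ug.region_outlet_flow(net_u, "external_iliac") / tot_u
        assert ei_u < ei_g
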