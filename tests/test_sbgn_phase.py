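"""Port machinery, signed angles, rotation decisions, gathering, phase 2."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbgnpd import (
    CompoundGraph,
    EdgeKind,
    ForceEngine,
    LayoutParams,
    NodeKind,
    Orientation,
    Point,
    Rect,
    RotationAccumulator,
    RotationAction,
    approximate_locations,
    attach_ports,
    decide_rotation,
    detach_ports,
    properly_oriented_ratio,
    rotate_unit,
    rotational_force,
    run_phase2,
    select_and_apply_rotation,
    signed_angle,
)
from sbgnpd.sbgn_phase import AngleField, _neighbor_terms

from conftest import build_unit


def atan2_signed_angle(connection, neighbor, ideal):
    """Independent oracle: wrapped arctangent difference; positive when the
    neighbor lies on the non-left side of the connection→ideal ray."""
    a_n = math.atan2(neighbor.y - connection.y, neighbor.x - connection.x)
    a_i = math.atan2(ideal.y - connection.y, ideal.x - connection.x)
    d = math.degrees(a_n - a_i) % 360.0
    if d > 180.0:
        d -= 360.0
    elif d <= -180.0:
        d += 360.0
    return d


class TestSignedAngle:
    def test_aligned_neighbor_is_zero(self):
        assert signed_angle(Point(0, 0), Point(5, 5), Point(1, 1)) == 0.0

    def test_worked_right_turn_example(self):
        a = signed_angle(Point(0, 0), Point(1, 1), Point(1, 0))
        assert a == pytest.approx(45.0)

    def test_antiparallel_is_positive_180(self):
        a = signed_angle(Point(0, 0), Point(-3, 0), Point(1, 0))
        assert a == pytest.approx(180.0)
        assert a > 0

    def test_degenerate_vector_rejected(self):
        with pytest.raises(ValueError):
            signed_angle(Point(0, 0), Point(0, 0), Point(1, 0))

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 10 ** 9))
    def test_agrees_with_arctangent_oracle(self, seed):
        rng = random.Random(seed)
        pts = []
        while len(pts) < 3:
            p = Point(rng.uniform(-100, 100), rng.uniform(-100, 100))
            if all(math.hypot(p.x - q.x, p.y - q.y) > 1e-3 for q in pts):
                pts.append(p)
        conn, nb, ideal = pts
        got = signed_angle(conn, nb, ideal)
        want = atan2_signed_angle(conn, nb, ideal)
        assert abs(abs(got) - abs(want)) < 1e-9
        if abs(abs(want) - 180.0) > 1e-9 and abs(want) > 1e-9:
            assert math.copysign(1, got) == math.copysign(1, want)

    def test_vectorized_field_matches_scalar_sum(self):
        rng = random.Random(2)
        pts = lambda k: [(rng.uniform(-200, 200), rng.uniform(-200, 200))
                         for _ in range(k)]
        cg, unit, params = build_unit(pts(3), pts(2), pts(2))
        eng = ForceEngine(cg, params, [unit])
        eng.read_geometry()
        field = AngleField(eng, [unit])
        ang, _ = field.compute(params.ideal_edge_length)
        assert ang.sum() == pytest.approx(
            rotational_force(unit, cg, params.ideal_edge_length))


class TestAttachDetach:
    def test_dummy_structure_counts(self):
        cg, unit, _ = build_unit([(100, 0), (100, 50)], [(-100, 0), (-90, 40)],
                                 [(0, 100)])
        # 1 process + 5 EPNs + 2 ports + 1 container
        assert len(cg.nodes) == 9
        rigid = [e for e in cg.edges if e.kind is EdgeKind.RIGID]
        assert len(rigid) == 2
        assert unit.container.kind is NodeKind.PROCESS_CONTAINER
        assert unit.process.parent_node is unit.container
        # substrate arcs moved onto the input port
        assert all(e.kind is EdgeKind.CONSUMPTION
                   for e in unit.input_port.edges
                   if e.kind is not EdgeKind.RIGID)

    def test_map_without_processes_unchanged(self):
        cg = CompoundGraph()
        cg.add_node("m", NodeKind.MACROMOLECULE, Rect(0, 0, 40, 20))
        assert attach_ports(cg, LayoutParams()) == []
        assert len(cg.nodes) == 1

    def test_double_attach_rejected(self):
        cg, _, params = build_unit([(100, 0)], [(-100, 0)])
        with pytest.raises(ValueError, match="already has ports"):
            attach_ports(cg, params)

    def test_detach_restores_original_structure(self):
        cg, unit, params = build_unit([(100, 0)], [(-100, 0)], [(0, 100)])
        arcs_before = sorted(
            (e.id, e.kind.value) for e in cg.edges
            if e.kind is not EdgeKind.RIGID)
        detach_ports(cg, [unit])
        assert sorted((e.id, e.kind.value) for e in cg.edges) == arcs_before
        proc = cg.nodes["p"]
        assert proc.parent_node is None
        assert cg.degree(proc) == 3
        assert all(n.kind not in (NodeKind.PORT, NodeKind.PROCESS_CONTAINER)
                   for n in cg.nodes.values())


class TestRotationalForce:
    def test_zero_when_neighbors_at_ideal_positions(self):
        L = LayoutParams().ideal_edge_length
        cg, unit, params = build_unit([(-150, 0)], [(150, 0)], [(0, -L)])
        assert rotational_force(unit, cg, params.ideal_edge_length) == \
            pytest.approx(0.0, abs=1e-9)

    def test_single_substrate_at_plus_ninety(self):
        # input port faces left; a substrate straight above it deviates 90°
        # on the positive (right-turn) side
        cg, unit, params = build_unit([(-12, -150)], [])
        assert rotational_force(unit, cg, params.ideal_edge_length) == \
            pytest.approx(90.0)

    def test_mirror_configurations_have_opposite_sign(self):
        rng = random.Random(5)
        for _ in range(20):
            pts = [(rng.uniform(-200, 200), rng.uniform(50, 200))
                   for _ in range(3)]
            mirrored = [(x, -y) for x, y in pts]
            cg1, u1, p = build_unit(pts[:2], pts[2:])
            cg2, u2, _ = build_unit(mirrored[:2], mirrored[2:])
            f1 = rotational_force(u1, cg1, p.ideal_edge_length)
            f2 = rotational_force(u2, cg2, p.ideal_edge_length)
            assert f1 == pytest.approx(-f2, abs=1e-9)

    def test_additive_over_neighbor_subsets(self):
        subs = [(-150, 60), (-120, -80)]
        prods = [(140, 30)]
        cg_all, u_all, p = build_unit(subs, prods)
        cg_s, u_s, _ = build_unit(subs, [])
        cg_p, u_p, _ = build_unit([], prods)
        total = rotational_force(u_all, cg_all, p.ideal_edge_length)
        parts = rotational_force(u_s, cg_s, p.ideal_edge_length) + \
            rotational_force(u_p, cg_p, p.ideal_edge_length)
        assert total == pytest.approx(parts, abs=1e-9)


def accumulate_window(unit, params):
    acc = RotationAccumulator()
    for _ in range(params.rp):
        for conn, nb, ideal in _neighbor_terms(unit,
                                               params.ideal_edge_length):
            acc.add(signed_angle(conn, nb, ideal))
    return acc


class TestDecideRotation:
    def test_cancelled_signal_with_obtuse_majority_swaps(self):
        # substrates sit on the product side (and vice versa), split
        # symmetrically so the signed sums cancel
        cg, unit, params = build_unit(
            sub_pos=[(150, 80), (150, -80)], prod_pos=[(-150, 80), (-150, -80)])
        acc = accumulate_window(unit, params)
        assert abs(acc.signed_sum) < 1e-9
        assert decide_rotation(unit, acc, params) is RotationAction.SWAP_180

    def test_neighbors_near_ideal_no_action(self):
        cg, unit, params = build_unit([(-150, 20)], [(150, -10)])
        acc = accumulate_window(unit, params)
        assert decide_rotation(unit, acc, params) is RotationAction.NONE

    def test_sustained_plus_ninety_triggers_clockwise(self):
        cg, unit, params = build_unit([(-12, -150)], [])
        acc = accumulate_window(unit, params)
        assert acc.signed_sum / acc.samples == pytest.approx(90.0)
        assert decide_rotation(unit, acc, params) is RotationAction.CW_90

    def test_sustained_minus_ninety_triggers_counterclockwise(self):
        cg, unit, params = build_unit([(-12, 150)], [])
        acc = accumulate_window(unit, params)
        assert decide_rotation(unit, acc, params) is RotationAction.CCW_90


class TestRotateUnit:
    def test_swap_reverses_orientation_and_ports(self):
        cg, unit, _ = build_unit([(-150, 0)], [(150, 0)])
        pin_before = (unit.input_port.rect.cx, unit.input_port.rect.cy)
        pout_before = (unit.output_port.rect.cx, unit.output_port.rect.cy)
        rotate_unit(unit, RotationAction.SWAP_180)
        assert unit.orientation is Orientation.RIGHT_TO_LEFT
        assert (unit.input_port.rect.cx, unit.input_port.rect.cy) == \
            pytest.approx(pout_before)
        assert (unit.output_port.rect.cx, unit.output_port.rect.cy) == \
            pytest.approx(pin_before)

    def test_four_clockwise_rotations_are_identity(self):
        cg, unit, _ = build_unit([(-150, 0)], [(150, 0)])
        before = (unit.orientation,
                  unit.input_port.rect.cx, unit.input_port.rect.cy)
        for _ in range(4):
            rotate_unit(unit, RotationAction.CW_90)
        after = (unit.orientation,
                 unit.input_port.rect.cx, unit.input_port.rect.cy)
        assert after == pytest.approx(before)

    def test_counterclockwise_from_l2r_is_bottom_to_top(self):
        cg, unit, _ = build_unit([(-150, 0)], [(150, 0)])
        rotate_unit(unit, RotationAction.CCW_90)
        assert unit.orientation is Orientation.BOTTOM_TO_TOP
        # input port below the process center (y grows downward)
        assert unit.input_port.rect.cy > unit.process.rect.cy

    def test_process_rect_unchanged_by_rotation(self):
        cg, unit, _ = build_unit([(-150, 0)], [(150, 0)])
        r = unit.process.rect.copy()
        rotate_unit(unit, RotationAction.CW_90)
        assert (r.x, r.y, r.width, r.height) == (
            unit.process.rect.x, unit.process.rect.y,
            unit.process.rect.width, unit.process.rect.height)

    def test_none_action_rejected(self):
        cg, unit, _ = build_unit([(-150, 0)], [(150, 0)])
        with pytest.raises(ValueError):
            rotate_unit(unit, RotationAction.NONE)


class TestSelectAndApply:
    def build_two_qualifying(self):
        cg = CompoundGraph()
        units = []
        params = LayoutParams()
        for k, x0 in enumerate((0.0, 600.0)):
            proc = cg.add_node(f"p{k}", NodeKind.PROCESS,
                               Rect(x0 - 10, -10, 20, 20))
            n = cg.add_node(f"s{k}", NodeKind.MACROMOLECULE,
                            Rect(x0 - 32, -160, 40, 20))
            cg.add_edge(f"e{k}", n, proc, EdgeKind.CONSUMPTION)
        units = attach_ports(cg, params)
        accs = [accumulate_window(u, params) for u in units]
        return cg, units, accs, params

    def test_exactly_one_rotation_per_window(self):
        cg, units, accs, params = self.build_two_qualifying()
        assert all(decide_rotation(u, a, params) is not RotationAction.NONE
                   for u, a in zip(units, accs))
        before = [u.orientation for u in units]
        applied = select_and_apply_rotation(cg, units, accs, params,
                                            random.Random(0))
        assert applied is not None
        changed = sum(1 for u, o in zip(units, before) if u.orientation != o)
        assert changed == 1

    def test_accumulators_reset_after_window(self):
        cg, units, accs, params = self.build_two_qualifying()
        select_and_apply_rotation(cg, units, accs, params, random.Random(0))
        assert all(a.samples == 0 and a.signed_sum == 0 for a in accs)

    def test_no_qualifying_units_no_change(self):
        cg, unit, params = build_unit([(-150, 0)], [(150, 0)])
        acc = accumulate_window(unit, params)
        applied = select_and_apply_rotation(cg, [unit], [acc], params,
                                            random.Random(0))
        assert applied is None
        assert unit.orientation is Orientation.LEFT_TO_RIGHT

    def test_same_seed_same_choice(self):
        picks = []
        for _ in range(2):
            cg, units, accs, params = self.build_two_qualifying()
            applied = select_and_apply_rotation(cg, units, accs, params,
                                                random.Random(123))
            picks.append((applied[0].process.id, applied[1]))
        assert picks[0] == picks[1]


class TestTransferForces:
    def test_port_force_moves_to_container(self):
        cg, unit, params = build_unit([(-150, 0)], [(150, 0)])
        eng = ForceEngine(cg, params, [unit])
        eng.read_geometry()
        eng.forces[eng.index[unit.input_port.id]] = (5.0, 0.0)
        eng.transfer_unit_forces()
        assert eng.forces[eng.index[unit.container.id]] == \
            pytest.approx((5.0, 0.0))
        assert np.allclose(eng.forces[eng.index[unit.input_port.id]], 0.0)
        assert np.allclose(eng.forces[eng.index[unit.process.id]], 0.0)

    def test_opposite_port_forces_cancel(self):
        cg, unit, params = build_unit([(-150, 0)], [(150, 0)])
        eng = ForceEngine(cg, params, [unit])
        eng.read_geometry()
        eng.forces[eng.index[unit.input_port.id]] = (7.0, -2.0)
        eng.forces[eng.index[unit.output_port.id]] = (-7.0, 2.0)
        eng.transfer_unit_forces()
        assert np.allclose(eng.forces[eng.index[unit.container.id]], 0.0)

    def test_unit_stays_rigid_under_random_forces(self):
        rng = random.Random(8)
        cg, unit, params = build_unit([(-150, 0)], [(150, 0)])
        eng = ForceEngine(cg, params, [unit])
        offsets_before = (
            unit.input_port.rect.cx - unit.process.rect.cx,
            unit.input_port.rect.cy - unit.process.rect.cy,
            unit.output_port.rect.cx - unit.process.rect.cx,
            unit.output_port.rect.cy - unit.process.rect.cy,
        )
        for _ in range(10):
            eng.read_geometry()
            eng.forces[:] = [[rng.uniform(-50, 50), rng.uniform(-50, 50)]
                             for _ in range(len(eng.nodes))]
            eng.transfer_unit_forces()
            eng.move_nodes(1.0)
        offsets_after = (
            unit.input_port.rect.cx - unit.process.rect.cx,
            unit.input_port.rect.cy - unit.process.rect.cy,
            unit.output_port.rect.cx - unit.process.rect.cx,
            unit.output_port.rect.cy - unit.process.rect.cy,
        )
        assert offsets_after == pytest.approx(offsets_before, abs=1e-9)


class TestApproximateLocations:
    def build_gathering_map(self):
        cg = CompoundGraph()
        params = LayoutParams()
        p1 = cg.add_node("p1", NodeKind.PROCESS, Rect(-10, -10, 20, 20))
        p2 = cg.add_node("p2", NodeKind.PROCESS, Rect(800, -10, 20, 20))
        # hub substrate shared by both processes: degree 2, becomes the seed
        hub = cg.add_node("hub", NodeKind.MACROMOLECULE,
                          Rect(-200, -10, 40, 20))
        cg.add_edge("h1", hub, p1, EdgeKind.CONSUMPTION)
        cg.add_edge("h2", hub, p2, EdgeKind.CONSUMPTION)
        frees = []
        for i in range(3):
            n = cg.add_node(f"f{i}", NodeKind.MACROMOLECULE,
                            Rect(400 + 50 * i, 300, 40, 20))
            cg.add_edge(f"c{i}", n, p1, EdgeKind.CONSUMPTION)
            frees.append(n)
        prod = cg.add_node("o", NodeKind.MACROMOLECULE, Rect(100, -10, 40, 20))
        cg.add_edge("pr", p1, prod, EdgeKind.PRODUCTION)
        cg.add_edge("pr2", p2, prod, EdgeKind.PRODUCTION)
        units = attach_ports(cg, params)
        return cg, units, frees, hub, params

    def test_degree_one_substrates_gather_around_seed(self):
        cg, units, frees, hub, params = self.build_gathering_map()
        approximate_locations(cg, units, params, random.Random(0))
        hc = hub.rect.center
        for n in frees:
            c = n.rect.center
            assert math.hypot(c.x - hc.x, c.y - hc.y) <= params.ad + 1e-9

    def test_hop_nodes_never_moved(self):
        cg, units, frees, hub, params = self.build_gathering_map()
        hub_before = (hub.rect.x, hub.rect.y)
        prod_before = (cg.nodes["o"].rect.x, cg.nodes["o"].rect.y)
        approximate_locations(cg, units, params, random.Random(0))
        assert (hub.rect.x, hub.rect.y) == hub_before
        assert (cg.nodes["o"].rect.x, cg.nodes["o"].rect.y) == prod_before

    def test_lone_substrate_stays_within_ad_of_itself(self):
        cg, unit, params = build_unit([(300, 300)], [(-150, 0)])
        s = cg.nodes["s0"]
        before = s.rect.center
        approximate_locations(cg, [unit], params, random.Random(1))
        after = s.rect.center
        assert math.hypot(after.x - before.x, after.y - before.y) \
            <= params.ad + 1e-9

    def test_effector_teleports_to_nearer_anchor(self):
        cg, unit, params = build_unit([(-150, 0)], [(150, 0)],
                                      [(30, 400)])
        approximate_locations(cg, [unit], params, random.Random(2))
        eff = cg.nodes["f2"]
        c = eff.rect.center
        # nearer anchor for a node far below an L2R process is the bottom one
        anchor = (unit.process.rect.cx,
                  unit.process.rect.cy + params.ideal_edge_length)
        assert math.hypot(c.x - anchor[0], c.y - anchor[1]) \
            <= params.ad + 1e-9


class TestProperlyOrientedRatio:
    def test_perfect_configuration_scores_one(self):
        L = 70
        cg, unit, params = build_unit([(-150, 0)], [(150, 0)], [(0, -L)])
        assert properly_oriented_ratio(cg, [unit], params.at, L) == 1.0

    def test_half_proper_counts_half(self):
        cg, unit, params = build_unit(
            sub_pos=[(-150, 0), (150, 20)],   # second sits on the wrong side
            prod_pos=[(150, 0), (-150, -20)])
        ratio = properly_oriented_ratio(cg, [unit], params.at,
                                        params.ideal_edge_length)
        assert ratio == 0.5

    def test_invariant_under_translation_and_uniform_scaling(self):
        rng = random.Random(6)
        pts = lambda k: [(rng.uniform(-300, 300), rng.uniform(-300, 300))
                         for _ in range(k)]
        subs, prods, effs = pts(2), pts(2), pts(1)

        def build_scaled(s, dx, dy):
            f = lambda ps: [(x * s + dx, y * s + dy) for x, y in ps]
            cg, unit, params = build_unit(f(subs), f(prods), f(effs),
                                          process_size=20 * s)
            return properly_oriented_ratio(cg, [unit], params.at,
                                           params.ideal_edge_length * s)

        base = build_scaled(1.0, 0.0, 0.0)
        assert build_scaled(2.5, 1000.0, -500.0) == base

    def test_empty_map_scores_one(self):
        cg = CompoundGraph()
        assert properly_oriented_ratio(cg, [], 45.0) == 1.0


class TestRunPhase2:
    def test_same_seed_identical_result(self, quick_params):
        from sbgnpd import generate_pd_map, run_phase1, scatter_initial, \
            spec_for_node_count

        def run():
            pd = generate_pd_map(spec_for_node_count(40, seed=4))
            cg = pd.graph
            rng = random.Random(4)
            units = attach_ports(cg, quick_params)
            scatter_initial(cg, quick_params, rng)
            run_phase1(cg, quick_params, units)
            res = run_phase2(cg, units, quick_params, rng)
            coords = {nid: (n.rect.x, n.rect.y)
                      for nid, n in cg.nodes.items()}
            return res, coords

        r1, c1 = run()
        r2, c2 = run()
        assert c1 == c2
        assert (r1.iterations, r1.rotation_count, r1.swap_count,
                r1.final_ratio) == \
            (r2.iterations, r2.rotation_count, r2.swap_count, r2.final_ratio)

    def test_equilibrated_perfect_layout_stops_without_rotations(self):
        L = 70.0
        params = LayoutParams(max_iter=200, ap=0)
        cg, unit, _ = build_unit([(-unit_x(L), 0)], [(unit_x(L), 0)],
                                 params=params)
        res = run_phase2(cg, [unit], params, random.Random(0))
        assert res.rotation_count == 0 and res.swap_count == 0
        assert res.final_ratio == 1.0

    def test_vertical_neighbors_end_properly_oriented(self):
        # substrates above, products below: a quarter rotation (or
        # re-gathering) must fix the initial horizontal orientation
        params = LayoutParams(max_iter=400, seed=0)
        cg, unit, _ = build_unit([(0, -160)], [(0, 160)], params=params)
        res = run_phase2(cg, [unit], params, random.Random(0))
        assert res.final_ratio == 1.0
        assert unit.orientation in (Orientation.TOP_TO_BOTTOM,
                                    Orientation.BOTTOM_TO_TOP)


def unit_x(L):
    """Equilibrium-ish distance used to build near-relaxed fixtures."""
    return 12.0 + L
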