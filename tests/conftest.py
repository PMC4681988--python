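"""Shared fixtures: tiny hand-built maps and the seeded layout batch."""

from __future__ import annotations

import math
import random

import pytest

from sbgnpd import (
    CompoundGraph,
    EdgeKind,
    LayoutParams,
    NodeKind,
    Rect,
    attach_ports,
    detach_ports,
    generate_pd_map,
    properly_oriented_ratio,
    run_phase1,
    run_phase2,
    scatter_initial,
    spec_for_node_count,
    write_map,
)
from sbgnpd.packing import pack_disconnected
from sbgnpd.sbgn_phase import ProcessUnit


def build_unit(sub_pos=(), prod_pos=(), eff_pos=(), process_size=20.0,
               params=None):
    """One process at the origin with neighbors at given center positions;
    ports attached, left-to-right."""
    cg = CompoundGraph()
    half = process_size / 2.0
    proc = cg.add_node("p", NodeKind.PROCESS,
                       Rect(-half, -half, process_size, process_size))
    i = 0
    for x, y in sub_pos:
        n = cg.add_node(f"s{i}", NodeKind.MACROMOLECULE,
                        Rect(x - 20, y - 10, 40, 20))
        cg.add_edge(f"es{i}", n, proc, EdgeKind.CONSUMPTION)
        i += 1
    for x, y in prod_pos:
        n = cg.add_node(f"q{i}", NodeKind.MACROMOLECULE,
                        Rect(x - 20, y - 10, 40, 20))
        cg.add_edge(f"ep{i}", proc, n, EdgeKind.PRODUCTION)
        i += 1
    for x, y in eff_pos:
        n = cg.add_node(f"f{i}", NodeKind.MACROMOLECULE,
                        Rect(x - 20, y - 10, 40, 20))
        cg.add_edge(f"ee{i}", n, proc, EdgeKind.EFFECTOR)
        i += 1
    params = params or LayoutParams()
    units = attach_ports(cg, params)
    return cg, units[0], params


@pytest.fixture
def quick_params():
    """Reduced iteration budget for tests that exercise mechanics, not
    layout quality."""
    return LayoutParams(ip1=40, max_iter=120, ap=30, seed=7)


class BatchRecord:
    """Checks and metrics captured from one full layout run."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


def run_full_layout(seed: int, n_nodes: int) -> BatchRecord:
    """Layout one synthetic map with the published defaults, capturing the
    phase-1-only baseline ratio and structural checks along the way."""
    spec = spec_for_node_count(n_nodes, seed=seed)
    params = LayoutParams(seed=seed)
    pd = generate_pd_map(spec)
    cg = pd.graph
    rng = random.Random(seed)
    pack_disconnected(cg)
    units = attach_ports(cg, params)
    scatter_initial(cg, params, rng)
    run_phase1(cg, params, units)
    base_ratio = properly_oriented_ratio(cg, units, params.at,
                                         params.ideal_edge_length)
    res = run_phase2(cg, units, params, rng)

    def port_geometry_ok(u: ProcessUnit) -> bool:
        ax, ay = u.axis()
        cx, cy = u.process.rect.cx, u.process.rect.cy
        for port, s in ((u.input_port, -1.0), (u.output_port, 1.0)):
            if not math.isclose(port.rect.cx, cx + s * ax * u.port_offset,
                                abs_tol=1e-6):
                return False
            if not math.isclose(port.rect.cy, cy + s * ay * u.port_offset,
                                abs_tol=1e-6):
                return False
        return True

    ports_ok = all(port_geometry_ok(u) for u in units)
    containment_with_dummies = cg.containment_ok()
    for unit in units:
        info = pd.port_info(unit.process)
        info.in_xy = (unit.input_port.rect.cx, unit.input_port.rect.cy)
        info.out_xy = (unit.output_port.rect.cx, unit.output_port.rect.cy)
    detach_ports(cg, units)
    cg.update_bounds()
    data = write_map(pd)
    return BatchRecord(
        seed=seed,
        n_nodes=len(cg.nodes),
        base_ratio=base_ratio,
        full_ratio=res.final_ratio,
        ports_ok=ports_ok,
        containment_ok=containment_with_dummies and cg.containment_ok(),
        finite=cg.all_finite(),
        serialized=data,
    )


@pytest.fixture(scope="session")
def layout_batch():
    """30 seeded synthetic maps (50-300 nodes) laid out with the full
    pipeline; shared by the structural-invariant and paired-improvement
    checks."""
    records = []
    for i in range(30):
        n = 50 + (i * 97) % 251
        records.append(run_full_layout(seed=1000 + i, n_nodes=n))
    return records
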