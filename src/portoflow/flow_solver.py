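"""Steady laminar flow on the vessel network and vFPP extraction.

Governing model
---------------
Blood is treated as an incompressible Newtonian fluid in steady, fully
developed laminar flow.  Under those assumptions the momentum balance in
each circular segment reduces to the Hagen-Poiseuille law

    dP = 128 mu L Q / (pi d^4),

and mass conservation reduces to junction continuity (the sum of signed
segment flows at every interior node is zero, with no mass sources).
Gravity and external body forces are neglected (supine animal, venous
scale); the energy equation is decoupled by the isothermal assumption and
never solved.  A linearly tapered segment integrates to the closed-form
resistance

    R = 128 mu L (d0^2 + d0 d1 + d1^2) / (3 pi d0^3 d1^3).

The network problem is the sparse linear system of nodal continuity
equations with segment conductances 1/R, one node pinned to the gauge
pressure of the reference outlet.  A direct sparse solve keeps results
bit-reproducible.

The virtual free portal pressure (vFPP) is the pressure at the centre of
the portal vein trunk: the midpoint value interpolated linearly along the
trunk segment, converted to mmHg, plus the configurable absolute reference
``p_ref``.  With a gauge-0 outlet the viscous network drop at canine portal
scale is sub-mmHg, so absolute vFPP values are meaningful only relative to
``p_ref`` (see docs/methods.md on the absolute-calibration question).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .doppler_bc import BoundaryCondition
from .errors import ParameterError, PreconditionError, SolverError
from .vessel_tree import VesselTree, layout_nodes

logger = logging.getLogger(__name__)

#: Conversion constant, 1 mmHg in Pa.
MMHG_PA = 133.322


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings.

    p_ref_mmhg
        Absolute pressure (mmHg) added to the gauge trunk pressure when
        reporting vFPP; default 0 (pure gauge).
    re_max
        Reynolds number above which a turbulence warning is logged (the
        laminar closure is still applied); default 2000.
    tol
        Relative tolerance for the post-solve residual check.
    """

    p_ref_mmhg: float = 0.0
    re_max: float = 2000.0
    tol: float = 1e-10

    def __post_init__(self):
        if not (self.tol > 0):
            raise ParameterError("solver tolerance must be > 0")


@dataclass
class FlowSolution:
    """Nodal gauge pressures (Pa), signed segment flows (m^3/s, proximal ->
    distal positive) and residual diagnostics."""

    pressures_pa: dict[str, float]
    segment_flows: dict[str, float]
    max_junction_imbalance: float = 0.0
    solver_residual: float = 0.0


def segment_resistance(d_prox_mm: float, d_dist_mm: float, length_mm: float, mu: float) -> float:
    """Poiseuille resistance (Pa s/m^3) of a linearly tapered segment."""
    if not (d_prox_mm > 0 and d_dist_mm > 0 and length_mm > 0 and mu > 0):
        raise ParameterError("all of d_prox, d_dist, length, mu must be > 0")
    d0 = d_prox_mm / 1000.0
    d1 = d_dist_mm / 1000.0
    L = length_mm / 1000.0
    return 128.0 * mu * L * (d0 * d0 + d0 * d1 + d1 * d1) / (3.0 * math.pi * d0**3 * d1**3)


def poiseuille_drop(d_mm: float, length_mm: float, mu: float, q_m3_s: float) -> float:
    """Pressure drop 128 mu L Q / (pi d^4) in Pa for a uniform tube.

    Analytic reference for single-segment solves; ``Q = 0`` gives 0.
    """
    if not (d_mm > 0 and length_mm > 0 and mu > 0):
        raise ParameterError("d, L, mu must be > 0")
    d = d_mm / 1000.0
    return 128.0 * mu * (length_mm / 1000.0) * q_m3_s / (math.pi * d**4)


def reynolds(d_mm: float, v_cm_s: float, rho: float, mu: float) -> float:
    """Reynolds number rho*v*d/mu (inputs mm, cm/s, kg/m^3, Pa s)."""
    if not (d_mm > 0 and v_cm_s > 0 and rho > 0 and mu > 0):
        raise ParameterError("all Reynolds inputs must be > 0")
    return rho * (v_cm_s / 100.0) * (d_mm / 1000.0) / mu


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_PA


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_PA


def solve_network(
    tree: VesselTree,
    bcs: list[BoundaryCondition],
    blood,
    config: SolverConfig | None = None,
) -> FlowSolution:
    """Solve nodal continuity with Poiseuille conductances.

    ``blood`` needs ``viscosity`` (Pa s) and ``density`` (kg/m^3)
    attributes.  Boundary conditions must be mass-reconciled (signed
    velocity flows summing to ~0) and contain exactly one pressure outlet.
    """
    config = config or SolverConfig()
    mu = blood.viscosity

    pressure_bcs = [bc for bc in bcs if bc.kind == "pressure_outlet"]
    velocity_bcs = [bc for bc in bcs if bc.kind == "velocity_inlet"]
    if len(pressure_bcs) != 1:
        raise SolverError(f"need exactly one pressure outlet, got {len(pressure_bcs)}")
    total_q = sum(bc.q_m3_s for bc in velocity_bcs)
    max_q = max((abs(bc.q_m3_s) for bc in velocity_bcs), default=0.0)
    has_inflow = any(bc.q_m3_s > 0 for bc in velocity_bcs)
    has_outflow = any(bc.q_m3_s < 0 for bc in velocity_bcs)
    # With velocity faces of both signs the system is over-determined unless
    # the set was reconciled; with inflow only, the pressure outlet absorbs
    # the net flow (single-tube and Y-junction configurations).
    if has_inflow and has_outflow and abs(total_q) > 1e-9 * max_q:
        raise PreconditionError(
            f"boundary flows are not reconciled (net {total_q:.3e} m^3/s); "
            "run reconcile_mass_balance first"
        )

    nodes = sorted(tree.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    ref_face = tree.faces[pressure_bcs[0].face_id]
    ref_node = ref_face.node
    gauge = pressure_bcs[0].gauge_pa

    conductance = {
        s.id: 1.0 / segment_resistance(s.d_prox_mm, s.d_dist_mm, s.length_mm, mu)
        for s in tree.segments
    }

    n = len(nodes)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    for s in tree.segments:
        i, j = index[s.node_prox], index[s.node_dist]
        g = conductance[s.id]
        for a, b in ((i, j), (j, i)):
            rows.append(a); cols.append(a); vals.append(g)
            rows.append(a); cols.append(b); vals.append(-g)
    for bc in velocity_bcs:
        rhs[index[tree.faces[bc.face_id].node]] += bc.q_m3_s

    # pin the reference node: overwrite its row with identity
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n)).tolil()
    r = index[ref_node]
    A.rows[r] = [r]
    A.data[r] = [1.0]
    rhs[r] = gauge
    A = A.tocsr()
    try:
        p = spla.spsolve(A, rhs)
    except Exception as exc:  # pragma: no cover - singular systems
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(p)):
        raise SolverError("singular network system (non-finite pressures)")

    pressures = {node: float(p[index[node]]) for node in nodes}
    flows = {}
    for s in tree.segments:
        flows[s.id] = conductance[s.id] * (pressures[s.node_prox] - pressures[s.node_dist])

    # residual check: signed flow balance at every node incl. boundary flows
    balance = {node: 0.0 for node in nodes}
    for s in tree.segments:
        balance[s.node_prox] -= flows[s.id]
        balance[s.node_dist] += flows[s.id]
    for bc in velocity_bcs:
        balance[tree.faces[bc.face_id].node] += bc.q_m3_s
    balance[ref_node] = 0.0  # reference face absorbs the (zero) remainder
    max_imb = max(abs(v) for v in balance.values()) if balance else 0.0
    residual = float(np.linalg.norm(A @ p - rhs))
    if max_q > 0 and max_imb > config.tol * max_q:
        raise SolverError(
            f"junction mass imbalance {max_imb:.3e} exceeds {config.tol:.1e} x max|Q|"
        )

    _warn_if_turbulent(tree, flows, blood, config)
    return FlowSolution(
        pressures_pa=pressures,
        segment_flows=flows,
        max_junction_imbalance=max_imb,
        solver_residual=residual,
    )


def _warn_if_turbulent(tree: VesselTree, flows: dict[str, float], blood, config: SolverConfig):
    for s in tree.segments:
        d_mean = 0.5 * (s.d_prox_mm + s.d_dist_mm)
        area = 0.25 * math.pi * (d_mean / 1000.0) ** 2
        v = abs(flows[s.id]) / area  # m/s
        if v > 0:
            re = reynolds(d_mean, v * 100.0, blood.density, blood.viscosity)
            if re > config.re_max:
                logger.warning(
                    "segment %s: Re = %.0f exceeds laminar threshold %.0f",
                    s.id, re, config.re_max,
                )


def extract_vfpp(
    solution: FlowSolution, tree: VesselTree, config: SolverConfig | None = None
) -> float:
    """vFPP (mmHg) = p_ref + gauge pressure at the portal-trunk midpoint.

    The midpoint pressure is the linear interpolant along the trunk segment,
    i.e. the mean of its end-node pressures.
    """
    config = config or SolverConfig()
    trunk = tree.segment_by_name("portal_vein")  # ConfigurationError if absent
    mid_pa = 0.5 * (
        solution.pressures_pa[trunk.node_prox] + solution.pressures_pa[trunk.node_dist]
    )
    return config.p_ref_mmhg + pa_to_mmhg(mid_pa)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def solution_to_csv(solution: FlowSolution, tree: VesselTree, node_path, segment_path) -> None:
    """Write nodal pressures and segment flows as two small CSV files."""
    import pandas as pd

    pd.DataFrame(
        {
            "node": list(solution.pressures_pa),
            "p_Pa": list(solution.pressures_pa.values()),
            "p_mmHg": [pa_to_mmhg(v) for v in solution.pressures_pa.values()],
        }
    ).to_csv(node_path, index=False)
    pd.DataFrame(
        {"segment": list(solution.segment_flows), "Q_m3_s": list(solution.segment_flows.values())}
    ).to_csv(segment_path, index=False)


def solution_to_vtk(solution: FlowSolution, tree: VesselTree, path) -> None:
    """Write the tree centreline as VTK polylines with per-vertex pressure,
    for quick pressure-field visualisation."""
    pos = layout_nodes(tree)
    nodes = sorted(tree.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nportoflow pressure field\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(nodes)} float\n")
        for n in nodes:
            p = pos[n]
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"LINES {len(tree.segments)} {3 * len(tree.segments)}\n")
        for s in tree.segments:
            fh.write(f"2 {index[s.node_prox]} {index[s.node_dist]}\n")
        fh.write(f"POINT_DATA {len(nodes)}\n")
        fh.write("SCALARS pressure_Pa float 1\nLOOKUP_TABLE default\n")
        for n in nodes:
            fh.write(f"{solution.pressures_pa[n]:.9g}\n")
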