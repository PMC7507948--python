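"""Doppler measurements -> solver boundary conditions.

A Doppler examination of the portal system yields, per vessel, an inner
diameter ``d_us`` (mm) and a maximum velocity ``v_max`` (cm/s).  The solver
needs a mean velocity normal to each boundary face of the model geometry.
The conversion chain is:

1. mean velocity: ``v_mean = 0.7 * v_max`` (the envelope-averaged portal
   waveform carries roughly 70% of its peak; the factor is configurable);
2. flow rate through the measurement site: ``Q = (pi/4) d_us^2 v_mean``;
3. rescaling to the model boundary diameter ``d_b`` so that Q is conserved:
   ``v_b = (d_us^2 / d_b^2) v_mean``;
4. mass-balance reconciliation: with velocities imposed on every branch the
   network is over-determined, so all non-reference outflows are scaled by a
   common factor until total inflow equals total outflow exactly.  Inflow
   (splanchnic) measurements are kept as anchors because they drive the
   system physiologically; the reference pressure-outlet face carries no
   flow.

All BoundaryCondition values are SI (m/s, m^3/s, Pa); measurement-side
units (mm, cm/s) never leak past this module.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .errors import ConfigurationError, ParameterError, ReconciliationError
from .vessel_tree import VesselTree

logger = logging.getLogger(__name__)

#: Default ratio of mean to maximum velocity in the Doppler envelope.
MEAN_VELOCITY_FACTOR = 0.7

#: Vessels whose faces receive velocity-inlet conditions (flow into the tree).
INLET_VESSELS = frozenset({"splenic", "superior_mesenteric", "inferior_mesenteric"})
#: Vessels whose faces receive velocity conditions with outflow sign.
OUTLET_VESSELS = frozenset({"left_portal", "right_portal"})


@dataclass(frozen=True)
class DopplerMeasurement:
    """One vessel's ultrasound readout (measurement-side units)."""

    vessel: str
    d_us_mm: float
    v_max_cm_s: float
    direction: str = "toward_liver"  # or "away_from_liver" (hepatofugal)


@dataclass(frozen=True)
class BoundaryCondition:
    """SI boundary assignment for one face.

    For velocity kinds, ``q_m3_s`` and ``v_b_m_s`` are signed with positive
    meaning flow *into* the network.  ``q_m3_s = (pi/4) d_b^2 v_b`` holds by
    construction.
    """

    face_id: str
    kind: str  # "velocity_inlet" | "pressure_outlet"
    role: str  # "inlet" | "outlet" | "reference_outlet"
    d_b_mm: float
    v_b_m_s: float | None = None
    q_m3_s: float | None = None
    gauge_pa: float | None = None

    def to_dict(self) -> dict:
        out = {"face": self.face_id, "kind": self.kind, "role": self.role}
        if self.kind == "velocity_inlet":
            out["v_b_m_s"] = self.v_b_m_s
            out["Q_m3_s"] = self.q_m3_s
        else:
            out["gauge_Pa"] = self.gauge_pa
        return out


def mean_velocity(v_max_cm_s: float, factor: float = MEAN_VELOCITY_FACTOR) -> float:
    """Mean velocity (cm/s) from the Doppler maximum."""
    if not (v_max_cm_s > 0):
        raise ParameterError(f"v_max must be > 0, got {v_max_cm_s}")
    if not (factor > 0):
        raise ParameterError(f"mean-velocity factor must be > 0, got {factor}")
    return factor * v_max_cm_s


def flow_rate(d_mm: float, v_cm_s: float) -> float:
    """Volumetric flow rate Q = A*v = (pi/4) d^2 v, in m^3/s (inputs mm, cm/s)."""
    if not (d_mm > 0) or not (v_cm_s > 0):
        raise ParameterError(f"diameter and velocity must be > 0, got d={d_mm}, v={v_cm_s}")
    return 0.25 * math.pi * (d_mm / 1000.0) ** 2 * (v_cm_s / 100.0)


def boundary_velocity(d_us_mm: float, v_us_cm_s: float, d_b_mm: float) -> float:
    """Velocity (cm/s) at a boundary face of diameter ``d_b`` that carries the
    same flow as measured at the ultrasound site: v_b = (d_us/d_b)^2 v_us."""
    if not (d_us_mm > 0) or not (v_us_cm_s > 0) or not (d_b_mm > 0):
        raise ParameterError("all of d_us, v_us, d_b must be > 0")
    return (d_us_mm / d_b_mm) ** 2 * v_us_cm_s


@dataclass(frozen=True)
class ReconciliationResult:
    bcs: list[BoundaryCondition]
    factor: float          # applied to all non-reference outflows
    imbalance_before: float  # (inflow - outflow) / inflow before scaling


def reconcile_mass_balance(bcs: list[BoundaryCondition]) -> ReconciliationResult:
    """Scale all non-reference outflows by one factor so that total signed
    flow is exactly zero.

    The reference pressure-outlet face absorbs no flow; inflow measurements
    are left untouched.  A no-op (factor 1.0) when the set is already
    balanced to 1e-12 relative.
    """
    inflow = sum(bc.q_m3_s for bc in bcs if bc.kind == "velocity_inlet" and bc.q_m3_s > 0)
    outflow = -sum(bc.q_m3_s for bc in bcs if bc.kind == "velocity_inlet" and bc.q_m3_s < 0)
    if inflow <= 0:
        raise ReconciliationError("no velocity inflow to reconcile against")
    if outflow <= 0:
        raise ReconciliationError("zero total outflow against non-zero inflow")
    imbalance = (inflow - outflow) / inflow
    if abs(imbalance) < 1e-12:
        return ReconciliationResult(bcs=list(bcs), factor=1.0, imbalance_before=imbalance)
    factor = inflow / outflow
    out = []
    for bc in bcs:
        if bc.kind == "velocity_inlet" and bc.q_m3_s < 0:
            out.append(replace(bc, q_m3_s=bc.q_m3_s * factor, v_b_m_s=bc.v_b_m_s * factor))
        else:
            out.append(bc)
    return ReconciliationResult(bcs=out, factor=factor, imbalance_before=imbalance)


def assemble_bcs(
    record,
    tree: VesselTree,
    mean_factor: float = MEAN_VELOCITY_FACTOR,
    gauge_pa: float = 0.0,
) -> list[BoundaryCondition]:
    """Full boundary-condition set for one animal on one tree.

    The reference_outlet face becomes a gauge-``gauge_pa`` pressure outlet;
    splanchnic faces (splenic, superior/inferior mesenteric) become velocity
    inlets; the hepatic branches (left/right portal) become velocity
    conditions with outflow sign.  Velocities pass ``mean_velocity`` then
    ``boundary_velocity``, and the set is mass-reconciled last.

    ``record`` needs a ``doppler`` attribute with one
    :class:`DopplerMeasurement` per boundary vessel.
    """
    by_vessel: dict[str, DopplerMeasurement] = {m.vessel: m for m in record.doppler}
    bcs: list[BoundaryCondition] = []
    for face in tree.faces.values():
        if face.role == "reference_outlet":
            bcs.append(
                BoundaryCondition(
                    face_id=face.id, kind="pressure_outlet", role=face.role,
                    d_b_mm=face.diameter_mm, gauge_pa=gauge_pa,
                )
            )
            continue
        vessel = tree.face_segment(face.id).name
        if vessel not in by_vessel:
            raise ConfigurationError(f"record lacks a Doppler measurement for vessel {vessel!r}")
        m = by_vessel[vessel]
        v_mean = mean_velocity(m.v_max_cm_s, mean_factor)
        v_b_cm_s = boundary_velocity(m.d_us_mm, v_mean, face.diameter_mm)
        q = flow_rate(face.diameter_mm, v_b_cm_s)  # == flow_rate(d_us, v_mean)
        sign = 1.0 if vessel in INLET_VESSELS else -1.0
        if m.direction == "away_from_liver":
            # hepatofugal flow reverses the physiological sign
            logger.warning("face %s (%s): hepatofugal flow, reversing sign", face.id, vessel)
            sign = -sign
        bcs.append(
            BoundaryCondition(
                face_id=face.id, kind="velocity_inlet", role=face.role,
                d_b_mm=face.diameter_mm,
                v_b_m_s=sign * v_b_cm_s / 100.0,
                q_m3_s=sign * q,
            )
        )
    return reconcile_mass_balance(bcs).bcs
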