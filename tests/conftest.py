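"""Shared fixtures: canonical tree, table-mean records, random networks."""
from __future__ import annotations

import numpy as np
import pytest

from portoflow import (
    AnimalRecord,
    BloodProperties,
    BoundaryCondition,
    DopplerMeasurement,
    canonical_tree,
)
from portoflow.doppler_bc import reconcile_mass_balance
from portoflow.synthetic_cohort import DIAMETERS_MM, VELOCITIES_CM_S
from portoflow.vessel_tree import VesselTree, build_tree


@pytest.fixture(scope="session")
def tree():
    return canonical_tree()


def record_at_group_means(group: str = "Control", fpp: float = 6.6) -> AnimalRecord:
    """An animal sitting exactly at its group's published means."""
    doppler = tuple(
        DopplerMeasurement(
            vessel=v, d_us_mm=DIAMETERS_MM[v][group][0], v_max_cm_s=VELOCITIES_CM_S[v][group][0]
        )
        for v in sorted(DIAMETERS_MM)
    )
    return AnimalRecord(
        animal_id=f"{group}_mean", group=group, doppler=doppler,
        blood=BloodProperties(1050.0, 3.5e-3), fpp_true_mmhg=fpp,
    )


@pytest.fixture
def control_record():
    return record_at_group_means("Control", 6.6)


def single_tube_tree(d_prox=4.0, d_dist=4.0, length=20.0) -> VesselTree:
    return build_tree(
        {
            "segments": [
                {"id": "s", "name": "portal_vein", "length_mm": length,
                 "d_prox_mm": d_prox, "d_dist_mm": d_dist, "nodes": ["a", "b"]}
            ],
            "faces": [
                {"id": "fa", "node": "a", "diameter_mm": d_prox, "role": "inlet"},
                {"id": "fb", "node": "b", "diameter_mm": d_dist, "role": "reference_outlet"},
            ],
        }
    )


def random_network(rng: np.random.Generator, max_segments: int = 50):
    """A random connected vessel tree plus a reconciled boundary set.

    Segments attach to random existing nodes; every degree-1 node gets a
    face; one leaf is the pressure reference, the rest are split into at
    least one inlet and one outlet with random flows.
    """
    while True:
        n_seg = int(rng.integers(3, max_segments + 1))
        segs = []
        nodes = ["n0", "n1"]
        segs.append(_rand_seg(rng, "s0", "n0", "n1"))
        for i in range(1, n_seg):
            parent = nodes[int(rng.integers(len(nodes)))]
            child = f"n{i + 1}"
            nodes.append(child)
            segs.append(_rand_seg(rng, f"s{i}", parent, child))
        tree = VesselTree(segments=segs)
        leaves = sorted(n for n in tree.nodes if tree.degree(n) == 1)
        if len(leaves) >= 3:
            break
    rng.shuffle(leaves)
    ref, inlets_out = leaves[0], leaves[1:]
    n_in = int(rng.integers(1, len(inlets_out)))
    faces = [{"id": f"face_{ref}", "node": ref, "diameter_mm": 4.0, "role": "reference_outlet"}]
    bcs = []
    for j, leaf in enumerate(inlets_out):
        role = "inlet" if j < n_in else "outlet"
        d = float(rng.uniform(1.5, 8.0))
        faces.append({"id": f"face_{leaf}", "node": leaf, "diameter_mm": d, "role": role})
        q = float(rng.uniform(0.2e-6, 4e-6))
        sign = 1.0 if role == "inlet" else -1.0
        area = 0.25 * np.pi * (d / 1000.0) ** 2
        bcs.append(
            BoundaryCondition(
                face_id=f"face_{leaf}", kind="velocity_inlet", role=role, d_b_mm=d,
                v_b_m_s=sign * q / area, q_m3_s=sign * q,
            )
        )
    bcs.append(
        BoundaryCondition(
            face_id=f"face_{ref}", kind="pressure_outlet", role="reference_outlet",
            d_b_mm=4.0, gauge_pa=0.0,
        )
    )
    tree = build_tree({"segments": [_seg_dict(s) for s in segs], "faces": faces})
    return tree, reconcile_mass_balance(bcs).bcs


def _rand_seg(rng, sid, a, b):
    from portoflow.vessel_tree import VesselSegment

    return VesselSegment(
        id=sid, name="other",
        length_mm=float(rng.uniform(5.0, 80.0)),
        d_prox_mm=float(rng.uniform(1.5, 8.0)),
        d_dist_mm=float(rng.uniform(1.5, 8.0)),
        node_prox=a, node_dist=b,
    )


def _seg_dict(s):
    return {"id": s.id, "name": s.name, "length_mm": s.length_mm,
            "d_prox_mm": s.d_prox_mm, "d_dist_mm": s.d_dist_mm,
            "nodes": [s.node_prox, s.node_dist]}
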