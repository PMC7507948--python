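"""Network solver vs analytic Poiseuille oracles and physical invariants."""
import math
from dataclasses import replace

import numpy as np
import pytest

from portoflow import (
    BloodProperties,
    BoundaryCondition,
    ConfigurationError,
    ParameterError,
    SolverConfig,
    extract_vfpp,
    pa_to_mmhg,
    poiseuille_drop,
    reynolds,
    segment_resistance,
    solve_network,
)
from portoflow.errors import PreconditionError, SolverError
from portoflow.flow_solver import MMHG_PA, solution_to_csv, solution_to_vtk

from conftest import random_network, single_tube_tree

BLOOD = BloodProperties(1050.0, 3.5e-3)


def _inlet_bc(face, d_mm, q):
    area = 0.25 * math.pi * (d_mm / 1000.0) ** 2
    return BoundaryCondition(face_id=face, kind="velocity_inlet", role="inlet",
                             d_b_mm=d_mm, v_b_m_s=q / area, q_m3_s=q)


def _ref_bc(face, d_mm, gauge=0.0):
    return BoundaryCondition(face_id=face, kind="pressure_outlet", role="reference_outlet",
                             d_b_mm=d_mm, gauge_pa=gauge)


class TestSegmentResistance:
    def test_uniform_tube_reduces_to_poiseuille(self):
        d, L, mu = 4.5, 50.0, 3.5e-3
        expected = 128.0 * mu * (L / 1000.0) / (math.pi * (d / 1000.0) ** 4)
        assert segment_resistance(d, d, L, mu) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(1.7388e7, rel=1e-4)

    def test_taper_matches_quadrature(self):
        from scipy.integrate import simpson

        d0, d1, L, mu = 4.0, 6.0, 30.0, 3.5e-3
        x = np.linspace(0.0, L / 1000.0, 10_001)
        d = (d0 + (d1 - d0) * x / x[-1]) / 1000.0
        oracle = simpson(128.0 * mu / (math.pi * d**4), x=x)
        assert segment_resistance(d0, d1, L, mu) == pytest.approx(oracle, rel=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            segment_resistance(0.0, 4.0, 10.0, 3.5e-3)


class TestReynolds:
    def test_canine_portal_control_is_laminar(self):
        re = reynolds(4.5, 23.66, 1050.0, 3.5e-3)
        assert re == pytest.approx(1050.0 * 0.2366 * 0.0045 / 3.5e-3, rel=1e-12)
        assert 300 < re < 340  # comfortably below transition

    def test_inverse_in_viscosity(self):
        assert reynolds(4.5, 20.0, 1050.0, 7e-3) == pytest.approx(
            0.5 * reynolds(4.5, 20.0, 1050.0, 3.5e-3)
        )


class TestPoiseuilleDrop:
    def test_zero_flow_zero_drop(self):
        assert poiseuille_drop(4.5, 50.0, 3.5e-3, 0.0) == 0.0

    def test_canine_scale_value(self):
        q = 0.25 * math.pi * 0.0045**2 * 0.2366
        dp = poiseuille_drop(4.5, 50.0, 3.5e-3, q)
        expected = 128.0 * 3.5e-3 * 0.05 * q / (math.pi * 0.0045**4)
        assert dp == pytest.approx(expected, rel=1e-14)
        assert dp == pytest.approx(65.4, abs=0.2)

    def test_fourth_power_diameter_scaling(self):
        assert poiseuille_drop(2.25, 50.0, 3.5e-3, 1e-6) == pytest.approx(
            16.0 * poiseuille_drop(4.5, 50.0, 3.5e-3, 1e-6)
        )


class TestUnitBridge:
    def test_pa_to_mmhg(self):
        assert pa_to_mmhg(133.322) == pytest.approx(1.0)
        assert pa_to_mmhg(0.0) == 0.0
        assert pa_to_mmhg(65.5) == pytest.approx(65.5 / MMHG_PA)


class TestSolveNetwork:
    def test_single_tube_is_ohmic(self):
        tree = single_tube_tree(4.5, 4.5, 50.0)
        q = 3.763e-6
        sol = solve_network(tree, [_inlet_bc("fa", 4.5, q), _ref_bc("fb", 4.5)], BLOOD)
        r = segment_resistance(4.5, 4.5, 50.0, BLOOD.viscosity)
        assert sol.pressures_pa["a"] == pytest.approx(r * q, rel=1e-12)
        assert sol.segment_flows["s"] == pytest.approx(q, rel=1e-12)

    def test_tapered_tube_matches_resistance_oracle(self):
        tree = single_tube_tree(4.0, 6.0, 30.0)
        q = 2e-6
        sol = solve_network(tree, [_inlet_bc("fa", 4.0, q), _ref_bc("fb", 6.0)], BLOOD)
        r = segment_resistance(4.0, 6.0, 30.0, BLOOD.viscosity)
        assert sol.pressures_pa["a"] == pytest.approx(r * q, rel=1e-10)

    def test_symmetric_y_junction(self):
        from portoflow import build_tree

        spec = {
            "segments": [
                {"id": "b1", "name": "other", "length_mm": 30, "d_prox_mm": 3,
                 "d_dist_mm": 3, "nodes": ["i1", "j"]},
                {"id": "b2", "name": "other", "length_mm": 30, "d_prox_mm": 3,
                 "d_dist_mm": 3, "nodes": ["i2", "j"]},
                {"id": "t", "name": "other", "length_mm": 40, "d_prox_mm": 5,
                 "d_dist_mm": 5, "nodes": ["j", "o"]},
            ],
            "faces": [
                {"id": "f1", "node": "i1", "diameter_mm": 3, "role": "inlet"},
                {"id": "f2", "node": "i2", "diameter_mm": 3, "role": "inlet"},
                {"id": "fo", "node": "o", "diameter_mm": 5, "role": "reference_outlet"},
            ],
        }
        tree = build_tree(spec)
        q = 1e-6
        sol = solve_network(tree, [_inlet_bc("f1", 3, q), _inlet_bc("f2", 3, q), _ref_bc("fo", 5)], BLOOD)
        assert sol.pressures_pa["i1"] == pytest.approx(sol.pressures_pa["i2"], rel=1e-12)

    def test_junction_mass_conservation_on_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tree, bcs = random_network(rng, max_segments=30)
            sol = solve_network(tree, bcs, BLOOD)
            max_q = max(abs(q) for q in sol.segment_flows.values())
            assert sol.max_junction_imbalance <= 1e-10 * max(max_q, 1e-30)

    def test_linear_in_viscosity_and_flow(self):
        tree = single_tube_tree(4.5, 4.5, 50.0)
        q = 1e-6
        base = solve_network(tree, [_inlet_bc("fa", 4.5, q), _ref_bc("fb", 4.5)], BLOOD)
        thick = solve_network(
            tree, [_inlet_bc("fa", 4.5, q), _ref_bc("fb", 4.5)], BloodProperties(1050.0, 7e-3)
        )
        double_q = solve_network(tree, [_inlet_bc("fa", 4.5, 2 * q), _ref_bc("fb", 4.5)], BLOOD)
        assert thick.pressures_pa["a"] == pytest.approx(2 * base.pressures_pa["a"], rel=1e-12)
        assert double_q.pressures_pa["a"] == pytest.approx(2 * base.pressures_pa["a"], rel=1e-12)

    def test_widening_a_vessel_never_raises_trunk_pressure(self, tree, control_record):
        from portoflow import canonical_tree
        from portoflow.doppler_bc import assemble_bcs

        def trunk_gauge(diams):
            t = canonical_tree(diams)
            bcs = assemble_bcs(control_record, t)
            sol = solve_network(t, bcs, BLOOD)
            return extract_vfpp(sol, t)

        base = trunk_gauge(None)
        for vessel in ("portal_vein", "splenic", "superior_mesenteric"):
            from portoflow.vessel_tree import CONTROL_DIAMETERS_MM

            wider = dict(CONTROL_DIAMETERS_MM)
            wider[vessel] *= 1.5
            assert trunk_gauge(wider) <= base + 1e-12

    def test_bit_identical_determinism(self, tree, control_record):
        from portoflow.doppler_bc import assemble_bcs

        bcs = assemble_bcs(control_record, tree)
        a = solve_network(tree, bcs, BLOOD)
        b = solve_network(tree, bcs, BLOOD)
        assert a.pressures_pa == b.pressures_pa
        assert a.segment_flows == b.segment_flows

    def test_unreconciled_bcs_rejected(self):
        from portoflow import build_tree

        spec = {
            "segments": [
                {"id": "b1", "name": "other", "length_mm": 30, "d_prox_mm": 3,
                 "d_dist_mm": 3, "nodes": ["i1", "j"]},
                {"id": "b2", "name": "other", "length_mm": 30, "d_prox_mm": 3,
                 "d_dist_mm": 3, "nodes": ["j", "o1"]},
                {"id": "b3", "name": "other", "length_mm": 30, "d_prox_mm": 3,
                 "d_dist_mm": 3, "nodes": ["j", "o2"]},
            ],
            "faces": [
                {"id": "f1", "node": "i1", "diameter_mm": 3, "role": "inlet"},
                {"id": "f2", "node": "o1", "diameter_mm": 3, "role": "outlet"},
                {"id": "fo", "node": "o2", "diameter_mm": 3, "role": "reference_outlet"},
            ],
        }
        tree = build_tree(spec)
        bad = [
            _inlet_bc("f1", 3, 2e-6),
            replace(_inlet_bc("f2", 3, -0.5e-6), role="outlet"),
            _ref_bc("fo", 3),
        ]
        with pytest.raises(PreconditionError):
            solve_network(tree, bad, BLOOD)

    def test_missing_pressure_reference_rejected(self):
        tree = single_tube_tree()
        with pytest.raises(SolverError):
            solve_network(tree, [_inlet_bc("fa", 4.0, 1e-6)], BLOOD)


class TestExtractVfpp:
    def test_midpoint_interpolation_and_offset(self):
        tree = single_tube_tree(4.5, 4.5, 50.0)
        q = 3.763e-6
        bcs = [_inlet_bc("fa", 4.5, q), _ref_bc("fb", 4.5)]
        sol = solve_network(tree, bcs, BLOOD)
        drop = sol.pressures_pa["a"]
        gauge_mid = extract_vfpp(sol, tree)
        assert gauge_mid == pytest.approx(pa_to_mmhg(drop / 2), rel=1e-12)
        with_ref = extract_vfpp(sol, tree, SolverConfig(p_ref_mmhg=6.6))
        assert with_ref == pytest.approx(gauge_mid + 6.6, rel=1e-12)

    def test_requires_a_portal_vein_segment(self):
        rng = np.random.default_rng(2)
        tree, bcs = random_network(rng, max_segments=5)  # all segments named "other"
        sol = solve_network(tree, bcs, BLOOD)
        with pytest.raises(ConfigurationError):
            extract_vfpp(sol, tree)


class TestSolutionExport:
    def test_csv_and_vtk_outputs(self, tmp_path, tree, control_record):
        from portoflow.doppler_bc import assemble_bcs

        sol = solve_network(tree, assemble_bcs(control_record, tree), BLOOD)
        solution_to_csv(sol, tree, tmp_path / "nodes.csv", tmp_path / "segs.csv")
        solution_to_vtk(sol, tree, tmp_path / "field.vtk")
        import pandas as pd

        nodes = pd.read_csv(tmp_path / "nodes.csv")
        assert set(nodes["node"]) == tree.nodes
        text = (tmp_path / "field.vtk").read_text()
        assert "pressure_Pa" in text and "LINES" in text
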