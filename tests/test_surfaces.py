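"""Parametric bifurcation surfaces and their consistency with continuation."""

import numpy as np
import pytest

from thetanet import (ModelParams, build_surface_mesh, cross_validate_point,
                      equilibrium_parameter_system, jacobian,
                      pulse_coefficients, reduced_vector_field,
                      surface_line_intersections, surface_point)
from thetanet.surfaces import (DegeneratePointError, _affine_in_k0,
                               _params_at, default_surface_grid)

CLIP = {"eta0": (-30.0, 30.0), "k0": (-40.0, 40.0), "delta_eta": (0.0, 3.0)}


class TestParameterSystem:
    def test_family_members_are_equilibria(self, pulse2, rng):
        # the affine solution family substituted back into the vector field
        for _ in range(15):
            x, y = rng.uniform(-0.6, 0.6, 2)
            if np.hypot(x, y) > 0.9:
                continue
            dk = rng.uniform(0.0, 2.0)
            A, b = equilibrium_parameter_system(x, y, dk, pulse2)
            P, Q = _affine_in_k0(A, b)
            for k0 in rng.uniform(-10, 10, 3):
                p = _params_at(k0, P, Q, dk, 2)
                assert abs(reduced_vector_field(complex(x, y), p, pulse2)) < 1e-10

    def test_one_parameter_family(self, pulse2):
        A, _ = equilibrium_parameter_system(0.3, -0.2, 0.0, pulse2)
        assert np.linalg.matrix_rank(A) == 2  # 2 constraints on 3 unknowns

    @pytest.mark.parametrize("loc", [(-1.0, 0.0), (1.0, 0.0),
                                     (-0.9995, 0.0)])
    def test_degenerate_locations_rejected(self, loc, pulse2):
        with pytest.raises((DegeneratePointError, ValueError)):
            equilibrium_parameter_system(*loc, 0.0, pulse2)


class TestSurfacePoint:
    @pytest.mark.parametrize("kind", ["saddle-node", "hopf", "node-focus"])
    def test_residuals_below_tolerance(self, kind, pulse2, rng):
        for _ in range(20):
            x, y = rng.uniform(-0.8, 0.8, 2)
            if np.hypot(x, y) > 0.9 or abs(complex(x, y) + 1) < 0.01 \
                    or abs(complex(x, y) - 1) < 0.01:
                continue
            sp = surface_point(kind, x, y, 0.3, pulse2)
            for r_eq, r_test in sp.residuals:
                assert r_eq < 1e-9
                assert r_test < 1e-9

    def test_saddle_node_roots_match_bracketing_scan(self, pulse2, rng):
        # brute-force oracle: scan det J along the affine family and
        # bracket its sign changes
        for _ in range(10):
            x, y = rng.uniform(-0.7, 0.7, 2)
            if np.hypot(x, y) > 0.85:
                continue
            A, b = equilibrium_parameter_system(x, y, 0.0, pulse2)
            P, Q = _affine_in_k0(A, b)
            ks = np.linspace(-60, 60, 4001)
            det = np.array([jacobian(complex(x, y),
                                     _params_at(k, P, Q, 0.0, 2), pulse2
                                     ).determinant for k in ks])
            brackets = np.where(np.diff(np.sign(det)) != 0)[0]
            sp = surface_point("saddle-node", x, y, 0.0, pulse2)
            in_range = [s for s in sp.solutions if -60 <= s[2] <= 60]
            assert len(in_range) == len(brackets)
            for s in in_range:
                assert np.min(np.abs(ks[brackets] - s[2])) < 0.05

    def test_hopf_solutions_satisfy_admissibility(self, pulse2, rng):
        for _ in range(25):
            x, y = rng.uniform(-0.7, 0.7, 2)
            if np.hypot(x, y) > 0.85:
                continue
            sp = surface_point("hopf", x, y, 0.0, pulse2)
            for s, dp in zip(sp.solutions, sp.det_positive):
                p = _mk(s, 0.0)
                J = jacobian(complex(x, y), p, pulse2)
                assert dp == (J.determinant > 0)

    def test_node_focus_solutions_have_repeated_eigenvalues(self, pulse2):
        sp = surface_point("node-focus", 0.3, -0.2, 0.0, pulse2)
        assert sp.solutions
        for s in sp.solutions:
            J = jacobian(0.3 - 0.2j, _mk(s, 0.0), pulse2)
            assert abs(J.discriminant) < 1e-9


def _mk(sol, dk):
    p = ModelParams.__new__(ModelParams)
    object.__setattr__(p, "eta0", sol[0])
    object.__setattr__(p, "delta_eta", sol[1])
    object.__setattr__(p, "k0", sol[2])
    object.__setattr__(p, "delta_k", dk)
    object.__setattr__(p, "n", 2)
    return p


class TestRegionStructure:
    def test_saddle_node_sheets_occupy_the_two_competition_quadrants(
            self, pulse2):
        # excitable+excitatory (eta0<0, k0>0) and spiking+inhibitory
        # (eta0>0, k0<0): bifurcations need competing tendencies
        mesh = build_surface_mesh("saddle-node", 0.0, pulse2, clip=CLIP)
        arr = mesh.solutions_array()
        assert len(arr) > 1000
        case1 = (arr[:, 2] < 0) & (arr[:, 4] > 0)
        case2 = (arr[:, 2] > 0) & (arr[:, 4] < 0)
        assert np.mean(case1 | case2) > 0.95
        assert case1.sum() > 100 and case2.sum() > 100

    def test_hopf_sheet_only_with_spiking_inhibitory_networks(self, pulse2):
        mesh = build_surface_mesh("hopf", 0.0, pulse2, clip=CLIP)
        arr = mesh.solutions_array()
        assert len(arr) > 500
        assert np.all(arr[:, 2] > 0)  # eta0 > 0
        assert np.all(arr[:, 4] < 0)  # k0 < 0

    def test_synaptic_diversity_empties_the_view(self, pulse2):
        n0 = len(build_surface_mesh("hopf", 0.0, pulse2, clip=CLIP)
                 .solutions_array())
        n3 = len(build_surface_mesh("hopf", 3.0, pulse2, clip=CLIP)
                 .solutions_array())
        assert n3 < 0.01 * n0

    def test_unphysical_sheet_retained_when_unfiltered(self, pulse2):
        mesh = build_surface_mesh("hopf", 3.0, pulse2, clip=None,
                                  physical_filter=False)
        arr = mesh.solutions_array()
        # the migrated sheet lives at negative delta_eta
        assert np.sum(arr[:, 3] < 0) > 100


class TestLineConsistency:
    def test_case1_line_saddle_node_intersections(self, case1_branches):
        # the independent (x, y, k0) solve reproduces the continuation folds
        for dk, expected in ((0.0, 2), (0.2, 0)):
            hits = surface_line_intersections(
                "saddle-node", {"eta0": -0.3, "delta_eta": 0.08}, "k0",
                (0.0, 3.0), dk, n_seeds=150)
            assert len(hits) == expected
            if expected:
                sns = sorted(e.value for b in case1_branches[dk]
                             for e in b.events_of("saddle-node"))
                assert np.allclose(sorted(h[0] for h in hits), sns, atol=1e-3)

    def test_case2_line_hopf_intersections(self, case2_branches):
        for dk, expected in ((0.0, 1), (1.3, 2), (1.7, 0)):
            hits = surface_line_intersections(
                "hopf", {"k0": -9.0, "delta_eta": 0.5}, "eta0",
                (0.0, 15.0), dk, n_seeds=150)
            assert len(hits) == expected
            hopfs = sorted(e.value for b in case2_branches[dk]
                           for e in b.events_of("hopf"))
            assert np.allclose(sorted(h[0] for h in hits), hopfs, atol=1e-3)


class TestCrossValidation:
    @pytest.mark.parametrize("kind", ["saddle-node", "hopf", "node-focus"])
    def test_random_round_trip(self, kind, pulse2, rng):
        # every surface solution must reappear as a continuation event at
        # the same parameters
        grid = default_surface_grid(20, 40)
        rng.shuffle(grid)
        checked = 0
        for x, y in grid:
            if checked >= 12:
                break
            try:
                sp = surface_point(kind, float(x), float(y), 0.0, pulse2)
            except DegeneratePointError:
                continue
            for s, ph, dp in zip(sp.solutions, sp.physical, sp.det_positive):
                if not ph or s[1] < 1e-9 or (kind == "hopf" and not dp) \
                        or abs(s[2]) > 40 or abs(s[0]) > 30:
                    continue
                rep = cross_validate_point(s, kind, complex(x, y), 0.0, pulse2)
                assert rep["ok"], rep
                checked += 1
                break
        assert checked >= 10


class TestSharperPulse:
    def test_region_structure_persists_at_n9(self, pulse9):
        sn = build_surface_mesh("saddle-node", 0.0, pulse9, clip=CLIP)
        arr = sn.solutions_array()
        case1 = (arr[:, 2] < 0) & (arr[:, 4] > 0)
        case2 = (arr[:, 2] > 0) & (arr[:, 4] < 0)
        assert np.mean(case1 | case2) > 0.95
        hopf = build_surface_mesh("hopf", 0.0, pulse9, clip=CLIP)
        ah = hopf.solutions_array()
        assert len(ah) > 100
        assert np.all(ah[:, 2] > 0)
        assert np.all(ah[:, 4] < 0)


class TestMeshExport:
    def test_obj_export_point_count_and_faces(self, pulse2, tmp_path):
        from thetanet.surfaces import export_mesh_obj

        mesh = build_surface_mesh("hopf", 0.0, pulse2, clip=CLIP)
        path = tmp_path / "hopf.obj"
        n = export_mesh_obj(mesh, path, grid_shape=(60, 120))
        text = path.read_text()
        assert n == len(mesh.points)
        assert text.count("\nv ") + text.startswith("v ") == n
        assert "\nf " in text  # adjacency produced at least one face
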