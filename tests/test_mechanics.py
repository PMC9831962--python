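"""Hexahedral FE solver: patch test against the closed-form uniaxial
solution, equilibrium, element quality screening, linearity, and the
Abaqus INP round trip."""

import numpy as np
import pytest

import spineshape.mechanics as mech
from spineshape.inp import export_inp, read_inp
from spineshape.mechanics import (
    LoadCase,
    MaterialSet,
    SimulationResult,
    batch_simulate,
    corner_jacobians,
    element_stiffness,
    element_stresses,
    scaled_jacobians,
    screen_quality,
    solve_axial,
    solve_linear_elastic,
)
from tests.conftest import make_box_mesh


def _roller_patch_solution(mesh, pressure):
    """Uniaxial compression with lateral rollers on the symmetry faces."""
    mats = MaterialSet.default()
    top = np.flatnonzero(np.isclose(mesh.nodes[:, 2], mesh.nodes[:, 2].max()))
    bottom = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 0.0))
    faces = mech._faces_on_nodes(mesh.hexahedra, top)
    forces, area = mech._quad_face_forces(
        mesh.nodes, faces, np.array([0.0, 0.0, -1.0])
    )
    forces *= pressure
    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    fixed[bottom, 2] = True
    fixed[np.isclose(mesh.nodes[:, 0], 0.0), 0] = True
    fixed[np.isclose(mesh.nodes[:, 1], 0.0), 1] = True
    u, K = solve_linear_elastic(mesh, mats, forces, fixed)
    return u, K, forces, fixed, area, mats


class TestPatchTest:
    def test_uniaxial_closed_form(self, box_mesh):
        P, L = 2.0, 10.0
        u, _, _, _, area, mats = _roller_patch_solution(box_mesh, P)
        E, nu = mats.linear["cancellous"]
        top = np.isclose(box_mesh.nodes[:, 2], L)
        np.testing.assert_allclose(u[top, 2], -P * L / E, rtol=1e-6)
        sigma = element_stresses(
            box_mesh, mats, u, np.arange(box_mesh.n_elements)
        )
        np.testing.assert_allclose(sigma[:, :, 2], -P, rtol=1e-6)
        np.testing.assert_allclose(sigma[:, :, 0], 0.0, atol=1e-9 * P * 1e3)

    def test_hydrostatic_proxy_matches_closed_form_across_refinements(self):
        # uniaxial stress: hydrostatic pressure is P/3, at any refinement
        P = 3.0
        for n in (2, 4):
            mesh = make_box_mesh(n, n, n, label="nucleus")
            u, *_ , mats = _roller_patch_solution(mesh, P)
            sigma = element_stresses(mesh, mats, u, np.arange(mesh.n_elements))
            hydro = -(sigma[:, :, 0] + sigma[:, :, 1] + sigma[:, :, 2]) / 3.0
            assert hydro.max() == pytest.approx(P / 3.0, rel=1e-6)

    def test_load_doubling_scales_linearly(self, box_mesh):
        u1, *_ = _roller_patch_solution(box_mesh, 1.0)
        u2, *_ = _roller_patch_solution(box_mesh, 2.0)
        np.testing.assert_allclose(u2, 2.0 * u1, rtol=1e-9, atol=1e-15)


class TestElementStiffness:
    def test_unit_cube_symmetric_psd_with_six_rigid_modes(self):
        coords = make_box_mesh(1, 1, 1, lengths=(1.0, 1.0, 1.0)).nodes[
            make_box_mesh(1, 1, 1, lengths=(1.0, 1.0, 1.0)).hexahedra[0]
        ]
        K = element_stiffness(coords, 100.0, 0.3)[0]
        assert np.abs(K - K.T).max() <= 1e-10 * np.abs(K).max()
        eig = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(eig) < 1e-9 * eig.max()) == 6
        assert np.all(eig > -1e-9 * eig.max())

    def test_assembled_stiffness_symmetric(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        mesh = meshes[0]
        solved = np.flatnonzero(
            ~np.isin(mesh.structure_label.astype(str),
                     ("facet_cartilage_left", "facet_cartilage_right"))
        )
        K = mech.assemble_stiffness(mesh, MaterialSet.default(), solved)
        assert abs(K - K.T).max() <= 1e-10 * abs(K).max()


class TestScreening:
    def test_unit_cube_is_perfect(self):
        mesh = make_box_mesh(1, 1, 1, lengths=(1.0, 1.0, 1.0))
        valid, metrics = screen_quality(mesh)
        assert valid
        assert metrics["min_scaled_jacobian"] == pytest.approx(1.0)

    def test_inverted_element_detected(self):
        mesh = make_box_mesh(1, 1, 1, lengths=(1.0, 1.0, 1.0))
        nodes = mesh.nodes.copy()
        nodes[4] = [0.5, 0.5, -2.0]  # push a top node through the bottom face
        bad = mesh.with_nodes(nodes)
        valid, metrics = screen_quality(bad)
        assert not valid
        assert metrics["inverted_elements"] == 1
        assert corner_jacobians(bad).min() < 0

    def test_sheared_cube_scaled_jacobian(self):
        mesh = make_box_mesh(1, 1, 1, lengths=(1.0, 1.0, 1.0))
        nodes = mesh.nodes.copy()
        nodes[:, 0] += 0.5 * nodes[:, 2]  # simple shear, gamma = 0.5
        sheared = mesh.with_nodes(nodes)
        # edge vectors at each corner: (1,0,0), (0,1,0), (0.5,0,1)
        # det = 1; norms 1, 1, sqrt(1.25)
        expected = 1.0 / np.sqrt(1.25)
        np.testing.assert_allclose(scaled_jacobians(sheared), expected, rtol=1e-12)


class TestSolveAxial:
    def test_equilibrium_reactions_balance_load(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        result, state = solve_axial(meshes[0], full_output=True)
        assert result.valid
        K, u, f = state["stiffness"], state["displacements"], state["forces"]
        residual = K @ u.ravel() - f.ravel()
        reactions = residual.reshape(-1, 3)[state["fixed_dof"][:, 2]]
        total = reactions[:, 2].sum()
        assert total == pytest.approx(400.0, rel=1e-8)
        free = ~state["fixed_dof"].ravel()
        assert np.abs(residual[free]).max() <= 1e-8 * np.abs(f).max()

    def test_zero_force_zero_response(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        result = solve_axial(meshes[0], load=LoadCase(total_force=0.0))
        assert result.idp == pytest.approx(0.0, abs=1e-12)

    def test_outputs_scale_linearly_with_load(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        r1 = solve_axial(meshes[0], load=LoadCase(400.0))
        r2 = solve_axial(meshes[0], load=LoadCase(800.0))
        assert r2.idp == pytest.approx(2.0 * r1.idp, rel=1e-9)

    def test_invalid_mesh_refused_with_status(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        nodes = meshes[0].nodes.copy()
        hex0 = meshes[0].hexahedra[0]
        nodes[hex0[4]] = nodes[hex0[0]] - [0, 0, 5.0]
        broken = meshes[0].with_nodes(nodes)
        result = solve_axial(broken)
        assert not result.valid
        assert "element quality" in result.failure_reason


class TestBatchSimulate:
    def test_all_valid_toy_cohort(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        results = batch_simulate(meshes[:3])
        assert len(results) == 3
        assert all(isinstance(r, SimulationResult) for r in results)

    def test_single_inverted_subject_flagged(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        nodes = meshes[1].nodes.copy()
        hex0 = meshes[1].hexahedra[10]
        nodes[hex0[4]] = nodes[hex0[0]] - [0, 0, 5.0]
        cohort = [meshes[0], meshes[1].with_nodes(nodes)]
        results = batch_simulate(cohort)
        assert [r.valid for r in results] == [True, False]
        assert "element quality" in results[1].failure_reason

    def test_bitwise_deterministic(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        a = batch_simulate(meshes[:2])
        b = batch_simulate(meshes[:2])
        for ra, rb in zip(a, b):
            assert (ra.idp, ra.fcp, ra.valid) == (rb.idp, rb.fcp, rb.valid)


class TestMaterials:
    def test_default_set_covers_phantom(self, phantom_cohort):
        _, _, meshes, _ = phantom_cohort
        MaterialSet.default().validate_for(meshes[0])

    def test_missing_structure_rejected(self, box_mesh):
        mats = MaterialSet(linear={"cortical": (12000.0, 0.3)})
        with pytest.raises(ValueError, match="cancellous"):
            mats.validate_for(box_mesh)

    def test_invalid_poisson_rejected(self, box_mesh):
        mats = MaterialSet(linear={"cancellous": (100.0, 0.6)})
        with pytest.raises(ValueError, match="Poisson"):
            mats.validate_for(box_mesh)

    def test_disc_surrogates_derive_from_ground_stiffness(self):
        mats = MaterialSet.default()
        E, nu = mats.linear["nucleus"]
        assert E == pytest.approx(4.0 * 0.16 * (1.0 + nu))
        E, nu = mats.linear["annulus_layer_3"]
        assert E == pytest.approx(4.0 * 0.34 * (1.0 + nu))


class TestInpExport:
    def test_round_trip_preserves_mesh(self, phantom_cohort, tmp_path):
        _, _, meshes, _ = phantom_cohort
        path = tmp_path / "subject.inp"
        export_inp(meshes[0], path=str(path))
        back = read_inp(str(path))
        np.testing.assert_array_equal(back.hexahedra, meshes[0].hexahedra)
        np.testing.assert_allclose(back.nodes, meshes[0].nodes, atol=1e-8)
        assert back.label_histogram() == meshes[0].label_histogram()

    def test_single_element_deck_structure(self, tmp_path):
        mesh = make_box_mesh(1, 1, 1, lengths=(1.0, 1.0, 1.0))
        path = tmp_path / "one.inp"
        export_inp(mesh, path=str(path))
        text = path.read_text()
        for keyword in ("*HEADING", "*NODE", "*ELEMENT", "*SOLID SECTION",
                        "*MATERIAL", "*STEP", "*END STEP"):
            assert keyword in text
        assert text.index("*NODE") < text.index("*ELEMENT") < text.index("*STEP")
        back = read_inp(str(path))
        assert back.n_nodes == 8 and back.n_elements == 1

    def test_structure_counts_match_label_histogram(self, phantom_cohort, tmp_path):
        _, _, meshes, _ = phantom_cohort
        path = tmp_path / "counts.inp"
        export_inp(meshes[0], path=str(path))
        hist = meshes[0].label_histogram()
        text = path.read_text().splitlines()
        counts = {}
        current = None
        for line in text:
            if line.startswith("*ELEMENT"):
                current = line.split("ELSET=")[1].strip().lower()
                counts[current] = 0
            elif line.startswith("*"):
                current = None
            elif current is not None:
                counts[current] += 1
        assert counts == hist

    def test_hyperelastic_materials_in_deck(self, phantom_cohort, tmp_path):
        _, _, meshes, _ = phantom_cohort
        path = tmp_path / "mats.inp"
        export_inp(meshes[0], path=str(path))
        text = path.read_text()
        assert "*HYPERELASTIC, NEO HOOKE" in text
        assert "HOLZAPFEL" in text
        assert "0.34, 0.3, 1.81, 11.0, 0.0" in text
        assert "PRESSURE-OVERCLOSURE=HARD" in text
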