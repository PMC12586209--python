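"""Finite-element strength solver: posing, assembly, plasticity, scaling."""

import numpy as np
import pytest

import femfall as ff
from femfall.fe import (FemurSystem, _constraints, _solve_constrained,
                        rotation_about_axis)
from femfall.materials import MaterialField

# ------------------------------------------------------------------ posing


def test_rotation_matrix_hand_values():
    """-5 deg rotation about y applied to (1,0,0), hand-computed."""
    R = rotation_about_axis([0, 1, 0], -5.0)
    got = R @ np.array([1.0, 0.0, 0.0])
    np.testing.assert_allclose(got, [0.9961946981, 0.0, 0.0871557427], atol=1e-9)


def test_pose_is_rigid(coarse_mesh):
    cfg = ff.FallConfig(adduction_angle=-5.0, internal_rotation=10.0)
    posed = ff.pose_femur(coarse_mesh, cfg)
    idx = np.arange(0, coarse_mesh.n_nodes, max(1, coarse_mesh.n_nodes // 40))
    d0 = np.linalg.norm(coarse_mesh.nodes[idx][:, None] - coarse_mesh.nodes[idx], axis=2)
    d1 = np.linalg.norm(posed.nodes[idx][:, None] - posed.nodes[idx], axis=2)
    bbox = np.ptp(coarse_mesh.nodes, axis=0).max()
    assert np.abs(d1 - d0).max() < 1e-9 * bbox


def test_zero_pose_is_canonical_alignment_only(coarse_mesh):
    """(0, 0) pose applies only the documented canonical alignment:
    shaft along +x, head centre at the origin."""
    cfg = ff.FallConfig(adduction_angle=0.0, internal_rotation=0.0)
    posed = ff.pose_femur(coarse_mesh, cfg)
    p0, d = posed.landmarks["shaft_axis"]
    np.testing.assert_allclose(d, [1.0, 0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(posed.landmarks["head_center"], 0.0, atol=1e-9)
    # trochanter sits below the head along the load axis
    assert posed.landmarks["greater_trochanter"][2] < 0


def test_pose_missing_landmark_errors(coarse_mesh):
    bare = ff.TetMesh(coarse_mesh.nodes.copy(), coarse_mesh.elements.copy())
    with pytest.raises(ValueError, match="landmark"):
        ff.pose_femur(bare, ff.FallConfig())


# ---------------------------------------------------------------- assembly


def _patch_solution(A):
    """Impose u = A x on the boundary of a unit cube and solve the
    interior; returns the system and full displacement vector."""
    mesh = ff.box_mesh((1, 1, 1), (2, 2, 2))
    mat = MaterialField.uniform(mesh.n_elements, E=1000.0, nu=0.3)
    sysm = FemurSystem(mesh, mat)
    from femfall.mesh import surface_nodes
    surf = surface_nodes(mesh)
    fixed = (3 * surf[:, None] + np.arange(3)).ravel()
    vals = (mesh.nodes[surf] @ A.T).ravel()
    K = sysm.stiffness()
    u = _solve_constrained(K, fixed, vals)
    return sysm, u


def test_patch_test_constant_strain():
    """A linear displacement field is reproduced exactly: every element
    carries the same strain (patch test for the linear tetrahedron)."""
    A = np.array([[1e-3, 4e-4, 0.0], [0.0, -2e-4, 1e-4], [2e-4, 0.0, 5e-4]])
    sysm, u = _patch_solution(A)
    strains = sysm.element_strains(u)
    sym = 0.5 * (A + A.T)
    expected = np.array([sym[0, 0], sym[1, 1], sym[2, 2],
                         2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]])
    np.testing.assert_allclose(strains, np.tile(expected, (len(strains), 1)),
                               atol=1e-12)


def test_patch_test_uniaxial_constrained_modulus():
    """Uniaxial strain: stress = E(1-nu)/((1+nu)(1-2nu)) * eps."""
    eps = 1e-3
    A = np.diag([0.0, 0.0, eps])
    sysm, u = _patch_solution(A)
    E, nu = 1000.0, 0.3
    sigma = E * sysm.D1 @ sysm.element_strains(u).T
    expected = E * (1 - nu) / ((1 + nu) * (1 - 2 * nu)) * eps
    np.testing.assert_allclose(sigma[2], expected, rtol=1e-9)


def test_stiffness_linear_in_modulus():
    mesh = ff.box_mesh((1, 1, 2), (1, 1, 2))
    K1 = ff.assemble_system(mesh, MaterialField.uniform(mesh.n_elements, E=500.0))
    K2 = ff.assemble_system(mesh, MaterialField.uniform(mesh.n_elements, E=1000.0))
    assert abs(K2 - 2 * K1).max() < 1e-9 * abs(K1).max()


def test_unconstrained_stiffness_has_six_rigid_modes():
    mesh = ff.box_mesh((1, 1, 1), (1, 1, 1))
    K = ff.assemble_system(mesh, MaterialField.uniform(mesh.n_elements, E=1000.0))
    eig = np.linalg.eigvalsh(K.toarray())
    tol = 1e-9 * eig.max()
    assert int((np.abs(eig) < tol).sum()) == 6


def test_zero_modulus_elements_warn(caplog):
    mesh = ff.box_mesh((1, 1, 2), (1, 1, 2))
    E = np.full(mesh.n_elements, 1000.0)
    E[:3] = 0.0
    mat = MaterialField(E, np.full_like(E, np.inf), np.full_like(E, np.inf),
                        np.ones_like(E))
    with caplog.at_level("WARNING", logger="femfall.fe"):
        FemurSystem(mesh, mat)
    assert any("zero modulus" in r.getMessage() for r in caplog.records)


# ------------------------------------------------------------------ solver


def _column(nu=0.0):
    """10 x 10 x 40 mm column driven axially from the top."""
    mesh = ff.box_mesh((10.0, 10.0, 40.0), (2, 2, 8))
    z = mesh.nodes[:, 2]
    top = np.flatnonzero(z > 40 - 1e-9)
    bottom = np.flatnonzero(z < 1e-9)
    hinge = bottom[np.argmin(np.linalg.norm(mesh.nodes[bottom], axis=1))]
    mesh.node_sets = {"head": top, "trochanter": np.setdiff1d(bottom, [hinge]),
                      "hinge": np.array([hinge])}
    return mesh


def test_elastic_limit_matches_linear_oracle():
    """With yields scaled out of reach the incremental solve is linear:
    the force curve is proportional and the peak equals the one-shot
    linear solution within 0.1%."""
    mesh = _column()
    mat = MaterialField.uniform(mesh.n_elements, E=8000.0, yield_t=1e12, nu=0.0)
    cfg = ff.FallConfig(max_displacement=1.0, n_increments=4, patch_radius=1.0)
    res = ff.solve_strength(mesh, mat, cfg)
    # proportionality of the recorded curve
    ratio = res.head_force[1:] / res.displacement[1:]
    np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)
    # independent linear solve at full displacement
    sysm = FemurSystem(mesh, mat)
    K = sysm.stiffness()
    fixed, vals = _constraints(mesh, cfg, cfg.max_displacement)
    u = _solve_constrained(K, fixed, vals)
    head_force = np.linalg.norm((K @ u).reshape(-1, 3)[mesh.node_sets["head"]].sum(axis=0))
    assert res.head_force[-1] == pytest.approx(head_force, rel=1e-3)
    assert res.femoral_strength == pytest.approx(head_force / 1000.0, rel=1e-3)


def test_perfect_plasticity_plateau():
    """Elastic-perfectly-plastic column: plateau force = area x yield
    stress (1-D closed form), within 5%."""
    sigma_y = 100.0
    mesh = _column()
    mat = MaterialField.uniform(mesh.n_elements, E=10000.0, yield_t=sigma_y, nu=0.0)
    cfg = ff.FallConfig(max_displacement=1.2, n_increments=6,
                        post_yield_tangent=0.0, patch_radius=1.0)
    res = ff.solve_strength(mesh, mat, cfg)
    plateau = 10.0 * 10.0 * sigma_y   # N
    assert res.head_force[-1] == pytest.approx(plateau, rel=0.05)
    assert res.yield_fraction[-1] > 0.9


def test_zero_displacement_gives_zero_strength():
    mesh = _column()
    mat = MaterialField.uniform(mesh.n_elements, E=8000.0, yield_t=1e12, nu=0.0)
    cfg = ff.FallConfig(max_displacement=0.0, n_increments=2, patch_radius=1.0)
    res = ff.solve_strength(mesh, mat, cfg)
    assert res.femoral_strength == 0.0
    np.testing.assert_allclose(res.head_force, 0.0, atol=1e-9)


def test_global_equilibrium(coarse_mesh, coarse_phantom):
    """Head reaction balances trochanter + hinge reactions along the
    load axis to 1e-6 of the peak force."""
    cal = ff.CalibrationParams()
    mat = ff.map_to_elements(coarse_phantom, coarse_mesh, cal)
    cfg = ff.FallConfig(max_displacement=1.5, n_increments=3)
    posed = ff.pose_femur(coarse_mesh, cfg)
    ff.assign_contact_sets(posed, cfg)
    res = ff.solve_strength(posed, mat, cfg)
    total_z = (res.reactions["head"][2] + res.reactions["trochanter"][2]
               + res.reactions["hinge"][2])
    peak = res.head_force.max()
    assert abs(total_z) < 1e-6 * peak
    assert res.femoral_strength > 0


def test_frame_indifference(coarse_mesh, coarse_phantom):
    """Rigidly pre-rotating the input mesh leaves strength unchanged
    (within 1%) because posing is intrinsic."""
    cal = ff.CalibrationParams()
    mat = ff.map_to_elements(coarse_phantom, coarse_mesh, cal)
    cfg = ff.FallConfig(max_displacement=1.5, n_increments=3)

    posed = ff.pose_femur(coarse_mesh, cfg)
    ff.assign_contact_sets(posed, cfg)
    s0 = ff.solve_strength(posed, mat, cfg).femoral_strength

    R = rotation_about_axis([0.3, 0.5, 0.8], 33.0)
    rotated = coarse_mesh.transformed(R, np.array([5.0, -7.0, 3.0]))
    posed2 = ff.pose_femur(rotated, cfg)
    ff.assign_contact_sets(posed2, cfg)
    s1 = ff.solve_strength(posed2, mat, cfg).femoral_strength
    assert s1 == pytest.approx(s0, rel=0.01)


def _elastic_stiffness(vol, target_edge):
    mesh = ff.mesh_from_volume(vol, target_edge=target_edge)
    mat = ff.map_to_elements(vol, mesh, ff.CalibrationParams(yield_strain=10.0))
    cfg = ff.FallConfig(max_displacement=0.5, n_increments=1)
    posed = ff.pose_femur(mesh, cfg)
    ff.assign_contact_sets(posed, cfg)
    res = ff.solve_strength(posed, mat, cfg)
    return res.head_force[-1] / cfg.max_displacement


def test_mesh_refinement_stability(coarse_phantom_spec):
    """Halving the target edge changes elastic stiffness by < 10%."""
    import dataclasses
    spec = dataclasses.replace(coarse_phantom_spec, voxel_spacing=1.5)
    vol = ff.generate_femur_phantom(spec, seed=0)
    k_coarse = _elastic_stiffness(vol, 6.0)
    k_fine = _elastic_stiffness(vol, 3.0)
    assert abs(k_fine - k_coarse) / k_coarse < 0.10


def test_quadratic_elements_not_stiffer_than_linear():
    mesh = _column()
    matL = MaterialField.uniform(mesh.n_elements, E=8000.0, yield_t=1e12, nu=0.3)
    cfg = ff.FallConfig(max_displacement=0.5, n_increments=1, patch_radius=1.0)
    fL = ff.solve_strength(mesh, matL, cfg).head_force[-1]
    quad = ff.to_quadratic(mesh)
    fQ = ff.solve_strength(quad, matL, cfg).head_force[-1]
    assert fQ <= fL * (1 + 1e-9)


def test_strength_vs_density_monotone_and_power_law(coarse_phantom_spec):
    """Elastic-regime strength scales with density as the modulus power
    law (pure power-law calibration), and is monotone in the scale."""
    cal = ff.CalibrationParams(ash_intercept=0.0, yield_strain=10.0)
    cfg = ff.FallConfig(max_displacement=1.0, n_increments=2)
    table = ff.strength_vs_density(coarse_phantom_spec, [1.0, 1.6], cal, cfg,
                                   target_edge=8.0, seed=0)
    s1, s2 = table.strength_kN.to_numpy()
    assert s2 >= s1
    assert s2 / s1 == pytest.approx(1.6**cal.modulus_exponent, rel=0.10)
    with pytest.raises(ValueError):
        ff.strength_vs_density(coarse_phantom_spec, [0.0], cal, cfg, seed=0)


def test_singular_system_reported():
    mesh = _column()
    mesh.node_sets = {"head": mesh.node_sets["head"]}  # no supports at all
    mat = MaterialField.uniform(mesh.n_elements, E=8000.0, yield_t=1e12)
    cfg = ff.FallConfig(max_displacement=0.5, n_increments=1)
    with pytest.raises((RuntimeError, KeyError)):
        ff.solve_strength(mesh, mat, cfg)
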