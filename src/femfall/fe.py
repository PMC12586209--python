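"""Sideways-fall femoral strength by quasi-static finite elements.

The femur is posed in a sideways-fall configuration (default -5 deg
adduction, 0 deg internal rotation), supported at the greater trochanter,
pinned at a distal hinge point, and driven downward at the femoral head
in displacement increments.  Femoral strength is the peak resultant
reaction force at the head (reported in kN).

The solver is small-strain with a bilinear elastic-plastic element law:
an element yields when its von Mises stress exceeds the sign-appropriate
yield stress (tension vs. compression selected by the sign of the
volumetric strain), with a post-yield tangent equal to a configurable
fraction of E.  Plasticity is resolved by secant-stiffness iteration
(deformation plasticity), which is adequate for the monotonic,
proportional loading applied here.  This quasi-static scheme replaces an
explicit dynamic contact simulation: the nominal 1 m/s impact speed
enters only through the material rate factor, and the rigid supports are
idealised as nodal constraint sets rather than contact surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialField
from .mesh import TET10_EDGES, TetMesh

log = logging.getLogger(__name__)


@dataclass
class FallConfig:
    """Loading geometry and incremental-solve settings.

    Angles in degrees; ``prescribed_speed`` (m/s) is metadata in this
    quasi-static mode; displacements in mm.
    """

    adduction_angle: float = -5.0
    internal_rotation: float = 0.0
    prescribed_speed: float = 1.0
    max_displacement: float = 3.0
    n_increments: int = 12
    load_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    post_yield_tangent: float = 0.05
    trochanter_support: str = "fixed"   # "fixed" (all DOFs) or "frictionless"
    patch_radius: float = 12.0          # mm, contact patch extraction
    max_iterations: int = 40
    tolerance: float = 1e-3
    max_bisections: int = 5

    def validate(self) -> None:
        if self.n_increments < 1:
            raise ValueError("n_increments must be >= 1")
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")
        if self.trochanter_support not in ("fixed", "frictionless"):
            raise ValueError("trochanter_support must be 'fixed' or 'frictionless'")
        if not 0 <= self.post_yield_tangent < 1:
            raise ValueError("post_yield_tangent must be in [0, 1)")


@dataclass
class StrengthResult:
    """Force-displacement response and its peak."""

    displacement: np.ndarray            # mm, starts at 0
    head_force: np.ndarray              # N, resultant at the head, starts at 0
    femoral_strength: float             # kN, peak of head_force
    converged: np.ndarray               # per-increment flags
    yield_fraction: np.ndarray          # per-increment yielded-element fraction
    reactions: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.displacement) != len(self.head_force):
            raise ValueError("curves must have equal length")
        if abs(self.head_force[0]) > 1e-9:
            raise ValueError("force curve must start at 0")
        if abs(self.femoral_strength - self.head_force.max() / 1000.0) > 1e-9:
            raise ValueError("femoral_strength must be the curve peak")


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _intrinsic_frame(landmarks: dict):
    """Orthonormal (shaft, anterior, medial) triad from landmarks."""
    try:
        _, s = landmarks["shaft_axis"]
        _, n = landmarks["neck_axis"]
        head = np.asarray(landmarks["head_center"], float)
    except KeyError as e:
        raise ValueError(f"missing landmark required for posing: {e}") from None
    s = np.asarray(s, float) / np.linalg.norm(s)
    n = np.asarray(n, float)
    m = n - (n @ s) * s
    norm = np.linalg.norm(m)
    if norm < 1e-9:
        raise ValueError("neck axis parallel to shaft axis; medial direction undefined")
    m /= norm
    return s, np.cross(m, s), m, head


def pose_femur(mesh: TetMesh, cfg: FallConfig) -> TetMesh:
    """Rigidly pose the femur for a sideways fall.

    The intrinsic frame (shaft axis, anterior, medial) is mapped so the
    shaft lies along +x, the anterior direction along +y and the medial
    direction (towards the head) along +z, with the head centre at the
    origin; internal rotation is applied about the shaft axis and
    adduction about the anterior axis.  The load axis becomes global -z.
    Pure rigid motion: pairwise distances are preserved, and the result
    depends only on intrinsic geometry (frame indifference).
    """
    cfg.validate()
    s, a, m, head = _intrinsic_frame(mesh.landmarks)
    T = np.vstack([s, a, m])                       # world -> canonical
    R = (rotation_about_axis([0, 1, 0], cfg.adduction_angle)
         @ rotation_about_axis([1, 0, 0], cfg.internal_rotation) @ T)
    return mesh.transformed(R, -R @ head)


def assign_contact_sets(mesh: TetMesh, cfg: FallConfig) -> TetMesh:
    """Attach head/trochanter patches and the distal hinge node.

    On the posed mesh (load axis -z): the head patch is the set of
    surface nodes within ``patch_radius`` of the topmost point, the
    trochanter patch those within ``patch_radius`` of the lowest point
    near the greater-trochanter landmark, and the hinge is the node
    nearest the distal landmark.  Patch geometry is an implementation
    choice standing in for unquantified rigid-support surfaces.
    """
    nodes = mesh.nodes
    z = nodes[:, 2]
    # band selection (not nearest-node balls): robust to roundoff ties
    head_set = np.flatnonzero(z >= z.max() - cfg.patch_radius - 1e-9)

    gt = np.asarray(mesh.landmarks.get("greater_trochanter", nodes[np.argmin(z)]))
    near_gt = np.linalg.norm(nodes - gt, axis=1) <= 2.5 * cfg.patch_radius
    if not near_gt.any():
        near_gt = np.ones(len(nodes), bool)
    z_lo = z[near_gt].min()
    troch_set = np.flatnonzero(near_gt & (z <= z_lo + cfg.patch_radius + 1e-9))

    distal = np.asarray(mesh.landmarks.get("distal_end", nodes[np.argmin(nodes[:, 0])]))
    hinge = int(np.argmin(np.linalg.norm(nodes - distal, axis=1)))

    troch_set = np.setdiff1d(troch_set, head_set)
    head_set = np.setdiff1d(head_set, [hinge])
    troch_set = np.setdiff1d(troch_set, [hinge])
    if head_set.size == 0 or troch_set.size == 0:
        raise ValueError("empty contact patch; increase patch_radius")
    mesh.node_sets = {"head": head_set, "trochanter": troch_set,
                      "hinge": np.array([hinge])}
    mesh.validate()
    return mesh


# ----------------------------------------------------------------- assembly

def _elastic_D(nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix for E = 1 (engineering shears)."""
    f = 1.0 / ((1 + nu) * (1 - 2 * nu))
    D = np.zeros((6, 6))
    D[:3, :3] = nu * f
    np.fill_diagonal(D[:3, :3], (1 - nu) * f)
    D[3:, 3:] = np.eye(3) * (0.5 / (1 + nu))
    return D


def _shape_gradients(mesh: TetMesh):
    """Barycentric gradients g_i = grad L_i (E, 4, 3) and volumes."""
    x = mesh.corner_coords()
    ones = np.ones((mesh.n_elements, 4, 1))
    A = np.concatenate([ones, x], axis=2)          # (E, 4, 4)
    vols = np.linalg.det(A) / 6.0
    C = np.linalg.inv(A)                           # (E, 4, 4); C[:,1:4,i] = grad L_i
    grads = np.transpose(C[:, 1:4, :], (0, 2, 1))  # (E, 4, 3)
    return grads, vols


def _b_from_gradients(dN: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (E, 6, 3n) from (E, n, 3) gradients."""
    E, n, _ = dN.shape
    B = np.zeros((E, 6, 3 * n))
    gx, gy, gz = dN[..., 0], dN[..., 1], dN[..., 2]
    cols = np.arange(n)
    B[:, 0, 3 * cols] = gx
    B[:, 1, 3 * cols + 1] = gy
    B[:, 2, 3 * cols + 2] = gz
    B[:, 3, 3 * cols] = gy
    B[:, 3, 3 * cols + 1] = gx
    B[:, 4, 3 * cols + 1] = gz
    B[:, 4, 3 * cols + 2] = gy
    B[:, 5, 3 * cols] = gz
    B[:, 5, 3 * cols + 2] = gx
    return B


_GAUSS_A, _GAUSS_B = 0.5854101966249685, 0.13819660112501052


def _tet10_B(grads: np.ndarray):
    """Quadratic-tet B at the 4 interior Gauss points, (E, 4, 6, 30).

    Subparametric: edge midside nodes sit at true midpoints, so the
    Jacobian is the linear element's and only the shape-function
    gradients vary across the element.
    """
    E = grads.shape[0]
    bary = np.full((4, 4), _GAUSS_B)
    np.fill_diagonal(bary, _GAUSS_A)
    Bs = np.zeros((E, 4, 6, 30))
    for q in range(4):
        L = bary[q]
        dN = np.zeros((E, 10, 3))
        for i in range(4):
            dN[:, i] = (4 * L[i] - 1) * grads[:, i]
        for j, (a, b) in enumerate(TET10_EDGES):
            dN[:, 4 + j] = 4 * (L[a] * grads[:, b] + L[b] * grads[:, a])
        Bs[:, q] = _b_from_gradients(dN)
    return Bs


class FemurSystem:
    """Precomputed element matrices and assembly machinery for one mesh.

    Element stiffnesses are stored for unit Young's modulus; assembling
    with a per-element modulus (or secant-scaled modulus) is a weighted
    scatter into a sparse matrix.
    """

    def __init__(self, mesh: TetMesh, mat: MaterialField):
        mesh.validate()
        mat.validate()
        if len(mat.young_modulus) != mesh.n_elements:
            raise ValueError("one material entry per element required")
        self.mesh = mesh
        self.mat = mat
        self.ndof = 3 * mesh.n_nodes
        self.D1 = _elastic_D(mat.poisson_ratio)
        grads, vols = _shape_gradients(mesh)
        self.vols = vols

        if mesh.order == 1:
            B = _b_from_gradients(grads)                       # (E, 6, 12)
            self.Ke1 = vols[:, None, None] * np.einsum(
                "eji,jk,ekl->eil", B, self.D1, B)
            self.B_mean = B
        else:
            Bs = _tet10_B(grads)                               # (E, 4, 6, 30)
            w = vols / 4.0
            self.Ke1 = np.einsum("e,eqji,jk,eqkl->eil", w, Bs, self.D1, Bs)
            self.B_mean = Bs.mean(axis=1)

        conn = mesh.elements
        dofs = (3 * conn[:, :, None] + np.arange(3)).reshape(mesh.n_elements, -1)
        n = dofs.shape[1]
        self._rows = np.repeat(dofs, n, axis=1).ravel()
        self._cols = np.tile(dofs, (1, n)).ravel()
        self._dofs = dofs
        if np.any(mat.young_modulus <= 0):
            log.warning("%d elements have zero modulus and contribute no stiffness",
                        int((mat.young_modulus <= 0).sum()))

    def stiffness(self, scale: np.ndarray | None = None) -> sp.csr_matrix:
        """Assemble K with per-element modulus ``scale * E`` (scale=1 elastic)."""
        E = self.mat.young_modulus
        if scale is not None:
            E = E * scale
        data = (E[:, None, None] * self.Ke1).ravel()
        K = sp.coo_matrix((data, (self._rows, self._cols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        return K

    def element_strains(self, u: np.ndarray) -> np.ndarray:
        """Mean element strains (E, 6) from a displacement vector."""
        ue = u[self._dofs]
        return np.einsum("eij,ej->ei", self.B_mean, ue)


def assemble_system(mesh: TetMesh, mat: MaterialField) -> sp.csr_matrix:
    """Elastic stiffness matrix (3N x 3N, N/mm with E in MPa, mm mesh).

    Symmetric; without constraints it has exactly six zero-energy
    rigid-body modes.
    """
    return FemurSystem(mesh, mat).stiffness()


def _von_mises(stress: np.ndarray) -> np.ndarray:
    sx, sy, sz, txy, tyz, tzx = stress.T
    return np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                   + 3.0 * (txy**2 + tyz**2 + tzx**2))


def _solve_constrained(K: sp.csr_matrix, fixed: np.ndarray, values: np.ndarray):
    ndof = K.shape[0]
    free = np.setdiff1d(np.arange(ndof), fixed)
    u = np.zeros(ndof)
    u[fixed] = values
    rhs = -K[free][:, fixed] @ values
    Kff = K[free][:, free].tocsc()
    u[free] = spla.spsolve(Kff, rhs)
    if not np.all(np.isfinite(u)):
        raise RuntimeError("singular system after constraints; check that all "
                           "rigid-body components are constrained")
    return u


def _constraints(mesh: TetMesh, cfg: FallConfig, head_disp: float):
    """Fixed DOF indices and values for one increment.

    Head patch driven along -z; trochanter patch fully fixed (default,
    matching a support with all degrees of freedom constrained) or held
    axially with one anti-spin pin ("frictionless"); hinge node pinned
    in translation (rotation is free by construction of solid elements).
    """
    head = np.asarray(mesh.node_sets["head"])
    troch = np.asarray(mesh.node_sets["trochanter"])
    hinge = np.asarray(mesh.node_sets["hinge"])
    dofs, vals = [], []
    dofs.append(3 * head + 2)
    vals.append(np.full(head.size, -head_disp))
    if cfg.trochanter_support == "fixed":
        for c in range(3):
            dofs.append(3 * troch + c)
            vals.append(np.zeros(troch.size))
    else:
        dofs.append(3 * troch + 2)
        vals.append(np.zeros(troch.size))
        pin = troch[0]          # anti-spin pin: removes in-plane rotation
        dofs.append(np.array([3 * pin, 3 * pin + 1]))
        vals.append(np.zeros(2))
    for c in range(3):
        dofs.append(3 * hinge + c)
        vals.append(np.zeros(hinge.size))
    return np.concatenate(dofs), np.concatenate(vals)


def _patch_reaction(K, u, node_set) -> np.ndarray:
    R = K @ u
    return R.reshape(-1, 3)[np.asarray(node_set)].sum(axis=0)


def solve_strength(mesh: TetMesh, mat: MaterialField, cfg: FallConfig) -> StrengthResult:
    """Displacement-controlled incremental solve; returns the
    force-displacement curve and femoral strength (kN).

    Each increment equilibrates the bilinear elastic-plastic system by
    secant-stiffness iteration: elements whose trial von Mises stress
    exceeds the sign-appropriate yield stress have their modulus scaled
    to the bilinear stress at their equivalent strain.  Non-converged
    increments are flagged and the run continues from the last converged
    state; if no increment converges a solver error is raised.
    """
    cfg.validate()
    if not mesh.node_sets:
        assign_contact_sets(mesh, cfg)
    sysm = FemurSystem(mesh, mat)

    E = np.asarray(mat.young_modulus, float)
    # tiny floor keeps nodes of zero-density elements from making K singular
    e_floor = max(E.max(), 1.0) * 1e-6
    E_eff = np.maximum(E, e_floor)
    sysm.mat = MaterialField(E_eff, mat.yield_stress_tension,
                             mat.yield_stress_compression, mat.density_app,
                             mat.poisson_ratio)

    disps = np.linspace(0.0, cfg.max_displacement, cfg.n_increments + 1)[1:]
    forces = [0.0]
    conv_flags, yield_fracs = [], []
    scale = np.ones(mesh.n_elements)
    last_reactions = {}
    n_ok = 0
    tangent = cfg.post_yield_tangent

    for d in disps:
        converged = False
        s = scale.copy()
        f_prev, stall = None, 0
        for _ in range(cfg.max_iterations):
            K = sysm.stiffness(s)
            fixed, vals = _constraints(mesh, cfg, d)
            u = _solve_constrained(K, fixed, vals)
            strain = sysm.element_strains(u)
            # elastic trial stress at full modulus
            sigma_tr = E_eff[:, None] * (strain @ sysm.D1.T)
            vm = _von_mises(sigma_tr)
            vol_strain = strain[:, :3].sum(axis=1)
            sig_y = np.where(vol_strain < 0, mat.yield_stress_compression,
                             mat.yield_stress_tension)
            with np.errstate(divide="ignore", invalid="ignore"):
                target = np.where(vm > sig_y,
                                  sig_y + tangent * (vm - sig_y), vm)
                s_new = np.where(vm > 1e-12, target / np.maximum(vm, 1e-300), 1.0)
            s_new = np.clip(s_new, 1e-6, 1.0)
            delta = np.abs(s_new - s).max()
            if delta < cfg.tolerance:
                s = s_new
                converged = True
                break
            # force stationarity: a handful of elements flickering at the
            # yield boundary must not stall an already-converged response
            F = np.linalg.norm(_patch_reaction(K, u, mesh.node_sets["head"]))
            if f_prev is not None and abs(F - f_prev) <= 1e-4 * max(F, 1.0):
                stall += 1
                if stall >= 3:
                    s = s_new
                    converged = True
                    break
            else:
                stall = 0
            f_prev = F
            s = 0.5 * s + 0.5 * s_new
        if converged:
            scale = s
            n_ok += 1
            K = sysm.stiffness(scale)
            u = _solve_constrained(K, *_constraints(mesh, cfg, d))
            head_R = _patch_reaction(K, u, mesh.node_sets["head"])
            last_reactions = {
                "head": head_R,
                "trochanter": _patch_reaction(K, u, mesh.node_sets["trochanter"]),
                "hinge": _patch_reaction(K, u, mesh.node_sets["hinge"]),
            }
            forces.append(float(np.linalg.norm(head_R)))
            yield_fracs.append(float(np.mean(scale < 1 - 1e-9)))
        else:
            log.warning("increment at %.3f mm did not converge; keeping last state", d)
            forces.append(forces[-1])
            yield_fracs.append(yield_fracs[-1] if yield_fracs else 0.0)
        conv_flags.append(converged)

    if n_ok == 0:
        raise RuntimeError("no increment converged; solver failed")
    force = np.array(forces)
    res = StrengthResult(
        displacement=np.concatenate([[0.0], disps]),
        head_force=force,
        femoral_strength=float(force.max() / 1000.0),
        converged=np.array(conv_flags),
        yield_fraction=np.array(yield_fracs),
        reactions=last_reactions,
    )
    res.validate()
    return res


def strength_vs_density(spec, scales, cal, cfg: FallConfig,
                        target_edge: float = 6.0, seed: int | None = None):
    """Run the phantom -> materials -> strength chain at density scales.

    Returns a DataFrame with columns (scale, abmd, strength_kN); strength
    is nondecreasing in scale for monotone materials.
    """
    import pandas as pd

    from .materials import map_to_elements
    from .mesh import mesh_from_volume
    from .phantom import generate_femur_phantom, project_abmd

    rows = []
    base = generate_femur_phantom(spec, seed=seed)
    for k in scales:
        if k <= 0:
            raise ValueError("density scale must be > 0")
        vol = base.copy()
        vol.values = vol.values * k
        abmd = project_abmd(vol, direction="y")
        mesh = mesh_from_volume(vol, target_edge=target_edge)
        mat = map_to_elements(vol, mesh, cal)
        posed = pose_femur(mesh, cfg)
        assign_contact_sets(posed, cfg)
        result = solve_strength(posed, mat, cfg)
        rows.append({"scale": float(k), "abmd": abmd,
                     "strength_kN": result.femoral_strength})
    return pd.DataFrame(rows)
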