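"""Tetrahedral meshes for the femoral-strength model.

Meshes are generated internally: a structured lattice over the density
volume is split into tetrahedra (Kuhn/Freudenthal 6-tet subdivision of
each hexahedral cell, which is conforming on a structured grid), and a
box mesher provides verification geometries (patch tests, columns).
Linear 4-node tetrahedra are the default; 10-node quadratic elements are
derived by edge-midpoint insertion.

Conventions: 0-based node/element indices, world coordinates in mm,
positive element volumes (orientation fixed at construction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .phantom import DensityVolume

#: VTK edge ordering of the quadratic tetrahedron's midside nodes.
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


@dataclass
class TetMesh:
    """Tetrahedral mesh with contact node sets and anatomical landmarks.

    ``elements`` is (E, 4) for linear or (E, 10) for quadratic
    tetrahedra; ``node_sets`` maps set names ("head", "trochanter",
    "hinge") to node-index arrays; ``landmarks`` mirrors the source
    volume's anatomical points.
    """

    nodes: np.ndarray
    elements: np.ndarray
    node_sets: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)
    target_edge: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def order(self) -> int:
        return 1 if self.elements.shape[1] == 4 else 2

    def corner_coords(self) -> np.ndarray:
        """(E, 4, 3) coordinates of the corner nodes."""
        return self.nodes[self.elements[:, :4]]

    def volumes(self) -> np.ndarray:
        x = self.corner_coords()
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0

    def centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)

    def validate(self) -> None:
        if self.elements.shape[1] not in (4, 10):
            raise ValueError("elements must be 4- or 10-node tetrahedra")
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= self.n_nodes:
            raise ValueError("element node index out of range")
        vols = self.volumes()
        bad = np.flatnonzero(vols <= 1e-12)
        if bad.size:
            raise ValueError(f"degenerate (non-positive volume) elements: {bad[:5].tolist()}")
        sets = [frozenset(np.asarray(v).tolist()) for v in self.node_sets.values()]
        for a, b in itertools.combinations(range(len(sets)), 2):
            if sets[a] & sets[b]:
                raise ValueError("contact node sets must be disjoint")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "TetMesh":
        """Rigidly transform nodes and landmarks: p -> R p + t."""
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        lm = {}
        for k, v in self.landmarks.items():
            if isinstance(v, tuple):
                lm[k] = (R @ np.asarray(v[0]) + t, R @ np.asarray(v[1]))
            else:
                lm[k] = R @ np.asarray(v) + t
        return TetMesh(self.nodes @ R.T + t, self.elements.copy(),
                       {k: np.array(v) for k, v in self.node_sets.items()},
                       lm, self.target_edge)


def _kuhn_tets() -> np.ndarray:
    """Six tetrahedra splitting the unit cube, all sharing the main
    diagonal; corner index = 4*dx + 2*dy + dz."""
    def cidx(d):
        return 4 * d[0] + 2 * d[1] + d[2]

    eye = np.eye(3, dtype=int)
    tets = []
    for perm in itertools.permutations(range(3)):
        v0 = np.zeros(3, dtype=int)
        v1 = v0 + eye[perm[0]]
        v2 = v1 + eye[perm[1]]
        v3 = np.ones(3, dtype=int)
        tet = [cidx(v) for v in (v0, v1, v2, v3)]
        # odd permutations produce negative orientation; swap to fix
        parity = (np.array(perm) == (0, 1, 2)).all() or perm in ((1, 2, 0), (2, 0, 1))
        if not parity:
            tet[2], tet[1] = tet[1], tet[2]
        tets.append(tet)
    return np.array(tets)


_KUHN = _kuhn_tets()


def _lattice_mesh(cell_ijk: np.ndarray, spacing: np.ndarray, origin: np.ndarray) -> TetMesh:
    """Mesh a set of lattice cells (integer (i,j,k) of their low corner)."""
    if len(cell_ijk) == 0:
        raise ValueError("no cells to mesh")
    offs = np.array([[dx, dy, dz] for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)])
    corners = cell_ijk[:, None, :] + offs[None, :, :]          # (C, 8, 3)
    flat = corners.reshape(-1, 3)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    conn8 = inv.reshape(len(cell_ijk), 8)
    elements = conn8[:, _KUHN].reshape(-1, 4)
    nodes = origin + uniq * spacing
    return TetMesh(nodes.astype(float), elements)


def box_mesh(lengths, divisions, origin=(0.0, 0.0, 0.0)) -> TetMesh:
    """Structured tet mesh of a box (lengths mm, divisions per axis)."""
    lengths = np.asarray(lengths, float)
    divisions = np.asarray(divisions, int)
    if np.any(divisions < 1) or np.any(lengths <= 0):
        raise ValueError("need positive lengths and >= 1 division per axis")
    cells = np.array(list(itertools.product(*[range(n) for n in divisions])))
    mesh = _lattice_mesh(cells, lengths / divisions, np.asarray(origin, float))
    mesh.validate()
    return mesh


def mesh_from_volume(vol: DensityVolume, target_edge: float = 6.0,
                     density_threshold: float = 1e-6) -> TetMesh:
    """Mesh the bone region of a density volume at ~``target_edge`` mm.

    Voxels are coarsened by an integer factor to approach the target
    edge length; a lattice cell becomes bone if the density interpolated
    at its centre exceeds ``density_threshold``.  Landmarks are copied
    from the volume; contact node sets are assigned after posing.
    """
    from scipy.interpolate import RegularGridInterpolator

    vol.validate()
    if target_edge <= 0:
        raise ValueError("target_edge must be > 0")
    h = float(np.asarray(vol.spacing).min())
    factor = max(1, int(round(target_edge / h)))
    cell = np.asarray(vol.spacing, float) * factor
    shape = np.asarray(vol.values.shape)
    n_cells = np.maximum((shape - 1) // factor, 1)

    interp = RegularGridInterpolator(vol.world_coords(), vol.values,
                                     bounds_error=False, fill_value=0.0)
    ijk = np.array(list(itertools.product(*[range(n) for n in n_cells])))
    centers = np.asarray(vol.origin) + (ijk + 0.5) * cell
    dens = interp(centers)
    bone = ijk[dens > density_threshold]
    if len(bone) == 0:
        raise ValueError("no bone cells found at this threshold")
    mesh = _lattice_mesh(bone, cell, np.asarray(vol.origin, float))
    mesh.landmarks = dict(vol.landmarks)
    mesh.target_edge = float(target_edge)
    mesh.validate()
    return mesh


def to_quadratic(mesh: TetMesh) -> TetMesh:
    """Convert a linear mesh to 10-node tetrahedra by edge-midpoint
    insertion (VTK midside ordering)."""
    if mesh.order != 1:
        raise ValueError("mesh is already quadratic")
    conn = mesh.elements
    edges = np.concatenate([np.sort(conn[:, e], axis=1) for e in TET10_EDGES], axis=0)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid_nodes = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    mid_idx = mesh.n_nodes + inv.reshape(len(TET10_EDGES), -1).T  # (E, 6)
    elements = np.concatenate([conn, mid_idx], axis=1)
    out = TetMesh(np.vstack([mesh.nodes, mid_nodes]), elements,
                  {k: np.array(v) for k, v in mesh.node_sets.items()},
                  dict(mesh.landmarks), mesh.target_edge)
    out.validate()
    return out


def surface_nodes(mesh: TetMesh) -> np.ndarray:
    """Indices of nodes on the mesh boundary (faces used once)."""
    conn = mesh.elements[:, :4]
    faces = np.concatenate([conn[:, f] for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))])
    faces = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])
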