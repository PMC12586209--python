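"""Parametric proximal-femur density phantoms.

A phantom stands in for the 3D reconstruction a DXA-based shape model
would provide: a head sphere, an angled neck cylinder and a shaft
cylinder, each with a cortical shell around a trabecular interior,
voxelised onto an axis-aligned grid of K2HPO4-equivalent mineral density
(g/cm^3).  An areal projection links the phantom to a requested total-hip
aBMD.  No attempt is made to mimic real DXA image appearance or
statistical shape variation.

Geometry frame: the shaft axis runs along +z from the distal cut plane at
z = 0; +x points medially (the neck and head extend towards +x); the
greater-trochanter landmark sits on the lateral shaft surface at the
proximal end.  All geometry is in mm, densities in g/cm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class FemurPhantomSpec:
    """Parametric phantom description (lengths/radii mm, densities g/cm^3)."""

    head_radius: float = 22.0
    neck_radius: float = 14.0
    neck_length: float = 45.0
    neck_shaft_angle: float = 125.0
    shaft_radius: float = 15.0
    shaft_length: float = 70.0
    cortical_thickness: float = 3.0
    cortical_density: float = 0.9
    trabecular_density: float = 0.25
    voxel_spacing: float = 2.0
    target_abmd: float | None = None
    noise_sd: float = 0.0  # smooth multiplicative noise amplitude

    def validate(self) -> None:
        for name in ("head_radius", "neck_radius", "neck_length", "shaft_radius",
                     "shaft_length", "voxel_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.trabecular_density <= self.cortical_density:
            raise ValueError("need cortical_density >= trabecular_density >= 0")
        if self.cortical_thickness < 0 or self.noise_sd < 0:
            raise ValueError("cortical_thickness and noise_sd must be >= 0")


@dataclass
class DensityVolume:
    """Axis-aligned voxel grid of mineral-equivalent density.

    ``values[i, j, k]`` lives at world position ``origin + (i, j, k) *
    spacing`` (mm); ``landmarks`` holds anatomical points in world mm
    (head_center, neck_axis, shaft_axis, greater_trochanter,
    distal_end).  Axis entries are (point, unit direction) pairs.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    landmarks: dict = field(default_factory=dict)

    def validate(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or min(v.shape) < 2:
            raise ValueError("values must be a 3D grid with >= 2 voxels per axis")
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("densities must be finite and >= 0")
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("spacing must be > 0")

    def world_coords(self):
        """Per-axis world coordinates of voxel centres (mm)."""
        return [self.origin[a] + self.spacing[a] * np.arange(self.values.shape[a])
                for a in range(3)]

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.values.copy(), np.array(self.spacing, float),
                             np.array(self.origin, float), dict(self.landmarks))


def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment a-b."""
    d = b - a
    t = np.clip((pts - a) @ d / (d @ d), 0.0, 1.0)
    proj = a + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=1)


def generate_femur_phantom(spec: FemurPhantomSpec, seed: int | None = None) -> DensityVolume:
    """Voxelise the parametric phantom into a :class:`DensityVolume`.

    The union of head sphere, neck cylinder and shaft cylinder is filled
    with ``trabecular_density``; voxels within ``cortical_thickness`` of
    the outer surface get ``cortical_density``; background is 0.  If
    ``target_abmd`` is set, the whole field is rescaled so the simulated
    anterior-posterior areal projection matches it.
    """
    spec.validate()
    h = spec.voxel_spacing
    if h > spec.cortical_thickness > 0:
        warnings.warn("voxel spacing exceeds cortical thickness; the shell is unresolvable",
                      stacklevel=2)

    theta = np.deg2rad(180.0 - spec.neck_shaft_angle)
    neck_dir = np.array([np.sin(theta), 0.0, np.cos(theta)])
    shaft_top = np.array([0.0, 0.0, spec.shaft_length])
    head_center = shaft_top + spec.neck_length * neck_dir

    lo = np.minimum(head_center - spec.head_radius,
                    [-spec.shaft_radius, -max(spec.shaft_radius, spec.neck_radius,
                                              spec.head_radius), 0.0]) - 2 * h
    hi = np.maximum(head_center + spec.head_radius,
                    [spec.shaft_radius, max(spec.shaft_radius, spec.neck_radius,
                                            spec.head_radius), spec.shaft_length]) + 2 * h
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    origin = lo

    ax = [origin[a] + h * np.arange(shape[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    in_head = np.linalg.norm(pts - head_center, axis=1) <= spec.head_radius
    in_neck = _segment_distance(pts, shaft_top, head_center) <= spec.neck_radius
    in_shaft = _segment_distance(pts, np.zeros(3), shaft_top) <= spec.shaft_radius
    inside = (in_head | in_neck | in_shaft).reshape(shape)

    n_comp = ndimage.label(inside)[1]
    if n_comp != 1:
        raise ValueError(f"phantom primitives do not form one connected body "
                         f"({n_comp} components)")

    values = np.zeros(shape)
    values[inside] = spec.trabecular_density
    if spec.cortical_thickness > 0 and spec.cortical_density > 0:
        # distance (mm) from each inside voxel to the nearest outside voxel
        dist_in = ndimage.distance_transform_edt(inside, sampling=(h, h, h))
        shell = inside & (dist_in <= spec.cortical_thickness)
        values[shell] = spec.cortical_density

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        noise /= max(noise.std(), 1e-12)
        values[inside] *= np.clip(1.0 + spec.noise_sd * noise[inside], 0.0, None)

    vol = DensityVolume(
        values=values, spacing=np.array([h, h, h]), origin=np.asarray(origin, float),
        landmarks={
            "head_center": head_center,
            "neck_axis": (shaft_top, neck_dir),
            "shaft_axis": (np.zeros(3), np.array([0.0, 0.0, 1.0])),
            "greater_trochanter": np.array([-spec.shaft_radius, 0.0, spec.shaft_length]),
            "distal_end": np.array([0.0, 0.0, 0.0]),
        })
    if spec.target_abmd is not None:
        current = project_abmd(vol, direction="y")
        vol.values *= spec.target_abmd / current
    return vol


_AXES = {"x": 0, "y": 1, "z": 2}


def project_abmd(vol: DensityVolume, direction: str | int = "y") -> float:
    """Mean areal density (g/cm^2) of the projected bone footprint.

    Line-integrates the volumetric density along ``direction`` and
    averages over pixels whose ray crosses any bone; linear in density
    and independent of grid translation.
    """
    vol.validate()
    axis = _AXES.get(direction, direction)
    if axis not in (0, 1, 2):
        raise ValueError(f"unknown projection direction {direction!r}")
    thickness_cm = vol.spacing[axis] / 10.0
    areal = vol.values.sum(axis=axis) * thickness_cm
    footprint = (vol.values > 0).any(axis=axis)
    if not footprint.any():
        raise ValueError("projection undefined: volume contains no bone")
    return float(areal[footprint].mean())
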