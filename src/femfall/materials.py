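"""Density-to-material mapping.

Converts calibrated K2HPO4-equivalent mineral density to elastic and
yield properties through the chain

    rho_ash = ash_slope * rho_K2HPO4 + ash_intercept      [g/cm^3]
    rho_app = rho_ash / ash_fraction                      [g/cm^3]
    E       = modulus_coeff * rho_app ** modulus_exponent [MPa]

and maps the result onto mesh elements, after an optional surface
partial-volume correction.  All calibration constants are configurable;
the defaults are widely used literature values for this chain (a
trabecular-bone power law validated across the full density range), not
values verified against any single scanner.

Yield is bilinear with tension-compression asymmetry: the tensile yield
stress is E * yield_strain * rate_factor, the compressive one is larger
by a fixed ratio.  Strain-rate sensitivity of the fall loading survives
only as the static ``rate_factor`` multiplier (the solver is
quasi-static and carries no rate state).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mesh import TetMesh
from .phantom import DensityVolume

log = logging.getLogger(__name__)


@dataclass
class CalibrationParams:
    """Constants of the density-to-modulus chain (see module docstring)."""

    ash_slope: float = 0.877
    ash_intercept: float = 0.0789     # g/cm^3
    ash_fraction: float = 0.6
    modulus_coeff: float = 6850.0     # MPa at rho_app = 1 g/cm^3
    modulus_exponent: float = 1.49
    poisson_ratio: float = 0.3
    yield_strain: float = 0.0085
    rate_factor: float = 1.0
    compression_tension_ratio: float = 1.2

    def validate(self) -> None:
        if self.ash_slope <= 0:
            raise ValueError("ash_slope must be > 0")
        if not 0 < self.ash_fraction <= 1:
            raise ValueError("ash_fraction must be in (0, 1]")
        if self.modulus_coeff <= 0 or self.modulus_exponent <= 0:
            raise ValueError("modulus power law requires positive coefficient and exponent")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.yield_strain <= 0:
            raise ValueError("yield_strain must be > 0")
        if self.rate_factor < 1 or self.compression_tension_ratio < 1:
            raise ValueError("rate_factor and compression_tension_ratio must be >= 1")


@dataclass
class MaterialField:
    """Per-element material arrays (MPa, g/cm^3)."""

    young_modulus: np.ndarray
    yield_stress_tension: np.ndarray
    yield_stress_compression: np.ndarray
    density_app: np.ndarray
    poisson_ratio: float = 0.3

    def validate(self) -> None:
        for name in ("young_modulus", "yield_stress_tension",
                     "yield_stress_compression", "density_app"):
            arr = getattr(self, name)
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"{name} must be >= 0")
        if np.any(self.yield_stress_compression < self.yield_stress_tension - 1e-12):
            raise ValueError("compressive yield must be >= tensile yield")

    @classmethod
    def uniform(cls, n: int, E: float, yield_t: float = np.inf,
                yield_c: float | None = None, nu: float = 0.3) -> "MaterialField":
        if yield_c is None:
            yield_c = yield_t
        one = np.ones(n)
        return cls(E * one, yield_t * one, yield_c * one, one, nu)


def density_to_modulus(rho_k2hpo4, cal: CalibrationParams):
    """Apply the calibration chain; returns (rho_ash, rho_app, E).

    Negative intermediate densities are clamped to zero before the power
    law (a contract, not an error); the map is monotone nondecreasing.
    """
    cal.validate()
    rho = np.asarray(rho_k2hpo4, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("density must be finite")
    rho_ash = np.clip(cal.ash_slope * rho + cal.ash_intercept, 0.0, None)
    rho_app = np.clip(rho_ash / cal.ash_fraction, 0.0, None)
    E = cal.modulus_coeff * rho_app**cal.modulus_exponent
    if np.ndim(rho_k2hpo4) == 0:
        return float(rho_ash), float(rho_app), float(E)
    return rho_ash, rho_app, E


def correct_partial_volume(vol: DensityVolume, bone_mask: np.ndarray | None = None,
                           depth: int = 1) -> DensityVolume:
    """Replace surface-layer voxel values by nearest interior values.

    Voxels within ``depth`` voxels of the bone boundary inherit the
    density of the nearest voxel deeper than ``depth`` (an inward-normal
    propagation), undoing the artificially low densities of voxels that
    straddle the bone surface.  Interior voxels are untouched;
    ``depth=0`` is the identity.
    """
    vol.validate()
    if depth < 0:
        raise ValueError("depth must be >= 0")
    out = vol.copy()
    if depth == 0:
        return out
    mask = (vol.values > 0) if bone_mask is None else np.asarray(bone_mask, bool)
    if mask.shape != vol.values.shape:
        raise ValueError("bone mask shape mismatch")
    if not mask.any():
        raise ValueError("empty bone mask")
    dist = ndimage.distance_transform_edt(mask)   # voxel units
    interior = dist > depth
    if not interior.any():
        raise ValueError("partial-volume correction impossible: "
                         f"bone is nowhere thicker than 2x depth={depth}")
    # nearest interior voxel for every position
    _, idx = ndimage.distance_transform_edt(~interior, return_indices=True)
    surface = mask & ~interior
    src = tuple(ind[surface] for ind in idx)
    out.values[surface] = vol.values[src]
    return out


def map_to_elements(vol: DensityVolume, mesh: TetMesh, cal: CalibrationParams,
                    sampling: str = "centroid") -> MaterialField:
    """Interpolate density onto mesh elements and convert to materials.

    Density is trilinearly interpolated at each element's centroid (or
    averaged over its 4 interior quadrature points with
    ``sampling="gauss"``), then pushed through
    :func:`density_to_modulus`.  Elements outside the volume get density
    0 (counted and logged).
    """
    from scipy.interpolate import RegularGridInterpolator

    vol.validate()
    mesh.validate()
    cal.validate()
    interp = RegularGridInterpolator(vol.world_coords(), vol.values,
                                     bounds_error=False, fill_value=np.nan)
    corners = mesh.corner_coords()
    if sampling == "centroid":
        pts = corners.mean(axis=1)[:, None, :]
    elif sampling == "gauss":
        a, b = 0.5854101966249685, 0.13819660112501052
        bary = np.full((4, 4), b)
        np.fill_diagonal(bary, a)
        pts = np.einsum("qi,eic->eqc", bary, corners)
    else:
        raise ValueError("sampling must be 'centroid' or 'gauss'")
    dens = interp(pts.reshape(-1, 3)).reshape(pts.shape[:2])
    outside = np.isnan(dens)
    if outside.any():
        log.warning("%d element sample points lie outside the volume; density 0 assigned",
                    int(outside.sum()))
        dens = np.nan_to_num(dens, nan=0.0)
    rho_elem = np.clip(dens.mean(axis=1), 0.0, None)
    _, rho_app, E = density_to_modulus(rho_elem, cal)
    fully_outside = outside.all(axis=1)
    if fully_outside.any():   # no bone at all: zero material, not intercept-floor
        rho_app = np.where(fully_outside, 0.0, rho_app)
        E = np.where(fully_outside, 0.0, E)
    yield_t = E * cal.yield_strain * cal.rate_factor
    yield_c = yield_t * cal.compression_tension_ratio
    field = MaterialField(E, yield_t, yield_c, rho_app, cal.poisson_ratio)
    field.validate()
    return field
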