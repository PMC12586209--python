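"""Trochanteric soft tissue thickness (TSTT).

TSTT is the lateral soft-tissue layer over the greater trochanter that
attenuates the impact of a sideways fall.  Supine TSTT is measured on a
whole-body DXA-like planar image; standing TSTT is predicted from the
supine value with sex- and ethnicity-specific linear coefficients:

    TSTT_standing = slope * TSTT_supine + intercept   [cm]

The coefficients ship as an editable table.  The planar measurement here
is a deliberately simple two-threshold edge walk validated only on
phantoms; the clinical image-processing pipeline it stands in for is not
reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Default (slope, intercept-cm) per (sex, ethnicity) for the
#: supine-to-standing conversion.
DEFAULT_COEFFICIENTS = {
    ("male", "Chinese"): (0.63, 3.12),
    ("female", "Chinese"): (0.59, 2.29),
    ("male", "Indian"): (0.54, 10.54),
    ("female", "Indian"): (0.51, 12.26),
    ("male", "Malay"): (0.53, 8.94),
    ("female", "Malay"): (0.62, 6.23),
}


@dataclass
class TSTTCoefficients:
    """Per-(sex, ethnicity) slope (dimensionless) and intercept (cm)."""

    table: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))

    def validate(self) -> None:
        for key in DEFAULT_COEFFICIENTS:
            if key not in self.table:
                raise ValueError(f"missing coefficient cell {key}")
        for (sex, eth), (slope, _) in self.table.items():
            if slope <= 0:
                raise ValueError(f"slope must be > 0 for ({sex}, {eth})")

    def lookup(self, sex: str, ethnicity: str) -> tuple[float, float]:
        try:
            return self.table[(sex, ethnicity)]
        except KeyError:
            raise KeyError(f"no TSTT coefficients for ({sex!r}, {ethnicity!r}); "
                           "no pooled fallback is applied") from None


def standing_tstt(tstt_sup: float, sex: str, ethnicity: str,
                  coeffs: TSTTCoefficients | None = None) -> float:
    """Predict standing TSTT (cm) from supine TSTT (cm)."""
    if coeffs is None:
        coeffs = TSTTCoefficients()
    if tstt_sup < 0:
        raise ValueError("tstt_sup must be >= 0")
    if tstt_sup > 10.0:
        log.warning("tstt_sup %.2f cm lies outside the 0-10 cm range the "
                    "conversion was fitted on", tstt_sup)
    slope, intercept = coeffs.lookup(sex, ethnicity)
    return slope * tstt_sup + intercept


def add_standing_tstt(records, coeffs: TSTTCoefficients | None = None):
    """Fill ``tstt_standing`` on a list of SubjectRecord in place."""
    for r in records:
        r.tstt_standing = standing_tstt(r.tstt_sup, r.sex, r.ethnicity, coeffs)
    return records


@dataclass
class DXAPlanarImage:
    """Areal-density-like 2D image (rows x columns), spacing in mm."""

    values: np.ndarray
    pixel_spacing: float
    trochanter_row: int | None = None

    def validate(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("planar image must be 2D")
        if v.min() < 0:
            raise ValueError("pixel values must be >= 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")


def measure_tstt_sup(img: DXAPlanarImage, side: str = "left",
                     body_threshold: float = 0.05,
                     bone_threshold: float = 0.5,
                     hip_band: tuple[int, int] | None = None) -> float:
    """Supine TSTT (cm) from a planar image by a two-threshold edge walk.

    At the greater-trochanter row (given, or detected as the row with
    the widest bone extent within ``hip_band``), the result is the
    lateral distance from the outer bone edge to the skin edge on the
    requested ``side``.  Thresholds separate "body" (soft tissue and
    above) from "bone".
    """
    img.validate()
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    vals = np.asarray(img.values, dtype=float)
    bone = vals >= bone_threshold
    body = vals >= body_threshold

    if hip_band is not None:
        lo, hi = hip_band
    else:
        lo, hi = 0, vals.shape[0]
    band_bone = bone[lo:hi]
    if not band_bone.any():
        raise ValueError("no bone pixels in the hip band")

    if img.trochanter_row is not None:
        row = img.trochanter_row
        if not bone[row].any():
            raise ValueError("no bone pixels at the given trochanter row")
    else:
        widths = band_bone.sum(axis=1)
        row = lo + int(np.argmax(widths))

    bone_cols = np.flatnonzero(bone[row])
    body_cols = np.flatnonzero(body[row])
    if side == "left":
        bone_edge = bone_cols.min()
        skin_edge = body_cols.min()
        thickness_px = bone_edge - skin_edge
    else:
        bone_edge = bone_cols.max()
        skin_edge = body_cols.max()
        thickness_px = skin_edge - bone_edge
    if thickness_px < 0:
        raise ValueError("skin edge lies medial to the bone edge (negative thickness)")
    return thickness_px * img.pixel_spacing / 10.0
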