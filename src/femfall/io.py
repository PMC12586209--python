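"""File formats: cohort CSV, legacy ASCII VTK, NIfTI volumes, configs.

CSV dialect is fixed (comma separator, "." decimal, UTF-8, mandatory
header); unknown columns are preserved as passthrough.  Meshes and
result fields are written as legacy ASCII VTK unstructured grids (chosen
over XML for diffability).  Density volumes round-trip through NIfTI
with a JSON landmark sidecar.  Configs are YAML with a JSON fallback.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ETHNICITIES, SEXES, SubjectRecord, cohort_to_frame, frame_to_cohort
from .phantom import DensityVolume

MANDATORY_COLUMNS = ("id", "age", "sex", "ethnicity", "weight", "height",
                     "abmd", "t_score", "frax_hfp", "tstt_sup")

_ETH_NORMALIZE = {e.lower(): e for e in ETHNICITIES}
_SEX_NORMALIZE = {s.lower(): s for s in SEXES}
_SEX_NORMALIZE.update({"m": "male", "f": "female"})


def write_cohort(records, path) -> None:
    """Write a cohort (records or DataFrame) as CSV."""
    df = records if isinstance(records, pd.DataFrame) else cohort_to_frame(records)
    df.to_csv(path, index=False, encoding="utf-8")


def read_cohort_frame(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; normalises sex/ethnicity spelling.

    Unknown columns are kept; a missing mandatory column raises a schema
    error naming it; unrecognised category values raise row-level errors.
    """
    df = pd.read_csv(path, encoding="utf-8")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort schema error: missing mandatory column {col!r}")
    for col, table in (("sex", _SEX_NORMALIZE), ("ethnicity", _ETH_NORMALIZE)):
        raw = df[col].astype(str)
        canon = raw.str.strip().str.lower().map(table)
        bad = canon.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"unparseable {col} value {raw.iloc[row]!r} "
                             f"at data line {row + 2}")
        changed = (canon != raw).sum()
        if changed:
            warnings.warn(f"normalised {changed} {col} values to canonical spelling")
        df[col] = canon
    for col in ("age", "weight", "height", "abmd", "t_score", "frax_hfp", "tstt_sup"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as e:
            raise ValueError(f"unparseable numeric cell in column {col!r}: {e}") from None
    if "bmi" not in df.columns:
        df["bmi"] = df["weight"] / (df["height"] / 100.0) ** 2
    return df


def read_cohort(path) -> list[SubjectRecord]:
    return frame_to_cohort(read_cohort_frame(path))


# ------------------------------------------------------------- legacy VTK

_VTK_CELL_TYPE = {4: 10, 10: 24}


def write_vtk(path, nodes, elements, point_data: dict | None = None,
              cell_data: dict | None = None, title: str = "femfall mesh") -> None:
    """Write a tetrahedral mesh as a legacy ASCII VTK unstructured grid.

    ``point_data``/``cell_data`` map names to scalar (N,) or vector
    (N, 3) arrays.
    """
    nodes = np.asarray(nodes, float)
    elements = np.asarray(elements, int)
    ctype = _VTK_CELL_TYPE[elements.shape[1]]
    lines = ["# vtk DataFile Version 2.0", title, "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(nodes)} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in nodes]
    nper = elements.shape[1]
    lines.append(f"CELLS {len(elements)} {len(elements) * (nper + 1)}")
    lines += [f"{nper} " + " ".join(map(str, e)) for e in elements]
    lines.append(f"CELL_TYPES {len(elements)}")
    lines += [str(ctype)] * len(elements)

    def emit(block: dict, kind: str, count: int):
        lines.append(f"{kind} {count}")
        for name, arr in block.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)

    if point_data:
        emit(point_data, "POINT_DATA", len(nodes))
    if cell_data:
        emit(cell_data, "CELL_DATA", len(elements))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vtk(path):
    """Minimal legacy-VTK reader (round-trip checks): nodes, elements."""
    tokens = Path(path).read_text(encoding="utf-8").split()
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3:i + 3 + 3 * n], float).reshape(n, 3)
    j = tokens.index("CELLS")
    ncell = int(tokens[j + 1])
    total = int(tokens[j + 2])
    flat = np.array(tokens[j + 3:j + 3 + total], int)
    nper = flat[0]
    cells = flat.reshape(ncell, nper + 1)[:, 1:]
    return pts, cells


# ------------------------------------------------------------- volumes

def save_density_volume(vol: DensityVolume, path) -> None:
    """Save as NIfTI (.nii) plus a JSON landmark sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([*np.asarray(vol.spacing, float), 1.0])
    affine[:3, 3] = np.asarray(vol.origin, float)
    nib.save(nib.Nifti1Image(np.asarray(vol.values, np.float32), affine), str(path))
    side = {}
    for k, v in vol.landmarks.items():
        if isinstance(v, tuple):
            side[k] = {"point": np.asarray(v[0]).tolist(),
                       "direction": np.asarray(v[1]).tolist()}
        else:
            side[k] = np.asarray(v).tolist()
    path.with_suffix(path.suffix + ".landmarks.json").write_text(
        json.dumps(side, indent=1), encoding="utf-8")


def load_density_volume(path) -> DensityVolume:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    affine = img.affine
    vol = DensityVolume(values=np.asarray(img.get_fdata(), float),
                        spacing=np.diag(affine)[:3].copy(),
                        origin=affine[:3, 3].copy())
    sidecar = path.with_suffix(path.suffix + ".landmarks.json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text(encoding="utf-8"))
        lm = {}
        for k, v in raw.items():
            if isinstance(v, dict):
                lm[k] = (np.array(v["point"]), np.array(v["direction"]))
            else:
                lm[k] = np.array(v)
        vol.landmarks = lm
    return vol


# ------------------------------------------------------------- configs

def load_config(path) -> dict:
    """Load a YAML config (JSON is valid YAML, so both parse)."""
    import yaml

    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data
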