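"""Reading and writing 2-D fields as NIfTI-1 or CSV, with JSON metadata.

NIfTI voxel sizes are stored in millimeters per the format convention and
converted back to meters on read.  CSV files hold one image row per line;
a JSON sidecar (``<name>.json``) carries the grid spacing and any extra
metadata so that CSV round trips preserve geometry too.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import Grid

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_csv",
    "read_csv",
    "write_json",
    "read_json",
]


def write_nifti(path, values: np.ndarray, grid: Grid, meta: dict | None = None):
    path = Path(path)
    affine = np.diag([grid.pixel_size * 1e3, grid.pixel_size * 1e3, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    img.header.set_zooms((grid.pixel_size * 1e3, grid.pixel_size * 1e3))
    nib.save(img, str(path))
    if meta is not None:
        write_json(path.with_suffix("").with_suffix(".json"), meta)


def read_nifti(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {values.shape}")
    zoom_mm = img.header.get_zooms()[0]
    grid = Grid(values.shape[0], values.shape[1], float(zoom_mm) * 1e-3)
    return values, grid


def write_csv(path, values: np.ndarray, grid: Grid | None = None,
              meta: dict | None = None):
    path = Path(path)
    np.savetxt(path, np.asarray(values, dtype=np.float64), delimiter=",",
               fmt="%.17g")
    sidecar = dict(meta or {})
    if grid is not None:
        sidecar["pixel_size_m"] = grid.pixel_size
    if sidecar:
        write_json(path.with_suffix(".json"), sidecar)


def read_csv(path, pixel_size: float | None = None) -> tuple[np.ndarray, Grid | None]:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                row = [float(tok) for tok in line.split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}, line {ln}: {exc}") from None
            if rows and len(row) != len(rows[0]):
                raise ValueError(
                    f"{path}, line {ln}: expected {len(rows[0])} values, "
                    f"got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty CSV image")
    values = np.asarray(rows, dtype=np.float64)
    if pixel_size is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            pixel_size = read_json(sidecar).get("pixel_size_m")
    grid = None
    if pixel_size is not None:
        grid = Grid(values.shape[0], values.shape[1], float(pixel_size))
    return values, grid


def write_json(path, obj: dict):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
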