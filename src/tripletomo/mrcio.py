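"""MRC2014 volume I/O.

Maps are written as mode-2 (float32) MRC/CCP4 with the voxel size recorded
in the header via the unit cell.  Reading accepts modes 0/1/2 and returns
the data with the voxel size in nm.
"""

from __future__ import annotations

import os
from typing import Tuple

import numpy as np
import gemmi

__all__ = ["read_mrc", "write_mrc", "MRCFormatError"]


class MRCFormatError(ValueError):
    """Malformed or unreadable MRC file."""


def write_mrc(path, data: np.ndarray, voxel_nm: float) -> None:
    """Write a 3D volume as mode-2 MRC2014 with the given voxel size (nm)."""
    if data.ndim != 3:
        raise MRCFormatError("only 3D volumes are supported")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data, dtype=np.float32))
    nz, ny, nx = data.shape
    a = voxel_nm * 10.0  # Å
    m.grid.unit_cell = gemmi.UnitCell(nz * a, ny * a, nx * a, 90, 90, 90)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> Tuple[np.ndarray, float]:
    """Read an MRC2014 map; returns (data, voxel_nm)."""
    if not os.path.exists(path):
        raise MRCFormatError(f"no such file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MRCFormatError(f"cannot parse MRC file {path}: {exc}") from exc
    data = np.array(m.grid, copy=True)
    n0 = m.grid.shape[0] if hasattr(m.grid, "shape") else data.shape[0]
    voxel_nm = m.grid.unit_cell.a / max(data.shape[0], 1) / 10.0
    return data, float(voxel_nm)
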