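"""Volume and table I/O.

Volumes go through NIfTI (nibabel) with the voxel size carried in the
header zooms; tables are UTF-8 CSV with '.' decimal and a header row.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["read_volume", "write_volume", "read_table", "write_table"]


def write_volume(path, data: np.ndarray, spacing_mm) -> None:
    """Write a 3D array as NIfTI with mm spacing on the diagonal affine."""
    path = Path(path)
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"invalid spacing for {path.name}: {spacing_mm}")
    affine = np.diag(spacing + (1.0,))
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI volume; returns (data, spacing_mm).

    Raises if the file carries no positive voxel spacing.
    """
    path = Path(path)
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path.name}: missing or invalid voxel spacing metadata {zooms}")
    data = np.asanyarray(img.dataobj)
    return data, zooms


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read a CSV table; malformed rows raise with the offending line number."""
    path = Path(path)
    try:
        return pd.read_csv(path, encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path.name}: malformed CSV ({exc})") from exc
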