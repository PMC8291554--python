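"""Reading and writing the on-disk formats used by the pipeline.

Columns travel as OME-TIFF frame stacks with a ``geometry.json`` sidecar
per column (every acquisition parameter needed to deskew them later);
fused slices as (Big)TIFF; cell and activation tables as plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import AcquisitionGeometry
from .stitching import ImageColumn

__all__ = [
    "write_column",
    "read_column",
    "write_volume",
    "read_volume",
    "write_cell_table",
    "read_cell_table",
    "read_activation_table",
    "write_activation_table",
]

CELL_COLUMNS = ["id", "x_um", "y_um", "z_um", "volume_um3", "eccentricity",
                "intensity", "channel", "n_sections", "valid"]


def write_column(col: ImageColumn, directory: str | Path) -> Path:
    """Write one column as OME-TIFF plus its geometry sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / f"column_{col.column_id:04d}"
    tifffile.imwrite(stem.with_suffix(".ome.tif"), col.frames,
                     metadata={"axes": "ZYX"})
    col.geometry.to_json(stem.with_suffix(".geometry.json"))
    return stem.with_suffix(".ome.tif")


def read_column(path: str | Path, column_id: int | None = None) -> ImageColumn:
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = path.with_suffix("").with_suffix(".geometry.json")
    if not sidecar.exists():  # column_0000.ome.tif → column_0000.geometry.json
        sidecar = Path(str(path).replace(".ome.tif", ".geometry.json"))
    geometry = AcquisitionGeometry.from_json(sidecar)
    if column_id is None:
        column_id = int(path.stem.split("_")[-1].split(".")[0])
    return ImageColumn(frames=frames, geometry=geometry, column_id=column_id,
                       nominal_origin_um=geometry.column_origin_um)


def write_volume(volume: np.ndarray, path: str | Path) -> None:
    """Write a (z, y, x) volume as TIFF (BigTIFF when above 2 GiB)."""
    big = volume.nbytes > 2**31
    tifffile.imwrite(path, volume, bigtiff=big)


def read_volume(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_cell_table(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CELL_COLUMNS if c in records.columns]
    records[cols].to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_activation_table(table: pd.DataFrame, path: str | Path) -> None:
    table[["animal_id", "group", "region", "count"]].to_csv(path, index=False)


def read_activation_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"animal_id", "group", "region", "count"} - set(table.columns)
    if missing:
        raise ValueError(f"activation table missing columns {sorted(missing)}")
    return table
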