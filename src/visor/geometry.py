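"""Deterministic arithmetic of 45°-oblique on-the-fly acquisition.

The microscope images an oblique plane (tilted by ``tilt_angle_deg`` to the
sample surface) while the stage translates the sample continuously along +x.
Every frame is therefore a sheared section of the volume; this module is the
single source of truth for the mapping between frame pixels and world
micrometre coordinates, and for the derived scalar quantities (voxel size,
imageable depth, camera throughput, motion blur).

Coordinate convention (used by the whole package):

* world frame: right-handed, units µm; x = stage travel, y = illumination
  beam width (camera columns), z = depth, *decreasing* into the tissue;
* pixel indices are 0-based, ranges half-open;
* frame pixel (row, col): rows run down the oblique plane (into the
  tissue), cols run along y.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "VoxelGrid",
    "effective_magnification",
    "voxel_grid",
    "imageable_depth",
    "motion_blur_extent",
    "voxel_throughput",
    "oblique_to_world",
    "world_to_oblique",
]


class GeometryError(ValueError):
    """Invalid acquisition-geometry parameter."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """All scan/optics parameters needed to map frame pixels to world µm.

    Parameters
    ----------
    tilt_angle_deg
        Angle between the imaging plane and the sample surface, in (0, 90).
    objective_mag
        Nominal magnification of the imaging objective (e.g. 20).
    tube_focal_mm
        Focal length of the tube lens actually installed, mm.
    reference_tube_mm
        Tube length the objective's nominal magnification assumes
        (manufacturer convention; 180 mm for Olympus).
    camera_pixel_um
        Physical sensor pixel pitch, µm.
    scan_rate_hz
        Frame (scan) rate, frames/s.
    stage_speed_um_s
        Stage translation speed along x, µm/s.
    frame_shape
        (rows, cols) of one acquired frame.
    exposure_per_voxel_s
        Effective per-voxel excitation time of the synchronized beam scan, s.
    column_origin_um
        World (x, y, z) of frame 0, pixel (0, 0).
    """

    tilt_angle_deg: float = 45.0
    objective_mag: float = 20.0
    tube_focal_mm: float = 120.0
    reference_tube_mm: float = 180.0
    camera_pixel_um: float = 6.5
    scan_rate_hz: float = 200.0
    stage_speed_um_s: float = 1000.0
    frame_shape: tuple[int, int] = (1000, 2000)
    exposure_per_voxel_s: float = 100e-6
    column_origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.tilt_angle_deg < 90.0 or self.tilt_angle_deg == 90.0):
            # 90° is allowed as the degenerate "no shear" case used in tests
            raise GeometryError(f"tilt_angle_deg must be in (0, 90], got {self.tilt_angle_deg}")
        for name in ("objective_mag", "tube_focal_mm", "reference_tube_mm",
                     "camera_pixel_um", "scan_rate_hz", "stage_speed_um_s"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        rows, cols = self.frame_shape
        if rows <= 0 or cols <= 0 or rows != int(rows) or cols != int(cols):
            raise GeometryError(f"frame_shape must be positive integers, got {self.frame_shape}")
        if self.exposure_per_voxel_s < 0:
            raise GeometryError("exposure_per_voxel_s must be >= 0")

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Write the geometry sidecar (``geometry.json`` schema)."""
        d = asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        d["column_origin_um"] = list(self.column_origin_um)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionGeometry":
        d = json.loads(Path(path).read_text())
        d["frame_shape"] = tuple(d["frame_shape"])
        d["column_origin_um"] = tuple(d["column_origin_um"])
        return cls(**d)

    # convenience
    @property
    def tilt_rad(self) -> float:
        return math.radians(self.tilt_angle_deg)


@dataclass(frozen=True)
class VoxelGrid:
    """Sampling grid of one oblique acquisition.

    ``axial_step_um`` is the spacing perpendicular to the imaging plane,
    i.e. ``frame_step_um * sin(tilt)``.
    """

    pixel_um: float
    frame_step_um: float
    axial_step_um: float

    def __post_init__(self) -> None:
        if min(self.pixel_um, self.frame_step_um, self.axial_step_um) <= 0:
            raise GeometryError("all voxel-grid spacings must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_um * self.pixel_um * self.axial_step_um


def effective_magnification(g: AcquisitionGeometry) -> float:
    """Effective magnification = nominal mag × tube focal / reference tube.

    A 20× objective (180 mm reference) behind a 120 mm tube lens gives
    20 · 120/180 = 13.3×.
    """
    return g.objective_mag * g.tube_focal_mm / g.reference_tube_mm


def voxel_grid(g: AcquisitionGeometry) -> VoxelGrid:
    """Derive in-plane pixel size, frame step, and axial step from geometry.

    At 200 Hz / 1 mm/s / 45° with 13.3× magnification and a 6.5 µm sensor
    pitch this yields ~0.49 × 0.49 µm pixels and a 3.54 µm axial step — the
    nominal 0.5 × 0.5 × 3.5 µm³ voxel.
    """
    pixel_um = g.camera_pixel_um / effective_magnification(g)
    frame_step_um = g.stage_speed_um_s / g.scan_rate_hz
    axial_step_um = frame_step_um * math.sin(g.tilt_rad)
    return VoxelGrid(pixel_um=pixel_um, frame_step_um=frame_step_um,
                     axial_step_um=axial_step_um)


def imageable_depth(oblique_field_um: float, tilt_angle_deg: float) -> float:
    """Vertical depth covered by an oblique field of given length.

    A ~420 µm oblique field at 45° spans ~297 µm of depth, which is what
    bounds the usable slice thickness to ~300 µm.
    """
    if oblique_field_um <= 0:
        raise GeometryError("oblique field length must be positive")
    if not 0 < tilt_angle_deg <= 90:
        raise GeometryError("tilt angle must be in (0, 90]")
    return oblique_field_um * math.sin(math.radians(tilt_angle_deg))


def motion_blur_extent(stage_speed_um_s: float, effective_exposure_s: float) -> float:
    """Lateral smear accumulated during one exposure, µm.

    With the synchronized beam scan the effective exposure per voxel is the
    beam dwell time (~100 µs), so at 0.5 mm/s the smear is only 0.05 µm.
    In unsynchronized ("light-sheet mode") acquisition the exposure is the
    full frame period and the same stage speed smears by several µm; pass
    ``1/scan_rate`` as the exposure to model that case.
    """
    if stage_speed_um_s < 0 or effective_exposure_s < 0:
        raise GeometryError("speed and exposure must be >= 0")
    return stage_speed_um_s * effective_exposure_s


def voxel_throughput(volume_rate_um3_s: float, voxel: VoxelGrid) -> float:
    """Voxels per second implied by a volumetric acquisition rate."""
    if volume_rate_um3_s < 0:
        raise GeometryError("volume rate must be >= 0")
    return volume_rate_um3_s / voxel.voxel_volume_um3


def oblique_to_world(
    g: AcquisitionGeometry,
    frame_index: np.ndarray | float,
    pixel_row: np.ndarray | float,
    pixel_col: np.ndarray | float,
    *,
    check_bounds: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map frame/pixel indices to world (x, y, z) µm.

    The shear mapping of the oblique plane under stage motion along +x::

        x = ox + frame * frame_step + row * pixel * cos(tilt)
        y = oy + col * pixel
        z = oz - row * pixel * sin(tilt)

    Accepts scalars or broadcastable arrays; fractional indices are allowed
    (the mapping is affine) but integer indices are bounds-checked against
    ``frame_shape`` when ``check_bounds`` is set.
    """
    frame_index = np.asarray(frame_index, dtype=float)
    pixel_row = np.asarray(pixel_row, dtype=float)
    pixel_col = np.asarray(pixel_col, dtype=float)
    if check_bounds:
        rows, cols = g.frame_shape
        if np.any(pixel_row < 0) or np.any(pixel_row > rows - 1) \
                or np.any(pixel_col < 0) or np.any(pixel_col > cols - 1):
            raise IndexError("pixel index outside frame_shape")
    grid = voxel_grid(g)
    ox, oy, oz = g.column_origin_um
    ct, st = math.cos(g.tilt_rad), math.sin(g.tilt_rad)
    x = ox + frame_index * grid.frame_step_um + pixel_row * grid.pixel_um * ct
    y = oy + pixel_col * grid.pixel_um
    z = oz - pixel_row * grid.pixel_um * st
    return x, y, z


def world_to_oblique(
    g: AcquisitionGeometry,
    x: np.ndarray | float,
    y: np.ndarray | float,
    z: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`oblique_to_world`; returns fractional indices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    grid = voxel_grid(g)
    ox, oy, oz = g.column_origin_um
    ct, st = math.cos(g.tilt_rad), math.sin(g.tilt_rad)
    pixel_row = (oz - z) / (grid.pixel_um * st)
    pixel_col = (y - oy) / grid.pixel_um
    frame_index = (x - ox - pixel_row * grid.pixel_um * ct) / grid.frame_step_um
    return frame_index, pixel_row, pixel_col
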