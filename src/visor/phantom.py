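"""Ground-truthed synthetic phantoms and oblique-acquisition simulation.

Phantoms are two-channel 3D volumes containing ellipsoidal somata/nuclei
(anisotropic Gaussian profiles) and tubular dendrites on a constant
background, with optional Poisson shot noise and Gaussian read noise.  The
module also simulates the oblique on-the-fly camera (frame streams =
"columns" with configurable overlap, synchronized or unsynchronized
exposure) and the slice-cutting step with smooth per-slice deformations, so
the stitching, alignment, detection and statistics stages can all be tested
against exact ground truth without a microscope.

Volume arrays are indexed ``(z, y, x)`` with ``z`` the depth below the top
surface (µm, increasing downward); positions in :class:`GroundTruth` use the
same (x, y, z-depth) frame.  Conversion to the acquisition world frame
(where z decreases into tissue) happens inside :func:`simulate_acquisition`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import AcquisitionGeometry, voxel_grid

__all__ = [
    "CellSpec",
    "DendriteSpec",
    "NoiseSpec",
    "PhantomSpec",
    "GroundTruth",
    "render_phantom",
    "simulate_acquisition",
    "cut_and_deform_slices",
    "evaluate_deformation",
    "invert_deformation",
    "pvn_preset",
    "mea_preset",
    "soma_field_preset",
    "cortex_block_preset",
    "make_fst_cohort",
    "REGIONS_14",
]

CHANNELS = ("red", "green")


@dataclass
class CellSpec:
    """One soma or nucleus: truncated anisotropic Gaussian, σ = radius/2."""

    center_um: tuple[float, float, float]  # (x, y, z-depth)
    radii_um: tuple[float, float, float]
    peak_intensity: float
    channel: str = "red"
    colabel_partner: int | None = None  # id of the paired cell in the other channel


@dataclass
class DendriteSpec:
    """Tubular process: Gaussian cross-section around a polyline path."""

    path_um: np.ndarray  # (N, 3) points, (x, y, z-depth)
    radius_um: float
    intensity: float
    channel: str = "red"


@dataclass
class NoiseSpec:
    poisson: bool = True
    read_sigma: float = 2.0  # counts, sCMOS-like


@dataclass
class PhantomSpec:
    """Everything needed to render a phantom deterministically."""

    volume_shape_um: tuple[float, float, float]  # (x, y, z)
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (dx, dy, dz)
    cells: list[CellSpec] = field(default_factory=list)
    dendrites: list[DendriteSpec] = field(default_factory=list)
    background_level: float = 100.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    rng_seed: int = 0
    region: str = "phantom"

    def validate(self) -> None:
        X, Y, Z = self.volume_shape_um
        if min(self.volume_shape_um) <= 0 or min(self.spacing_um) <= 0:
            raise ValueError("volume shape and spacing must be positive")
        for i, c in enumerate(self.cells):
            x, y, z = c.center_um
            if not (0 <= x < X and 0 <= y < Y and 0 <= z < Z):
                raise ValueError(f"cell {i} center {c.center_um} outside volume {self.volume_shape_um}")
            if min(c.radii_um) <= 0 or c.peak_intensity < 0:
                raise ValueError(f"cell {i} has nonpositive radius or negative intensity")
            if c.channel not in CHANNELS:
                raise ValueError(f"cell {i} channel {c.channel!r} not in {CHANNELS}")


@dataclass
class GroundTruth:
    """Exact bookkeeping of what was rendered / simulated."""

    cells: pd.DataFrame  # id, x_um, y_um, z_um, r*_um, channel, partner_id, region
    region_counts: pd.DataFrame | None = None
    deformations: list[dict] | None = None  # per-slice deformation parameters
    column_offsets_um: list[tuple[float, float, float]] | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.cells.to_csv(path.with_suffix(".csv"), index=False)
        meta = {
            "deformations": _jsonify(self.deformations),
            "column_offsets_um": _jsonify(self.column_offsets_um),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _jsonify(obj):
    if obj is None:
        return None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonify(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# rendering


def render_phantom(spec: PhantomSpec) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render the phantom into per-channel uint16 volumes plus ground truth.

    Somata are additive anisotropic Gaussians truncated at 3σ with
    σ = radius/2, so the intensity at the nominal cell boundary has fallen
    to ~13% of the peak and a DoG detector peaks at the soma centre.
    Deterministic given ``spec.rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    dx, dy, dz = spec.spacing_um
    X, Y, Z = spec.volume_shape_um
    shape = (int(round(Z / dz)), int(round(Y / dy)), int(round(X / dx)))

    vols = {ch: np.full(shape, float(spec.background_level)) for ch in CHANNELS}

    for c in spec.cells:
        _add_gaussian_blob(vols[c.channel], c.center_um, c.radii_um,
                           c.peak_intensity, spec.spacing_um)
    for d in spec.dendrites:
        _add_tube(vols[d.channel], d.path_um, d.radius_um, d.intensity,
                  spec.spacing_um)

    out = {}
    for ch, v in vols.items():
        if spec.noise.poisson:
            v = rng.poisson(np.clip(v, 0, None)).astype(float)
        if spec.noise.read_sigma > 0:
            v = v + rng.normal(0.0, spec.noise.read_sigma, size=v.shape)
        out[ch] = np.clip(np.round(v), 0, 65535).astype(np.uint16)

    rows = []
    for i, c in enumerate(spec.cells):
        rows.append(dict(id=i, x_um=c.center_um[0], y_um=c.center_um[1],
                         z_um=c.center_um[2], rx_um=c.radii_um[0],
                         ry_um=c.radii_um[1], rz_um=c.radii_um[2],
                         channel=c.channel, partner_id=c.colabel_partner,
                         region=spec.region))
    cells = pd.DataFrame(rows, columns=["id", "x_um", "y_um", "z_um", "rx_um",
                                        "ry_um", "rz_um", "channel",
                                        "partner_id", "region"])
    if len(cells):
        counts = (cells.groupby(["region", "channel"]).size()
                  .rename("count").reset_index())
    else:
        counts = pd.DataFrame(columns=["region", "channel", "count"])
    return out, GroundTruth(cells=cells, region_counts=counts)


def _add_gaussian_blob(vol, center_um, radii_um, peak, spacing_um):
    dx, dy, dz = spacing_um
    cx, cy, cz = center_um
    sx, sy, sz = (r / 2.0 for r in radii_um)  # σ = radius/2
    # bounding box at 3σ
    z0 = max(int((cz - 3 * sz) / dz), 0)
    z1 = min(int(math.ceil((cz + 3 * sz) / dz)) + 1, vol.shape[0])
    y0 = max(int((cy - 3 * sy) / dy), 0)
    y1 = min(int(math.ceil((cy + 3 * sy) / dy)) + 1, vol.shape[1])
    x0 = max(int((cx - 3 * sx) / dx), 0)
    x1 = min(int(math.ceil((cx + 3 * sx) / dx)) + 1, vol.shape[2])
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = (np.arange(z0, z1) * dz - cz) / sz
    yy = (np.arange(y0, y1) * dy - cy) / sy
    xx = (np.arange(x0, x1) * dx - cx) / sx
    r2 = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2)
    blob = peak * np.exp(-0.5 * r2)
    blob[r2 > 9.0] = 0.0  # truncate at 3σ
    vol[z0:z1, y0:y1, x0:x1] += blob


def _add_tube(vol, path_um, radius_um, intensity, spacing_um):
    """Rasterize a tube by stamping Gaussian cross-sections along the path."""
    path = np.asarray(path_um, dtype=float)
    if path.ndim != 2 or path.shape[1] != 3:
        raise ValueError("dendrite path must be (N, 3)")
    # resample the polyline at ~radius/2 steps
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = seglen.sum()
    step = max(radius_um / 2.0, 0.25)
    n = max(int(total / step), 1)
    t = np.linspace(0, total, n + 1)
    cum = np.concatenate([[0], np.cumsum(seglen)])
    pts = np.empty((n + 1, 3))
    for k in range(3):
        pts[:, k] = np.interp(t, cum, path[:, k])
    sigma = radius_um / 2.0
    for p in pts:
        _add_gaussian_blob(vol, tuple(p), (2 * sigma,) * 3, intensity, spacing_um)


# ---------------------------------------------------------------------------
# oblique acquisition simulation


def simulate_acquisition(
    volume: np.ndarray,
    g: AcquisitionGeometry,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mode: str = "synchronized",
    overlap: float = 0.10,
    noise: NoiseSpec | None = None,
    rng_seed: int = 0,
    n_blur_samples: int = 5,
    n_frames: int | None = None,
):
    """Sample oblique frames from a volume, returning a list of ImageColumn.

    Each column is one continuous stage sweep along x; adjacent columns tile
    the y extent with fractional ``overlap``.  ``mode="unsynchronized"``
    emulates light-sheet-mode exposure over the full frame period: each
    frame is the average of samples spread over one frame-step of stage
    travel along x, which smears structures by stage_speed/scan_rate.

    Frames sampled (partly) outside the volume are still emitted; the
    out-of-volume fraction reads as zero.
    """
    from .stitching import ImageColumn  # local import to avoid cycle

    if mode not in ("synchronized", "unsynchronized"):
        raise ValueError(f"unknown mode {mode!r}")
    dx, dy, dz = spacing_um
    nz, ny, nx = volume.shape
    X_um, Y_um = nx * dx, ny * dy
    grid = voxel_grid(g)
    rows, cols = g.frame_shape
    ct = math.cos(g.tilt_rad)
    st = math.sin(g.tilt_rad)

    col_width_um = cols * grid.pixel_um
    stride_um = col_width_um * (1.0 - overlap)
    n_cols = max(int(math.ceil(max(Y_um - col_width_um, 0) / stride_um)) + 1, 1)
    shear_reach = rows * grid.pixel_um * ct
    if n_frames is None:
        n_frames = int(math.ceil((X_um + shear_reach) / grid.frame_step_um)) + 1
        if n_frames > 100_000:
            raise ValueError("frame step too small for volume extent; "
                             "pass n_frames explicitly")

    rng = np.random.default_rng(rng_seed)
    r_idx = np.arange(rows, dtype=float)
    c_idx = np.arange(cols, dtype=float)
    columns = []
    for ci in range(n_cols):
        y0 = ci * stride_um
        origin = (-shear_reach, y0, 0.0)  # world z=0 at the top surface
        frames = np.zeros((n_frames, rows, cols), dtype=float)
        # world coordinates of every pixel of frame f:
        #   x = ox + f*step + r*pix*ct ; y = oy + c*pix ; depth = r*pix*st
        depth = r_idx * grid.pixel_um * st          # (rows,)
        ywo = y0 + c_idx * grid.pixel_um            # (cols,)
        if mode == "unsynchronized" and g.stage_speed_um_s > 0:
            sub = np.linspace(0, grid.frame_step_um, n_blur_samples, endpoint=False)
        else:
            sub = np.array([0.0])
        for f in range(n_frames):
            acc = np.zeros((rows, cols))
            for u in sub:
                xw = origin[0] + f * grid.frame_step_um + r_idx * grid.pixel_um * ct + u
                coords = np.empty((3, rows, cols))
                coords[0] = (depth / dz)[:, None]
                coords[1] = (ywo / dy)[None, :]
                coords[2] = (xw / dx)[:, None]
                acc += ndimage.map_coordinates(volume.astype(float), coords,
                                               order=1, mode="constant", cval=0.0)
            frame = acc / len(sub)
            if noise is not None:
                if noise.poisson:
                    frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
                if noise.read_sigma > 0:
                    frame = frame + rng.normal(0, noise.read_sigma, frame.shape)
            frames[f] = frame
        geo = AcquisitionGeometry(
            tilt_angle_deg=g.tilt_angle_deg, objective_mag=g.objective_mag,
            tube_focal_mm=g.tube_focal_mm, reference_tube_mm=g.reference_tube_mm,
            camera_pixel_um=g.camera_pixel_um, scan_rate_hz=g.scan_rate_hz,
            stage_speed_um_s=g.stage_speed_um_s, frame_shape=g.frame_shape,
            exposure_per_voxel_s=g.exposure_per_voxel_s,
            column_origin_um=origin)
        frames16 = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
        columns.append(ImageColumn(frames=frames16, geometry=geo,
                                   column_id=ci, nominal_origin_um=origin))
    return columns


# ---------------------------------------------------------------------------
# slice cutting and deformation


def _random_deformation(rng, amplitude_um, extent_um, n_waves=5):
    """Sum of ≤ n_waves random-phase low-frequency sinusoids per component."""
    comps = []
    for _ in range(2):  # dx, dy components
        waves = []
        for _ in range(rng.integers(1, n_waves + 1)):
            # ≤ 0.8 cycles per extent: slice deformation is dominated by
            # low-order bending/stretching modes
            waves.append(dict(
                amp=float(rng.uniform(0.3, 1.0)),
                kx=float(rng.uniform(0.2, 0.8) / extent_um * 2 * np.pi),
                ky=float(rng.uniform(0.2, 0.8) / extent_um * 2 * np.pi),
                phase=float(rng.uniform(0, 2 * np.pi)),
            ))
        comps.append(waves)
    # normalize so the max displacement magnitude ≈ amplitude
    probe = np.linspace(0, extent_um, 33)
    gx, gy = np.meshgrid(probe, probe, indexing="ij")
    d = _eval_waves(comps, gx, gy)
    mx = float(np.abs(d).max())
    scale = amplitude_um / mx if mx > 0 else 0.0
    for waves in comps:
        for w in waves:
            w["amp"] *= scale
    return comps


def _eval_waves(comps, x, y):
    out = np.zeros((2,) + np.shape(x))
    for k, waves in enumerate(comps):
        for w in waves:
            out[k] += w["amp"] * np.sin(w["kx"] * x + w["ky"] * y + w["phase"])
    return out


def evaluate_deformation(params: dict, x, y):
    """Forward in-plane displacement (dx, dy) at positions (x, y) µm."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return _eval_waves(params["waves"], x, y)


def invert_deformation(params: dict, x, y, n_iter: int = 20):
    """Find source positions mapping to (x, y) under the forward field."""
    xs, ys = np.array(x, dtype=float), np.array(y, dtype=float)
    for _ in range(n_iter):
        d = evaluate_deformation(params, xs, ys)
        xs = np.asarray(x) - d[0]
        ys = np.asarray(y) - d[1]
    return xs, ys


def cut_and_deform_slices(
    volume: np.ndarray,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    slice_thickness_um: float = 300.0,
    deform_amplitude_um: float = 0.0,
    tilt_amplitude: float = 0.0,
    expansion_factor: float = 1.0,
    rng_seed: int = 0,
):
    """Cut a volume into z-slices and deform each independently.

    Mimics what mechanical sectioning plus clearing does to a brain: each
    slice acquires (i) a smooth low-frequency in-plane deformation,
    (ii) a small surface tilt and (iii) an optional uniform in-plane
    expansion about the slice centre (clearing mildly expands sections;
    the factor is unknown in general, hence default 1.0).  The applied
    fields are returned so tests can measure alignment residuals against
    truth.

    Returns (slices, deformation parameter list).  The in-plane warp moves
    content at p to exactly p + D(p): resampling uses the true inverse of
    the forward field (fixed-point iteration), so the recorded parameters
    are exact ground truth for alignment metrics.
    """
    if slice_thickness_um <= 0:
        raise ValueError("slice thickness must be positive")
    dx, dy, dz = spacing_um
    nz, ny, nx = volume.shape
    n_per = max(int(round(slice_thickness_um / dz)), 1)
    n_slices = max(int(math.ceil(nz / n_per)), 1)
    rng = np.random.default_rng(rng_seed)
    extent = max(nx * dx, ny * dy)

    slices, params_list = [], []
    yy, xx = np.meshgrid(np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij")
    for si in range(n_slices):
        sl = volume[si * n_per:(si + 1) * n_per].astype(float)
        if deform_amplitude_um > 0:
            waves = _random_deformation(rng, deform_amplitude_um, extent)
        else:
            waves = [[], []]
        a = float(rng.uniform(-tilt_amplitude, tilt_amplitude)) if tilt_amplitude else 0.0
        b = float(rng.uniform(-tilt_amplitude, tilt_amplitude)) if tilt_amplitude else 0.0
        params = {"waves": waves, "tilt": (a, b), "slice_index": si,
                  "expansion": expansion_factor}
        if deform_amplitude_um > 0 or tilt_amplitude or expansion_factor != 1.0:
            # undo the expansion about the slice centre, then the exact
            # inverse of the forward field: find source s with s + D(s) = p
            cx, cy = (nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0
            px = cx + (xx - cx) / expansion_factor
            py = cy + (yy - cy) / expansion_factor
            sx, sy = invert_deformation(params, px, py)
            ztilt = (a * xx + b * yy) / dz
            coords = np.empty((3,) + sl.shape)
            coords[0] = np.arange(sl.shape[0])[:, None, None] + ztilt[None]
            coords[1] = sy[None] / dy
            coords[2] = sx[None] / dx
            sl = ndimage.map_coordinates(sl, coords, order=1, mode="nearest")
        slices.append(sl)
        params_list.append(params)
    return slices, params_list


# ---------------------------------------------------------------------------
# presets


def _sample_separated(rng, n, lo, hi, min_sep):
    """Random uniform points with a minimum pairwise separation (RSA)."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    pts = np.empty((n, len(lo)))
    k, tries = 0, 0
    while k < n:
        cand = rng.uniform(lo, hi)
        if k and np.min(np.sum((pts[:k] - cand) ** 2, axis=1)) < min_sep ** 2:
            tries += 1
            if tries > 200 * n:
                raise RuntimeError("cannot place points at requested density")
            continue
        pts[k] = cand
        k += 1
    return pts


def _dual_channel_spec(
    n_red: int,
    n_double: int,
    n_green_only: int,
    volume_shape_um,
    region: str,
    seed: int,
    red_radius_um: float = 6.0,
    green_radius_um: float = 5.0,
    min_sep_um: float = 14.0,
    margin_um: float = 16.0,
    spacing_um=(1.0, 1.0, 2.0),
) -> PhantomSpec:
    if n_double > n_red:
        raise ValueError("double-positive count cannot exceed red count")
    rng = np.random.default_rng(seed)
    lo = (margin_um,) * 3
    hi = tuple(s - margin_um for s in volume_shape_um)
    pts = _sample_separated(rng, n_red + n_green_only, lo, hi, min_sep_um)
    cells: list[CellSpec] = []
    for i in range(n_red):
        cells.append(CellSpec(center_um=tuple(pts[i]),
                              radii_um=(red_radius_um,) * 3,
                              peak_intensity=float(rng.uniform(1500, 3000)),
                              channel="red"))
    # a random subset of red cells carries a co-centred green nucleus
    double_ids = rng.choice(n_red, size=n_double, replace=False)
    for red_id in double_ids:
        green_id = len(cells)
        cells[red_id].colabel_partner = green_id
        cells.append(CellSpec(center_um=cells[red_id].center_um,
                              radii_um=(green_radius_um,) * 3,
                              peak_intensity=float(rng.uniform(1500, 3000)),
                              channel="green",
                              colabel_partner=int(red_id)))
    for k in range(n_green_only):
        cells.append(CellSpec(center_um=tuple(pts[n_red + k]),
                              radii_um=(green_radius_um,) * 3,
                              peak_intensity=float(rng.uniform(1500, 3000)),
                              channel="green"))
    return PhantomSpec(volume_shape_um=volume_shape_um, spacing_um=spacing_um,
                       cells=cells, rng_seed=seed, region=region)


def pvn_preset(seed: int = 0) -> PhantomSpec:
    """Dual-channel PVN-like phantom.

    Ground-truth class counts follow the stimulated animal's paraventricular
    nucleus: 834 CRH somata (red), 430 of them c-Fos positive (co-centred
    green nuclei), plus a small non-CRH activated population (25 green-only
    cells, extrapolated from the control animal's ~5% non-CRH fraction).
    """
    return _dual_channel_spec(n_red=834, n_double=430, n_green_only=25,
                              volume_shape_um=(380.0, 380.0, 140.0),
                              region="PVN", seed=seed)


def mea_preset(seed: int = 0) -> PhantomSpec:
    """Dual-channel MEA-like phantom: 1018 CRH somata, 569 activated cells,
    104 double-positive — the near-orthogonal labeling pattern of the medial
    amygdala."""
    return _dual_channel_spec(n_red=1018, n_double=104, n_green_only=569 - 104,
                              volume_shape_um=(460.0, 460.0, 160.0),
                              region="MEA", seed=seed)


def soma_field_preset(n_cells: int = 200, seed: int = 0,
                      noise: NoiseSpec | None = None) -> PhantomSpec:
    """Single-channel field of somata for detector precision/recall checks."""
    if noise is None:
        noise = NoiseSpec(poisson=False, read_sigma=0.0)
    rng = np.random.default_rng(seed)
    shape = (300.0, 300.0, 120.0)
    pts = _sample_separated(rng, n_cells, (16.0,) * 3,
                            tuple(s - 16.0 for s in shape), 14.0)
    cells = [CellSpec(center_um=tuple(p), radii_um=(6.0,) * 3,
                      peak_intensity=float(rng.uniform(1500, 3000)),
                      channel="red") for p in pts]
    return PhantomSpec(volume_shape_um=shape, spacing_um=(1.0, 1.0, 2.0),
                       cells=cells, noise=noise, rng_seed=seed,
                       region="field")


def cortex_block_preset(seed: int = 7, n_cells: int = 250, n_fibers: int = 80,
                        fiber_wander_um: float = 2.0) -> PhantomSpec:
    """Densely textured tissue block for slice-alignment experiments.

    Somata plus near-vertical dendritic fibers crossing the cutting planes,
    so opposing cut faces share trackable texture — the situation the
    serial-section aligner relies on.
    """
    rng = np.random.default_rng(seed)
    X = Y = 200.0
    Z = 96.0
    cells = [CellSpec(center_um=tuple(rng.uniform([8, 8, 8], [X - 8, Y - 8, Z - 8])),
                      radii_um=(5.0,) * 3,
                      peak_intensity=float(rng.uniform(1000, 2500)))
             for _ in range(n_cells)]
    dendrites = []
    for _ in range(n_fibers):
        x, y = rng.uniform(15, X - 15, 2)
        path = []
        for z in np.linspace(2, Z - 2, 8):
            x = float(np.clip(x + rng.normal(0, fiber_wander_um), 5, X - 5))
            y = float(np.clip(y + rng.normal(0, fiber_wander_um), 5, Y - 5))
            path.append((x, y, z))
        dendrites.append(DendriteSpec(np.array(path), 2.0, 800.0))
    return PhantomSpec(volume_shape_um=(X, Y, Z), spacing_um=(1.0, 1.0, 2.0),
                       cells=cells, dendrites=dendrites, background_level=50.0,
                       noise=NoiseSpec(poisson=True, read_sigma=2.0),
                       rng_seed=seed, region="block")


# ---------------------------------------------------------------------------
# cohort generator for the activation statistics

REGIONS_14 = ["BMA", "MEA", "VMH", "DMH", "CEA", "BLA", "PMv", "AHN", "ZI",
              "PVH", "TU", "SUM", "PH", "LHA"]

# per-region baseline activated-cell count and control CV; fixed study
# conditions, not seed-dependent
_REGION_BASE = {
    "BMA": 600, "MEA": 900, "VMH": 1200, "DMH": 500, "CEA": 700,
    "BLA": 1000, "PMv": 300, "AHN": 450, "ZI": 800, "PVH": 650,
    "TU": 250, "SUM": 350, "PH": 550, "LHA": 750,
}
_CONTROL_CV = 0.30


def make_fst_cohort(
    seed: int = 0,
    n_per_group: int = 8,
    effect_regions: tuple[str, ...] = ("BMA", "MEA", "VMH"),
    effect_sd: float = 3.0,
    fst_cv_inflation: float = 1.8,
    low_var_regions: tuple[str, ...] = ("VMH",),
    null: bool = False,
) -> pd.DataFrame:
    """Synthesize a 16-animal, 14-region activated-cell count table.

    Emulates the forced-swim cohort: ``effect_regions`` get a mean shift of
    ``effect_sd`` control SDs in the FST group; most regions get inflated
    FST variability; ``low_var_regions`` instead get reduced FST CV (the
    ceiling effect seen in strongly driven regions).  ``null=True`` draws
    both groups from the control distribution (for false-discovery checks).

    Returns a long DataFrame (animal_id, group, region, count).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for region in REGIONS_14:
        mu = _REGION_BASE[region]
        sd = _CONTROL_CV * mu
        ctrl = rng.normal(mu, sd, n_per_group)
        if null:
            fst = rng.normal(mu, sd, n_per_group)
        else:
            mu_f = mu + (effect_sd * sd if region in effect_regions else 0.0)
            if region in low_var_regions and region in effect_regions:
                sd_f = 0.5 * _CONTROL_CV * mu_f
            else:
                sd_f = fst_cv_inflation * _CONTROL_CV * mu_f
            fst = rng.normal(mu_f, sd_f, n_per_group)
        for i, v in enumerate(ctrl):
            rows.append(dict(animal_id=f"ctrl{i + 1}", group="control",
                             region=region, count=max(int(round(v)), 0)))
        for i, v in enumerate(fst):
            rows.append(dict(animal_id=f"fst{i + 1}", group="FST",
                             region=region, count=max(int(round(v)), 0)))
    return pd.DataFrame(rows)
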