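"""Deskew oblique frame streams into world-space columns and stitch them.

A "column" is the frame stream from one continuous stage sweep.  Because
the imaging plane is tilted, the raw frame stack is a sheared sampling of
the tissue; :func:`stack_column` resamples it onto an axis-aligned µm grid
(the deskew step).  Adjacent columns overlap by ~10% of their width, and
the actual inter-column offsets are recovered from phase correlation plus
normalized cross-correlation in those overlaps, solved globally by
score-weighted least squares, and the columns fused with linear feathering.

Offsets are kept at integer voxels: the downstream consumers (cell
detection and counting) operate at voxel scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .geometry import AcquisitionGeometry, voxel_grid

__all__ = [
    "ImageColumn",
    "OffsetEdge",
    "OffsetGraph",
    "stack_column",
    "estimate_pair_offset",
    "solve_global_offsets",
    "fuse_columns",
    "stitch_columns",
]

log = logging.getLogger(__name__)

MIN_OVERLAP_VOXELS = 16


@dataclass
class ImageColumn:
    """One oblique frame stream with its world anchor."""

    frames: np.ndarray  # (frame, row, col), uint16
    geometry: AcquisitionGeometry
    column_id: int
    nominal_origin_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.size == 0:
            raise ValueError("frames must be a nonempty 3D array")
        if self.geometry is None:
            raise ValueError("column requires acquisition geometry")


@dataclass
class OffsetEdge:
    a: int
    b: int
    offset_vox: tuple[int, int, int]  # (z, y, x): position_b − position_a
    score: float
    fallback: bool = False


@dataclass
class OffsetGraph:
    nodes: list[int]
    edges: list[OffsetEdge] = field(default_factory=list)

    def is_connected(self) -> bool:
        if not self.nodes:
            return False
        adj = {n: set() for n in self.nodes}
        for e in self.edges:
            adj[e.a].add(e.b)
            adj[e.b].add(e.a)
        seen = {self.nodes[0]}
        stack = [self.nodes[0]]
        while stack:
            for m in adj[stack.pop()]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return len(seen) == len(self.nodes)


def stack_column(col: ImageColumn, z_step_um: float | None = None) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Deskew one column onto an axis-aligned (z, y, x) µm grid.

    Output spacing is (axial step, pixel, pixel) — the native anisotropic
    voxel — unless ``z_step_um`` overrides the axial spacing.  The world z
    axis points down into the tissue here (depth), matching the phantom
    volume convention.  Returns (volume, (dx, dy, dz)).
    """
    g = col.geometry
    grid = voxel_grid(g)
    dz = z_step_um if z_step_um is not None else grid.axial_step_um
    dy = dx = grid.pixel_um
    n_frames, rows, cols = col.frames.shape
    ct, st = math.cos(g.tilt_rad), math.sin(g.tilt_rad)

    depth_um = rows * grid.pixel_um * st
    x_extent = n_frames * grid.frame_step_um - rows * grid.pixel_um * ct
    x_extent = max(x_extent, grid.frame_step_um)
    y_extent = cols * grid.pixel_um

    nz = max(int(depth_um / dz), 1)
    ny = cols
    nx = max(int(x_extent / dx), 1)

    # world (depth, y, x) of each output voxel, relative to column origin:
    # the first fully sampled x position is origin_x + rows*pixel*ct
    z_w = (np.arange(nz) + 0.5) * dz
    y_w = np.arange(ny) * dy
    x_w = np.arange(nx) * dx + rows * grid.pixel_um * ct
    # invert the shear: row from depth, frame from x
    pixel_row = z_w / (grid.pixel_um * st)
    frame_idx = (x_w[None, :] - pixel_row[:, None] * grid.pixel_um * ct) / grid.frame_step_um

    out = np.empty((nz, ny, nx), dtype=float)
    vol = col.frames.astype(float)
    for yi in range(ny):
        coords_y = np.stack([frame_idx, np.broadcast_to(pixel_row[:, None], frame_idx.shape),
                             np.full_like(frame_idx, yi)])
        out[:, yi, :] = ndimage.map_coordinates(vol, coords_y, order=1,
                                                mode="constant", cval=0.0)
    return out, (dx, dy, dz)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(float).ravel() - a.mean()
    b = b.astype(float).ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / denom, -1.0, 1.0))


def _shifted_overlap(a, b, shift):
    """Overlapping views of a and b when b is displaced by ``shift``."""
    sl_a, sl_b = [], []
    for ax, s in enumerate(shift):
        n = min(a.shape[ax] - max(s, 0), b.shape[ax] - max(-s, 0))
        if n <= 0:
            return None, None
        sl_a.append(slice(max(s, 0), max(s, 0) + n))
        sl_b.append(slice(max(-s, 0), max(-s, 0) + n))
    return a[tuple(sl_a)], b[tuple(sl_b)]


def estimate_pair_offset(
    a: np.ndarray,
    b: np.ndarray,
    nominal_offset_vox: tuple[int, int, int],
    ids: tuple[int, int] = (0, 1),
    subtract_background: bool = True,
) -> OffsetEdge:
    """Estimate the integer-voxel offset of subvolume ``b`` relative to ``a``.

    ``nominal_offset_vox`` is the stage-coordinate offset (z, y, x); the
    overlap it implies is cut out of both volumes, FFT phase correlation
    proposes a correction, and the normalized cross-correlation of the
    shifted overlap is the edge score.  Overlaps thinner than 16 voxels in
    any axis (or incoherent matches) fall back to the nominal offset with
    a low-confidence flag.
    """
    nominal = np.array(nominal_offset_vox, dtype=int)
    ov_a, ov_b = _shifted_overlap(a, b, nominal)
    fallback = OffsetEdge(ids[0], ids[1], tuple(nominal), 0.0, fallback=True)
    if ov_a is None or min(ov_a.shape) < MIN_OVERLAP_VOXELS:
        log.warning("overlap below %d voxels for pair %s; using nominal",
                    MIN_OVERLAP_VOXELS, ids)
        return fallback
    fa, fb = ov_a.astype(float), ov_b.astype(float)
    if subtract_background:
        fa = fa - np.median(fa)
        fb = fb - np.median(fb)
    shift, _, _ = phase_cross_correlation(fa, fb, upsample_factor=1,
                                          normalization="phase")
    correction = np.round(shift).astype(int)
    refined = nominal + correction
    ra, rb = _shifted_overlap(a, b, refined)
    if ra is None or min(ra.shape) < MIN_OVERLAP_VOXELS:
        return fallback
    score = _ncc(ra - np.median(ra) if subtract_background else ra,
                 rb - np.median(rb) if subtract_background else rb)
    nominal_score = _ncc(fa, fb)
    if score < nominal_score:  # correlation tie/regression → trust the stage
        refined, score = nominal, nominal_score
    if score < 0.1:
        log.warning("no coherent overlap correlation for pair %s (ncc=%.3f)",
                    ids, score)
        return fallback
    return OffsetEdge(ids[0], ids[1], tuple(int(v) for v in refined), score)


def solve_global_offsets(
    graph: OffsetGraph,
    nominal_origins_vox: dict[int, np.ndarray],
) -> dict[int, np.ndarray]:
    """Score-weighted least squares for per-column origins.

    Minimizes Σ_e w_e ‖(o_b − o_a) − Δ_e‖² with the first column anchored
    at its nominal origin.  Disconnected components are each anchored at
    their nominal coordinates with a warning.
    """
    nodes = list(graph.nodes)
    if not nodes:
        return {}
    comp = _components(graph)
    out: dict[int, np.ndarray] = {}
    for members in comp:
        members = sorted(members)
        anchor = members[0]
        if len(comp) > 1:
            log.warning("offset graph not connected; component %s anchored "
                        "at nominal coordinates", members)
        edges = [e for e in graph.edges if e.a in members and e.b in members]
        idx = {n: i for i, n in enumerate(members)}
        n = len(members)
        if n == 1 or not edges:
            for m in members:
                out[m] = np.asarray(nominal_origins_vox[m], dtype=float)
            continue
        rows = []
        rhs = []
        w = []
        for e in edges:
            r = np.zeros(n)
            r[idx[e.b]] = 1.0
            r[idx[e.a]] = -1.0
            rows.append(r)
            rhs.append(np.asarray(e.offset_vox, dtype=float))
            w.append(max(e.score, 1e-3))
        # anchor
        r = np.zeros(n)
        r[idx[anchor]] = 1.0
        rows.append(r)
        rhs.append(np.asarray(nominal_origins_vox[anchor], dtype=float))
        w.append(1e3)
        A = np.array(rows) * np.sqrt(np.array(w))[:, None]
        B = np.array(rhs) * np.sqrt(np.array(w))[:, None]
        sol, *_ = np.linalg.lstsq(A, B, rcond=None)
        for m in members:
            out[m] = sol[idx[m]]
    return out


def _components(graph: OffsetGraph) -> list[set[int]]:
    adj = {n: set() for n in graph.nodes}
    for e in graph.edges:
        adj[e.a].add(e.b)
        adj[e.b].add(e.a)
    seen: set[int] = set()
    comps = []
    for n in graph.nodes:
        if n in seen:
            continue
        comp = {n}
        stack = [n]
        while stack:
            for m in adj[stack.pop()]:
                if m not in comp:
                    comp.add(m)
                    stack.append(m)
        seen |= comp
        comps.append(comp)
    return comps


def fuse_columns(
    volumes: list[np.ndarray],
    origins_vox: dict[int, np.ndarray] | list[np.ndarray],
) -> np.ndarray:
    """Fuse deskewed columns at solved integer origins with feather blending.

    The blend weight of each column tapers linearly to zero at its y-edges
    (the tiling axis), so seams inside overlaps are convex combinations of
    the two columns; output intensities stay within input bounds.
    """
    if isinstance(origins_vox, dict):
        origins = [np.round(np.asarray(origins_vox[i], float)).astype(int)
                   for i in range(len(volumes))]
    else:
        origins = [np.round(np.asarray(o, float)).astype(int) for o in origins_vox]
    lo = np.min([o for o in origins], axis=0)
    hi = np.max([o + np.array(v.shape) for o, v in zip(origins, volumes)], axis=0)
    shape = tuple((hi - lo).astype(int))
    acc = np.zeros(shape, dtype=float)
    wacc = np.zeros(shape, dtype=float)
    for vol, org in zip(volumes, origins):
        ny = vol.shape[1]
        ramp = np.minimum(np.arange(ny) + 1, np.arange(ny)[::-1] + 1).astype(float)
        w = np.broadcast_to(ramp[None, :, None], vol.shape)
        sl = tuple(slice(o - l, o - l + s) for o, l, s in zip(org, lo, vol.shape))
        acc[sl] += vol * w
        wacc[sl] += w
    out = np.divide(acc, wacc, out=np.zeros_like(acc), where=wacc > 0)
    return out


def stitch_columns(
    columns: list[ImageColumn],
    overlap_hint: float = 0.10,
    z_step_um: float | None = None,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Deskew, register, solve and fuse a list of columns into one volume."""
    vols = []
    spacings = []
    nominal: dict[int, np.ndarray] = {}
    for col in columns:
        v, sp = stack_column(col, z_step_um=z_step_um)
        vols.append(v)
        spacings.append(sp)
        ox, oy, oz = col.nominal_origin_um
        dx, dy, dz = sp
        # origin of the deskewed volume in voxels of the fused grid;
        # deskewed volumes share x origin handling from stack_column
        nominal[col.column_id] = np.array([0.0, oy / dy, 0.0])
    graph = OffsetGraph(nodes=[c.column_id for c in columns])
    order = sorted(columns, key=lambda c: c.nominal_origin_um[1])
    for ca, cb in zip(order, order[1:]):
        a, b = vols[ca.column_id], vols[cb.column_id]
        nom = np.round(nominal[cb.column_id] - nominal[ca.column_id]).astype(int)
        graph.edges.append(estimate_pair_offset(a, b, tuple(nom),
                                                ids=(ca.column_id, cb.column_id)))
    solved = solve_global_offsets(graph, nominal)
    fused = fuse_columns(vols, solved)
    return fused, spacings[0]
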