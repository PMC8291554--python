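"""Whole-brain reconstruction from serially cut, individually deformed slices.

Cutting a brain into ~300 µm slices and clearing them deforms every slice
independently, so the imaged slices no longer agree where they meet.  The
reconstruction proceeds in four steps:

1. **flatten** — fit each slice's top and bottom surfaces with planes
   (excluding masked structures such as ventricles) and resample so both
   faces are flat;
2. **correspond** — extract dense correspondences between the opposing
   faces of adjacent slices.  The backend is pluggable; the default is
   coarse-to-fine block matching on gradient-magnitude images with local
   NCC as confidence;
3. **adjust** — jointly shrink the correspondence displacements across the
   whole stack under smoothness and small-displacement penalties, which
   limits error accumulation through the stack;
4. **warp** — deform each slice with a similarity-variant moving-least-
   squares (MLS) transform through the adjusted control points.  Similarity
   MLS reproduces global similarity transforms exactly and keeps local
   shapes and sizes, i.e. it morphs minimally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree
from skimage.feature import match_template
from skimage.filters import threshold_otsu, sobel

__all__ = [
    "SurfaceModel",
    "CorrespondenceSet",
    "fit_surface",
    "flatten_slice",
    "extract_correspondences",
    "adjust_correspondences",
    "mls_transform",
    "mls_warp",
    "reconstruct_brain",
]

log = logging.getLogger(__name__)


@dataclass
class SurfaceModel:
    """Planes z = a·x + b·y + c (µm) for the top and bottom faces."""

    top: tuple[float, float, float]
    bottom: tuple[float, float, float]
    top_height_um: np.ndarray | None = None
    bottom_height_um: np.ndarray | None = None
    residual_um: float = 0.0

    def top_z(self, x, y):
        a, b, c = self.top
        return a * np.asarray(x) + b * np.asarray(y) + c

    def bottom_z(self, x, y):
        a, b, c = self.bottom
        return a * np.asarray(x) + b * np.asarray(y) + c


@dataclass
class CorrespondenceSet:
    """Matched points between the opposing faces of one slice pair.

    ``points_a`` lie on the lower face of the upper slice, ``points_b`` on
    the upper face of the lower slice, both in µm; ``displacements`` is
    points_a − points_b (what must be added to b to meet a).
    """

    pair_id: int
    points_a: np.ndarray  # (N, 2) (x, y) µm
    points_b: np.ndarray
    confidence: np.ndarray  # (N,) in [0, 1]

    @property
    def displacements(self) -> np.ndarray:
        return self.points_a - self.points_b

    def __len__(self) -> int:
        return len(self.points_a)


# ---------------------------------------------------------------------------
# step (i): surface fitting and flattening


def _height_maps(volume: np.ndarray, dz: float, threshold: float | None = None):
    """First/last z-crossing of an intensity threshold per (y, x) column.

    Crossings are refined to subvoxel precision by linear interpolation of
    the intensity profile through the threshold.
    """
    if threshold is None:
        threshold = threshold_otsu(volume)
    vol = volume.astype(float)
    above = vol > threshold
    any_above = above.any(axis=0)
    first = np.argmax(above, axis=0)
    last = volume.shape[0] - 1 - np.argmax(above[::-1], axis=0)
    ny, nx = first.shape
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ffrac = first.astype(float)
    interior = first > 0
    v1 = vol[first, jj, ii]
    v0 = vol[np.maximum(first - 1, 0), jj, ii]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (threshold - v0) / (v1 - v0)
    ffrac[interior] = (first - 1 + np.clip(frac, 0, 1))[interior]
    lfrac = last.astype(float)
    interior = last < volume.shape[0] - 1
    v1 = vol[last, jj, ii]
    v0 = vol[np.minimum(last + 1, volume.shape[0] - 1), jj, ii]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (threshold - v0) / (v1 - v0)
    lfrac[interior] = (last + 1 - np.clip(frac, 0, 1))[interior]
    ffrac[~any_above] = np.nan
    lfrac[~any_above] = np.nan
    ffrac = ndimage.median_filter(np.nan_to_num(ffrac, nan=0.0), size=3)
    lfrac = ndimage.median_filter(
        np.nan_to_num(lfrac, nan=volume.shape[0] - 1.0), size=3)
    ffrac[~any_above] = np.nan
    lfrac[~any_above] = np.nan
    return ffrac * dz, lfrac * dz


def _fit_plane(height_um: np.ndarray, spacing_xy: tuple[float, float],
               mask: np.ndarray | None):
    ny, nx = height_um.shape
    yy, xx = np.meshgrid(np.arange(ny) * spacing_xy[1],
                         np.arange(nx) * spacing_xy[0], indexing="ij")
    good = np.isfinite(height_um)
    if mask is not None:
        good &= ~mask
    if good.sum() < 3:
        raise ValueError("surface fit needs >= 3 unmasked support points")
    A = np.column_stack([xx[good], yy[good], np.ones(good.sum())])
    coef, *_ = np.linalg.lstsq(A, height_um[good], rcond=None)
    resid = float(np.sqrt(np.mean((A @ coef - height_um[good]) ** 2)))
    return tuple(float(v) for v in coef), resid


def fit_surface(
    volume: np.ndarray,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
    threshold: float | None = None,
) -> SurfaceModel:
    """Fit flattening planes to the top and bottom faces of a slice volume.

    Surface heights are the first (top) and last (bottom) voxel above an
    Otsu threshold in each (y, x) column, median-filtered; ``mask`` marks
    in-plane regions (ventricles, tears) to exclude from the fit.  Masked
    or empty columns are interpolated by the fitted plane.
    """
    dx, dy, dz = spacing_um
    top_h, bot_h = _height_maps(volume, dz, threshold)
    top, r1 = _fit_plane(top_h, (dx, dy), mask)
    bottom, r2 = _fit_plane(bot_h, (dx, dy), mask)
    return SurfaceModel(top=top, bottom=bottom, top_height_um=top_h,
                        bottom_height_um=bot_h, residual_um=max(r1, r2))


def flatten_slice(
    volume: np.ndarray,
    model: SurfaceModel,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Resample a slice so its fitted faces become constant-z planes.

    The output keeps the input z grid; the fitted top/bottom planes map to
    the constant levels mean(top)/mean(bottom) and the interior is
    interpolated linearly between them (extended linearly outside).  A
    slice whose faces are already flat comes back unchanged.
    """
    dx, dy, dz = spacing_um
    nz, ny, nx = volume.shape
    yy, xx = np.meshgrid(np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij")
    top = model.top_z(xx, yy)
    bottom = model.bottom_z(xx, yy)
    mean_top = float(top.mean())
    mean_bot = float(bottom.mean())
    z_out = np.arange(nz) * dz
    if mean_bot > mean_top:
        frac = (z_out - mean_top) / (mean_bot - mean_top)
    else:
        frac = np.zeros_like(z_out)
    src_z = top[None] + frac[:, None, None] * (bottom - top)[None]
    coords = np.empty((3, nz, ny, nx))
    coords[0] = src_z / dz
    coords[1] = np.broadcast_to((yy / dy)[None], (nz, ny, nx))
    coords[2] = np.broadcast_to((xx / dx)[None], (nz, ny, nx))
    return ndimage.map_coordinates(volume.astype(float), coords, order=1,
                                   mode="nearest")


# ---------------------------------------------------------------------------
# step (ii): dense correspondences (pluggable; block-matching default)


def _block_match(ga, gb, grid_rc, block, search, prior_rc):
    """NCC block matching of ``ga`` blocks into ``gb`` search windows."""
    half = block // 2
    flows = np.zeros((len(grid_rc), 2))
    confs = np.zeros(len(grid_rc))
    H, W = ga.shape
    for i, (r, c) in enumerate(grid_rc):
        pr, pc = prior_rc[i]
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
            continue
        tmpl = ga[r0:r1, c0:c1]
        sr0 = int(r + pr) - half - search
        sc0 = int(c + pc) - half - search
        sr1 = int(r + pr) + half + search + 1
        sc1 = int(c + pc) + half + search + 1
        if sr0 < 0 or sc0 < 0 or sr1 > H or sc1 > W:
            continue
        win = gb[sr0:sr1, sc0:sc1]
        if tmpl.std() == 0 or win.std() == 0:
            continue
        resp = match_template(win, tmpl)
        dr, dc = np.unravel_index(np.argmax(resp), resp.shape)
        fr, fc = float(dr), float(dc)
        # parabolic subpixel refinement of the correlation peak
        if 0 < dr < resp.shape[0] - 1:
            den = resp[dr - 1, dc] - 2 * resp[dr, dc] + resp[dr + 1, dc]
            if den < 0:
                fr += 0.5 * (resp[dr - 1, dc] - resp[dr + 1, dc]) / den
        if 0 < dc < resp.shape[1] - 1:
            den = resp[dr, dc - 1] - 2 * resp[dr, dc] + resp[dr, dc + 1]
            if den < 0:
                fc += 0.5 * (resp[dr, dc - 1] - resp[dr, dc + 1]) / den
        flows[i] = (sr0 + fr + half - r, sc0 + fc + half - c)
        confs[i] = float(np.clip(resp[dr, dc], 0.0, 1.0))
    return flows, confs


def extract_correspondences(
    face_a: np.ndarray,
    face_b: np.ndarray,
    spacing_xy_um: tuple[float, float] = (1.0, 1.0),
    pair_id: int = 0,
    grid_step_px: int = 10,
    block_px: int = 25,
    search_px: int = 10,
    coarse_factor: int = 4,
    texture_percentile: float = 30.0,
    min_confidence: float = 0.3,
    backend=None,
) -> CorrespondenceSet:
    """Dense correspondences between two opposing face images.

    Default backend: gradient-magnitude images matched coarse-to-fine with
    NCC block matching on a regular grid restricted to textured locations;
    the resulting flow is Gaussian-smoothed and each match's confidence is
    its local NCC.  ``backend(face_a, face_b)`` may instead supply a dense
    (2, H, W) flow taking a → b, from which correspondences are sampled.
    """
    if face_a.shape != face_b.shape:
        raise ValueError("faces must have the same extent")
    dx, dy = spacing_xy_um
    H, W = face_a.shape
    if backend is not None:
        flow = backend(face_a, face_b)
        rr, cc = np.meshgrid(np.arange(grid_step_px // 2, H, grid_step_px),
                             np.arange(grid_step_px // 2, W, grid_step_px),
                             indexing="ij")
        pa = np.column_stack([cc.ravel() * dx, rr.ravel() * dy])
        disp = np.column_stack([flow[1][rr.ravel(), cc.ravel()] * dx,
                                flow[0][rr.ravel(), cc.ravel()] * dy])
        return CorrespondenceSet(pair_id, pa, pa - disp,
                                 np.ones(len(pa)))

    ga = sobel(ndimage.gaussian_filter(face_a.astype(float), 1.5))
    gb = sobel(ndimage.gaussian_filter(face_b.astype(float), 1.5))
    # texture gate: local gradient energy
    energy = ndimage.uniform_filter(ga, size=block_px)
    rr, cc = np.meshgrid(np.arange(block_px, H - block_px, grid_step_px),
                         np.arange(block_px, W - block_px, grid_step_px),
                         indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(int)
    gate = energy[grid[:, 0], grid[:, 1]] >= np.percentile(energy, texture_percentile)
    grid = grid[gate]
    if len(grid) == 0:
        log.warning("textureless faces for pair %d: no correspondences", pair_id)
        return CorrespondenceSet(pair_id, np.empty((0, 2)), np.empty((0, 2)),
                                 np.empty(0))

    # coarse pass on downsampled gradients; only its robust (median) flow
    # is kept, as a global prior capturing bulk translation — per-point
    # coarse matches on face images are too unreliable to trust directly
    f = coarse_factor
    ga_c = ndimage.zoom(ga, 1 / f, order=1)
    gb_c = ndimage.zoom(gb, 1 / f, order=1)
    grid_c = np.clip(grid // f, 0, None)
    coarse_flow, coarse_conf = _block_match(ga_c, gb_c, grid_c,
                                            max(block_px // f | 1, 5),
                                            search_px,
                                            np.zeros_like(grid_c, float))
    confident = coarse_conf > 0.5
    if confident.sum() >= 4:
        global_prior = np.median(coarse_flow[confident], axis=0) * f
    else:
        global_prior = np.zeros(2)
    prior = np.tile(np.round(global_prior), (len(grid), 1))
    flows, confs = _block_match(ga, gb, grid, block_px, search_px, prior)

    good = confs > min_confidence
    grid, flows, confs = grid[good], flows[good], confs[good]
    if len(grid) == 0:
        return CorrespondenceSet(pair_id, np.empty((0, 2)), np.empty((0, 2)),
                                 np.empty(0))
    # lightly smooth the flow field over the (scattered) grid with a
    # confidence-weighted Gaussian in point space; strong regularization
    # is the adjustment stage's job
    tree = cKDTree(grid.astype(float))
    sigma = 0.75 * grid_step_px
    smooth = np.empty_like(flows)
    for i, g in enumerate(grid):
        idx = tree.query_ball_point(g.astype(float), r=3 * sigma)
        d2 = np.sum((grid[idx] - g) ** 2, axis=1)
        w = confs[idx] * np.exp(-0.5 * d2 / sigma**2)
        smooth[i] = (flows[idx] * w[:, None]).sum(axis=0) / w.sum()
    pa = np.column_stack([grid[:, 1] * dx, grid[:, 0] * dy])
    disp = np.column_stack([smooth[:, 1] * dx, smooth[:, 0] * dy])
    # flow takes a→b, so the matching point on b is pa + disp
    cs = CorrespondenceSet(pair_id, pa, pa + disp, confs)
    return _reject_outliers(cs)


def _reject_outliers(cs: CorrespondenceSet, k: int = 8,
                     tol_um: float = 2.0) -> CorrespondenceSet:
    """Drop matches inconsistent with the median flow of their neighbors."""
    if len(cs) < k + 1:
        return cs
    tree = cKDTree(cs.points_a)
    _, idx = tree.query(cs.points_a, k=k + 1)
    med = np.median(cs.displacements[idx[:, 1:]], axis=1)
    keep = np.linalg.norm(cs.displacements - med, axis=1) < tol_um
    return CorrespondenceSet(cs.pair_id, cs.points_a[keep],
                             cs.points_b[keep], cs.confidence[keep])


# ---------------------------------------------------------------------------
# step (iii): global adjustment


def adjust_correspondences(
    sets: list[CorrespondenceSet],
    lambda_smooth: float = 0.25,
    lambda_small: float = 0.01,
    k_neighbors: int = 8,
) -> list[CorrespondenceSet]:
    """Jointly regularize displacements across the whole slice stack.

    Minimizes::

        Σ_i ‖d_i − d̂_i‖² + λ_smooth Σ_{i~j} ‖d_i − d_j‖² + λ_small Σ_i ‖d_i‖²

    over all correspondences of all slice pairs, where i~j runs over
    k-nearest in-plane neighbors within a pair plus nearest points across
    adjacent pairs.  The quadratic form is solved exactly (sparse SPD
    system); the result is returned as new CorrespondenceSets with
    points_b shifted so that their displacements equal the adjusted d.
    """
    if not sets:
        raise ValueError("need at least one correspondence set")
    offsets = np.cumsum([0] + [len(s) for s in sets])
    n = offsets[-1]
    if n == 0:
        return [CorrespondenceSet(s.pair_id, s.points_a.copy(),
                                  s.points_b.copy(), s.confidence.copy())
                for s in sets]
    d_hat = np.vstack([s.displacements for s in sets])

    # neighbor weights are averaged (1/k per edge) so λ_smooth has the
    # same meaning regardless of neighborhood size
    rows, cols, vals = [], [], []
    for si, s in enumerate(sets):
        if len(s) < 2:
            continue
        tree = cKDTree(s.points_a)
        k = min(k_neighbors + 1, len(s))
        _, idx = tree.query(s.points_a, k=k)
        for i in range(len(s)):
            for j in idx[i, 1:]:
                rows.append(offsets[si] + i)
                cols.append(offsets[si] + j)
                vals.append(1.0 / (k - 1))
    for si in range(len(sets) - 1):
        a, b = sets[si], sets[si + 1]
        if len(a) == 0 or len(b) == 0:
            continue
        tree = cKDTree(b.points_a)
        _, idx = tree.query(a.points_a, k=1)
        for i, j in enumerate(idx):
            rows.append(offsets[si] + i)
            cols.append(offsets[si + 1] + int(j))
            vals.append(1.0 / max(k_neighbors, 1))
    if rows:
        W = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
        W = W.maximum(W.T)  # symmetric neighbor graph
        L = sparse.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    else:
        L = sparse.csr_matrix((n, n))
    A = sparse.identity(n) * (1.0 + lambda_small) + lambda_smooth * L
    d = np.column_stack([spsolve(A.tocsr(), d_hat[:, k]) for k in range(2)])

    out = []
    for si, s in enumerate(sets):
        di = d[offsets[si]:offsets[si + 1]]
        out.append(CorrespondenceSet(s.pair_id, s.points_a.copy(),
                                     s.points_a - di, s.confidence.copy()))
    return out


# ---------------------------------------------------------------------------
# step (iv): moving least squares warp


def mls_transform(points: np.ndarray, control_p: np.ndarray,
                  control_q: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Similarity-variant MLS mapping of ``points`` (control p → q).

    Weights w_i = 1/|p_i − v|^(2α).  The map interpolates the controls
    exactly and reproduces any global similarity transform of the control
    points everywhere.
    """
    v = np.atleast_2d(np.asarray(points, float))
    p = np.atleast_2d(np.asarray(control_p, float))
    q = np.atleast_2d(np.asarray(control_q, float))
    if len(p) != len(q) or len(p) == 0:
        raise ValueError("need equal, nonzero numbers of control points")
    dup = cKDTree(p).query_pairs(1e-9)
    for i, j in dup:
        if not np.allclose(q[i], q[j]):
            raise ValueError("coincident control points with conflicting displacements")
    if len(p) == 1:
        return v + (q[0] - p[0])

    out = np.empty_like(v)
    d2 = ((v[:, None, :] - p[None, :, :]) ** 2).sum(-1)  # (M, N)
    exact = d2 < 1e-18
    w = 1.0 / np.maximum(d2, 1e-18) ** alpha
    w[exact.any(axis=1)] = 0.0  # handled separately
    ws = w.sum(axis=1, keepdims=True)
    ws[ws == 0] = 1.0
    p_star = (w @ p) / ws
    q_star = (w @ q) / ws
    # similarity MLS
    for m in range(len(v)):
        if exact[m].any():
            out[m] = q[np.argmax(exact[m])]
            continue
        ph = p - p_star[m]
        qh = q - q_star[m]
        wm = w[m]
        mu = (wm * (ph ** 2).sum(axis=1)).sum()
        vd = v[m] - p_star[m]
        vperp = np.array([vd[1], -vd[0]])  # −(v−p*)^⊥
        acc = np.zeros(2)
        for i in range(len(p)):
            phi = ph[i]
            phip = np.array([phi[1], -phi[0]])  # −p̂^⊥
            Ai = wm[i] * np.array([[phi @ vd, phi @ vperp],
                                   [phip @ vd, phip @ vperp]])
            acc += qh[i] @ Ai
        out[m] = acc / mu + q_star[m]
    return out


def _mls_transform_grid(grid_pts, p, q, alpha=1.0):
    """Vectorized similarity MLS over many evaluation points."""
    v = np.asarray(grid_pts, float)
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if len(p) == 1:
        return v + (q[0] - p[0])
    diff = v[:, None, :] - p[None, :, :]
    d2 = (diff ** 2).sum(-1)
    w = 1.0 / np.maximum(d2, 1e-18) ** alpha
    ws = w.sum(1, keepdims=True)
    p_star = (w @ p) / ws
    q_star = (w @ q) / ws
    ph = p[None, :, :] - p_star[:, None, :]   # (M, N, 2)
    qh = q[None, :, :] - q_star[:, None, :]
    mu = (w * (ph ** 2).sum(-1)).sum(1)       # (M,)
    vd = v - p_star                            # (M, 2)
    vperp = np.stack([vd[:, 1], -vd[:, 0]], -1)   # −(v−p*)^⊥
    php = np.stack([ph[..., 1], -ph[..., 0]], -1)  # −p̂^⊥
    a11 = (ph * vd[:, None, :]).sum(-1)
    a12 = (ph * vperp[:, None, :]).sum(-1)
    a21 = (php * vd[:, None, :]).sum(-1)
    a22 = (php * vperp[:, None, :]).sum(-1)
    fx = (w * (qh[..., 0] * a11 + qh[..., 1] * a21)).sum(1)
    fy = (w * (qh[..., 0] * a12 + qh[..., 1] * a22)).sum(1)
    return np.stack([fx / mu, fy / mu], -1) + q_star


def mls_warp(
    image: np.ndarray,
    control_points: np.ndarray,
    displacements: np.ndarray,
    spacing_xy_um: tuple[float, float] = (1.0, 1.0),
    alpha: float = 1.0,
    grid_step_px: int = 4,
) -> np.ndarray:
    """Warp a 2D image (or each plane of a 3D volume) by MLS controls.

    Control points move by their displacements; the inverse map needed for
    resampling is the MLS transform with source/target roles swapped,
    evaluated on a coarse grid and interpolated.  Zero displacements give
    the identity.
    """
    control_points = np.atleast_2d(np.asarray(control_points, float))
    displacements = np.atleast_2d(np.asarray(displacements, float))
    if np.allclose(displacements, 0):
        return image.astype(float).copy()
    q = control_points + displacements
    is3d = image.ndim == 3
    planes = image if is3d else image[None]
    dx, dy = spacing_xy_um
    H, W = planes.shape[1:]
    gy = np.arange(0, H + grid_step_px, grid_step_px, dtype=float)
    gx = np.arange(0, W + grid_step_px, grid_step_px, dtype=float)
    yy, xx = np.meshgrid(gy * dy, gx * dx, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    src = _mls_transform_grid(pts, q, control_points, alpha=alpha)  # backward
    src_x = src[:, 0].reshape(yy.shape) / dx
    src_y = src[:, 1].reshape(yy.shape) / dy
    # upsample the backward map to full resolution
    zoomy = ndimage.zoom(src_y, (H / src_y.shape[0], W / src_y.shape[1]), order=1)
    zoomx = ndimage.zoom(src_x, (H / src_x.shape[0], W / src_x.shape[1]), order=1)
    out = np.empty((planes.shape[0], H, W), dtype=float)
    for k in range(planes.shape[0]):
        out[k] = ndimage.map_coordinates(planes[k].astype(float),
                                         [zoomy, zoomx], order=1,
                                         mode="nearest")
    return out if is3d else out[0]


# ---------------------------------------------------------------------------
# the composed pipeline


def reconstruct_brain(
    slices: list[np.ndarray],
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    lambda_smooth: float = 0.25,
    lambda_small: float = 0.01,
    face_planes: int = 1,
    alpha: float = 2.0,
    flatten: bool = True,
    backend=None,
    control_subsample: int = 1,
    flow_kwargs: dict | None = None,
    min_warp_um: float = 0.25,
) -> dict:
    """Run the four-step reconstruction on an ordered slice stack.

    Returns a dict with the aligned ``volume`` (slices stacked along z),
    per-slice in-plane ``warp`` control tuples (points, displacements),
    the adjusted correspondence ``sets`` and per-interface residual
    metrics (median endpoint mismatch before/after, µm).
    """
    dx, dy, dz = spacing_um
    work = []
    for s in slices:
        if flatten:
            try:
                model = fit_surface(s, spacing_um)
                work.append(flatten_slice(s, model, spacing_um))
            except ValueError:
                work.append(s.astype(float))
        else:
            work.append(s.astype(float))

    sets = []
    for k in range(len(work) - 1):
        bottom_face = work[k][-face_planes:].mean(axis=0)
        top_face = work[k + 1][:face_planes].mean(axis=0)
        sets.append(extract_correspondences(bottom_face, top_face,
                                            (dx, dy), pair_id=k,
                                            backend=backend,
                                            **(flow_kwargs or {})))
    if sets:
        adjusted = adjust_correspondences(sets, lambda_smooth, lambda_small)
    else:
        adjusted = []

    warped = [work[0]]
    warps: list[tuple[np.ndarray, np.ndarray]] = [
        (np.zeros((0, 2)), np.zeros((0, 2)))]
    residuals = []
    for k, cs in enumerate(adjusted):
        if len(cs) == 0:
            warped.append(work[k + 1])
            warps.append((np.zeros((0, 2)), np.zeros((0, 2))))
            residuals.append(dict(interface=k, before_um=0.0, after_um=0.0))
            continue
        sel = slice(None, None, control_subsample)
        p_b = cs.points_b[sel]      # on the top face of slice k+1
        target = cs.points_a[sel]   # matching points on warped slice k
        if len(warps[k][0]):
            pk, dk = warps[k]
            target = _mls_transform_grid(target, pk, pk + dk, alpha=alpha)
        disp = target - p_b
        if np.median(np.linalg.norm(disp, axis=1)) < min_warp_um:
            # interface already aligned to within matcher noise
            warped.append(work[k + 1])
            warps.append((np.zeros((0, 2)), np.zeros((0, 2))))
            residuals.append(dict(interface=k,
                                  before_um=float(np.median(
                                      np.linalg.norm(sets[k].displacements, axis=1))),
                                  after_um=float(np.median(
                                      np.linalg.norm(disp, axis=1)))))
            continue
        warped.append(mls_warp(work[k + 1], p_b, disp, (dx, dy), alpha=alpha))
        warps.append((p_b, disp))
        # endpoint mismatch at this interface, before vs after warping
        before = np.linalg.norm(sets[k].displacements, axis=1)
        a_pos = cs.points_a
        if len(warps[k][0]):
            pk, dk = warps[k]
            a_pos = _mls_transform_grid(a_pos, pk, pk + dk, alpha=alpha)
        b_pos = _mls_transform_grid(cs.points_b, p_b, p_b + disp, alpha=alpha)
        after = np.linalg.norm(a_pos - b_pos, axis=1)
        residuals.append(dict(interface=k,
                              before_um=float(np.median(before)),
                              after_um=float(np.median(after))))
    volume = np.concatenate(warped, axis=0)
    return dict(volume=volume, warps=warps, sets=adjusted,
                residuals=residuals)
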