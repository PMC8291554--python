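"""Soma/nucleus detection: per-plane DoG + watershed, 3D linking, validation.

The detector follows the classic three-step scheme used for counting
fluorescently labeled cells in light-sheet volumes:

1. find local maxima of a Difference-of-Gaussians computed on the 4×
   downsized 2D plane, splitting merged maxima with a watershed;
2. around each maximum, cut a patch of side 3 × the predefined cell size
   and threshold it at the mean of the peak value and the patch-border
   mean, giving the in-plane cell area;
3. link the per-plane segments of the same cell across neighboring planes
   into a 3D record.

Each record then gets position, volume, eccentricity and mean intensity,
which are compared against predefined ranges to validate the cell.
Detection is 2D-then-link on purpose: the axial sampling (3.5 µm nominal)
is much coarser than in-plane, so 3D blob detection would mix scales.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import watershed
from skimage.transform import downscale_local_mean

__all__ = [
    "DetectorConfig",
    "dog_maxima",
    "patch_threshold",
    "watershed_segment",
    "detect_plane",
    "link_3d",
    "validate_cells",
    "detect_cells",
    "colocalize",
    "downscale_for_atlas",
    "apply_affine",
]


@dataclass
class DetectorConfig:
    """Detector parameters.

    ``cell_size_px`` is the predefined cell diameter at full resolution.
    DoG sigmas are expressed at the downsampled scale and default to
    σ1 = cell_size_px/(4√2)/downsample, σ2 = 2σ1.
    """

    cell_size_px: float = 12.0
    downsample: int = 4
    dog_sigmas: tuple[float, float] | None = None  # at downsampled scale
    noise_floor_k: float = 3.0  # maxima must exceed median + k·MAD of DoG
    volume_range_um3: tuple[float, float] = (100.0, 4000.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.95)
    intensity_range: tuple[float, float] | None = None  # None → bg + 5σ rule
    link_max_dist_um: float = 6.0
    link_min_overlap: float = 0.25  # IoU between successive-plane segments
    min_sections: int = 2

    def __post_init__(self) -> None:
        if self.dog_sigmas is None:
            # σ1 = cell_size/(4√2) full-res pixels, re-expressed at the
            # downsampled scale; σ2 = 2σ1
            s1 = self.cell_size_px / (4.0 * math.sqrt(2.0)) / self.downsample
            self.dog_sigmas = (s1, 2.0 * s1)
        s1, s2 = self.dog_sigmas
        if not 0 < s1 < s2:
            raise ValueError("require 0 < sigma1 < sigma2")
        lo, hi = self.volume_range_um3
        if lo >= hi:
            raise ValueError("volume range must be ordered")


@dataclass
class Segment:
    """One in-plane cell cross-section."""

    plane: int
    centroid_rc: tuple[float, float]  # full-res (row, col)
    area_px: int
    mean_intensity: float
    bbox: tuple[int, int, int, int]  # r0, c0, r1, c1 (half-open)
    mask: np.ndarray  # boolean, bbox-local
    peak_rc: tuple[int, int]
    clipped: bool = False


def dog_maxima(image: np.ndarray, cfg: DetectorConfig) -> list[tuple[int, int]]:
    """Local maxima of the DoG of the 4×-downsized plane, at full-res coords.

    The plane is block-mean downsampled, band-passed with G(σ1) − G(σ2),
    and strict 8-neighborhood maxima above a robust noise floor
    (median + k·MAD) are kept.  Coordinates are mapped back to full
    resolution and refined to the local argmax of the raw image.
    """
    ds = cfg.downsample
    small = downscale_local_mean(image.astype(float), (ds, ds))
    s1, s2 = cfg.dog_sigmas
    dog = ndimage.gaussian_filter(small, s1) - ndimage.gaussian_filter(small, s2)
    med = np.median(dog)
    mad = np.median(np.abs(dog - med)) + 1e-12
    floor = med + cfg.noise_floor_k * 1.4826 * mad
    footprint = np.ones((3, 3), bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(dog, footprint=footprint, mode="nearest")
    peaks = np.argwhere((dog > neigh_max) & (dog > floor))

    out = []
    half = max(ds, 2)
    for r, c in peaks:
        r0, c0 = r * ds + ds // 2, c * ds + ds // 2
        rl, rh = max(r0 - half, 0), min(r0 + half + 1, image.shape[0])
        cl, ch = max(c0 - half, 0), min(c0 + half + 1, image.shape[1])
        win = image[rl:rh, cl:ch]
        dr, dc = np.unravel_index(np.argmax(win), win.shape)
        out.append((rl + int(dr), cl + int(dc)))
    # deduplicate peaks that refined to the same full-res pixel
    return sorted(set(out))


def patch_threshold(
    image: np.ndarray, peak: tuple[int, int], cfg: DetectorConfig
) -> tuple[np.ndarray, float, tuple[int, int, int, int], bool]:
    """Threshold the 3×cell-size patch around a peak.

    The threshold is the average of the peak value and the mean of the
    one-pixel border ring of the patch — a local rule that makes the
    detected area invariant to global intensity gain.  Returns (mask,
    threshold, bbox, clipped-at-border flag).
    """
    side = int(round(3 * cfg.cell_size_px))
    half = side // 2
    r, c = peak
    r0, c0 = r - half, c - half
    r1, c1 = r0 + side, c0 + side
    clipped = r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, image.shape[0]), min(c1, image.shape[1])
    patch = image[r0:r1, c0:c1].astype(float)
    border = np.concatenate([patch[0, :], patch[-1, :], patch[1:-1, 0], patch[1:-1, -1]])
    thr = 0.5 * (float(image[r, c]) + float(border.mean()))
    mask = patch >= thr
    return mask, thr, (r0, c0, r1, c1), clipped


def watershed_segment(patch: np.ndarray, mask: np.ndarray,
                      seeds: list[tuple[int, int]]) -> np.ndarray:
    """Seeded watershed on inverted intensity, restricted to the mask.

    Returns an int label image (0 = background), one label per seed in
    order; a seed falling outside the mask yields an empty segment.
    """
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds, start=1):
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]:
            markers[r, c] = i
    markers[~mask] = 0
    if len(seeds) == 1:
        lab, _ = ndimage.label(mask)
        r, c = seeds[0]
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or lab[r, c] == 0:
            return np.zeros(mask.shape, np.int32)
        return (lab == lab[r, c]).astype(np.int32)
    return watershed(-patch.astype(float), markers=markers, mask=mask)


def detect_plane(image: np.ndarray, cfg: DetectorConfig, plane: int = 0) -> list[Segment]:
    """Run steps (i)–(ii) on one 2D plane and return its segments."""
    peaks = dog_maxima(image, cfg)
    if not peaks:
        return []
    peak_arr = np.array(peaks)
    tree = cKDTree(peak_arr)
    segments: list[Segment] = []
    side = int(round(3 * cfg.cell_size_px))
    for idx, pk in enumerate(peaks):
        mask, thr, bbox, clipped = patch_threshold(image, pk, cfg)
        r0, c0, r1, c1 = bbox
        local_peak = (pk[0] - r0, pk[1] - c0)
        if not mask[local_peak]:
            continue  # degenerate: peak at border level
        # other peaks inside this patch that share the connected component
        near = tree.query_ball_point(pk, r=side)
        seeds = [local_peak]
        for j in near:
            if j == idx:
                continue
            r, c = peak_arr[j]
            if r0 <= r < r1 and c0 <= c < c1 and mask[r - r0, c - c0]:
                seeds.append((int(r - r0), int(c - c0)))
        patch = image[r0:r1, c0:c1]
        if len(seeds) > 1:
            lab = ndimage.label(mask)[0]
            comp = lab[local_peak]
            shared = [s for s in seeds[1:] if lab[s] == comp]
            if shared:
                labels = watershed_segment(patch, mask, seeds)
                seg_mask = labels == 1
            else:
                seg_mask = lab == comp
        else:
            seg_mask = watershed_segment(patch, mask, seeds).astype(bool)
        if not seg_mask.any():
            continue
        rr, cc = np.nonzero(seg_mask)
        inten = patch[rr, cc].astype(float)
        w = inten.sum()
        centroid = (r0 + float((rr * inten).sum() / w), c0 + float((cc * inten).sum() / w))
        segments.append(Segment(plane=plane, centroid_rc=centroid,
                                area_px=int(seg_mask.sum()),
                                mean_intensity=float(inten.mean()),
                                bbox=bbox, mask=seg_mask, peak_rc=pk,
                                clipped=clipped))
    return _dedupe_segments(segments)


def _dedupe_segments(segments: list[Segment]) -> list[Segment]:
    """Drop duplicate segments whose centroids coincide (< 1 px apart)."""
    kept: list[Segment] = []
    for s in segments:
        if any(abs(s.centroid_rc[0] - k.centroid_rc[0]) < 1.0
               and abs(s.centroid_rc[1] - k.centroid_rc[1]) < 1.0 for k in kept):
            continue
        kept.append(s)
    return kept


def _segment_iou(a: Segment, b: Segment) -> float:
    r0 = max(a.bbox[0], b.bbox[0]); c0 = max(a.bbox[1], b.bbox[1])
    r1 = min(a.bbox[2], b.bbox[2]); c1 = min(a.bbox[3], b.bbox[3])
    if r0 >= r1 or c0 >= c1:
        return 0.0
    am = a.mask[r0 - a.bbox[0]:r1 - a.bbox[0], c0 - a.bbox[1]:c1 - a.bbox[1]]
    bm = b.mask[r0 - b.bbox[0]:r1 - b.bbox[0], c0 - b.bbox[1]:c1 - b.bbox[1]]
    inter = int(np.logical_and(am, bm).sum())
    if inter == 0:
        return 0.0
    union = a.mask.sum() + b.mask.sum() - inter
    return inter / union


def link_3d(
    plane_segments: list[list[Segment]],
    pixel_um: float,
    z_spacing_um: float,
    cfg: DetectorConfig,
) -> pd.DataFrame:
    """Greedy chain linking of per-plane segments into 3D cell records.

    Segments in adjacent planes are linked when their centroids are within
    ``link_max_dist_um`` and their areas overlap with IoU above
    ``link_min_overlap``; many-to-one conflicts are resolved by max IoU,
    ties by min centroid distance.  Volume is Σ area × z spacing; the
    centroid is intensity-weighted; eccentricity comes from the 3D
    second-moment ellipsoid of the (intensity-weighted) voxel cloud.
    """
    chains: list[list[Segment]] = []
    open_chains: list[int] = []
    for plane_idx, segs in enumerate(plane_segments):
        if plane_idx == 0:
            for s in segs:
                chains.append([s])
            open_chains = list(range(len(chains)))
            continue
        prev = [(ci, chains[ci][-1]) for ci in open_chains]
        candidates = []
        for si, s in enumerate(segs):
            for ci, p in prev:
                d = math.hypot(s.centroid_rc[0] - p.centroid_rc[0],
                               s.centroid_rc[1] - p.centroid_rc[1]) * pixel_um
                if d > cfg.link_max_dist_um:
                    continue
                iou = _segment_iou(s, p)
                if iou > cfg.link_min_overlap:
                    candidates.append((iou, -d, si, ci))
        candidates.sort(reverse=True)
        used_s, used_c = set(), set()
        next_open = []
        for iou, negd, si, ci in candidates:
            if si in used_s or ci in used_c:
                continue
            chains[ci].append(segs[si])
            used_s.add(si); used_c.add(ci)
            next_open.append(ci)
        for si, s in enumerate(segs):
            if si not in used_s:
                chains.append([s])
                next_open.append(len(chains) - 1)
        open_chains = next_open

    chains = [frag for chain in chains for frag in _split_chain(chain)]

    records = []
    for cid, chain in enumerate(chains):
        areas = np.array([s.area_px for s in chain], float)
        weights = np.array([s.mean_intensity * s.area_px for s in chain])
        zs = np.array([s.plane for s in chain], float) * z_spacing_um
        rs = np.array([s.centroid_rc[0] for s in chain]) * pixel_um
        cs = np.array([s.centroid_rc[1] for s in chain]) * pixel_um
        w = weights / weights.sum()
        volume = float(areas.sum()) * pixel_um * pixel_um * z_spacing_um
        records.append(dict(
            id=cid,
            x_um=float((cs * w).sum()),
            y_um=float((rs * w).sum()),
            z_um=float((zs * w).sum()),
            volume_um3=volume,
            eccentricity=_chain_eccentricity(chain, pixel_um, z_spacing_um),
            intensity=float((np.array([s.mean_intensity for s in chain]) * w).sum()),
            n_sections=len(chain),
            clipped=any(s.clipped for s in chain),
        ))
    return pd.DataFrame(records, columns=["id", "x_um", "y_um", "z_um",
                                          "volume_um3", "eccentricity",
                                          "intensity", "n_sections", "clipped"])


def _split_chain(chain: list[Segment], valley_ratio: float = 0.75,
                 min_frag: int = 2) -> list[list[Segment]]:
    """Split a chain whose axial intensity profile is multi-modal.

    Two cells stacked along z but overlapping in-plane link into a single
    chain; their summed per-plane intensity profile is bimodal while a
    single soma's is unimodal.  An interior minimum below ``valley_ratio``
    of both flanking maxima marks a cell boundary; the chain is cut there
    recursively.
    """
    if len(chain) < 2 * min_frag + 1:
        return [chain]
    prof = np.array([s.area_px * s.mean_intensity for s in chain])
    best, best_score = None, 1.0
    for k in range(min_frag, len(chain) - min_frag):
        left = prof[:k].max()
        right = prof[k + 1:].max()
        score = prof[k] / max(min(left, right), 1e-12)
        if score < best_score:
            best, best_score = k, score
    if best is None or best_score > valley_ratio:
        return [chain]
    return _split_chain(chain[:best + 1]) + _split_chain(chain[best + 1:])


def _chain_eccentricity(chain: list[Segment], pixel_um: float,
                        z_spacing_um: float) -> float:
    """√(1 − (minor/major)²) of the intensity-weighted moment ellipsoid."""
    pts, wts = [], []
    for s in chain:
        rr, cc = np.nonzero(s.mask)
        pts.append(np.column_stack([
            np.full(rr.size, s.plane * z_spacing_um),
            (rr + s.bbox[0]) * pixel_um,
            (cc + s.bbox[1]) * pixel_um,
        ]))
        wts.append(np.full(rr.size, s.mean_intensity))
    p = np.concatenate(pts)
    w = np.concatenate(wts)
    w = w / w.sum()
    mu = (p * w[:, None]).sum(axis=0)
    d = p - mu
    cov = (d * w[:, None]).T @ d
    ev = np.linalg.eigvalsh(cov)
    major = max(ev[-1], 1e-12)
    minor = max(ev[0], 0.0)
    return float(math.sqrt(max(1.0 - minor / major, 0.0)))


def validate_cells(records: pd.DataFrame, cfg: DetectorConfig,
                   background: float = 0.0, noise_sigma: float = 0.0) -> pd.DataFrame:
    """Set the ``valid`` flag: every feature inside its predefined range."""
    rec = records.copy()
    lo_v, hi_v = cfg.volume_range_um3
    lo_e, hi_e = cfg.eccentricity_range
    if cfg.intensity_range is not None:
        lo_i, hi_i = cfg.intensity_range
    else:
        lo_i, hi_i = background + 5.0 * noise_sigma, float("inf")
    ok = ((rec.volume_um3 >= lo_v) & (rec.volume_um3 <= hi_v)
          & (rec.eccentricity >= lo_e) & (rec.eccentricity <= hi_e)
          & (rec.intensity >= lo_i) & (rec.intensity <= hi_i)
          & (rec.n_sections >= cfg.min_sections))
    rec["valid"] = ok
    return rec


def detect_cells(
    volume: np.ndarray,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    cfg: DetectorConfig | None = None,
    channel: str = "",
) -> pd.DataFrame:
    """Full detector on a (z, y, x) volume; returns validated cell records.

    Positions are reported in µm in the volume frame (x = col·dx,
    y = row·dy, z = plane·dz).  ``spacing_um`` is (dx, dy, dz); in-plane
    spacing must be isotropic.
    """
    dx, dy, dz = spacing_um
    if abs(dx - dy) > 1e-9:
        raise ValueError("in-plane spacing must be isotropic")
    if cfg is None:
        cfg = DetectorConfig(cell_size_px=12.0 / dx)
    plane_segments = [detect_plane(volume[k], cfg, plane=k)
                      for k in range(volume.shape[0])]
    records = link_3d(plane_segments, pixel_um=dx, z_spacing_um=dz, cfg=cfg)
    background = float(np.median(volume))
    mad = float(np.median(np.abs(volume.astype(float) - background)))
    records = validate_cells(records, cfg, background=background,
                             noise_sigma=1.4826 * mad)
    if channel:
        records["channel"] = channel
    return records


def colocalize(records_a: pd.DataFrame, records_b: pd.DataFrame,
               radius_um: float = 6.0) -> tuple[int, int, int]:
    """Mutual-nearest-neighbor pairing of two channels within a radius.

    Returns (n_a, n_b, n_double): valid counts per channel and the number
    of mutually nearest pairs closer than ``radius_um``.
    """
    a = records_a[records_a.get("valid", True) == True]  # noqa: E712
    b = records_b[records_b.get("valid", True) == True]  # noqa: E712
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        return n_a, n_b, 0
    pa = a[["x_um", "y_um", "z_um"]].to_numpy()
    pb = b[["x_um", "y_um", "z_um"]].to_numpy()
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab, j_ab = tb.query(pa, k=1)          # nearest b for each a
    d_ba, j_ba = ta.query(pb, k=1)          # nearest a for each b
    n_double = 0
    for i in range(n_a):
        j = j_ab[i]
        if d_ab[i] <= radius_um and j_ba[j] == i:
            n_double += 1
    return n_a, n_b, n_double


def downscale_for_atlas(volume: np.ndarray,
                        spacing_um: tuple[float, float, float],
                        target_um: float = 25.0) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Block-mean downscale toward isotropic 25 µm voxels (atlas space)."""
    dx, dy, dz = spacing_um
    fz = max(int(round(target_um / dz)), 1)
    fy = max(int(round(target_um / dy)), 1)
    fx = max(int(round(target_um / dx)), 1)
    out = downscale_local_mean(volume.astype(float), (fz, fy, fx))
    return out, (dx * fx, dy * fy, dz * fz)


def apply_affine(records: pd.DataFrame, matrix: np.ndarray) -> pd.DataFrame:
    """Apply a 4×4 affine (atlas registration transform) to cell positions."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("expected a 4x4 affine matrix")
    if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
        raise ValueError("affine matrix is singular")
    rec = records.copy()
    pts = np.column_stack([rec.x_um, rec.y_um, rec.z_um, np.ones(len(rec))])
    out = pts @ matrix.T
    rec["x_um"], rec["y_um"], rec["z_um"] = out[:, 0], out[:, 1], out[:, 2]
    return rec
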