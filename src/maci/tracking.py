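"""Speckle tracking: pyramidal Lucas-Kanade point tracking and derived measures.

Speckle patterns in B-mode ultrasound are stable enough to follow
frame-by-frame.  Given a patch around a seed point in frame t, the tracker
finds the displacement (dy, dx) minimising the (uniformly weighted) sum of
squared intensity differences

    sum_window [ I(x, y, t) - I(x + dx, y + dy, t + 1) ]^2

by Gauss-Newton iteration on the linearised brightness-constancy equations,
solved coarse-to-fine over a Gaussian image pyramid so large inter-frame
motion is handled.  All points are advanced jointly with vectorised bilinear
sampling.

Derived outputs: segmented-ROI transversal displacement series (the depth
axis is the row axis), whole-image ROI grids, PCA of the tracked coordinate
table (for comparison with the wavelet-domain analysis), and the pennation
angle between three tracked points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .image_io import ImageSequence, RoiRect
from .pca import NipalsPCA
from .trajectory import ScoreTrajectory

__all__ = [
    "TrackSet",
    "DisplacementSeries",
    "PennationSeries",
    "DegenerateDataError",
    "track_points",
    "track_segmented_roi",
    "track_grid",
    "pca_of_tracks",
    "pennation_angle",
]


class DegenerateDataError(ValueError):
    """Input carries no usable variation (e.g. a static scene)."""


@dataclass
class TrackSet:
    """Tracked (row, col) positions of a set of ROIs over time.

    positions : (n_rois, n_frames, 2) subpixel coordinates; frozen at the
        last valid position once a track goes invalid.
    valid : (n_rois, n_frames) flags; monotone non-increasing over time.
    """

    positions: np.ndarray
    valid: np.ndarray
    roi_size: tuple[int, int]
    grid_shape: tuple[int, int] | None = None

    @property
    def n_rois(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def fully_valid(self) -> np.ndarray:
        """Mask of tracks valid in every frame."""
        return self.valid.all(axis=1)

    def transversal_displacement(self) -> np.ndarray:
        """(n_rois, n_frames) row-direction displacement relative to frame 0."""
        return self.positions[:, :, 0] - self.positions[:, :1, 0]


@dataclass
class DisplacementSeries:
    """Per-segment transversal displacement versus frame 0."""

    displacement_px: np.ndarray
    valid: np.ndarray
    displacement_mm: np.ndarray | None = None
    frame_rate: float | None = None


@dataclass
class PennationSeries:
    """Angle at vertex p2 between the arms to p1 and p3, per frame, degrees."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    angles_deg: np.ndarray
    valid: np.ndarray


def _pyramid_with_gradients(img: np.ndarray, levels: int):
    """Gaussian pyramid; each level carries (image, d/drow, d/dcol)."""
    out = []
    cur = img.astype(np.float64)
    for lv in range(levels):
        gy, gx = np.gradient(cur)
        out.append((cur, gy, gx))
        if lv < levels - 1:
            cur = gaussian_filter(cur, 1.0, mode="nearest")[::2, ::2]
    return out


def _sample(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return map_coordinates(
        img, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(rows.shape)


def _clamp_levels(frame_shape: tuple[int, int], window: int, levels: int) -> int:
    lv = 1
    h, w = frame_shape
    while lv < levels and min(h, w) // (2**lv) >= window + 2:
        lv += 1
    return lv


def _lk_pair(pyr_prev, pyr_next, points, window, max_iter, eps, min_eig_scale):
    """Displacement of each point from the previous frame to the next.

    Returns (displacements (N, 2), ok (N,) flags).  A point is not ok when the
    local gradient system is degenerate (low texture): smallest eigenvalue of
    the structure tensor below ``min_eig_scale * window**2``.
    """
    n_pts = points.shape[0]
    r = window // 2
    oy, ox = np.mgrid[-r : r + 1, -r : r + 1]
    oy, ox = oy.ravel()[None, :], ox.ravel()[None, :]
    levels = len(pyr_prev)
    d = np.zeros((n_pts, 2))
    ok = np.ones(n_pts, dtype=bool)
    eig_min_fine = np.zeros(n_pts)
    for lv in range(levels - 1, -1, -1):
        img_p, gy, gx = pyr_prev[lv]
        img_n = pyr_next[lv][0]
        scale = 2.0**lv
        pl = points / scale
        dl = d / scale
        rows_t = pl[:, :1] + oy
        cols_t = pl[:, 1:] + ox
        T = _sample(img_p, rows_t, cols_t)
        gys = _sample(gy, rows_t, cols_t)
        gxs = _sample(gx, rows_t, cols_t)
        gyy = np.sum(gys * gys, axis=1)
        gxy = np.sum(gys * gxs, axis=1)
        gxx = np.sum(gxs * gxs, axis=1)
        det = gyy * gxx - gxy * gxy
        solvable = det > 1e-12
        if lv == 0:
            trace = gyy + gxx
            eig_min_fine = 0.5 * (trace - np.sqrt((gyy - gxx) ** 2 + 4.0 * gxy**2))
        # refine only where the whole window fits inside this level's image:
        # border replication corrupts the gradients and can make the
        # iteration diverge, so such points keep the coarser-level estimate
        hl, wl = img_p.shape
        in_level = (
            (pl[:, 0] >= r) & (pl[:, 0] <= hl - 1 - r)
            & (pl[:, 1] >= r) & (pl[:, 1] <= wl - 1 - r)
        )
        active = solvable & in_level
        for _ in range(max_iter):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            rows_n = pl[idx, :1] + dl[idx, :1] + oy
            cols_n = pl[idx, 1:] + dl[idx, 1:] + ox
            err = _sample(img_n, rows_n, cols_n) - T[idx]
            by = np.sum(gys[idx] * err, axis=1)
            bx = np.sum(gxs[idx] * err, axis=1)
            inv_det = 1.0 / det[idx]
            dy = (-by * gxx[idx] + bx * gxy[idx]) * inv_det
            dx = (-bx * gyy[idx] + by * gxy[idx]) * inv_det
            np.clip(dy, -r, r, out=dy)  # one window per step: divergence guard
            np.clip(dx, -r, r, out=dx)
            dl[idx, 0] += dy
            dl[idx, 1] += dx
            done = np.maximum(np.abs(dy), np.abs(dx)) < eps
            active[idx[done]] = False
        d = dl * scale
    ok &= eig_min_fine >= min_eig_scale * window * window
    return d, ok


def track_points(
    seq: ImageSequence,
    seeds,
    window: int = 21,
    pyramid_levels: int = 3,
    max_iter: int = 30,
    eps: float = 0.01,
    min_eig_scale: float = 1e-4,
    grid_shape: tuple[int, int] | None = None,
) -> TrackSet:
    """Track seed points through the whole sequence, frame to frame.

    ``seeds`` is a list/array of (row, col) positions in frame 0.  A track is
    flagged invalid — and stays invalid — once its point leaves the image or
    its patch loses trackable texture.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    if seeds.size == 0:
        raise ValueError("seed list is empty")
    if seeds.ndim != 2 or seeds.shape[1] != 2:
        raise ValueError("seeds must be (n, 2) (row, col) positions")
    h, w = seq.frame_shape
    if (seeds[:, 0] < 0).any() or (seeds[:, 0] > h - 1).any() or (
        seeds[:, 1] < 0
    ).any() or (seeds[:, 1] > w - 1).any():
        raise ValueError("seeds must lie inside the frame")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    levels = _clamp_levels((h, w), window, pyramid_levels)
    n_pts, n_frames = seeds.shape[0], seq.n_frames
    positions = np.empty((n_pts, n_frames, 2))
    positions[:, 0] = seeds
    valid = np.ones((n_pts, n_frames), dtype=bool)
    pyr_prev = _pyramid_with_gradients(seq.frames[0], levels)
    for t in range(1, n_frames):
        pyr_next = _pyramid_with_gradients(seq.frames[t], levels)
        alive = valid[:, t - 1]
        positions[:, t] = positions[:, t - 1]
        valid[:, t] = alive
        if alive.any():
            idx = np.flatnonzero(alive)
            d, ok = _lk_pair(
                pyr_prev, pyr_next, positions[idx, t - 1], window, max_iter, eps, min_eig_scale
            )
            new_pos = positions[idx, t - 1] + d
            r = window // 2
            # the whole patch must stay inside the frame; a track whose
            # window crosses the border has left the trackable image
            inside = (
                (new_pos[:, 0] >= r)
                & (new_pos[:, 0] <= h - 1 - r)
                & (new_pos[:, 1] >= r)
                & (new_pos[:, 1] <= w - 1 - r)
            )
            good = ok & inside
            positions[idx[good], t] = new_pos[good]
            valid[idx[~good], t] = False
        pyr_prev = pyr_next
    return TrackSet(positions=positions, valid=valid, roi_size=(window, window), grid_shape=grid_shape)


def track_segmented_roi(
    seq: ImageSequence,
    roi: RoiRect,
    n_segments: int = 5,
    window: int = 21,
    **lk_kwargs,
) -> DisplacementSeries:
    """Transversal displacement of equal bands of a rectangular ROI.

    The ROI is split into ``n_segments`` equal bands along its long axis;
    each band's center is tracked and its row-direction displacement versus
    frame 0 is reported, in pixels and (when the sequence carries a pixel
    spacing) in mm.
    """
    if roi.row0 + roi.height > seq.height or roi.col0 + roi.width > seq.width:
        raise ValueError("ROI extends outside the frame")
    long_axis = 0 if roi.height >= roi.width else 1
    extent = roi.height if long_axis == 0 else roi.width
    if not 1 <= n_segments <= extent:
        raise ValueError(f"n_segments={n_segments} must be in [1, {extent}]")
    centers = (np.arange(n_segments) + 0.5) * extent / n_segments
    if long_axis == 0:
        seeds = np.column_stack(
            [roi.row0 + centers, np.full(n_segments, roi.col0 + roi.width / 2.0)]
        )
    else:
        seeds = np.column_stack(
            [np.full(n_segments, roi.row0 + roi.height / 2.0), roi.col0 + centers]
        )
    tracks = track_points(seq, seeds, window=window, **lk_kwargs)
    disp_px = tracks.transversal_displacement()
    disp_mm = None
    if seq.pixel_spacing is not None:
        disp_mm = disp_px * seq.pixel_spacing[0]
    return DisplacementSeries(
        displacement_px=disp_px, valid=tracks.valid, displacement_mm=disp_mm,
        frame_rate=seq.frame_rate,
    )


def track_grid(
    seq: ImageSequence,
    grid_shape: tuple[int, int] = (12, 12),
    window: int = 21,
    **lk_kwargs,
) -> TrackSet:
    """Track an equidistant rows-by-cols grid of points over the whole frame.

    Points are laid out with a margin of half a window from the borders.
    """
    rows_n, cols_n = grid_shape
    if rows_n < 1 or cols_n < 1:
        raise ValueError(f"grid_shape must be positive, got {grid_shape}")
    margin = window // 2
    h, w = seq.frame_shape
    if h - 2 * margin < rows_n or w - 2 * margin < cols_n:
        raise ValueError(
            f"grid {grid_shape} too dense for frame {h}x{w} with window {window}"
        )
    rr = np.linspace(margin, h - 1 - margin, rows_n)
    cc = np.linspace(margin, w - 1 - margin, cols_n)
    seeds = np.column_stack([g.ravel() for g in np.meshgrid(rr, cc, indexing="ij")])
    return track_points(seq, seeds, window=window, grid_shape=grid_shape, **lk_kwargs)


def pca_of_tracks(tracks: TrackSet, k: int = 2) -> tuple[NipalsPCA, ScoreTrajectory]:
    """PCA of the frames-by-coordinates table built from fully valid tracks.

    Rows are frames; columns are the (row, col) coordinates of every track
    that stayed valid for the whole sequence.  The resulting score trajectory
    is directly comparable with the wavelet-table score trajectory.
    """
    keep = tracks.fully_valid()
    if not keep.any():
        raise DegenerateDataError("no fully valid tracks to analyse")
    pos = tracks.positions[keep]  # (nv, n_frames, 2)
    M = np.concatenate([pos[:, :, 0].T, pos[:, :, 1].T], axis=1)  # frames x 2*nv
    centered = M - M.mean(axis=0)
    if np.sum(centered**2) <= 1e-10 * M.size:
        raise DegenerateDataError("tracked coordinates carry no variation (static scene)")
    model = NipalsPCA(n_components=k).fit(M)
    return model, ScoreTrajectory(model.scores_)


def pennation_angle(p1, p2, p3) -> PennationSeries:
    """Angle at vertex ``p2`` between the arms to ``p1`` and ``p3``.

    Inputs are (n_frames, 2) tracked positions (or single points).  The angle
    is computed from the normalized dot product, in degrees, in [0, 180];
    frames where either arm has zero length are flagged undefined.  Invariant
    under global rotation and scaling of the three points.
    """
    p1 = np.atleast_2d(np.asarray(p1, dtype=np.float64))
    p2 = np.atleast_2d(np.asarray(p2, dtype=np.float64))
    p3 = np.atleast_2d(np.asarray(p3, dtype=np.float64))
    if not (p1.shape == p2.shape == p3.shape) or p1.shape[1] != 2:
        raise ValueError("p1, p2, p3 must share shape (n_frames, 2)")
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    valid = (n1 > 0) & (n2 > 0)
    cosang = np.zeros(p1.shape[0])
    cosang[valid] = np.sum(v1[valid] * v2[valid], axis=1) / (n1[valid] * n2[valid])
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angles[~valid] = np.nan
    return PennationSeries(p1=p1, p2=p2, p3=p3, angles_deg=angles, valid=valid)
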