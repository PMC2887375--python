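"""Congruent wavelet feature tables from image sequences.

Each frame is decomposed with the 2-D discrete wavelet transform (default
basis: Symlet 8).  Because every frame shares the same shape and transform
configuration, each wavelet coefficient occupies the same address in every
frame — the coefficients are *congruent* — so the sequence can be unfolded
into an ordinary two-way table with frames as rows and coefficients as
columns.  The table is compressed by keeping only the coefficients with the
largest variance across frames, i.e. the ones that carry the most information
about what changes during the movement.

Coefficient flattening order (fixed so index maps are portable): the
approximation band of the deepest level first, then for each level from
deepest to shallowest the detail bands in the order diagonal, vertical,
horizontal, each band row-major.  Level numbers follow the usual convention
that the deepest (coarsest) level has the largest number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .image_io import CongruenceError, ImageSequence

__all__ = [
    "WaveletConfig",
    "CoefficientIndexMap",
    "FeatureTable",
    "WaveletImageTransformer",
    "decompose_frame",
    "build_feature_table",
]

_DETAIL_ORDER = ("diag", "vert", "horiz")  # within a level
# pywt.wavedec2 detail tuples are (horizontal, vertical, diagonal)
_PYWT_DETAIL_POS = {"horiz": 0, "vert": 1, "diag": 2}


@dataclass(frozen=True)
class WaveletConfig:
    """2-D DWT configuration: basis, decomposition depth, boundary rule."""

    basis: str = "sym8"
    levels: int = 4
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        pywt.Wavelet(self.basis)  # raises on unknown basis

    def max_levels(self, frame_shape: tuple[int, int]) -> int:
        wavelet = pywt.Wavelet(self.basis)
        return pywt.dwtn_max_level(frame_shape, wavelet)

    def validate_for_shape(self, frame_shape: tuple[int, int]) -> None:
        max_lv = self.max_levels(frame_shape)
        if self.levels > max_lv:
            raise ValueError(
                f"levels={self.levels} too deep for frame shape {frame_shape} "
                f"with basis {self.basis!r} (max {max_lv})"
            )


class CoefficientIndexMap:
    """Addresses of retained wavelet coefficients.

    Each entry is a ``(level, subband, row, col)`` address with
    ``subband in {'approx', 'horiz', 'vert', 'diag'}``.  The map also records
    the shapes of all subbands so that a coefficient vector can be scattered
    back into a full decomposition structure (used for loading images).
    """

    def __init__(
        self,
        level: np.ndarray,
        subband: np.ndarray,
        row: np.ndarray,
        col: np.ndarray,
        band_shapes: dict[str, tuple[int, int]],
        frame_shape: tuple[int, int],
    ) -> None:
        self.level = np.asarray(level, dtype=np.int32)
        self.subband = np.asarray(subband)
        self.row = np.asarray(row, dtype=np.int32)
        self.col = np.asarray(col, dtype=np.int32)
        self.band_shapes = dict(band_shapes)
        self.frame_shape = tuple(frame_shape)

    def __len__(self) -> int:
        return self.level.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoefficientIndexMap):
            return NotImplemented
        return (
            self.frame_shape == other.frame_shape
            and self.band_shapes == other.band_shapes
            and np.array_equal(self.level, other.level)
            and np.array_equal(self.subband, other.subband)
            and np.array_equal(self.row, other.row)
            and np.array_equal(self.col, other.col)
        )

    def entries(self):
        """Iterate ``(level, subband, row, col)`` tuples."""
        for lv, sb, r, c in zip(self.level, self.subband, self.row, self.col):
            yield int(lv), str(sb), int(r), int(c)

    def take(self, indices: np.ndarray) -> "CoefficientIndexMap":
        """Sub-map for the given column indices (band shapes retained)."""
        idx = np.asarray(indices)
        return CoefficientIndexMap(
            self.level[idx], self.subband[idx], self.row[idx], self.col[idx],
            self.band_shapes, self.frame_shape,
        )

    def to_dict(self) -> dict:
        return {
            "frame_shape": list(self.frame_shape),
            "band_shapes": {k: list(v) for k, v in self.band_shapes.items()},
            "level": self.level.tolist(),
            "subband": self.subband.tolist(),
            "row": self.row.tolist(),
            "col": self.col.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientIndexMap":
        return cls(
            np.asarray(d["level"]), np.asarray(d["subband"]),
            np.asarray(d["row"]), np.asarray(d["col"]),
            {k: tuple(v) for k, v in d["band_shapes"].items()},
            tuple(d["frame_shape"]),
        )


def _band_key(level: int, subband: str) -> str:
    return f"L{level}:{subband}"


@lru_cache(maxsize=32)
def _layout(frame_shape: tuple[int, int], basis: str, levels: int, mode: str):
    """Full-decomposition layout for a frame shape + config.

    Returns (full index map, list of (level, subband, shape) in flattening
    order).  Cached: the layout is identical for every congruent frame.
    """
    probe = pywt.wavedec2(np.zeros(frame_shape), basis, mode=mode, level=levels)
    order: list[tuple[int, str, tuple[int, int]]] = [(levels, "approx", probe[0].shape)]
    band_shapes = {_band_key(levels, "approx"): probe[0].shape}
    for i, details in enumerate(probe[1:]):
        level = levels - i  # wavedec2 lists details from deepest to finest
        for sb in _DETAIL_ORDER:
            shape = details[_PYWT_DETAIL_POS[sb]].shape
            order.append((level, sb, shape))
            band_shapes[_band_key(level, sb)] = shape
    lv_parts, sb_parts, r_parts, c_parts = [], [], [], []
    for level, sb, shape in order:
        rr, cc = np.unravel_index(np.arange(shape[0] * shape[1]), shape)
        lv_parts.append(np.full(rr.size, level, dtype=np.int32))
        sb_parts.append(np.full(rr.size, sb, dtype=object))
        r_parts.append(rr.astype(np.int32))
        c_parts.append(cc.astype(np.int32))
    index_map = CoefficientIndexMap(
        np.concatenate(lv_parts), np.concatenate(sb_parts),
        np.concatenate(r_parts), np.concatenate(c_parts),
        band_shapes, frame_shape,
    )
    return index_map, order


def _flatten_coeffs(coeffs, order) -> np.ndarray:
    parts = [np.asarray(coeffs[0]).ravel()]
    for details in coeffs[1:]:
        for sb in _DETAIL_ORDER:
            parts.append(np.asarray(details[_PYWT_DETAIL_POS[sb]]).ravel())
    return np.concatenate(parts)


def decompose_frame(
    frame: np.ndarray, config: WaveletConfig = WaveletConfig()
) -> tuple[np.ndarray, CoefficientIndexMap]:
    """Full 2-D DWT of one frame, flattened in the documented fixed order.

    Returns the coefficient vector and the (shared, cached) index map; two
    frames of equal shape and config get identical index maps by construction.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D, got ndim={frame.ndim}")
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite values")
    config.validate_for_shape(frame.shape)
    index_map, order = _layout(frame.shape, config.basis, config.levels, config.boundary_mode)
    coeffs = pywt.wavedec2(frame, config.basis, mode=config.boundary_mode, level=config.levels)
    return _flatten_coeffs(coeffs, order), index_map


def reconstruct_frame(
    vector: np.ndarray, index_map: CoefficientIndexMap, config: WaveletConfig
) -> np.ndarray:
    """Inverse of :func:`decompose_frame` for a *full* coefficient vector."""
    coeffs = empty_coeff_structure(index_map, config)
    offset = 0
    levels = config.levels
    # fill in flattening order
    shape = index_map.band_shapes[_band_key(levels, "approx")]
    n = shape[0] * shape[1]
    coeffs[0][:] = np.asarray(vector[offset : offset + n]).reshape(shape)
    offset += n
    for i in range(levels):
        level = levels - i
        for sb in _DETAIL_ORDER:
            shape = index_map.band_shapes[_band_key(level, sb)]
            n = shape[0] * shape[1]
            coeffs[1 + i][_PYWT_DETAIL_POS[sb]][:] = np.asarray(
                vector[offset : offset + n]
            ).reshape(shape)
            offset += n
    if offset != len(vector):
        raise ValueError(f"vector length {len(vector)} does not match layout size {offset}")
    rec = pywt.waverec2(coeffs, config.basis, mode=config.boundary_mode)
    h, w = index_map.frame_shape
    return rec[:h, :w]


def empty_coeff_structure(index_map: CoefficientIndexMap, config: WaveletConfig):
    """All-zero wavedec2-style coefficient structure matching the layout."""
    levels = config.levels
    approx = np.zeros(index_map.band_shapes[_band_key(levels, "approx")])
    coeffs = [approx]
    for i in range(levels):
        level = levels - i
        bands = [None, None, None]
        for sb in _DETAIL_ORDER:
            bands[_PYWT_DETAIL_POS[sb]] = np.zeros(index_map.band_shapes[_band_key(level, sb)])
        coeffs.append(tuple(bands))
    return coeffs


class WaveletImageTransformer(BaseEstimator, TransformerMixin):
    """Turn a stack of congruent frames into a variance-selected coefficient table.

    scikit-learn style transformer: ``fit`` decomposes every frame, ranks all
    coefficients by their sample variance across frames and memorises the
    ``n_keep`` largest-variance addresses; ``transform`` extracts those
    columns (in descending-variance order, ties broken by flattening order)
    from any stack of frames of the same shape.

    Parameters
    ----------
    basis : str, default "sym8"
        Wavelet family (Symlet 8 by default).
    levels : int, default 4
        Decomposition depth; clipped to the maximum feasible depth for the
        frame size when ``clip_levels`` is true.
    boundary_mode : str, default "symmetric"
        Signal extension rule at frame borders.
    n_keep : int, default 3000
        Number of highest-variance coefficients retained.
    """

    def __init__(
        self,
        basis: str = "sym8",
        levels: int = 4,
        boundary_mode: str = "symmetric",
        n_keep: int = 3000,
        clip_levels: bool = True,
    ) -> None:
        self.basis = basis
        self.levels = levels
        self.boundary_mode = boundary_mode
        self.n_keep = n_keep
        self.clip_levels = clip_levels

    def _frames_array(self, X) -> np.ndarray:
        frames = X.frames if isinstance(X, ImageSequence) else np.asarray(X, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError("expected a 3-D stack (n_frames, height, width)")
        return frames

    def _resolved_config(self, frame_shape: tuple[int, int]) -> WaveletConfig:
        levels = self.levels
        cfg = WaveletConfig(self.basis, levels, self.boundary_mode)
        if self.clip_levels:
            levels = min(levels, cfg.max_levels(frame_shape))
            cfg = WaveletConfig(self.basis, max(levels, 1), self.boundary_mode)
        cfg.validate_for_shape(frame_shape)
        return cfg

    def _decompose_stack(self, frames: np.ndarray, cfg: WaveletConfig):
        vec0, index_map = decompose_frame(frames[0], cfg)
        C = np.empty((frames.shape[0], vec0.size))
        C[0] = vec0
        for i in range(1, frames.shape[0]):
            C[i], _ = decompose_frame(frames[i], cfg)
        return C, index_map

    def fit(self, X, y=None) -> "WaveletImageTransformer":
        frames = self._frames_array(X)
        if frames.shape[0] < 2:
            raise ValueError("need at least 2 frames to rank coefficient variances")
        cfg = self._resolved_config(frames.shape[1:])
        C, full_map = self._decompose_stack(frames, cfg)
        if not 1 <= self.n_keep <= C.shape[1]:
            raise ValueError(
                f"n_keep={self.n_keep} outside valid range [1, {C.shape[1]}] "
                f"for frame shape {frames.shape[1:]}"
            )
        variances = C.var(axis=0, ddof=1)
        # stable argsort on -variance: descending, ties by flattening order
        selection = np.argsort(-variances, kind="stable")[: self.n_keep]
        self.config_ = cfg
        self.frame_shape_ = frames.shape[1:]
        self.selection_ = selection
        self.index_map_ = full_map.take(selection)
        self.variances_ = variances[selection]
        self.n_total_coefficients_ = C.shape[1]
        self._fit_columns = C[:, selection]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "selection_"):
            raise RuntimeError("transformer is not fitted")
        frames = self._frames_array(X)
        if frames.shape[1:] != self.frame_shape_:
            raise CongruenceError(
                f"frame shape {frames.shape[1:]} differs from fitted shape {self.frame_shape_}"
            )
        C, _ = self._decompose_stack(frames, self.config_)
        return C[:, self.selection_]

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self._fit_columns


@dataclass
class FeatureTable:
    """Frames-by-coefficients two-way table with its address book.

    ``X[i, j]`` is the value of the ``j``-th retained wavelet coefficient in
    frame ``i``; ``index_map`` maps column ``j`` back to its
    ``(level, subband, row, col)`` address.  Columns are ordered by
    descending variance across frames.
    """

    X: np.ndarray
    index_map: CoefficientIndexMap
    config: WaveletConfig
    frame_shape: tuple[int, int]
    variances: np.ndarray
    n_total_coefficients: int = 0

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.index_map):
            raise CongruenceError(
                f"table has {self.X.shape[1]} columns but index map has {len(self.index_map)} entries"
            )

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_selected(self) -> int:
        return self.X.shape[1]

    def save(self, directory: str | Path, stem: str = "features") -> None:
        """Write X as CSV (rows = frames) plus a JSON sidecar with the
        index map and config."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(self.X).to_csv(directory / f"{stem}.csv", index_label="frame")
        sidecar = {
            "config": {
                "basis": self.config.basis,
                "levels": self.config.levels,
                "boundary_mode": self.config.boundary_mode,
            },
            "frame_shape": list(self.frame_shape),
            "n_total_coefficients": self.n_total_coefficients,
            "variances": self.variances.tolist(),
            "index_map": self.index_map.to_dict(),
        }
        (directory / f"{stem}.json").write_text(json.dumps(sidecar))


def build_feature_table(
    seq: ImageSequence | np.ndarray,
    config: WaveletConfig = WaveletConfig(),
    n_keep: int = 3000,
) -> FeatureTable:
    """Decompose every frame and keep the ``n_keep`` highest-variance coefficients.

    Variance is the sample variance across frames (ddof=1); ties are broken
    by flattening order, so the selection is deterministic.  The requested
    decomposition depth is clipped to the maximum feasible for the frame
    size; the table's ``config`` records the depth actually used.
    """
    tf = WaveletImageTransformer(
        basis=config.basis, levels=config.levels, boundary_mode=config.boundary_mode,
        n_keep=n_keep, clip_levels=True,
    )
    X = tf.fit_transform(seq)
    return FeatureTable(
        X=X,
        index_map=tf.index_map_,
        config=tf.config_,
        frame_shape=tf.frame_shape_,
        variances=tf.variances_,
        n_total_coefficients=tf.n_total_coefficients_,
    )
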