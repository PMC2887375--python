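"""Loading images: project PCA loadings back into pixel space.

A loading vector lives in wavelet-coefficient space.  Placing each loading
value at its coefficient address in an otherwise-zero decomposition and
applying the inverse 2-D wavelet transform yields a *loading image* showing
which image regions drive the component.  Coefficients that were not
retained in the feature table carry no model information and are left at
zero — the reconstruction shows only what the model saw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .image_io import CongruenceError
from .pca import NipalsPCA
from .wavelet_features import FeatureTable, _PYWT_DETAIL_POS, empty_coeff_structure

__all__ = ["LoadingImage", "reconstruct_loading_image", "loading_vector_to_image", "energy_fraction"]


@dataclass
class LoadingImage:
    """Spatial reconstruction of one component's loading vector."""

    component: int
    image: np.ndarray
    energy_fraction_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.energy_fraction_map is None:
            total = np.abs(self.image).sum()
            if total > 0:
                self.energy_fraction_map = np.abs(self.image) / total


def loading_vector_to_image(vector: np.ndarray, table: FeatureTable) -> np.ndarray:
    """Scatter a coefficient-space vector into the table's addresses and invert.

    Linear by construction: the image of ``a*p1 + b*p2`` equals
    ``a*image(p1) + b*image(p2)``.
    """
    import pywt

    vector = np.asarray(vector, dtype=np.float64)
    if vector.size != len(table.index_map):
        raise CongruenceError(
            f"vector has {vector.size} entries but the index map has {len(table.index_map)}"
        )
    coeffs = empty_coeff_structure(table.index_map, table.config)
    levels = table.config.levels
    imap = table.index_map
    for j in range(vector.size):
        lv, sb, r, c = int(imap.level[j]), str(imap.subband[j]), int(imap.row[j]), int(imap.col[j])
        if sb == "approx":
            coeffs[0][r, c] = vector[j]
        else:
            coeffs[1 + (levels - lv)][_PYWT_DETAIL_POS[sb]][r, c] = vector[j]
    rec = pywt.waverec2(coeffs, table.config.basis, mode=table.config.boundary_mode)
    h, w = table.frame_shape
    return rec[:h, :w]


def reconstruct_loading_image(
    model: NipalsPCA, table: FeatureTable, component: int
) -> LoadingImage:
    """Loading image for one fitted component.

    Raises :class:`CongruenceError` when the model's variable order does not
    match the table's index map.
    """
    model._check_fitted()
    if not 0 <= component < model.k_:
        raise ValueError(f"component {component} out of range (k={model.k_})")
    if model.n_features_in_ != len(table.index_map) or model.n_features_in_ != table.X.shape[1]:
        raise CongruenceError(
            f"model has {model.n_features_in_} variables but table has "
            f"{table.X.shape[1]} columns / {len(table.index_map)} addresses"
        )
    image = loading_vector_to_image(model.components_[component], table)
    return LoadingImage(component=component, image=image)


def energy_fraction(
    image: np.ndarray, mask: np.ndarray, dilation_radius: int
) -> float:
    """Fraction of the image's absolute-value mass inside the dilated mask.

    The mask is dilated by ``dilation_radius`` pixels (square structuring
    element) before measuring, to absorb the spatial spread of the wavelet
    filters' support at the frame boundary of the region.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if dilation_radius > 0:
        size = 2 * dilation_radius + 1
        mask = binary_dilation(mask, structure=np.ones((size, size), bool))
    total = np.abs(image).sum()
    if total == 0:
        return 0.0
    return float(np.abs(image[mask]).sum() / total)
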