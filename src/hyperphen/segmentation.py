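"""Plant/background segmentation of calibrated reflectance cubes.

Vegetation is separated from the pot and background by thresholding a
normalized-difference vegetation ratio built from the near-infrared and red
bands: green tissue is bright past the red edge (~800 nm) and dark in the
chlorophyll absorption region (~670 nm), while soil, pot and backdrop are
spectrally flat.  An Otsu threshold on the NDVI image, a small morphological
opening, and a minimum component size give the final mask; its pixel count
is the projected area S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import opening as _binary_opening

from .cube_io import SpectralCube

__all__ = ["PlantMask", "segment_plant", "apply_mask"]


@dataclass
class PlantMask:
    """Boolean plant mask and its projected area (pixel count)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (rows x cols)")

    @property
    def s_pixels(self) -> int:
        """Projected area S: number of plant pixels."""
        return int(self.mask.sum())


def segment_plant(
    cube: SpectralCube,
    *,
    red_nm: float = 670.0,
    nir_nm: float = 800.0,
    ndvi_floor: float = 0.2,
    min_size: int = 50,
    opening: bool = True,
) -> PlantMask:
    """Segment the plant in a calibrated cube.

    Parameters
    ----------
    red_nm, nir_nm
        Wavelengths whose nearest bands form the vegetation ratio
        ``(NIR - red) / (NIR + red)``.
    ndvi_floor
        Absolute NDVI a pixel must exceed in addition to the Otsu split;
        guards against splitting noise on plant-free scenes.
    min_size
        Connected components smaller than this many pixels are dropped
        (stray leaves reflections, noise speckle).  Disconnected blobs at
        least this large are all retained.
    opening
        Apply a 3x3 binary opening before the size filter.

    An empty result is legal (an all-background scene): a warning is issued
    and ``s_pixels`` is 0.
    """
    red = cube.reflectance[cube.nearest_band(red_nm)]
    nir = cube.reflectance[cube.nearest_band(nir_nm)]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = nir + red
        ndvi = np.where(denom != 0, (nir - red) / np.where(denom == 0, 1, denom), 0.0)
    ndvi = np.nan_to_num(ndvi, nan=0.0)

    finite = ndvi[np.isfinite(ndvi)]
    if finite.size == 0 or np.ptp(finite) < 1e-12:
        thr = np.inf  # no contrast at all
    else:
        thr = threshold_otsu(ndvi)
    mask = (ndvi > thr) & (ndvi > ndvi_floor)
    if opening:
        mask = _binary_opening(mask, footprint=np.ones((3, 3), dtype=bool))
    if min_size > 1:
        # drop connected components smaller than min_size pixels
        lab = label(mask, connectivity=1)
        keep = np.flatnonzero(np.bincount(lab.ravel())[1:] >= min_size) + 1
        mask = np.isin(lab, keep) if keep.size else np.zeros_like(mask)
    if not mask.any():
        warnings.warn("no plant pixels found; projected area S = 0", stacklevel=2)
    return PlantMask(mask)


def apply_mask(cube: SpectralCube, mask: PlantMask | np.ndarray) -> np.ndarray:
    """Extract plant-pixel spectra from a cube.

    Returns an array of shape (n_bands, s_pixels): one column per plant
    pixel.  All downstream statistics are computed from this view so
    background and pot never leak into the indices.
    """
    m = mask.mask if isinstance(mask, PlantMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.spatial_shape:
        raise ValueError(
            f"mask shape {m.shape} does not match cube spatial shape "
            f"{cube.spatial_shape}"
        )
    return cube.reflectance[:, m]
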