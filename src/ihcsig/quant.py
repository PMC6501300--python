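"""Cell-density quantification from chromogenic IHC images.

The readout pipeline is the classical one: convert the RGB image to optical
density (Beer–Lambert), express each pixel's OD vector in a stain basis
(color deconvolution), threshold the chromogen concentration map, label
connected components with an area filter, and normalize the in-mask count by
the annotated region's area to obtain cells/mm².

Touching cells are not split (no watershed); the synthetic generator keeps
cells separated by default, and the limitation is documented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator

__all__ = [
    "StainMatrix",
    "CellDetections",
    "DensityReadout",
    "DegenerateRegionError",
    "default_stain_matrix",
    "load_stain_matrix",
    "mask_area_mm2",
    "rgb_to_optical_density",
    "unmix_stains",
    "detect_positive_cells",
    "compute_density",
    "CellDensityQuantifier",
]

#: Intensity floor used in the OD transform (see rgb_to_optical_density).
OD_EPSILON = 1.0 / 255.0

# Optical-density directions of hematoxylin and DAB (Ruifrok & Johnston).
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
DAB_OD = np.array([0.268, 0.570, 0.776])


class DegenerateRegionError(ValueError):
    """The annotation mask is empty — density is undefined."""


@dataclass(frozen=True)
class StainMatrix:
    """Three unit-norm, non-negative OD direction vectors (rows).

    Row order: stain 1 (counterstain), stain 2 (chromogen), residual.
    """

    vectors: np.ndarray
    names: tuple = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError("StainMatrix.vectors must be 3x3")
        if np.any(v < -1e-12):
            raise ValueError("StainMatrix vectors must be non-negative")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("StainMatrix rows must have unit Euclidean norm")
        if np.linalg.cond(v) > 1e8:
            raise np.linalg.LinAlgError(
                f"StainMatrix is numerically singular (condition number {np.linalg.cond(v):.3g})"
            )
        object.__setattr__(self, "vectors", v)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def default_stain_matrix(
    stain1: np.ndarray = HEMATOXYLIN_OD, stain2: np.ndarray = DAB_OD
) -> StainMatrix:
    """Hematoxylin/DAB basis with a complement residual vector.

    The residual is the classic color-deconvolution third channel
    ``sqrt(max(0, 1 - v1_i^2 - v2_i^2))`` per component, normalized — it is
    non-negative by construction and keeps the matrix well conditioned.
    """
    v1 = np.asarray(stain1, float)
    v2 = np.asarray(stain2, float)
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 / np.linalg.norm(v2)
    res = np.sqrt(np.clip(1.0 - v1**2 - v2**2, 0.0, None))
    n = np.linalg.norm(res)
    if n == 0:
        raise ValueError("degenerate stain pair: residual vector is zero")
    return StainMatrix(vectors=np.vstack([v1, v2, res / n]))


def load_stain_matrix(path) -> StainMatrix:
    """Read a 3x3 stain matrix (rows = OD vectors) from CSV."""
    arr = np.loadtxt(path, delimiter=",")
    return StainMatrix(vectors=arr)


def rgb_to_optical_density(
    image: np.ndarray, background_intensity: float = 255.0, eps: float = OD_EPSILON
) -> np.ndarray:
    """Beer–Lambert transform: OD = -log10(max(pixel, eps) / background).

    ``eps`` (default 1/255) floors the intensity so zero pixels stay finite;
    the result is clipped at 0 so intensities above background carry no
    negative absorbance. Accepts uint8 images or float arrays with values on
    the 0–255 scale.
    """
    if background_intensity <= 0:
        raise ValueError("background_intensity must be > 0")
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        arr = arr.astype(float)
    elif not np.issubdtype(arr.dtype, np.floating):
        raise TypeError(f"expected 8-bit or float image, got dtype {arr.dtype}")
    od = -np.log10(np.maximum(arr, eps) / background_intensity)
    return np.clip(od, 0.0, None)


def unmix_stains(od: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Express each pixel's OD vector in the stain basis.

    Solves ``od = conc @ M`` (rows of ``M`` are the stain vectors) per pixel
    and clips negative concentrations to 0. Returns an array of the same
    leading shape with the last axis indexing stains.
    """
    m = stains.vectors
    cond = np.linalg.cond(m)
    if cond > 1e8:
        raise np.linalg.LinAlgError(
            f"stain matrix numerically singular (condition number {cond:.3g})"
        )
    od = np.asarray(od, dtype=float)
    conc = od @ np.linalg.inv(m)
    return np.clip(conc, 0.0, None)


@dataclass(frozen=True)
class CellDetections:
    """Connected-component detections in one concentration map."""

    centroids: tuple
    count: int
    per_object_area_px: tuple

    def __post_init__(self) -> None:
        if self.count != len(self.centroids):
            raise ValueError("count must equal number of centroids")


def detect_positive_cells(
    concentration_map: np.ndarray,
    threshold: float,
    area_min_px: float,
    area_max_px: float,
) -> CellDetections:
    """Threshold, label 8-connected components, keep areas in [min, max]."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not (0 < area_min_px < area_max_px):
        raise ValueError("require 0 < area_min_px < area_max_px")
    binary = np.asarray(concentration_map) >= threshold
    labels = measure.label(binary, connectivity=2)
    cents, areas = [], []
    for region in measure.regionprops(labels):
        if area_min_px <= region.area <= area_max_px:
            cents.append((float(region.centroid[0]), float(region.centroid[1])))
            areas.append(int(region.area))
    return CellDetections(centroids=tuple(cents), count=len(cents), per_object_area_px=tuple(areas))


def mask_area_mm2(mask: np.ndarray, microns_per_pixel: float) -> float:
    """Area of the true pixels in mm²."""
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    return float(np.count_nonzero(mask)) * (microns_per_pixel / 1000.0) ** 2


@dataclass(frozen=True)
class DensityReadout:
    count: int
    area_mm2: float
    density: float


def compute_density(
    detections: CellDetections, mask: np.ndarray, microns_per_pixel: float
) -> DensityReadout:
    """Count centroids inside the mask and normalize by its area in mm²."""
    mask = np.asarray(mask).astype(bool)
    area = mask_area_mm2(mask, microns_per_pixel)
    if area <= 0:
        raise DegenerateRegionError("annotation mask is empty; density undefined")
    h, w = mask.shape
    n_in = 0
    for row, col in detections.centroids:
        r, c = int(round(row)), int(round(col))
        if 0 <= r < h and 0 <= c < w and mask[r, c]:
            n_in += 1
    return DensityReadout(count=n_in, area_mm2=area, density=n_in / area)


class CellDensityQuantifier(BaseEstimator):
    """End-to-end quantifier: RGB image + mask -> cells/mm².

    Parameters
    ----------
    stain : str
        Which stain-basis channel to read ("dab" or "hematoxylin").
    threshold : float
        Concentration threshold (OD units) for positivity.
    area_min_px, area_max_px : float
        Connected-component area gate in pixels.
    background_intensity : float
        Blank-slide intensity for the OD transform.
    stain_matrix : StainMatrix or None
        Custom basis; default hematoxylin/DAB.
    """

    def __init__(
        self,
        stain: str = "dab",
        threshold: float = 0.3,
        area_min_px: float = 20.0,
        area_max_px: float = 2000.0,
        background_intensity: float = 255.0,
        stain_matrix: StainMatrix | None = None,
    ):
        self.stain = stain
        self.threshold = threshold
        self.area_min_px = area_min_px
        self.area_max_px = area_max_px
        self.background_intensity = background_intensity
        self.stain_matrix = stain_matrix

    def detect(self, image: np.ndarray) -> CellDetections:
        stains = self.stain_matrix or default_stain_matrix()
        od = rgb_to_optical_density(image, self.background_intensity)
        conc = unmix_stains(od, stains)[..., stains.index_of(self.stain)]
        return detect_positive_cells(conc, self.threshold, self.area_min_px, self.area_max_px)

    def quantify(
        self, image: np.ndarray, mask: np.ndarray, microns_per_pixel: float
    ) -> DensityReadout:
        return compute_density(self.detect(image), mask, microns_per_pixel)
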