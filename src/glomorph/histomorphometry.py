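"""Per-glomerulus measurements from stained tiles.

Operations mirror the manual protocol used on PAS / Masson-trichrome
sections: the tuft is circumscribed by its minimal convex polygon (GLA),
the PAS-positive area inside it is the mesangial area (MEA), the
trichrome blue/green area is the sclerosis/collagen area, and mesangial
cellularity (MEC) is the number of nuclei inside MEA.  Tuft profiles per
field of view feed the numerical-density estimator.

Stain quantification uses fixed-matrix colour deconvolution followed by
an Otsu threshold on the target optical-density channel (with a floor so
blank tiles yield zero), restricted to the polygon interior.  Pixel
coordinates are 0-based row-major; mask areas are pixel counts times the
squared pixel size, while GLA uses the analytic hull area over pixel
corners so a solid w x h rectangle measures exactly w*h pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure
from skimage.color import separate_stains
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .stain_model import stain_matrix_inverse

DEFAULT_PIXEL_SIZE_UM = 0.25  # x400 acquisition

#: accepted nucleus blob area band, um^2 (excludes debris and clusters)
NUCLEUS_AREA_BAND_UM2 = (10.0, 80.0)

#: minimum optical density for a pixel to count as stained at all; keeps
#: the Otsu threshold from splitting noise on unstained tiles
OD_FLOOR = {"hematoxylin": 0.20, "pas_positive": 0.15, "collagen": 0.15}


@dataclass(frozen=True)
class GlomerulusProfile:
    """2-D measurements of one sectioned glomerulus."""

    gla_um2: float
    mea_um2: float
    mec_count: int
    collagen_um2: float
    sclerosis_fraction: float
    deposit_class: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mea_um2 <= self.gla_um2:
            raise ValueError("MEA must lie in [0, GLA]")
        if not 0.0 <= self.collagen_um2 <= self.gla_um2:
            raise ValueError("collagen area must lie in [0, GLA]")
        if not 0.0 <= self.sclerosis_fraction <= 1.0:
            raise ValueError("sclerosis_fraction must lie in [0, 1]")
        if self.mec_count < 0:
            raise ValueError("MEC must be non-negative")


@dataclass(frozen=True)
class FieldCount:
    """Tuft profile count over one field of view."""

    n_a: int
    area_um2: float

    def __post_init__(self) -> None:
        if self.n_a < 0:
            raise ValueError("count must be non-negative")
        if self.area_um2 <= 0:
            raise ValueError("field area must be positive")


def trace_tuft(tuft_mask: np.ndarray,
               pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> tuple[np.ndarray, float]:
    """Minimal convex polygon circumscribing a tuft mask.

    Returns ``(polygon, gla)`` where ``polygon`` is an (m, 2) array of hull
    vertices in um (row, col order) and ``gla`` the hull area in um^2.
    The hull is taken over pixel corners, so the area of a solid raster
    shape is at least its pixel area.
    """
    mask = np.asarray(tuft_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tuft mask")
    n_comp = int(skmeasure.label(mask, connectivity=2).max())
    if n_comp > 1:
        raise ValueError(
            f"mask holds {n_comp} connected components; split before tracing")
    rr, cc = np.nonzero(mask)
    pts = np.stack([rr, cc], axis=1).astype(float)
    corners = np.concatenate([pts + d for d in
                              ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])])
    hull = ConvexHull(corners)
    polygon = corners[hull.vertices] * pixel_size
    gla = hull.volume * pixel_size ** 2  # ConvexHull 'volume' is area in 2-D
    return polygon, float(gla)


def _polygon_mask(polygon_or_mask, shape: tuple[int, int],
                  pixel_size: float) -> np.ndarray:
    arr = np.asarray(polygon_or_mask)
    if arr.dtype == bool and arr.shape == shape:
        return arr
    poly_px = arr / pixel_size
    if (poly_px < -0.5).any() or (poly_px[:, 0] > shape[0] - 0.5).any() \
            or (poly_px[:, 1] > shape[1] - 0.5).any():
        raise ValueError("polygon extends outside the tile")
    return polygon2mask(shape, poly_px)


def _od_channel(tile: np.ndarray, stain_target: str) -> np.ndarray:
    """Deconvolved optical-density channel for the requested stain."""
    if stain_target in ("pas_positive", "deposit"):
        inv, channel = stain_matrix_inverse("pas"), 1
    elif stain_target == "collagen":
        inv, channel = stain_matrix_inverse("trichrome"), 1
    elif stain_target == "hematoxylin_pas":
        inv, channel = stain_matrix_inverse("pas"), 0
    elif stain_target == "hematoxylin_trichrome":
        inv, channel = stain_matrix_inverse("trichrome"), 0
    else:
        raise ValueError(f"unknown stain target {stain_target!r}")
    od = separate_stains(tile, inv)
    # separate_stains scales optical density by 1/log(1e6); undo so the
    # channel is in the natural-OD units of the shared stain model
    return od[..., channel] * np.log(1e6)


def measure_stain_area(tile: np.ndarray, polygon, stain_target: str,
                       pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Stain-positive area (um^2) inside the polygon.

    ``stain_target`` is ``"pas_positive"`` (mesangium on a PAS tile) or
    ``"collagen"`` (blue/green on a trichrome tile).  Deterministic for a
    fixed tile and configuration.
    """
    if stain_target not in ("pas_positive", "collagen"):
        raise ValueError(f"unknown stain target {stain_target!r}")
    roi = _polygon_mask(polygon, tile.shape[:2], pixel_size)
    od = _od_channel(tile, stain_target)
    floor = OD_FLOOR[stain_target]
    vals = od[roi]
    if vals.size == 0 or vals.max() <= floor:
        return 0.0
    try:
        thresh = max(threshold_otsu(vals), floor)
    except ValueError:  # uniform ROI
        thresh = floor
    positive = (od > thresh) & roi
    return float(positive.sum()) * pixel_size ** 2


def count_mesangial_nuclei(tile: np.ndarray, mesangial_mask: np.ndarray,
                           pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                           stain: str = "pas") -> int:
    """Number of nucleus blobs whose centroid falls inside the mesangium.

    Nuclei are the dark hematoxylin blobs passing the size band; touching
    nuclei are split by a distance-transform watershed.
    """
    mask = np.asarray(mesangial_mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty mesangial mask; MEC = 0", stacklevel=2)
        return 0
    od = _od_channel(tile, f"hematoxylin_{stain}")
    floor = OD_FLOOR["hematoxylin"]
    vals = od[od > 0]
    if vals.size == 0 or od.max() <= floor:
        return 0
    try:
        thresh = max(threshold_otsu(od), floor)
    except ValueError:
        thresh = floor
    binary = od > thresh
    distance = ndimage.distance_transform_edt(binary)
    # peaks at least one nucleus radius apart seed the watershed
    min_dist = max(int(round(1.5 / pixel_size)), 1)
    footprint = np.ones((2 * min_dist + 1, 2 * min_dist + 1), dtype=bool)
    maxima = (distance == ndimage.maximum_filter(distance, footprint=footprint)) \
        & (distance > 0.5)
    markers, _ = ndimage.label(maxima)
    labels = watershed(-distance, markers, mask=binary)
    lo, hi = NUCLEUS_AREA_BAND_UM2
    count = 0
    for region in skmeasure.regionprops(labels):
        area = region.area * pixel_size ** 2
        if not lo <= area <= hi:
            continue
        r, c = (int(round(x)) for x in region.centroid)
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
            count += 1
    return count


def count_profiles_in_field(field_mask: np.ndarray,
                            field_area: float) -> FieldCount:
    """Tuft profiles per field under the unbiased counting-frame rule.

    Each distinct label is counted once; labels touching the exclusion
    edges (bottom or right) are omitted, labels touching the inclusion
    edges (top or left) are kept, which prevents overcounting across
    adjacent fields.
    """
    if field_area <= 0:
        raise ValueError("field area must be positive")
    labels = np.asarray(field_mask)
    present = np.unique(labels)
    present = present[present > 0]
    excluded = set(np.unique(labels[-1, :])) | set(np.unique(labels[:, -1]))
    n_a = int(sum(1 for lab in present if lab not in excluded))
    return FieldCount(n_a=n_a, area_um2=float(field_area))
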