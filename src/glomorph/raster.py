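"""Synthetic PAS / trichrome tile rendering with ground-truth masks.

Tiles are deliberately schematic, not photorealistic: a circular tuft,
a blobby mesangial compartment painted with the PAS-positive stain
vector, a collagen compartment painted blue/green on trichrome, hyaline
deposits painted red in BOTH stains, and nuclei as compact hematoxylin
blobs.  Compartment masks are thresholded noise fields cut at the exact
quantile, so the painted areal fractions hit their targets to the pixel
and the recorded truth areas equal the mask areas exactly.  The renderer
shares its stain matrix with the segmentation module, which makes the
render -> measure round trip a closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stain_model import od_to_rgb

DEFAULT_PIXEL_SIZE_UM = 0.25

#: OD amount painted per compartment, per stain
_STAIN_AMOUNTS = {
    "pas": {"mesangium": 1.0, "collagen": 0.30, "deposit": 1.2, "nuclei": 1.0},
    "trichrome": {"mesangium": 0.0, "collagen": 1.0, "deposit": 1.2, "nuclei": 1.0},
}
#: trichrome stains cytoplasm red; deposits add to the same red channel
_TRICHROME_CYTOPLASM_RED = 0.45

#: additive OD noise, small enough not to perturb Otsu segmentation
_OD_NOISE_SD = 0.02

_NUCLEUS_RADIUS_UM = (1.9, 2.6)


@dataclass
class RasterizedProfile:
    """Rendered tile plus per-compartment truth masks and recorded areas."""

    tile: np.ndarray
    masks: dict = field(repr=False, default_factory=dict)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    truth_areas_um2: dict = field(default_factory=dict)
    stain: str = "pas"


def _noise_blob_mask(shape, inside: np.ndarray, fraction: float,
                     rng: np.random.Generator, smooth_px: float) -> np.ndarray:
    """Smoothed-noise region covering an exact pixel fraction of ``inside``."""
    n_target = int(round(fraction * inside.sum()))
    if n_target <= 0:
        return np.zeros(shape, dtype=bool)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_px)
    vals = noise[inside]
    cutoff = np.sort(vals)[::-1][min(n_target, vals.size) - 1]
    mask = np.zeros(shape, dtype=bool)
    mask[inside] = noise[inside] >= cutoff
    # quantile ties can overshoot by a pixel or two; trim deterministically
    extra = int(mask.sum()) - n_target
    if extra > 0:
        rr, cc = np.nonzero(mask)
        order = np.argsort(noise[rr, cc])
        mask[rr[order[:extra]], cc[order[:extra]]] = False
    return mask


def _place_nuclei(inside: np.ndarray, count: int, rng: np.random.Generator,
                  pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Labelled nucleus disks with centroids inside ``inside``."""
    labels = np.zeros(inside.shape, dtype=np.int32)
    if count <= 0 or not inside.any():
        return labels, labels > 0
    rr_in, cc_in = np.nonzero(inside)
    taken: list[tuple[int, int, float]] = []
    yy, xx = np.mgrid[0:inside.shape[0], 0:inside.shape[1]]
    lab = 0
    attempts = 0
    while lab < count and attempts < count * 60:
        attempts += 1
        k = rng.integers(rr_in.size)
        r0, c0 = int(rr_in[k]), int(cc_in[k])
        rad = rng.uniform(*_NUCLEUS_RADIUS_UM) / pixel_size
        # keep centres separated so blobs stay countable (mild overlap ok)
        if any((r0 - r) ** 2 + (c0 - c) ** 2 < (0.9 * (rad + prev)) ** 2
               for r, c, prev in taken):
            continue
        lab += 1
        disk = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad ** 2
        labels[disk & (labels == 0)] = lab
        taken.append((r0, c0, rad))
    return labels, labels > 0


def rasterize_section(profile, stain: str = "pas",
                      pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                      seed: int = 0,
                      deposit_fraction: float = 0.12) -> RasterizedProfile:
    """Render one glomerulus profile as an RGB tile with truth masks.

    ``profile`` is a mapping (e.g. a measurement-table row) with
    ``gla_um2``, ``mea_um2``, ``collagen_um2``, ``mec_count`` and
    optionally ``deposit_class``.  The same profile rendered under "pas"
    and "trichrome" shares the geometry seed, mimicking serial sections.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if stain not in ("pas", "trichrome"):
        raise ValueError(f"unknown stain {stain!r}")
    gla = float(profile["gla_um2"])
    mes_fraction = float(profile["mea_um2"]) / gla
    col_fraction = float(profile["collagen_um2"]) / gla
    mec = int(profile["mec_count"])
    deposit_class = str(profile.get("deposit_class", "none")) \
        if hasattr(profile, "get") else str(profile["deposit_class"])

    geom_rng = np.random.default_rng(seed)          # shared across stains
    render_rng = np.random.default_rng((seed, 0 if stain == "pas" else 1))

    radius_px = np.sqrt(gla / np.pi) / pixel_size
    margin = 14
    size = int(np.ceil(2 * radius_px)) + 2 * margin
    yy, xx = np.mgrid[0:size, 0:size]
    c0 = size / 2 - 0.5
    tuft = (yy - c0) ** 2 + (xx - c0) ** 2 <= radius_px ** 2

    smooth = max(radius_px / 6.0, 2.0)
    mesangium = _noise_blob_mask((size, size), tuft, mes_fraction, geom_rng, smooth)
    collagen = _noise_blob_mask((size, size), tuft, col_fraction, geom_rng, smooth)
    deposit = _noise_blob_mask((size, size), tuft, deposit_fraction, geom_rng,
                               smooth * 1.5) if deposit_class != "none" \
        else np.zeros((size, size), dtype=bool)
    nuclei_labels, nuclei = _place_nuclei(
        mesangium if mesangium.any() else tuft, mec, geom_rng, pixel_size)

    amounts = _STAIN_AMOUNTS[stain]
    od = np.zeros((size, size, 3))
    od[..., 0] = amounts["nuclei"] * nuclei
    od[..., 1] += amounts["mesangium"] * mesangium
    od[..., 1] += amounts["collagen"] * collagen
    if stain == "pas":
        od[..., 1] += amounts["deposit"] * deposit
    else:
        od[..., 2] = _TRICHROME_CYTOPLASM_RED * (tuft & ~collagen & ~nuclei)
        od[..., 2] += amounts["deposit"] * deposit
    od += _OD_NOISE_SD * np.abs(render_rng.standard_normal(od.shape))

    tile = od_to_rgb(od, stain)
    masks = {"tuft": tuft, "mesangium": mesangium, "collagen": collagen,
             "deposit": deposit, "nuclei": nuclei_labels}
    px2 = pixel_size ** 2
    truth = {name: float(np.count_nonzero(m)) * px2
             for name, m in masks.items() if name != "nuclei"}
    truth["nuclei_count"] = float(nuclei_labels.max())
    return RasterizedProfile(tile=tile, masks=masks, pixel_size=pixel_size,
                             truth_areas_um2=truth, stain=stain)
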