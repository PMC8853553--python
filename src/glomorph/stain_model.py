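"""Shared stain colour model for rasterization and segmentation.

Both the synthetic tile renderer and the measurement module work in
optical density (Beer-Lambert): RGB = 255 * exp(-OD @ M), where each row
of M is the unit absorbance vector of one stain.  Using one fixed matrix
in both directions makes the render -> segment round trip a testable
property rather than an act of faith.

Channel order per stain:
  pas:       0 hematoxylin (nuclei), 1 PAS-positive magenta
             (mesangium, hyaline deposits), 2 residual counterstain
  trichrome: 0 hematoxylin, 1 aniline blue/green (collagen),
             2 red (cytoplasm and hyaline deposits)
"""

from __future__ import annotations

import numpy as np


def _unit_rows(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=1, keepdims=True)


STAIN_MATRICES: dict[str, np.ndarray] = {
    # hematoxylin / PAS-magenta / residual (eosin-like) absorbance vectors
    "pas": _unit_rows(np.array([
        [0.65, 0.70, 0.29],
        [0.07, 0.99, 0.11],
        [0.27, 0.57, 0.78],
    ])),
    # hematoxylin / collagen blue-green / red absorbance vectors
    "trichrome": _unit_rows(np.array([
        [0.65, 0.70, 0.29],
        [0.85, 0.47, 0.22],
        [0.05, 0.70, 0.71],
    ])),
}


def stain_matrix(stain: str) -> np.ndarray:
    try:
        return STAIN_MATRICES[stain]
    except KeyError:
        raise ValueError(
            f"unknown stain {stain!r}; expected one of {list(STAIN_MATRICES)}"
        ) from None


def stain_matrix_inverse(stain: str) -> np.ndarray:
    """Inverse matrix as consumed by skimage.color.separate_stains."""
    return np.linalg.inv(stain_matrix(stain))


def od_to_rgb(od: np.ndarray, stain: str) -> np.ndarray:
    """Compose an 8-bit RGB tile from per-stain OD amounts (H, W, 3)."""
    rgb = 255.0 * np.exp(-od @ stain_matrix(stain))
    return np.clip(rgb, 0, 255).astype(np.uint8)
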