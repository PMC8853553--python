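"""Simulated counting fields for numerical-density estimation.

The number of tuft profiles seen in a 2-D field of area A drawn through a
suspension of spheres with number density Nv and mean diameter D is
Poisson with mean Nv * D * A (every sphere whose centre lies within D/2
of the section plane leaves a profile).  The generator uses the same mean
tuft diameter the density estimator later divides by, so the estimator is
consistent by construction.
"""

from __future__ import annotations

import math

import numpy as np

from .histomorphometry import FieldCount
from .population import expected_mean_section_area
from .presets import GroupPreset
from .sectioning import MORPHOMETRY_OFFSET_FRACTION

#: default field of view at x100 magnification, um^2
DEFAULT_FIELD_AREA_UM2 = 2.0e6


def expected_count_per_field(preset: GroupPreset,
                             field_area: float = DEFAULT_FIELD_AREA_UM2,
                             offset_fraction: float = MORPHOMETRY_OFFSET_FRACTION) -> float:
    """Expected tuft profiles per field for a preset group."""
    nv_per_um3 = preset.baseline.nv_per_mm3 * preset.nv_multiplier * 1e-9
    mean_gla = expected_mean_section_area(preset, offset_fraction=offset_fraction)
    mean_diameter = math.sqrt(4.0 * mean_gla / math.pi)
    return nv_per_um3 * mean_diameter * field_area


def generate_field_counts(preset: GroupPreset, n_fields: int,
                          field_area: float = DEFAULT_FIELD_AREA_UM2,
                          seed: int = 1,
                          expectation: float | None = None) -> list[FieldCount]:
    """Poisson tuft counts over ``n_fields`` fields of view.

    ``expectation`` overrides the preset-derived mean count per field
    (useful for calibration experiments).
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if field_area <= 0:
        raise ValueError("field area must be positive")
    lam = expectation if expectation is not None \
        else expected_count_per_field(preset, field_area)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=n_fields)
    return [FieldCount(n_a=int(c), area_um2=float(field_area)) for c in counts]
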