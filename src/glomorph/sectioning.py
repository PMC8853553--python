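"""Random plane sectioning of virtual glomerulus populations.

Each tuft (a sphere of radius R) is cut by one random plane.  With the
plane offset uniform over the full extent [0, R] and isotropic
orientation, the mean profile area converges to (2/3) pi R^2 — the basis
of the shape-coefficient calibration (beta = V / E[A]^1.5 = 1.382 for
spheres).  The cohort morphometry protocol instead samples a
near-equatorial window (offset uniform in [0, 0.25 R]), emulating the
selection of profiles with visible macula densa and arterioles; grazing
sections below 5% of the expected great-circle area are discarded in the
full-extent mode as unrecognizable.

Measurements attached to each profile follow the stereological identity
(areal fraction = volume fraction): MEA and collagen area are the
glomerulus's volume fractions applied to the profile area, and the
nuclei count is Poisson with mean nuclei_density x MEA x thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import Glomerulus3D, SECTION_THICKNESS_UM, generate_population
from .presets import GroupPreset

#: relative offset window of the cohort sampling protocol (near-equatorial)
MORPHOMETRY_OFFSET_FRACTION = 0.25

#: grazing sections below this fraction of the expected great-circle area
#: are unrecognizable and discarded (full-extent mode)
MIN_AREA_FRACTION = 0.05

#: number of profiles imaged per kidney (20-30 per the sampling protocol)
PROFILES_PER_KIDNEY = 30

MEASUREMENT_COLUMNS = [
    "profile_id", "group", "kidney_id", "gla_um2", "mea_um2", "mec_count",
    "collagen_um2", "sclerosis_fraction", "deposit_class", "truth_size_class",
    "pas_deposit", "trichrome_colour",
]


@dataclass
class SyntheticSection:
    """Profiles emitted by sectioning one population, with ground truth."""

    profiles: pd.DataFrame
    glomeruli: list[Glomerulus3D]
    offset_fraction: float
    field_area_um2: float | None = None
    truth_masks: dict | None = field(default=None, repr=False)


def _deposit_columns(lesion: str) -> tuple[str, bool, str, ]:
    """Map a generative lesion label to stain observations.

    Hyaline deposits stain red in BOTH PAS and trichrome; sclerotic
    (collagenous) deposits are PAS-red but trichrome blue/green.
    """
    if lesion == "hyalinosis":
        return "hyalinosis", True, "red"
    if lesion in ("fsgs", "ggs"):
        return "sclerosis", True, "blue_green"
    return "none", False, "none"


def section_population(population: list[Glomerulus3D], seed: int,
                       offset_fraction: float = 1.0,
                       min_area_fraction: float = MIN_AREA_FRACTION,
                       group: str = "",
                       thickness_um: float = SECTION_THICKNESS_UM) -> SyntheticSection:
    """Cut every glomerulus with one random plane and measure the profiles.

    offset_fraction:
        plane offset is uniform in [0, offset_fraction * R].  1.0 is fully
        random sectioning; 0.0 forces the plane through the centre (great
        circle); the cohort protocol uses MORPHOMETRY_OFFSET_FRACTION.
    min_area_fraction:
        grazing-section cutoff relative to the population's expected
        great-circle area; set to 0 to keep every profile.
    """
    if not population:
        raise ValueError("empty population")
    if not 0.0 <= offset_fraction <= 1.0:
        raise ValueError("offset_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    radii = np.array([g.radius for g in population])
    offsets = offset_fraction * radii * rng.uniform(size=len(population))
    areas = math.pi * (radii ** 2 - offsets ** 2)

    keep = areas >= min_area_fraction * math.pi * np.mean(radii ** 2)
    mes_frac = np.array([g.mesangial_fraction for g in population])
    col_frac = np.array([g.collagen_fraction for g in population])
    rho = np.array([g.nuclei_density for g in population])

    mea = mes_frac * areas
    collagen = col_frac * areas
    mec = rng.poisson(rho * mea * thickness_um)

    rows = []
    pid = 0
    for i, glom in enumerate(population):
        if not keep[i]:
            continue
        deposit, pas_pos, tri_col = _deposit_columns(glom.lesion_label)
        if glom.lesion_label == "fsgs":
            scl = rng.uniform(0.10, 0.50)
        elif glom.lesion_label == "ggs":
            scl = rng.uniform(0.55, 0.90)
        else:
            scl = 0.0
        rows.append((
            pid, group, i // PROFILES_PER_KIDNEY,
            float(areas[i]), float(mea[i]), int(mec[i]), float(collagen[i]),
            float(scl), deposit, glom.size_class_truth, bool(pas_pos), tri_col,
        ))
        pid += 1
    profiles = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return SyntheticSection(profiles=profiles, glomeruli=list(population),
                            offset_fraction=offset_fraction)


def simulate_cohort(preset: GroupPreset, n: int, seed: int,
                    offset_fraction: float = MORPHOMETRY_OFFSET_FRACTION) -> pd.DataFrame:
    """Generate a group cohort measurement table under the sampling protocol.

    Convenience wrapper: population draw followed by near-equatorial
    sectioning; the grazing cutoff never triggers inside the equatorial
    window.  Returns the per-profile measurement table (CSV schema).
    """
    population = generate_population(preset, n, seed)
    section = section_population(
        population, seed=seed + 1, offset_fraction=offset_fraction,
        min_area_fraction=0.0, group=preset.name)
    return section.profiles


def calibrate_shape_coefficient(n_sections: int = 100_000, seed: int = 0,
                                radius: float = 1.0) -> float:
    """Monte-Carlo estimate of the sphere shape coefficient beta.

    Sections a single sphere with ``n_sections`` uniformly random planes
    (offset uniform over the full extent, no grazing cutoff) and returns
    V_true / E[A]^1.5.  Closed form: (4 pi/3) / ((2/3) pi)^1.5 = 1.382.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = radius * rng.uniform(size=n_sections)
    areas = math.pi * (radius ** 2 - offsets ** 2)
    v_true = 4.0 / 3.0 * math.pi * radius ** 3
    return float(v_true / np.mean(areas) ** 1.5)
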