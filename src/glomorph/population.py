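"""Virtual 3-D glomerulus populations.

Glomerular tufts are modeled as spheres whose radius is lognormal within
each size class (normal / hypertrophic / ischemic).  The size-distribution
coefficient used downstream (kappa = 1.01) assumes a nearly monodisperse
population, so the within-class log-volume SD defaults to 0.10.

Compartment composition is carried as volume fractions; by the standard
stereological identity the same fractions reappear as areal fractions on
random sections, which is how the section generator uses them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .presets import GroupPreset, LESION_LABELS, SIZE_CLASSES

#: within-class SD of log tuft volume (kappa=1.01 implies near-monodisperse)
LOG_VOLUME_SD = 0.10

#: histological section thickness, um
SECTION_THICKNESS_UM = 4.0

#: SD of the per-glomerulus jitter on the mesangial volume fraction
MESANGIAL_FRACTION_JITTER = 0.03


@dataclass(frozen=True)
class Glomerulus3D:
    """One virtual glomerular tuft.

    radius:
        tuft sphere radius, um.
    mesangial_fraction:
        mesangial volume fraction of the tuft, in [0, 1].
    nuclei_density:
        mesangial-cell nuclei per um^3 of mesangium.
    collagen_fraction:
        collagen-positive volume fraction of the tuft.
    lesion_label:
        one of none / hyalinosis / fsgs / ggs.
    size_class_truth:
        one of normal / hypertrophic / ischemic / solidified.
    """

    radius: float
    mesangial_fraction: float
    nuclei_density: float
    collagen_fraction: float
    lesion_label: str = "none"
    size_class_truth: str = "normal"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.mesangial_fraction <= 1.0:
            raise ValueError("mesangial_fraction must lie in [0, 1]")
        if self.lesion_label not in LESION_LABELS:
            raise ValueError(f"unknown lesion label {self.lesion_label!r}")
        if self.size_class_truth not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class_truth!r}")

    @property
    def volume(self) -> float:
        """Tuft volume, um^3."""
        return 4.0 / 3.0 * math.pi * self.radius ** 3


def control_median_radius(preset: GroupPreset,
                          log_volume_sd: float = LOG_VOLUME_SD) -> float:
    """Median radius of the control population implied by the baseline GLV.

    The baseline fixes the control *mean* volume; for a lognormal radius
    with log-radius SD sigma_r = sigma_v/3, E[R^3] = Rmed^3 exp(4.5 sigma_r^2).
    """
    sigma_r = log_volume_sd / 3.0
    mean_r3 = 3.0 * preset.baseline.glv_um3 / (4.0 * math.pi)
    return (mean_r3 / math.exp(4.5 * sigma_r ** 2)) ** (1.0 / 3.0)


def expected_mean_section_area(preset: GroupPreset,
                               offset_fraction: float = 0.25,
                               log_volume_sd: float = LOG_VOLUME_SD) -> float:
    """Expected mean profile area (um^2) under the sampling protocol.

    For plane offsets uniform in [0, w*R], E[A] = pi E[R^2] (1 - w^2/3).
    Used to normalize nuclei density and to set counting-field
    expectations consistently with what the morphometry measures.
    """
    sigma_r = log_volume_sd / 3.0
    rmed = control_median_radius(preset, log_volume_sd)
    mean_r2 = rmed ** 2 * math.exp(2.0 * sigma_r ** 2) * preset.mean_area_multiplier()
    return math.pi * mean_r2 * (1.0 - offset_fraction ** 2 / 3.0)


def generate_population(preset: GroupPreset, n: int, seed: int,
                        log_volume_sd: float = LOG_VOLUME_SD) -> list[Glomerulus3D]:
    """Draw ``n`` virtual glomeruli for one experimental group.

    The size-class mixture (normal / hypertrophic / ischemic) follows the
    preset fractions; class scales are solved so the cohort's mean section
    area reproduces the preset GLV multiplier under the mean-GLA volume
    estimator.  Reproducible for a fixed (preset, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sigma_r = log_volume_sd / 3.0
    rmed = control_median_radius(preset, log_volume_sd)
    a = preset.class_area_multipliers()

    w_h = preset.hypertrophic_fraction
    w_i = preset.ischemic_fraction
    classes = rng.choice(
        ["normal", "hypertrophic", "ischemic"],
        size=n, p=[1.0 - w_h - w_i, w_h, w_i])
    area_mult = np.array([a[c] for c in classes])
    radii = rmed * np.sqrt(area_mult) * np.exp(sigma_r * rng.standard_normal(n))

    f_group = preset.mesangial_areal_fraction()
    mes_frac = np.clip(
        f_group + MESANGIAL_FRACTION_JITTER * rng.standard_normal(n), 0.01, 0.97)

    c_group = preset.collagen_areal_fraction()
    col_frac = np.clip(c_group * (1.0 + 0.25 * rng.standard_normal(n)), 0.0, None)

    # nuclei density normalized so the expected nuclei count per profile
    # equals mec_multiplier x baseline (up to the shared sectioning factor)
    mean_mea = f_group * math.pi * (rmed ** 2) * math.exp(2 * sigma_r ** 2) \
        * preset.mean_area_multiplier()
    rho = (preset.baseline.mec_per_profile * preset.mec_multiplier
           / (mean_mea * SECTION_THICKNESS_UM))

    p_lesion = [preset.hyalinosis_freq, preset.fsgs_freq, preset.ggs_freq]
    p_lesion.append(1.0 - sum(p_lesion))
    lesions = rng.choice(["hyalinosis", "fsgs", "ggs", "none"], size=n, p=p_lesion)
    # collagen may not exceed the mesangial+sclerosed compartment
    col_frac = np.minimum(col_frac, mes_frac)

    return [
        Glomerulus3D(
            radius=float(radii[i]),
            mesangial_fraction=float(mes_frac[i]),
            nuclei_density=float(rho),
            collagen_fraction=float(col_frac[i]),
            lesion_label=str(lesions[i]),
            size_class_truth=str(classes[i]),
        )
        for i in range(n)
    ]
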