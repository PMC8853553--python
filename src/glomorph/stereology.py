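"""Stereological volume and numerical-density estimators.

Profile areas convert to volumes through the Weibel-type relation

    GLV = GLA^1.5 * beta / kappa

with beta the dimensionless shape coefficient (1.38 for spheres) and
kappa a size-distribution coefficient (1.01, appropriate for a nearly
monodisperse population).  Mesangial volume follows from the areal
fraction being an unbiased estimate of the volume fraction,
MEV = (MEA/GLA) * GLV, and the capillary compartment is the remainder,
GCV = GLV - MEV.  Numerical density divides the profile count per unit
area by the mean tuft diameter:

    Nv = (sum N_A / sum A) / sqrt(4 * mean_GLA / pi)

Internally everything is in um / um^2 / um^3; Nv is reported per mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .histomorphometry import FieldCount

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class StereologyParams:
    """Shape and size-distribution coefficients of the area-to-volume formula."""

    beta: float = 1.38
    kappa: float = 1.01

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.kappa < 1.0:
            raise ValueError("kappa must be >= 1")


DEFAULT_PARAMS = StereologyParams()


@dataclass(frozen=True)
class VolumeEstimate:
    """Glomerular, mesangial and capillary volumes (um^3); GLV = MEV + GCV."""

    glv_um3: float
    mev_um3: float
    gcv_um3: float

    def __post_init__(self) -> None:
        if min(self.glv_um3, self.mev_um3, self.gcv_um3) < 0:
            raise ValueError("volumes must be non-negative")
        if not math.isclose(self.glv_um3, self.mev_um3 + self.gcv_um3,
                            rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("GLV must equal MEV + GCV")


@dataclass(frozen=True)
class DensityEstimate:
    """Glomerular numerical density."""

    nv_per_mm3: float

    def __post_init__(self) -> None:
        if self.nv_per_mm3 < 0:
            raise ValueError("Nv must be non-negative")


def glomerular_volume(gla, params: StereologyParams = DEFAULT_PARAMS):
    """GLV = GLA^1.5 * beta / kappa.  Accepts scalars or arrays (um^2 -> um^3)."""
    gla_arr = np.asarray(gla, dtype=float)
    if (gla_arr < 0).any():
        raise ValueError("GLA must be non-negative")
    out = gla_arr ** 1.5 * params.beta / params.kappa
    return float(out) if np.isscalar(gla) or gla_arr.ndim == 0 else out


def mesangial_volume(gla: float, mea: float, glv: float) -> float:
    """MEV = (MEA/GLA) * GLV; areal fraction equals volume fraction."""
    if gla <= 0:
        raise ValueError("GLA must be positive")
    if not 0.0 <= mea <= gla:
        raise ValueError("MEA must lie in [0, GLA]")
    return mea / gla * glv


def capillary_volume(glv: float, mev: float) -> float:
    """GCV = GLV - MEV."""
    if mev > glv:
        raise ValueError("MEV cannot exceed GLV")
    return glv - mev


def cohort_volumes(measurements: pd.DataFrame,
                   params: StereologyParams = DEFAULT_PARAMS) -> VolumeEstimate:
    """Cohort-level volume estimate from mean profile areas.

    Follows the source convention: the mean GLV is computed from the
    cohort mean GLA (not the mean of per-profile volumes), and the
    mesangial fraction from pooled areas.
    """
    if measurements.empty:
        raise ValueError("no measurements")
    mean_gla = float(measurements["gla_um2"].mean())
    glv = glomerular_volume(mean_gla, params)
    frac = float(measurements["mea_um2"].sum() / measurements["gla_um2"].sum())
    mev = frac * glv
    return VolumeEstimate(glv_um3=glv, mev_um3=mev, gcv_um3=glv - mev)


def per_profile_glv(measurements: pd.DataFrame,
                    params: StereologyParams = DEFAULT_PARAMS) -> np.ndarray:
    """Per-profile GLV values for volume-histogram construction.

    The per-profile transform of the cohort formula; used for the size
    (hypertrophic/ischemic) classifier and distribution plots.
    """
    return glomerular_volume(measurements["gla_um2"].to_numpy(), params)


def numerical_density(field_counts: Sequence[FieldCount] | Iterable[FieldCount],
                      mean_gla: float) -> DensityEstimate:
    """Nv (per mm^3) from field counts and the cohort mean profile area.

    Uses the pooled-ratio estimator sum(N_A)/sum(A), unbiased under
    unequal field areas, divided by the mean tuft diameter
    sqrt(4 * mean_GLA / pi).
    """
    counts = list(field_counts)
    if not counts:
        raise ValueError("at least one field is required")
    if mean_gla <= 0:
        raise ValueError("mean GLA must be positive")
    total_n = sum(fc.n_a for fc in counts)
    total_a = sum(fc.area_um2 for fc in counts)
    mean_diameter = math.sqrt(4.0 * mean_gla / math.pi)
    nv_per_um3 = (total_n / total_a) / mean_diameter
    return DensityEstimate(nv_per_mm3=nv_per_um3 * UM3_PER_MM3)
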