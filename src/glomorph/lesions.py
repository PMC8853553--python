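"""Human-criteria lesion classification.

Three classifiers taken from clinical renal pathology:

* deposit class — the dual-stain rule: sclerotic areas are PAS-red but
  trichrome blue/green, hyalinotic areas are red in BOTH stains;
* global glomerulosclerosis (GGS) — sclerosis occupying strictly more
  than 50% of the glomerular area;
* size remodeling — hypertrophic / ischemic glomeruli identified on the
  glomerular volume histogram, operationalised as profiles above the
  control 95th / below the control 5th percentile.

Frequencies are reported as percentages of all scanned glomeruli; the
source protocol scanned 2400-3600 glomeruli per group, which sets the
default denominator floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stereology import StereologyParams, DEFAULT_PARAMS, per_profile_glv

#: GGS rule: sclerosis area strictly greater than this fraction of GLA
GGS_FRACTION = 0.5

#: control-distribution percentiles bounding the normal size class
SIZE_PERCENTILES = (5.0, 95.0)

#: minimum control sample for percentile thresholds
MIN_CONTROL_N = 100

#: denominator floor for lesion-frequency estimates
MIN_FREQUENCY_N = 2400

DEPOSIT_CLASSES = ("none", "hyalinosis", "sclerosis")
TRICHROME_COLOURS = ("red", "blue_green", "none")


@dataclass(frozen=True)
class LesionCall:
    """Per-profile classification outcome."""

    profile_id: int
    deposit_class: str
    ggs: bool
    size_class: str

    def __post_init__(self) -> None:
        if self.ggs and self.deposit_class != "sclerosis":
            raise ValueError("GGS implies a sclerotic deposit")


@dataclass(frozen=True)
class LesionFrequencies:
    """Cohort lesion frequencies (% of scanned glomeruli) with raw counts."""

    n_glomeruli: int
    hyalinosis_pct: float
    fsgs_pct: float
    ggs_pct: float
    hypertrophic_pct: float
    ischemic_pct: float
    counts: dict = field(default_factory=dict)
    below_floor: bool = False

    @property
    def hyalinosis_fsgs_pct(self) -> float:
        """Joint hyalinosis/FSGS frequency, the jointly reported figure."""
        return self.hyalinosis_pct + self.fsgs_pct


def classify_deposit(pas_positive: bool, trichrome_colour: str) -> str:
    """Dual-stain discrimination of glomerular deposits.

    (PAS+, trichrome red) -> hyalinosis; (PAS+, trichrome blue/green) ->
    sclerosis; anything unstained -> none.  A missing trichrome
    observation cannot be classified.
    """
    if trichrome_colour is None:
        return "unclassifiable"
    if trichrome_colour not in TRICHROME_COLOURS:
        raise ValueError(f"unknown trichrome colour {trichrome_colour!r}")
    if not pas_positive:
        return "none"
    if trichrome_colour == "red":
        return "hyalinosis"
    if trichrome_colour == "blue_green":
        return "sclerosis"
    return "none"


def flag_ggs(sclerosis_fraction: float) -> bool:
    """Global glomerulosclerosis: sclerosis area > 50% of GLA (strict)."""
    if not 0.0 <= sclerosis_fraction <= 1.0:
        raise ValueError("sclerosis fraction must lie in [0, 1]")
    return sclerosis_fraction > GGS_FRACTION


def classify_size(glv_values, control_glv_values,
                  percentiles: tuple[float, float] = SIZE_PERCENTILES,
                  min_control_n: int = MIN_CONTROL_N) -> np.ndarray:
    """Hypertrophic / ischemic / normal calls against the control histogram.

    A profile is hypertrophic if its GLV exceeds the control 95th
    percentile and ischemic if below the control 5th percentile
    (thresholds configurable).
    """
    control = np.asarray(control_glv_values, dtype=float)
    if control.size < min_control_n:
        raise ValueError(
            f"control sample too small ({control.size} < {min_control_n})")
    lo, hi = np.percentile(control, percentiles)
    values = np.asarray(glv_values, dtype=float)
    out = np.full(values.shape, "normal", dtype=object)
    out[values > hi] = "hypertrophic"
    out[values < lo] = "ischemic"
    return out


def lesion_frequencies(calls: list[LesionCall],
                       min_n: int = MIN_FREQUENCY_N) -> LesionFrequencies:
    """Cohort percentages over all scanned glomeruli.

    FSGS is counted as a sclerotic deposit that has not reached the GGS
    threshold (segmental involvement); exact counts are retained so
    chi-square tests can be run downstream.
    """
    n = len(calls)
    if n == 0:
        raise ValueError("no lesion calls")
    below_floor = n < min_n
    if below_floor:
        warnings.warn(
            f"only {n} glomeruli (< {min_n}); frequency estimate is flagged",
            stacklevel=2)
    counts = {
        "hyalinosis": sum(c.deposit_class == "hyalinosis" for c in calls),
        "fsgs": sum(c.deposit_class == "sclerosis" and not c.ggs for c in calls),
        "ggs": sum(c.ggs for c in calls),
        "hypertrophic": sum(c.size_class == "hypertrophic" for c in calls),
        "ischemic": sum(c.size_class == "ischemic" for c in calls),
    }
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    return LesionFrequencies(
        n_glomeruli=n,
        hyalinosis_pct=pct["hyalinosis"],
        fsgs_pct=pct["fsgs"],
        ggs_pct=pct["ggs"],
        hypertrophic_pct=pct["hypertrophic"],
        ischemic_pct=pct["ischemic"],
        counts=counts,
        below_floor=below_floor,
    )


def calls_from_measurements(measurements: pd.DataFrame,
                            control_measurements: pd.DataFrame,
                            params: StereologyParams = DEFAULT_PARAMS) -> list[LesionCall]:
    """Build per-profile lesion calls from a measurement table.

    Deposits are classified from the paired stain observations, GGS from
    the sclerosis fraction, and the size class from per-profile GLV
    against the control cohort's distribution.
    """
    glv = per_profile_glv(measurements, params)
    control_glv = per_profile_glv(control_measurements, params)
    sizes = classify_size(glv, control_glv)
    calls = []
    for i, (_, row) in enumerate(measurements.iterrows()):
        deposit = classify_deposit(bool(row["pas_deposit"]),
                                   str(row["trichrome_colour"]))
        ggs = flag_ggs(float(row["sclerosis_fraction"])) and deposit == "sclerosis"
        calls.append(LesionCall(
            profile_id=int(row["profile_id"]),
            deposit_class=deposit,
            ggs=ggs,
            size_class=str(sizes[i]),
        ))
    return calls
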