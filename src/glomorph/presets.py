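"""Experimental-group presets for the synthetic cohort generator.

Each preset encodes one hypertensive model (or its normotensive control) as
a set of effect-size multipliers relative to control: mean glomerular
volume (GLV), mesangial volume (MEV), capillary volume (GCV), mesangial
cellularity (MEC), tuft collagen, and glomerular numerical density (Nv),
together with the frequencies of the size-remodeling classes
(hypertrophic / ischemic) and of the stain-defined lesions
(hyalinosis / FSGS / GGS).

Only ratios are asserted by the source measurements; absolute scales
(control GLV, nuclei per profile, Nv, collagen fraction) are explicit,
configurable baseline parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

SIZE_CLASSES = ("normal", "hypertrophic", "ischemic", "solidified")
LESION_LABELS = ("none", "hyalinosis", "fsgs", "ggs")


@dataclass(frozen=True)
class CohortBaseline:
    """Absolute control-group scale for one species.

    glv_um3:
        mean glomerular tuft volume of the control group, um^3.
    mesangial_volume_fraction:
        control MEV/GLV.  Derived from the internal consistency of the
        published GLV/MEV/GCV effect sizes (~0.30 in mice, ~0.576 in rats).
    collagen_fraction:
        control collagen-positive areal fraction of the tuft (near zero).
    mec_per_profile:
        mean mesangial nuclei per glomerular section profile.
    nv_per_mm3:
        control glomerular numerical density, tufts per mm^3 of cortex.
    """

    species: str
    glv_um3: float
    mesangial_volume_fraction: float
    collagen_fraction: float = 0.01
    mec_per_profile: float = 20.0
    nv_per_mm3: float = 60.0


MOUSE_BASELINE = CohortBaseline(
    species="mouse",
    glv_um3=1.7e5,
    mesangial_volume_fraction=0.30,
    collagen_fraction=0.01,
    mec_per_profile=18.0,
    nv_per_mm3=100.0,
)

RAT_BASELINE = CohortBaseline(
    species="rat",
    glv_um3=8.0e5,
    mesangial_volume_fraction=0.576,
    collagen_fraction=0.01,
    mec_per_profile=30.0,
    nv_per_mm3=30.0,
)


@dataclass(frozen=True)
class GroupPreset:
    """Generative ground truth for one experimental group.

    Multipliers are ratios of the group value to its control; control
    presets have all multipliers equal to 1 and (near-)zero lesion
    frequencies.  ``hypertrophic_fold`` is the mean volume of the
    hypertrophic subpopulation relative to the control mean (~3-fold for
    the renin-transgenic mice; where only the fraction was reported the
    fold is solved from the cohort mean-volume constraint).
    """

    name: str
    baseline: CohortBaseline
    control_name: str
    glv_multiplier: float = 1.0
    gcv_multiplier: float = 1.0
    mev_multiplier: float = 1.0
    mec_multiplier: float = 1.0
    collagen_multiplier: float = 1.0
    nv_multiplier: float = 1.0
    hypertrophic_fraction: float = 0.0
    ischemic_fraction: float = 0.0
    #: mean hypertrophic volume relative to the control mean; None solves
    #: the fold from the cohort mean constraint with the normal class at
    #: control scale
    hypertrophic_fold: float | None = None
    hyalinosis_freq: float = 0.0
    fsgs_freq: float = 0.0
    ggs_freq: float = 0.0
    default_seed: int = 1

    def __post_init__(self) -> None:
        for attr in ("glv_multiplier", "gcv_multiplier", "mev_multiplier",
                     "mec_multiplier", "collagen_multiplier", "nv_multiplier"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        for attr in ("hypertrophic_fraction", "ischemic_fraction",
                     "hyalinosis_freq", "fsgs_freq", "ggs_freq"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1]")
        if self.hypertrophic_fraction + self.ischemic_fraction > 1.0:
            raise ValueError("size-class fractions must sum to <= 1")
        if self.hyalinosis_freq + self.fsgs_freq + self.ggs_freq > 1.0:
            raise ValueError("lesion frequencies must sum to <= 1")

    @property
    def is_control(self) -> bool:
        return self.name == self.control_name

    def mesangial_areal_fraction(self) -> float:
        """Group-level MEA/GLA implied by the MEV and GLV multipliers.

        Under the stereological identity (areal fraction = volume
        fraction), MEV/GLV scales as mev_multiplier/glv_multiplier times
        the control fraction.
        """
        f = (self.baseline.mesangial_volume_fraction
             * self.mev_multiplier / self.glv_multiplier)
        if not 0.0 < f < 1.0:
            raise ValueError(f"implied mesangial fraction {f:.3f} out of (0,1)")
        return f

    def collagen_areal_fraction(self) -> float:
        """Group-level collagen-positive fraction of GLA."""
        return (self.baseline.collagen_fraction
                * self.collagen_multiplier / self.glv_multiplier)

    def class_area_multipliers(self) -> dict[str, float]:
        """Mean-section-area multiplier per size class, relative to control.

        The published cohort volume change is a mean-GLA based estimate
        (GLV = mean(GLA)^1.5 * beta/kappa), so class multipliers are solved
        on the GLA scale such that the weighted mean section area satisfies
        (sum_k w_k a_k)^(3/2) = glv_multiplier.  With a stated
        ``hypertrophic_fold`` that class is pinned at fold^(2/3) and the
        normal class absorbs the residual; otherwise the normal class (and,
        for an ischemic preset, the hypertrophic class too) stays at
        control scale and the lesioned class takes the residual.
        """
        target = self.glv_multiplier ** (2.0 / 3.0)
        w_h = self.hypertrophic_fraction
        w_i = self.ischemic_fraction
        w_n = 1.0 - w_h - w_i
        a_n = a_h = a_i = 1.0
        if w_i > 0:
            a_i = (target - w_n * a_n - w_h * a_h) / w_i
        elif w_h > 0:
            if self.hypertrophic_fold is not None:
                a_h = self.hypertrophic_fold ** (2.0 / 3.0)
                a_n = (target - w_h * a_h) / w_n
            else:
                a_h = (target - w_n * a_n) / w_h
        else:
            a_n = target
        if min(a_n, a_h, a_i) <= 0:
            raise ValueError(
                f"preset {self.name!r}: inconsistent size-class structure "
                f"(a_n={a_n:.3f}, a_h={a_h:.3f}, a_i={a_i:.3f})")
        return {"normal": a_n, "hypertrophic": a_h, "ischemic": a_i}

    def solved_hypertrophic_fold(self) -> float:
        """Hypertrophic mean volume fold vs control implied by the solver."""
        return self.class_area_multipliers()["hypertrophic"] ** 1.5

    def mean_area_multiplier(self) -> float:
        a = self.class_area_multipliers()
        w_h = self.hypertrophic_fraction
        w_i = self.ischemic_fraction
        return ((1 - w_h - w_i) * a["normal"]
                + w_h * a["hypertrophic"] + w_i * a["ischemic"])


def _control(name: str, baseline: CohortBaseline) -> GroupPreset:
    return GroupPreset(name=name, baseline=baseline, control_name=name)


PRESETS: dict[str, GroupPreset] = {
    "control_mouse": _control("control_mouse", MOUSE_BASELINE),
    "angii": GroupPreset(
        name="angii", baseline=MOUSE_BASELINE, control_name="control_mouse",
        glv_multiplier=0.61, gcv_multiplier=0.32, mev_multiplier=1.29,
        mec_multiplier=1.93, collagen_multiplier=2.96, nv_multiplier=1.0,
    ),
    "ttrhren": GroupPreset(
        name="ttrhren", baseline=MOUSE_BASELINE, control_name="control_mouse",
        glv_multiplier=1.12, gcv_multiplier=1.10, mev_multiplier=1.18,
        mec_multiplier=0.88, collagen_multiplier=1.98, nv_multiplier=0.75,
        hypertrophic_fraction=0.10, hypertrophic_fold=3.0,
    ),
    "control_rat": _control("control_rat", RAT_BASELINE),
    "shr": GroupPreset(
        name="shr", baseline=RAT_BASELINE, control_name="control_rat",
        glv_multiplier=1.51, gcv_multiplier=2.34, mev_multiplier=0.90,
        mec_multiplier=0.62, collagen_multiplier=1.0, nv_multiplier=0.68,
        hypertrophic_fraction=0.56,
    ),
    "k2c1_nonclipped": GroupPreset(
        name="k2c1_nonclipped", baseline=RAT_BASELINE, control_name="control_rat",
        glv_multiplier=1.21, gcv_multiplier=1.15, mev_multiplier=1.26,
        mec_multiplier=1.09, collagen_multiplier=1.12, nv_multiplier=1.0,
        hypertrophic_fraction=0.34,
        hyalinosis_freq=0.0008,
    ),
    "k2c1_clipped": GroupPreset(
        name="k2c1_clipped", baseline=RAT_BASELINE, control_name="control_rat",
        glv_multiplier=0.51, gcv_multiplier=0.32, mev_multiplier=0.65,
        mec_multiplier=0.84, collagen_multiplier=3.40, nv_multiplier=1.37,
        ischemic_fraction=0.84,
        hyalinosis_freq=0.005,
    ),
}

#: treated group -> its normotensive control
CONTROL_OF = {name: p.control_name for name, p in PRESETS.items()}


def list_presets() -> list[str]:
    return list(PRESETS)


def get_preset(name: str) -> GroupPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}") from None


def preset_to_dict(preset: GroupPreset) -> dict:
    d = asdict(preset)
    d["baseline"] = asdict(preset.baseline)
    return d


def save_presets_yaml(path: str | Path, presets: dict[str, GroupPreset] | None = None) -> None:
    presets = presets if presets is not None else PRESETS
    payload = {name: preset_to_dict(p) for name, p in presets.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_presets_yaml(path: str | Path) -> dict[str, GroupPreset]:
    payload = yaml.safe_load(Path(path).read_text())
    out = {}
    for name, d in payload.items():
        d = dict(d)
        d["baseline"] = CohortBaseline(**d["baseline"])
        out[name] = GroupPreset(**d)
    return out
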