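"""Human reference values for hypertensive glomerulopathy.

Packaged table of clinical studies reporting FSGS / GGS percentages (or
glomerular-area scores) in hypertensive patients; animal cohorts are
compared against these values on the human scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import yaml

_DATA_FILE = "data/human_references.yaml"


@dataclass(frozen=True)
class HumanReference:
    study_label: str
    condition: str
    n_patients: int
    fsgs_pct: float | None = None
    fsgs_pct_range: tuple[float, float] | None = None
    ggs_pct: float | None = None
    ggs_pct_sd: float | None = None
    ggs_pct_range: tuple[float, float] | None = None
    score_mean: float | None = None
    score_max: float | None = None

    def __post_init__(self) -> None:
        for pct in (self.fsgs_pct, self.ggs_pct):
            if pct is not None and not 0.0 <= pct <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")


def _raw_text() -> str:
    return (resources.files("glomorph") / _DATA_FILE).read_text()


def load_human_references() -> list[HumanReference]:
    """All packaged clinical reference rows."""
    try:
        raw = yaml.safe_load(_raw_text())
    except yaml.YAMLError as exc:  # pragma: no cover
        raise RuntimeError("packaged human reference data is corrupted") from exc
    if not isinstance(raw, list) or not raw:
        raise RuntimeError("packaged human reference data is corrupted")
    out = []
    for row in raw:
        row = dict(row)
        for key in ("fsgs_pct_range", "ggs_pct_range"):
            if key in row:
                row[key] = tuple(row[key])
        out.append(HumanReference(**row))
    return out


def get_reference(study_label: str) -> HumanReference:
    """Look up one study by label (case-insensitive)."""
    for ref in load_human_references():
        if ref.study_label.lower() == study_label.lower():
            return ref
    raise KeyError(f"no human reference study {study_label!r}")


def references_round_trip() -> bool:
    """True when re-serializing the loader output regenerates the file."""
    def clean(d: dict) -> dict:
        out = {}
        for k, v in d.items():
            if v is None:
                continue
            out[k] = list(v) if isinstance(v, tuple) else v
        return out

    regenerated = [clean(asdict(r)) for r in load_human_references()]
    return regenerated == yaml.safe_load(_raw_text())
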