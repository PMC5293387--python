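"""Nephrometry covariates: a simplified C-index plus RENAL/PADUA validation.

The C-index measures tumor centrality: the distance from the tumor center to
the kidney center in units of tumor radius.  Scores near zero indicate
central tumors, which are surgically harder and lose more parenchyma.  The
original definition works in the axial imaging plane with a slice offset;
since this package handles center coordinates rather than an image stack, a
3-D Euclidean distance is used — identical whenever the offsets derive from
true center coordinates.

RENAL and PADUA complexity scores are user-supplied integers; their scoring
rubrics are not computed here.  Validation ranges follow the values observed
in open partial-nephrectomy cohorts (RENAL 4-12, PADUA 6-13).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import GeometryError, TumorGeometry

__all__ = [
    "TumorLocation",
    "c_index",
    "validate_renal_score",
    "validate_padua_score",
    "RENAL_SCORE_RANGE",
    "PADUA_SCORE_RANGE",
]

RENAL_SCORE_RANGE = (4, 12)
PADUA_SCORE_RANGE = (6, 13)


@dataclass(frozen=True)
class TumorLocation:
    """Signed displacement (cm) of the tumor center from the kidney center."""

    offset_x_cm: float
    offset_y_cm: float
    offset_z_cm: float

    def __post_init__(self) -> None:
        for name in ("offset_x_cm", "offset_y_cm", "offset_z_cm"):
            value = float(getattr(self, name))
            if not math.isfinite(value):
                raise GeometryError(f"{name} must be finite, got {value!r}")
            object.__setattr__(self, name, value)

    @property
    def distance_cm(self) -> float:
        return math.hypot(self.offset_x_cm, self.offset_y_cm, self.offset_z_cm)


def c_index(loc: TumorLocation, tumor: TumorGeometry) -> float:
    """Tumor centrality: center-to-center distance divided by tumor radius."""
    if tumor.radius_cm <= 0:
        raise GeometryError(f"tumor radius must be positive, got {tumor.radius_cm}")
    return loc.distance_cm / tumor.radius_cm


def _validate_score(value: float, lo: int, hi: int, name: str) -> int:
    v = float(value)
    if not v.is_integer():
        raise ValueError(f"{name} score must be an integer, got {value!r}")
    v = int(v)
    if not lo <= v <= hi:
        raise ValueError(f"{name} score must be in [{lo}, {hi}], got {v}")
    return v


def validate_renal_score(value: float) -> int:
    """Check a user-supplied RENAL nephrometry score (integer, 4-12)."""
    return _validate_score(value, *RENAL_SCORE_RANGE, name="RENAL")


def validate_padua_score(value: float) -> int:
    """Check a user-supplied PADUA nephrometry score (integer, 6-13)."""
    return _validate_score(value, *PADUA_SCORE_RANGE, name="PADUA")
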