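"""Renal-function assessment: MDRD eGFR, nadir selection, percent reduction.

eGFR is estimated from serum creatinine with the abbreviated 4-variable MDRD
equation.  The multiplicative constant is configurable: 186 (original
abbreviated equation) or 175 (IDMS-traceable re-expression); 186 is the
default.  The post-operative nadir is the lowest eGFR recorded between 3 and
12 months after surgery, implemented as the inclusive day window [90, 365].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "RenalFunctionError",
    "NoEligibleFollowUpError",
    "CreatinineMeasure",
    "Demographics",
    "FunctionOutcome",
    "egfr_mdrd",
    "nadir_egfr",
    "pct_egfr_reduction",
    "function_outcome",
    "MDRD_K_DEFAULT",
    "MDRD_K_IDMS",
    "NADIR_WINDOW_DAYS",
]

MDRD_K_DEFAULT = 186.0
MDRD_K_IDMS = 175.0

#: Inclusive follow-up window (days after surgery) for the nadir eGFR.
NADIR_WINDOW_DAYS = (90, 365)

_FEMALE_FACTOR = 0.742
_BLACK_FACTOR = 1.212
_SCR_EXPONENT = -1.154
_AGE_EXPONENT = -0.203


class RenalFunctionError(ValueError):
    """Raised for physiologically inadmissible renal-function inputs."""


class NoEligibleFollowUpError(RenalFunctionError):
    """No eGFR measurement falls inside the nadir follow-up window."""


@dataclass(frozen=True)
class CreatinineMeasure:
    """One serum creatinine value (mg/dL) at ``days_post_op`` (negative = pre-op)."""

    scr_mg_dl: float
    days_post_op: int = 0

    def __post_init__(self) -> None:
        if not self.scr_mg_dl > 0:
            raise RenalFunctionError(
                f"serum creatinine must be positive, got {self.scr_mg_dl}"
            )


@dataclass(frozen=True)
class Demographics:
    """Patient covariates entering the MDRD equation."""

    age_years: float
    sex: str  # "male" | "female" (also accepts "M"/"F", case-insensitive)
    black_race: bool = False

    def __post_init__(self) -> None:
        if not self.age_years > 0:
            raise RenalFunctionError(f"age must be positive, got {self.age_years}")
        sex = str(self.sex).strip().lower()
        if sex in ("m", "male"):
            sex = "male"
        elif sex in ("f", "female"):
            sex = "female"
        else:
            raise RenalFunctionError(f"sex must be male/female (or M/F), got {self.sex!r}")
        object.__setattr__(self, "sex", sex)

    @property
    def female(self) -> bool:
        return self.sex == "female"


@dataclass(frozen=True)
class FunctionOutcome:
    """Pre-operative eGFR, nadir eGFR and the percent reduction between them."""

    preop_egfr: float
    nadir_egfr: float
    pct_reduction: float


def egfr_mdrd(
    scr: CreatinineMeasure | float,
    demo: Demographics,
    k: float = MDRD_K_DEFAULT,
) -> float:
    """Estimated GFR (mL/min/1.73 m²) from the 4-variable MDRD equation.

    eGFR = k · Scr^(−1.154) · age^(−0.203) · 0.742[female] · 1.212[black].

    Parameters
    ----------
    scr
        Serum creatinine in mg/dL, either bare or as a :class:`CreatinineMeasure`.
    demo
        Age, sex and race factors.
    k
        Equation constant: 186 (default) or 175 (IDMS-traceable creatinine).
    """
    scr_value = scr.scr_mg_dl if isinstance(scr, CreatinineMeasure) else float(scr)
    if not scr_value > 0:
        raise RenalFunctionError(f"serum creatinine must be positive, got {scr_value}")
    egfr = k * scr_value**_SCR_EXPONENT * demo.age_years**_AGE_EXPONENT
    if demo.female:
        egfr *= _FEMALE_FACTOR
    if demo.black_race:
        egfr *= _BLACK_FACTOR
    return egfr


def nadir_egfr(series: Iterable[Sequence[float]]) -> float:
    """Lowest eGFR among measurements in the inclusive [90, 365]-day window.

    ``series`` is an iterable of ``(days_post_op, egfr)`` pairs.  Measurements
    outside the window are ignored; an empty window raises
    :class:`NoEligibleFollowUpError`.
    """
    lo, hi = NADIR_WINDOW_DAYS
    eligible = [float(egfr) for days, egfr in series if lo <= days <= hi]
    if not eligible:
        raise NoEligibleFollowUpError(
            f"no eGFR measurement between postoperative days {lo} and {hi}"
        )
    return min(eligible)


def pct_egfr_reduction(preop: float, nadir: float) -> float:
    """Percent reduction 100·(preop − nadir)/preop; negative = improvement."""
    if not preop > 0:
        raise RenalFunctionError(f"pre-operative eGFR must be positive, got {preop}")
    return 100.0 * (preop - nadir) / preop


def function_outcome(
    preop_egfr: float, series: Iterable[Sequence[float]]
) -> FunctionOutcome:
    """Select the nadir from a follow-up series and compute the percent reduction."""
    nadir = nadir_egfr(series)
    return FunctionOutcome(
        preop_egfr=float(preop_egfr),
        nadir_egfr=nadir,
        pct_reduction=pct_egfr_reduction(preop_egfr, nadir),
    )
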