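"""End-to-end cohort pipeline: derive volumes and outcomes, run the analysis.

``run_pipeline`` takes a validated patient table and, per patient, computes
RAIV and PRAIV from the stored geometry (when kidney axes are present), the
C-index from center offsets (when present), eGFR from creatinine via MDRD
(when eGFR is not supplied directly), the nadir eGFR from an optional
long-format follow-up table, and the percent eGFR reduction.  It then fits
the univariate screen and the single multivariate model and returns the
augmented cohort, a covariate-by-covariate analysis table (univariate and
multivariate standardized beta and p-value) and the per-covariate simple
regression-line parameters (intercept, slope, R²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry, nephrometry, renal_function, schema
from .regression import (
    EgfrReductionModel,
    ModelSpec,
    StatisticsError,
    fit_univariate,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "derive_columns"]

#: Covariates offered to the analysis stage when present in the table.
DEFAULT_ANALYSIS_COVARIATES = (
    "gender",
    "age",
    "tumor_diameter_cm",
    "invasion_depth_cm",
    "cold_ischemia_min",
    "preop_egfr",
    "renal_score",
    "padua_score",
    "cindex",
    "raiv",
    "praiv",
)


@dataclass(frozen=True)
class PipelineConfig:
    outcome: str = "pct_reduction"
    univariate: tuple[str, ...] | str = "all"  # "all" = every available covariate
    multivariate: tuple[str, ...] | None = None  # None = same as univariate list
    margin_cm: float = geometry.DEFAULT_MARGIN_CM
    mdrd_k: float = renal_function.MDRD_K_DEFAULT
    run_analysis: bool = True


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    analysis: pd.DataFrame | None = None
    regression_lines: pd.DataFrame | None = None
    n_input: int = 0
    n_complete: int = 0
    messages: list[str] = field(default_factory=list)


def _tumor(row: pd.Series) -> geometry.TumorGeometry:
    return geometry.TumorGeometry.from_diameter(
        row["tumor_diameter_cm"], row["invasion_depth_cm"]
    )


def derive_columns(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Add every derivable per-patient column to a copy of ``table``."""
    out = table.copy()
    # gender coded male=1, female=0 for regression (coding is arbitrary; the
    # sign of the gender beta follows from it).
    out["gender"] = out["sex"].astype(str).str.upper().str.startswith("M").astype(float)

    has_geom = {"tumor_diameter_cm", "invasion_depth_cm"}.issubset(out.columns)
    has_kidney = {"kidney_length_cm", "kidney_width_cm", "kidney_height_cm"}.issubset(
        out.columns
    )
    if has_geom:
        if "margin_cm" not in out.columns:
            out["margin_cm"] = config.margin_cm
        raiv_vals = []
        for _, row in out.iterrows():
            spec = geometry.ResectionSpec(row["margin_cm"])
            raiv_vals.append(geometry.raiv(_tumor(row), spec))
        out["raiv"] = raiv_vals
        if has_kidney:
            praiv_vals = []
            for _, row in out.iterrows():
                kidney = geometry.KidneyGeometry(
                    row["kidney_length_cm"], row["kidney_width_cm"], row["kidney_height_cm"]
                )
                praiv_vals.append(
                    geometry.praiv(_tumor(row), kidney, geometry.ResectionSpec(row["margin_cm"]))
                )
            out["praiv"] = praiv_vals

    offset_cols = {"offset_x_cm", "offset_y_cm", "offset_z_cm"}
    if offset_cols.issubset(out.columns) and has_geom:
        out["cindex"] = [
            nephrometry.c_index(
                nephrometry.TumorLocation(
                    row["offset_x_cm"], row["offset_y_cm"], row["offset_z_cm"]
                ),
                _tumor(row),
            )
            for _, row in out.iterrows()
        ]

    if "preop_egfr" not in out.columns and "preop_scr" in out.columns:
        out["preop_egfr"] = [
            renal_function.egfr_mdrd(
                row["preop_scr"],
                renal_function.Demographics(
                    row["age"], row["sex"], bool(row.get("black_race", False))
                ),
                k=config.mdrd_k,
            )
            for _, row in out.iterrows()
        ]

    if (
        "pct_reduction" not in out.columns
        and {"preop_egfr", "nadir_egfr"}.issubset(out.columns)
    ):
        out["pct_reduction"] = [
            renal_function.pct_egfr_reduction(row["preop_egfr"], row["nadir_egfr"])
            for _, row in out.iterrows()
        ]
    return out


def attach_followup_nadir(
    table: pd.DataFrame,
    followup: pd.DataFrame,
    demographics_from: pd.DataFrame | None = None,
    mdrd_k: float = renal_function.MDRD_K_DEFAULT,
) -> pd.DataFrame:
    """Fill ``nadir_egfr`` from a long-format follow-up table.

    ``followup`` needs columns ``patient_id``, ``days_post_op`` and either
    ``egfr`` or ``scr`` (creatinine is converted with MDRD using the
    patient's demographics from ``table``).
    """
    out = table.copy()
    fu = followup.copy()
    if "egfr" not in fu.columns:
        if "scr" not in fu.columns:
            raise schema.SchemaError([("-", "egfr/scr", "follow-up table needs egfr or scr")])
        demo_src = (demographics_from if demographics_from is not None else out).set_index(
            "patient_id"
        )
        egfr = []
        for _, row in fu.iterrows():
            patient = demo_src.loc[row["patient_id"]]
            demo = renal_function.Demographics(
                patient["age"], patient["sex"], bool(patient.get("black_race", False))
            )
            egfr.append(renal_function.egfr_mdrd(row["scr"], demo, k=mdrd_k))
        fu["egfr"] = egfr
    nadirs = {}
    for pid, group in fu.groupby("patient_id"):
        try:
            nadirs[pid] = renal_function.nadir_egfr(
                list(zip(group["days_post_op"], group["egfr"]))
            )
        except renal_function.NoEligibleFollowUpError:
            nadirs[pid] = np.nan
    out["nadir_egfr"] = out["patient_id"].map(nadirs)
    return out


def run_pipeline(
    source: str | Path | pd.DataFrame,
    config: PipelineConfig | None = None,
    followup: str | Path | pd.DataFrame | None = None,
) -> PipelineResult:
    """Validate, derive, and analyze one cohort; see module docstring."""
    if config is None:
        config = PipelineConfig()
    if isinstance(source, (str, Path)):
        table = schema.read_cohort(source)
    else:
        table = source.copy()
        schema.validate_cohort(table)
    if "patient_id" not in table.columns:
        table.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(len(table))])
    result = PipelineResult(cohort=table, n_input=len(table))

    if followup is not None:
        fu = (
            pd.read_csv(followup) if isinstance(followup, (str, Path)) else followup
        )
        table = attach_followup_nadir(table, fu, mdrd_k=config.mdrd_k)

    cohort = derive_columns(table, config)
    result.cohort = cohort

    if not config.run_analysis:
        return result
    if config.outcome not in cohort.columns:
        raise StatisticsError(
            f"outcome column {config.outcome!r} is absent and not derivable "
            "(need pct_reduction, preop+nadir eGFR, or follow-up data)"
        )

    if config.univariate == "all":
        covariates: Sequence[str] = [
            c for c in DEFAULT_ANALYSIS_COVARIATES if c in cohort.columns
        ]
    else:
        covariates = list(config.univariate)
    multi_covs = list(config.multivariate) if config.multivariate else list(covariates)

    uni_rows, line_rows = [], []
    for cov in covariates:
        res = fit_univariate(cohort, config.outcome, cov)
        uni_rows.append(
            {
                "covariate": cov,
                "uni_beta": float(res.std_betas[cov]),
                "uni_p": float(res.pvalues[cov]),
            }
        )
        line_rows.append(
            {
                "covariate": cov,
                "intercept": res.intercept,
                "slope": float(res.params[cov]),
                "r_squared": res.rsquared,
                "n": res.nobs,
            }
        )
    analysis = pd.DataFrame(uni_rows)

    multi = EgfrReductionModel(
        cohort, config.outcome, multi_covs
    ).fit()
    result.n_complete = multi.nobs
    analysis["multi_beta"] = analysis["covariate"].map(
        lambda c: float(multi.std_betas[c]) if c in multi.std_betas.index else np.nan
    )
    analysis["multi_p"] = analysis["covariate"].map(
        lambda c: float(multi.pvalues[c]) if c in multi.pvalues.index else np.nan
    )
    result.analysis = analysis
    result.regression_lines = pd.DataFrame(line_rows)
    msg = (
        f"{result.n_input} rows in; multivariate model on {multi.nobs} complete "
        f"cases ({multi.n_dropped} dropped)"
    )
    result.messages.append(msg)
    logger.info(msg)
    return result
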