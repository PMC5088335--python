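"""Allometric anthropometric indices.

BMI, ABSI, WHR and the hip index (HI) all derive from the same idea: express
one body measurement relative to the others through a power law, so that the
resulting index is (nearly) statistically independent of overall body size.
The general engine is a log-log least-squares fit of a circumference on
height, weight and a female indicator (:func:`fit_allometric_model`), followed
by normalization of the raw circumference to a reference body size
(:func:`apply_allometric_index`).

Unit conventions
----------------
Heights and circumferences enter the public API in centimetres and weights in
kilograms.  Inside the log-log regression height is converted to metres: the
published hip-allometry intercept (2.658) is on that scale, and BMI/ABSI are
conventionally stated in metre-kilogram units.  Index *application* only uses
the ratios ``H/ref_height`` and ``W/ref_weight`` and is unit-invariant.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, InsufficientDataError, SchemaError, SingularFitError

__all__ = [
    "AnthropometryRecord",
    "AllometricModel",
    "HIP_MODEL_NHANES3",
    "compute_bmi",
    "compute_absi",
    "compute_whr",
    "compute_hi",
    "apply_allometric_index",
    "fit_allometric_model",
    "compute_index_panel",
    "apply_eligibility",
    "COHORT_COLUMNS",
]

logger = logging.getLogger(__name__)

CM_PER_M = 100.0

#: Canonical cohort table schema (CSV column order).
COHORT_COLUMNS = [
    "subject_id",
    "female",
    "race_black",
    "age_years",
    "height_cm",
    "weight_kg",
    "waist_cm",
    "hip_cm",
    "sample_weight",
    "followup_years",
    "died",
    "pregnant",
]


@dataclass
class AnthropometryRecord:
    """One subject's raw measurements, demographics and follow-up."""

    subject_id: str
    female: int
    race_black: int
    age_years: float
    height_cm: float
    weight_kg: float
    waist_cm: float
    hip_cm: float
    sample_weight: float = 1.0
    followup_years: float = 0.0
    died: int = 0
    pregnant: int = 0

    def validate(self) -> None:
        for field in ("height_cm", "weight_kg", "waist_cm", "hip_cm"):
            v = getattr(self, field)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{field} must be positive and finite, got {v!r}")
        if self.sample_weight < 0 or not np.isfinite(self.sample_weight):
            raise DomainError(f"sample_weight must be nonnegative, got {self.sample_weight!r}")
        if self.followup_years < 0:
            raise DomainError(f"followup_years must be >= 0, got {self.followup_years!r}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def records_to_frame(records: Sequence[AnthropometryRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records], columns=COHORT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[AnthropometryRecord]:
    return [AnthropometryRecord(**row) for row in df[COHORT_COLUMNS].to_dict("records")]


@dataclass(frozen=True)
class AllometricModel:
    """A fitted power-law (allometric) model for one circumference.

    The regression is ``ln C = intercept + height_exponent*ln(H_m)
    + weight_exponent*ln(W_kg) + female_offset*f`` with the circumference in
    cm and height in metres.  The normalized index divides out the fitted
    height/weight dependence:

    ``index = C * (H/ref_height)**(-height_exponent) * (W/ref_weight)**(-weight_exponent)``

    so that at the reference body size the index equals the raw circumference.
    """

    intercept: float
    height_exponent: float
    weight_exponent: float
    female_offset: float
    ref_height_cm: float
    ref_weight_kg: float
    r_squared: float = float("nan")
    n_fit: int = 0
    residual_sd: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0):
            raise DomainError(f"r_squared must be in [0, 1], got {self.r_squared!r}")
        if self.ref_height_cm <= 0 or self.ref_weight_kg <= 0:
            raise DomainError("reference height/weight must be positive")

    def predict_log_circumference(self, height_cm, weight_kg, female) -> np.ndarray:
        h = _require_positive("height_cm", height_cm)
        w = _require_positive("weight_kg", weight_kg)
        return (
            self.intercept
            + self.height_exponent * np.log(h / CM_PER_M)
            + self.weight_exponent * np.log(w)
            + self.female_offset * np.asarray(female, dtype=float)
        )

    def to_json(self) -> str:
        keys = (
            "intercept",
            "height_exponent",
            "weight_exponent",
            "female_offset",
            "ref_height_cm",
            "ref_weight_kg",
            "r_squared",
            "n_fit",
            "residual_sd",
        )
        return json.dumps({k: getattr(self, k) for k in keys}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AllometricModel":
        return cls(**json.loads(text))


#: Published hip allometry: ln HC = 2.658 - 0.310 ln H_m + 0.482 ln W + 0.083 f,
#: R^2 = 0.887, reference body size <H> = 166 cm, <W> = 73 kg (n = 16,034).
HIP_MODEL_NHANES3 = AllometricModel(
    intercept=2.658,
    height_exponent=-0.310,
    weight_exponent=0.482,
    female_offset=0.083,
    ref_height_cm=166.0,
    ref_weight_kg=73.0,
    r_squared=0.887,
    n_fit=16034,
)


def _require_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} must be positive and finite")
    return arr


def compute_bmi(height_cm, weight_kg):
    """Body mass index W/H^2 in kg/m^2 (height supplied in cm)."""
    h = _require_positive("height_cm", height_cm)
    w = _require_positive("weight_kg", weight_kg)
    return w / (h / CM_PER_M) ** 2


def compute_absi(waist_cm, height_cm, weight_kg):
    """A body shape index: WC / (BMI^(2/3) * H^(1/2)), metre-kg units.

    WC and H are converted to metres internally; the numeric value is on the
    conventional m^(11/6) kg^(-2/3) scale (population values around 0.08).
    """
    wc = _require_positive("waist_cm", waist_cm)
    h = _require_positive("height_cm", height_cm)
    bmi = compute_bmi(height_cm, weight_kg)
    return (wc / CM_PER_M) / (bmi ** (2.0 / 3.0) * np.sqrt(h / CM_PER_M))


def compute_whr(waist_cm, hip_cm):
    """Waist-to-hip circumference ratio (dimensionless)."""
    wc = _require_positive("waist_cm", waist_cm)
    hc = _require_positive("hip_cm", hip_cm)
    return wc / hc


def apply_allometric_index(model: AllometricModel, circumference_cm, height_cm, weight_kg):
    """Normalize a circumference to the model's reference body size.

    Applies the *negatives* of the regression exponents, so the index is the
    residual circumference re-expressed at ``(ref_height, ref_weight)``; at the
    reference body size the index equals the raw circumference exactly.
    """
    c = _require_positive("circumference_cm", circumference_cm)
    h = _require_positive("height_cm", height_cm)
    w = _require_positive("weight_kg", weight_kg)
    return (
        c
        * (h / model.ref_height_cm) ** (-model.height_exponent)
        * (w / model.ref_weight_kg) ** (-model.weight_exponent)
    )


def compute_hi(hip_cm, height_cm, weight_kg, model: AllometricModel = HIP_MODEL_NHANES3):
    """Hip index: hip circumference normalized to reference height and weight.

    With the published default model this is
    ``HC * (H/166)**0.310 * (W/73)**(-0.482)`` (cm).
    """
    return apply_allometric_index(model, hip_cm, height_cm, weight_kg)


def apply_eligibility(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the analysis gate: nonpregnant adults (age >= 18).

    Returns the eligible subset and a count dict.  This is the single explicit
    exclusion gate; index/fit operations do not silently re-filter.
    """
    n0 = len(df)
    mask = np.ones(n0, dtype=bool)
    if "pregnant" in df.columns:
        mask &= ~(df["pregnant"].to_numpy(dtype=float) == 1)
    n_pregnant = int(n0 - mask.sum())
    if "age_years" in df.columns:
        mask &= df["age_years"].to_numpy(dtype=float) >= 18.0
    counts = {
        "n_input": n0,
        "n_excluded_pregnant": n_pregnant,
        "n_excluded_minor": int(n0 - mask.sum()) - n_pregnant,
        "n_eligible": int(mask.sum()),
    }
    if counts["n_excluded_pregnant"] or counts["n_excluded_minor"]:
        logger.info(
            "eligibility gate: %(n_excluded_pregnant)d pregnant and %(n_excluded_minor)d "
            "under-18 records excluded (%(n_eligible)d of %(n_input)d retained)",
            counts,
        )
    return df.loc[mask].reset_index(drop=True), counts


def fit_allometric_model(
    cohort: pd.DataFrame,
    circumference_field: str = "hip_cm",
    use_sample_weights: bool = True,
    round_reference: bool = True,
) -> AllometricModel:
    """Weighted log-log least squares of a circumference on height, weight, sex.

    Parameters
    ----------
    cohort
        Eligible records with columns ``height_cm``, ``weight_kg``, ``female``
        and *circumference_field* (plus ``sample_weight`` when weighting).
    circumference_field
        Column holding the circumference to model (``hip_cm`` or ``waist_cm``).
    use_sample_weights
        Fit by weighted least squares with the survey sample weights.
    round_reference
        Round the (weighted) mean height/weight to the nearest integer cm/kg
        when storing the reference body size, matching the published
        ⟨H⟩ = 166 cm, ⟨W⟩ = 73 kg convention.

    Returns the fitted :class:`AllometricModel`; the per-coefficient standard
    errors of (intercept, height, weight, female) are attached as a
    ``standard_errors`` attribute (not serialized).
    """
    required = {"height_cm", "weight_kg", "female", circumference_field}
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise SchemaError(f"cohort is missing columns: {missing}")
    n = len(cohort)
    if n < 5:
        raise InsufficientDataError(f"need >= 5 records to fit an allometric model, got {n}")

    h = _require_positive("height_cm", cohort["height_cm"].to_numpy(dtype=float))
    w = _require_positive("weight_kg", cohort["weight_kg"].to_numpy(dtype=float))
    c = _require_positive(circumference_field, cohort[circumference_field].to_numpy(dtype=float))
    f = cohort["female"].to_numpy(dtype=float)

    log_h = np.log(h / CM_PER_M)
    log_w = np.log(w)
    if np.ptp(log_h) < 1e-12 or np.ptp(log_w) < 1e-12:
        raise SingularFitError("constant ln(height) or ln(weight): design is singular")

    if use_sample_weights:
        if "sample_weight" not in cohort.columns:
            raise SchemaError("use_sample_weights=True requires a sample_weight column")
        wt = np.asarray(cohort["sample_weight"], dtype=float)
        if np.any(wt < 0) or not np.all(np.isfinite(wt)) or wt.sum() <= 0:
            raise DomainError("sample_weight must be nonnegative with positive total")
    else:
        wt = np.ones(n)

    X = np.column_stack([np.ones(n), log_h, log_w, f])
    res = sm.WLS(np.log(c), X, weights=wt).fit()

    ref_h = float(np.average(h, weights=wt))
    ref_w = float(np.average(w, weights=wt))
    if round_reference:
        ref_h, ref_w = float(round(ref_h)), float(round(ref_w))

    resid = np.log(c) - X @ res.params
    residual_sd = float(np.sqrt(np.average(resid**2, weights=wt)))
    model = AllometricModel(
        intercept=float(res.params[0]),
        height_exponent=float(res.params[1]),
        weight_exponent=float(res.params[2]),
        female_offset=float(res.params[3]),
        ref_height_cm=ref_h,
        ref_weight_kg=ref_w,
        r_squared=float(res.rsquared),
        n_fit=n,
        residual_sd=residual_sd,
    )
    # frozen dataclass: attach diagnostics via object.__setattr__
    object.__setattr__(model, "standard_errors", tuple(float(s) for s in res.bse))
    return model


def compute_index_panel(
    cohort: pd.DataFrame, hip_model: AllometricModel = HIP_MODEL_NHANES3
) -> pd.DataFrame:
    """Append the index columns (bmi, absi, hi, whr) to a cohort table."""
    out = cohort.copy()
    out["bmi"] = compute_bmi(cohort["height_cm"], cohort["weight_kg"])
    out["absi"] = compute_absi(cohort["waist_cm"], cohort["height_cm"], cohort["weight_kg"])
    out["hi"] = compute_hi(cohort["hip_cm"], cohort["height_cm"], cohort["weight_kg"], hip_model)
    out["whr"] = compute_whr(cohort["waist_cm"], cohort["hip_cm"])
    return out
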