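"""Composition of per-index risk curves into the anthropometric risk index (ARI).

The ARI of a subject is the sum of the fitted, centered log-hazard-ratio
functions of the four mutually near-independent indices — height, BMI, ABSI
and the hip index — each evaluated at the subject's age/sex z-score.  Under
the working assumption that the four hazards are independent, the sum is the
log of the combined mortality hazard ratio: positive values denote
above-average combined risk.  An :class:`ARIModel` bundles everything needed
to score a new cohort (reference statistics, hip allometry, curves and the
source-cohort standardization constants) and serializes to a single JSON
document.

Only the anthropometric curve values enter ARI; the sex/race adjuster
coefficients of the component fits do not (adjusters re-enter any downstream
Cox fit of ARI itself).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ScoringError
from .indices import (
    AllometricModel,
    AnthropometryRecord,
    apply_allometric_index,
    apply_eligibility,
    compute_absi,
    compute_bmi,
    compute_index_panel,
    fit_allometric_model,
)
from .reference import ReferenceStats, estimate_reference_stats, zscore_cohort
from .survival import (
    CoxFit,
    RiskCurve,
    SplineSpec,
    delta_aic_table,
    fit_cox_baseline,
    fit_cox_linear,
    fit_cox_spline,
    survival_frame,
)

__all__ = [
    "ARIModel",
    "ARIScore",
    "DEFAULT_ARI_INDICES",
    "build_ari_model",
    "score_cohort",
    "compute_ari",
    "fit_ari_linear",
    "model_comparison",
    "transfer_evaluate",
]

logger = logging.getLogger(__name__)

DEFAULT_ARI_INDICES = ("height", "bmi", "absi", "hi")
FORMAT_VERSION = 1


@dataclass
class ARIModel:
    """Serializable bundle: reference stats + centered risk curves + constants.

    ``ari_mean``/``ari_sd`` are the weighted mean and SD of the raw ARI over
    the source cohort, so the standardized ARI has weighted mean 0 and SD 1
    there.  A truncated model (e.g. height+BMI+ABSI when no hip circumference
    is available) carries fewer curves and says so in ``indices``.
    """

    reference_stats: ReferenceStats
    curves: dict
    hip_model: AllometricModel
    ari_mean: float
    ari_sd: float
    indices: tuple = DEFAULT_ARI_INDICES
    provenance: dict = field(default_factory=dict)
    component_fits: dict | None = None  # not serialized

    def __post_init__(self) -> None:
        if tuple(self.curves.keys()) != tuple(self.indices):
            raise DomainError(
                f"curves {tuple(self.curves)} do not match indices {tuple(self.indices)}"
            )
        if self.ari_sd <= 0:
            raise DomainError("ari_sd must be > 0")

    def to_json_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "indices": list(self.indices),
            "reference_stats": self.reference_stats.to_records(),
            "curves": {k: c.to_json_dict() for k, c in self.curves.items()},
            "hip_model": json.loads(self.hip_model.to_json()),
            "ari_mean": float(self.ari_mean),
            "ari_sd": float(self.ari_sd),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ARIModel":
        d = json.loads(text)
        indices = tuple(d["indices"])
        return cls(
            reference_stats=ReferenceStats.from_records(d["reference_stats"]),
            curves={k: RiskCurve.from_json_dict(d["curves"][k]) for k in indices},
            hip_model=AllometricModel(**d["hip_model"]),
            ari_mean=d["ari_mean"],
            ari_sd=d["ari_sd"],
            indices=tuple(d["indices"]),
            provenance=d.get("provenance", {}),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ARIModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


@dataclass
class ARIScore:
    """One subject's score: per-index contributions summing exactly to ARI."""

    subject_id: str
    ari: float
    ari_standardized: float
    contributions: dict
    zscores: dict


def build_ari_model(
    cohort: pd.DataFrame,
    spline_spec: SplineSpec | None = None,
    indices: tuple = DEFAULT_ARI_INDICES,
    age_bin_width: float = 5.0,
    use_sample_weights: bool = True,
    adjusters: tuple = ("female", "race_black"),
    provenance: dict | None = None,
    compute_metrics: bool = False,
) -> ARIModel:
    """Fit the full ARI pipeline on a source cohort.

    Pipeline: eligibility gate -> hip allometry fit -> index panel ->
    reference stats -> z-scores -> one penalized-spline Cox fit per index
    (adjusted for sex and race) -> centered curves -> ARI standardization
    constants.  The per-index :class:`CoxFit` objects are attached as
    ``component_fits`` (not serialized); they double as the single-index
    nonlinear models in comparisons.
    """
    eligible, gate_counts = apply_eligibility(cohort)
    hip_model = fit_allometric_model(eligible, "hip_cm", use_sample_weights=use_sample_weights)
    panel = compute_index_panel(eligible, hip_model=hip_model)
    stats = estimate_reference_stats(
        panel, index_names=indices, age_bin_width=age_bin_width,
        use_sample_weights=use_sample_weights,
    )
    panel = zscore_cohort(panel, stats, index_names=indices)
    frame = survival_frame(panel, keep=tuple(f"z_{name}" for name in indices))

    curves: dict = {}
    fits: dict = {}
    for name in indices:
        try:
            fit, curve = fit_cox_spline(
                frame, f"z_{name}", spec=spline_spec, adjusters=adjusters,
                use_sample_weights=use_sample_weights, compute_metrics=compute_metrics,
                label=name,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise naming the index
            raise type(exc)(f"ARI build failed on index {name!r}: {exc}") from exc
        curves[name] = curve
        fits[name] = fit

    ari_raw = np.zeros(len(panel))
    for name in indices:
        ari_raw += curves[name].evaluate(panel[f"z_{name}"].to_numpy())
    w = (
        panel["sample_weight"].to_numpy(dtype=float)
        if use_sample_weights
        else np.ones(len(panel))
    )
    w = w / w.sum()
    ari_mean = float(w @ ari_raw)
    ari_sd = float(np.sqrt(w @ (ari_raw - ari_mean) ** 2))
    if ari_sd <= 0:
        raise DomainError("degenerate ARI distribution (zero variance) on source cohort")

    prov = dict(provenance or {})
    prov.setdefault("n_source", len(panel))
    prov.setdefault("n_events_source", int(panel["died"].sum()))
    prov.setdefault("gate", gate_counts)
    return ARIModel(
        reference_stats=stats,
        curves=curves,
        hip_model=hip_model,
        ari_mean=ari_mean,
        ari_sd=ari_sd,
        indices=tuple(indices),
        provenance=prov,
        component_fits=fits,
    )


def _panel_for_model(model: ARIModel, cohort: pd.DataFrame, clamp_age: bool) -> pd.DataFrame:
    panel = compute_index_panel(cohort, hip_model=model.hip_model)
    return zscore_cohort(panel, model.reference_stats, index_names=model.indices, clamp_age=clamp_age)


def score_cohort(model: ARIModel, cohort: pd.DataFrame, clamp_age: bool = True) -> pd.DataFrame:
    """Score every subject of a cohort with a fitted ARI model.

    Returns one row per subject: z-scores, per-index log-hazard contributions,
    their exact sum ``ari`` and the standardized ``ari_standardized``
    (source-cohort mean 0, SD 1).  Ages and z-scores outside the model's
    coverage are clamped (and logged) by default, the policy needed when
    transferring a model to an older external cohort.
    """
    panel = _panel_for_model(model, cohort, clamp_age)
    out = pd.DataFrame({"subject_id": panel["subject_id"]})
    ari = np.zeros(len(panel))
    for name in model.indices:
        z = panel[f"z_{name}"].to_numpy()
        contrib = model.curves[name].evaluate(z)
        out[f"z_{name}"] = z
        out[f"contrib_{name}"] = contrib
        ari += contrib
    out["ari"] = ari
    out["ari_standardized"] = (ari - model.ari_mean) / model.ari_sd
    return out


def compute_ari(model: ARIModel, record: AnthropometryRecord, clamp_age: bool = True) -> ARIScore:
    """Score a single subject; contributions sum exactly to the ARI."""
    missing = [
        f for f in ("height_cm", "weight_kg", "waist_cm", "hip_cm")
        if not np.isfinite(getattr(record, f))
    ]
    if missing:
        raise ScoringError(f"cannot score subject {record.subject_id!r}: missing {missing}")
    record.validate()
    panel = {
        "height": record.height_cm,
        "bmi": float(compute_bmi(record.height_cm, record.weight_kg)),
        "absi": float(compute_absi(record.waist_cm, record.height_cm, record.weight_kg)),
        "hi": float(
            apply_allometric_index(model.hip_model, record.hip_cm, record.height_cm, record.weight_kg)
        ),
    }
    z = {}
    contributions = {}
    for name in model.indices:
        mean, sd = model.reference_stats.lookup(
            name, record.female, record.age_years, clamp_age=clamp_age
        )
        z[name] = (panel[name] - mean) / sd
        contributions[name] = float(model.curves[name].evaluate(z[name]))
    ari = float(sum(contributions.values()))
    return ARIScore(
        subject_id=record.subject_id,
        ari=ari,
        ari_standardized=(ari - model.ari_mean) / model.ari_sd,
        contributions=contributions,
        zscores=z,
    )


def fit_ari_linear(
    cohort: pd.DataFrame,
    model: ARIModel,
    use_sample_weights: bool = True,
    compute_metrics: bool = True,
    clamp_age: bool = True,
) -> CoxFit:
    """Cox fit with the standardized ARI as the single linear covariate.

    Reports the hazard ratio per SD increase of ARI, adjusted for sex/race.
    """
    scores = score_cohort(model, cohort, clamp_age=clamp_age)
    frame = survival_frame(cohort)
    frame["ari_standardized"] = scores["ari_standardized"].to_numpy()
    return fit_cox_linear(
        frame, "ari_standardized", use_sample_weights=use_sample_weights,
        compute_metrics=compute_metrics, label="ARI",
    )


def _comparison_table(fits: dict[str, CoxFit]) -> pd.DataFrame:
    """Assemble the standard comparison layout: HR/SD, delta_i, R^2, C."""
    delta = delta_aic_table(fits).set_index("predictor")
    rows = []
    for name, fit in fits.items():
        ci = fit.hr_ci or (np.nan, np.nan)
        rows.append(
            {
                "predictor": name,
                "form": fit.form,
                "hr_per_sd": fit.hr_per_sd if fit.hr_per_sd is not None else np.nan,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "delta_i": delta.loc[name, "delta_i"],
                "r2": fit.r_squared if fit.r_squared is not None else np.nan,
                "c": fit.concordance if fit.concordance is not None else np.nan,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("delta_i", kind="stable").reset_index(drop=True)
    )


def model_comparison(
    cohort: pd.DataFrame,
    model: ARIModel | None = None,
    spline_spec: SplineSpec | None = None,
    use_sample_weights: bool = True,
    compute_metrics: bool = True,
    clamp_age: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """In-sample model comparison: ARI (linear) vs. every single-index model.

    Builds the ARI model on the cohort when none is given (in which case the
    component spline fits are reused as the single-index nonlinear models),
    then fits the adjusters-only baseline and each index's linear model, and
    tabulates hazard ratios, AIC differences, explained variation and
    concordance.  Returns (table, fits).
    """
    if model is None:
        model = build_ari_model(
            cohort, spline_spec=spline_spec, use_sample_weights=use_sample_weights,
            compute_metrics=compute_metrics,
        )
        nonlinear_fits = dict(model.component_fits)
        panel = _panel_for_model(model, apply_eligibility(cohort)[0], clamp_age)
    else:
        panel = _panel_for_model(model, apply_eligibility(cohort)[0], clamp_age=True)
        nonlinear_fits = None

    frame = survival_frame(panel, keep=tuple(f"z_{n}" for n in model.indices))
    fits: dict[str, CoxFit] = {}
    fits["None"] = fit_cox_baseline(
        frame, use_sample_weights=use_sample_weights, compute_metrics=compute_metrics
    )
    for name in model.indices:
        fits[f"{name} (linear)"] = fit_cox_linear(
            frame, f"z_{name}", use_sample_weights=use_sample_weights,
            compute_metrics=compute_metrics, label=name,
        )
        if nonlinear_fits is not None:
            fits[f"{name} (nonlinear)"] = nonlinear_fits[name]
        else:
            fit, _ = fit_cox_spline(
                frame, f"z_{name}", spec=spline_spec,
                use_sample_weights=use_sample_weights,
                compute_metrics=compute_metrics, label=name,
            )
            fits[f"{name} (nonlinear)"] = fit

    scores = score_cohort(model, panel, clamp_age=True)
    frame["ari_standardized"] = scores["ari_standardized"].to_numpy()
    fits["ARI (linear)"] = fit_cox_linear(
        frame, "ari_standardized", use_sample_weights=use_sample_weights,
        compute_metrics=compute_metrics, label="ARI",
    )
    return _comparison_table(fits), fits


def transfer_evaluate(
    model: ARIModel,
    cohort_b: pd.DataFrame,
    spline_spec: SplineSpec | None = None,
    use_sample_weights: bool = True,
    compute_metrics: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate a fitted ARI model on an external cohort.

    Cohort B is scored entirely with cohort A's machinery (A's reference
    statistics, hip allometry and curves, with out-of-range ages and z-scores
    clamped and logged), then the transferred linear-ARI model is compared
    against B's own single-index linear and nonlinear models — all z-scored
    against A's normals, mirroring the external-validation design.
    Returns (comparison table, fits).
    """
    eligible, _ = apply_eligibility(cohort_b)
    return model_comparison(
        eligible, model=model, spline_spec=spline_spec,
        use_sample_weights=use_sample_weights, compute_metrics=compute_metrics,
    )
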