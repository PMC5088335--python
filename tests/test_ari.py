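"""ARI composition, scoring, serialization, and comparison/transfer plumbing."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from anthrorisk import (
    ARIModel,
    AnthropometryRecord,
    build_ari_model,
    compute_ari,
    fit_ari_linear,
    model_comparison,
    score_cohort,
    transfer_evaluate,
)
from anthrorisk.errors import ScoringError
from anthrorisk.reference import ReferenceStats
from anthrorisk.simulate import HazardSpec, default_config, generate_cohort
from anthrorisk.survival import RiskCurve

GRID = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.05), 10)


def _identity_curve(name: str) -> RiskCurve:
    """A RiskCurve representing f(z) = z exactly (cubic B-spline, Greville coefs)."""
    lo, hi, deg = -6.0, 6.0, 3
    interior = np.linspace(lo, hi, 9)[1:-1]
    knots = np.concatenate([[lo] * (deg + 1), interior, [hi] * (deg + 1)])
    m = len(knots) - deg - 1
    coefs = np.array([knots[j + 1 : j + 1 + deg].mean() for j in range(m)])
    return RiskCurve(
        knots=knots, degree=deg, coefficients=coefs, centering_offset=0.0,
        valid_range=(lo, hi), z_grid=GRID, log_hr=GRID.copy(),
        pointwise_se=np.zeros_like(GRID), index_name=name,
    )


def _flat_reference(index_names, mean=0.0, sd=1.0):
    rows = [
        (name, sex, 18.0, np.inf, mean, sd, 100.0)
        for name in index_names
        for sex in (0, 1)
    ]
    table = pd.DataFrame(
        rows, columns=["index_name", "sex", "age_lo", "age_hi", "mean", "sd", "effective_n"]
    )
    return ReferenceStats(table=table, age_bin_edges=np.array([18.0, np.inf]))


@pytest.fixture(scope="module")
def ari20k(cohort20k):
    return build_ari_model(cohort20k, compute_metrics=False)


def test_constructed_identity_model():
    """With identity curves and unit-variance references, a subject whose four
    indices sit 1 SD above their cell means scores ARI = 4 exactly."""
    from anthrorisk.indices import HIP_MODEL_NHANES3, compute_absi, compute_bmi, compute_hi

    h, w, wc, hc = 176.0, 89.0, 98.0, 103.0
    panel = {
        "height": h,
        "bmi": float(compute_bmi(h, w)),
        "absi": float(compute_absi(wc, h, w)),
        "hi": float(compute_hi(hc, h, w)),
    }
    indices = ("height", "bmi", "absi", "hi")
    # references centered one SD below each observed value -> all z = 1
    rows = [
        (name, sex, 18.0, np.inf, panel[name] - 2.5, 2.5, 100.0)
        for name in indices for sex in (0, 1)
    ]
    stats = ReferenceStats(
        table=pd.DataFrame(rows, columns=["index_name", "sex", "age_lo", "age_hi",
                                          "mean", "sd", "effective_n"]),
        age_bin_edges=np.array([18.0, np.inf]),
    )
    model = ARIModel(
        reference_stats=stats,
        curves={name: _identity_curve(name) for name in indices},
        hip_model=HIP_MODEL_NHANES3,
        ari_mean=0.0, ari_sd=1.0,
    )
    rec = AnthropometryRecord("X1", female=0, race_black=0, age_years=50.0,
                              height_cm=h, weight_kg=w, waist_cm=wc, hip_cm=hc)
    score = compute_ari(model, rec)
    assert score.ari == pytest.approx(4.0, abs=1e-9)
    assert all(v == pytest.approx(1.0, abs=1e-9) for v in score.contributions.values())


def test_contributions_sum_exactly(ari20k, cohort20k):
    scores = score_cohort(ari20k, cohort20k.head(500))
    total = sum(scores[f"contrib_{n}"] for n in ari20k.indices)
    np.testing.assert_array_equal(scores["ari"].to_numpy(), total.to_numpy())


def test_source_cohort_standardization(ari20k, cohort20k):
    scores = score_cohort(ari20k, cohort20k)
    w = cohort20k["sample_weight"].to_numpy()
    w = w / w.sum()
    s = scores["ari_standardized"].to_numpy()
    assert w @ s == pytest.approx(0.0, abs=1e-9)
    assert np.sqrt(w @ (s - w @ s) ** 2) == pytest.approx(1.0, abs=1e-9)


def test_single_record_matches_cohort_path(ari20k, cohort20k):
    row = cohort20k.iloc[7]
    rec = AnthropometryRecord(
        subject_id=row["subject_id"], female=int(row["female"]),
        race_black=int(row["race_black"]), age_years=row["age_years"],
        height_cm=row["height_cm"], weight_kg=row["weight_kg"],
        waist_cm=row["waist_cm"], hip_cm=row["hip_cm"],
    )
    score = compute_ari(ari20k, rec)
    frame_score = score_cohort(ari20k, cohort20k.iloc[[7]])
    assert score.ari == pytest.approx(frame_score["ari"].iloc[0], rel=1e-12)
    for name in ari20k.indices:
        assert score.contributions[name] == pytest.approx(
            frame_score[f"contrib_{name}"].iloc[0], rel=1e-10, abs=1e-12
        )


def test_scoring_error_on_missing_measurement(ari20k):
    rec = AnthropometryRecord("bad", 0, 0, 50.0, 170.0, 70.0, float("nan"), 100.0)
    with pytest.raises(ScoringError, match="waist_cm"):
        compute_ari(ari20k, rec)


def test_basis_evaluation_not_grid_interpolation(ari20k, rng):
    """Scoring evaluates the spline basis exactly; the dense grid is only a
    portable approximation.  Linear interpolation of the 0.05-step grid
    deviates from the basis by O(curvature * h^2 / 8) ~ 1e-4 — nonzero, which
    shows the two paths are distinct — while staying a faithful approximation."""
    curve = ari20k.curves["bmi"]
    lo, hi = curve.valid_range
    z = rng.uniform(max(lo, -3), min(hi, 3), 200)
    exact = curve.evaluate(z)
    interp = np.interp(z, curve.z_grid, curve.log_hr)
    diff = np.max(np.abs(exact - interp))
    assert 0 < diff < 5e-3


def test_build_determinism(cohort4k):
    m1 = build_ari_model(cohort4k, compute_metrics=False)
    m2 = build_ari_model(cohort4k, compute_metrics=False)
    assert m1.to_json() == m2.to_json()


def test_json_roundtrip_scores_identically(ari20k, cohort20k, tmp_path):
    path = tmp_path / "ari.json"
    ari20k.save(path)
    loaded = ARIModel.load(path)
    sample = cohort20k.head(200)
    a = score_cohort(ari20k, sample)
    b = score_cohort(loaded, sample)
    pd.testing.assert_frame_equal(a, b)


def test_null_build_gives_flat_curves():
    """With no true anthropometric effects the curves are near-flat and the
    ARI is uninformative (C ~ 0.5)."""
    cfg = dataclasses.replace(
        default_config(n=8000, seed=61),
        hazard=HazardSpec(beta_female=-0.4, beta_black=0.25, components={}),
    )
    cohort = generate_cohort(cfg)
    model = build_ari_model(cohort, compute_metrics=False)
    for name in model.indices:
        curve = model.curves[name]
        zq = np.quantile(cohort[f"z_{name}"], [0.05, 0.95])
        central = curve.evaluate(np.linspace(zq[0], zq[1], 50))
        assert np.max(np.abs(central)) < 0.25
    assert model.ari_sd < 0.2
    # ARI alone carries no signal: C ~ 0.5 and HR/SD ~ 1
    from anthrorisk import concordance_index, survival_frame

    scores = score_cohort(model, cohort)
    frame = survival_frame(cohort)
    c = concordance_index(
        frame["entry_age"], frame["exit_age"], frame["event"],
        scores["ari_standardized"].to_numpy(), frame["sample_weight"],
    )
    assert c == pytest.approx(0.5, abs=0.03)
    fit = fit_ari_linear(cohort, model, compute_metrics=False)
    assert fit.hr_per_sd == pytest.approx(1.0, abs=0.08)


def test_truncated_ari(cohort4k):
    model = build_ari_model(cohort4k, indices=("height", "bmi", "absi"), compute_metrics=False)
    assert set(model.curves) == {"height", "bmi", "absi"}
    scores = score_cohort(model, cohort4k.head(50))
    total = sum(scores[f"contrib_{n}"] for n in model.indices)
    np.testing.assert_array_equal(scores["ari"].to_numpy(), total.to_numpy())
    assert "contrib_hi" not in scores.columns


def test_curve_recovery_within_pointwise_ci(ari20k, cohort20k):
    """Each fitted curve covers its generating component function at >= 90% of
    central grid points (95% pointwise CIs)."""
    hz = default_config().hazard
    w = cohort20k["sample_weight"].to_numpy()
    w = w / w.sum()
    for name in ari20k.indices:
        curve = ari20k.curves[name]
        true_fn = hz.components[name].evaluate
        center = w @ true_fn(cohort20k[f"z_{name}"].to_numpy())
        zq = np.quantile(cohort20k[f"z_{name}"], [0.05, 0.95])
        mask = (curve.z_grid >= zq[0]) & (curve.z_grid <= zq[1])
        fitted = curve.log_hr[mask]
        se = curve.pointwise_se[mask]
        truth = true_fn(curve.z_grid[mask]) - center
        covered = np.abs(fitted - truth) <= 1.959964 * se
        assert covered.mean() >= 0.9, f"{name}: coverage {covered.mean():.2f}"


def test_self_transfer_matches_in_sample(cohort4k):
    """Transferring a model back onto its source cohort reproduces the
    in-sample ARI fit."""
    model = build_ari_model(cohort4k, compute_metrics=False)
    in_sample = fit_ari_linear(cohort4k, model, compute_metrics=False)
    table, fits = transfer_evaluate(model, cohort4k, compute_metrics=False)
    transferred = fits["ARI (linear)"]
    assert transferred.aic == pytest.approx(in_sample.aic, rel=1e-10)
    np.testing.assert_allclose(transferred.coefficients, in_sample.coefficients, rtol=1e-8)


def test_model_comparison_layout(cohort4k):
    table, fits = model_comparison(cohort4k, compute_metrics=True)
    assert list(table.columns) == [
        "predictor", "form", "hr_per_sd", "ci_lo", "ci_hi", "delta_i", "r2", "c",
    ]
    assert len(table) == 10  # baseline + 4 linear + 4 nonlinear + ARI
    assert table["delta_i"].iloc[0] == 0.0
    assert table["delta_i"].is_monotonic_increasing
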