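"""Cox engine: partial likelihood, linear fits, concordance, AICc, delta-AIC, R^2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import brute_concordance, brute_partial_ll

from anthrorisk import (
    aicc,
    concordance_index,
    delta_aic_table,
    explained_variation,
    fit_cox_baseline,
    fit_cox_linear,
    partial_log_likelihood,
    survival_frame,
)
from anthrorisk.errors import (
    ComparabilityError,
    UndefinedConcordanceError,
    UndefinedLikelihoodError,
)
from anthrorisk.simulate import default_config, generate_cohort
from anthrorisk.survival import CoxFit


# -- small random survival instances ----------------------------------------

@st.composite
def survival_instances(draw, max_n=6):
    n = draw(st.integers(min_value=1, max_value=max_n))
    entry = [draw(st.floats(0, 5)) for _ in range(n)]
    gaps = [draw(st.floats(0.1, 5)) for _ in range(n)]
    integer_times = draw(st.booleans())  # force tied event ages
    exit_ = [np.ceil(e + g) if integer_times else e + g for e, g in zip(entry, gaps)]
    entry = [min(e, x - 0.05) for e, x in zip(entry, exit_)]
    event = [draw(st.booleans()) for _ in range(n)]
    if not any(event):
        event[draw(st.integers(0, n - 1))] = True
    lp = [draw(st.floats(-2, 2)) for _ in range(n)]
    weighted = draw(st.booleans())
    w = [draw(st.floats(0.2, 3)) for _ in range(n)] if weighted else None
    return (np.array(entry), np.array(exit_), np.array(event, dtype=bool),
            np.array(lp), None if w is None else np.array(w))


@settings(max_examples=250, derandomize=True, deadline=None)
@given(survival_instances())
def test_partial_likelihood_matches_enumeration(instance):
    """The O(n log n) engine agrees with exhaustive risk-set enumeration,
    including tied event ages and case weights."""
    entry, exit_, event, lp, w = instance
    got = partial_log_likelihood(entry, exit_, event, lp, w)
    want = brute_partial_ll(entry, exit_, event, lp, w)
    assert got == pytest.approx(want, abs=1e-10, rel=1e-10)


@settings(max_examples=250, derandomize=True, deadline=None)
@given(survival_instances())
def test_concordance_matches_enumeration(instance):
    entry, exit_, event, lp, w = instance
    want = brute_concordance(entry, exit_, event, lp, w)
    if want is None:
        with pytest.raises(UndefinedConcordanceError):
            concordance_index(entry, exit_, event, lp, w)
    else:
        assert concordance_index(entry, exit_, event, lp, w) == pytest.approx(want)


def test_partial_likelihood_trivia():
    # single event with a risk set of one contributes log(1) = 0
    assert partial_log_likelihood([50.0], [60.0], [1], [0.7]) == pytest.approx(0.0)
    # translation invariance
    entry = np.array([40.0, 45.0, 50.0])
    exit_ = np.array([55.0, 52.0, 61.0])
    event = np.array([1, 1, 0])
    lp = np.array([0.3, -0.2, 0.9])
    a = partial_log_likelihood(entry, exit_, event, lp)
    b = partial_log_likelihood(entry, exit_, event, lp + 17.5)
    assert a == pytest.approx(b, rel=1e-12)
    with pytest.raises(UndefinedLikelihoodError):
        partial_log_likelihood(entry, exit_, [0, 0, 0], lp)


def test_linear_fit_matches_grid_search():
    """Three-subject fit agrees with direct maximization of the brute-force
    partial likelihood over a fine coefficient grid."""
    frame = pd.DataFrame(
        dict(entry_age=[40.0, 42.0, 45.0], exit_age=[50.0, 55.0, 58.0],
             event=[1, 1, 1], z=[1.0, -0.5, 0.3],
             female=[0, 0, 0], race_black=[0, 0, 0], sample_weight=[1.0, 1.0, 1.0])
    )
    fit = fit_cox_linear(frame, "z", adjusters=(), compute_metrics=False)
    grid = np.linspace(-4, 4, 8001)
    lls = [
        brute_partial_ll(frame.entry_age, frame.exit_age, frame.event, b * frame.z.to_numpy())
        for b in grid
    ]
    assert fit.coefficients[0] == pytest.approx(grid[int(np.argmax(lls))], abs=2e-3)
    assert fit.log_partial_likelihood == pytest.approx(max(lls), abs=1e-5)


def test_linear_fit_matches_lifelines(rng):
    """Independent cross-check: coefficients, log-likelihood and SEs against
    lifelines' Cox fit with delayed entry and case weights."""
    lifelines = pytest.importorskip("lifelines")
    n = 1500
    entry = rng.uniform(30, 70, n)
    z = rng.normal(0, 1, n)
    female = rng.integers(0, 2, n)
    black = rng.integers(0, 2, n)
    T = entry + rng.exponential(8 / np.exp(0.3 * z - 0.3 * female + 0.2 * black), n)
    frame = pd.DataFrame(
        dict(entry_age=entry, exit_age=np.minimum(T, entry + 15),
             event=(T <= entry + 15).astype(int), z=z, female=female,
             race_black=black, sample_weight=rng.uniform(0.5, 2, n))
    )
    fit = fit_cox_linear(frame, "z", compute_metrics=False)
    cph = lifelines.CoxPHFitter()
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(frame.rename(columns={"exit_age": "T", "event": "E"}),
                duration_col="T", event_col="E", entry_col="entry_age",
                weights_col="sample_weight", formula="z + female + race_black")
    np.testing.assert_allclose(
        fit.coefficients, cph.params_[["z", "female", "race_black"]], rtol=1e-5
    )
    assert fit.log_partial_likelihood == pytest.approx(cph.log_likelihood_, rel=1e-9)
    np.testing.assert_allclose(
        np.sqrt(np.diag(fit.covariance)),
        cph.standard_errors_[["z", "female", "race_black"]], rtol=1e-4,
    )


def test_null_covariate_hr_near_one():
    """A covariate permuted against outcomes gives HR ~ 1 with CI covering 1."""
    cohort = generate_cohort(default_config(n=8000, seed=21))
    frame = survival_frame(cohort, keep=("z_bmi",))
    perm = np.random.default_rng(5).permutation(len(frame))
    frame["z_perm"] = frame["z_bmi"].to_numpy()[perm]
    fit = fit_cox_linear(frame, "z_perm", compute_metrics=False)
    assert fit.hr_per_sd == pytest.approx(1.0, abs=0.06)
    lo, hi = fit.hr_ci
    assert lo < 1.0 < hi


def test_linear_slope_recovery_within_3se():
    """Cohorts with a true linear log-hazard slope 0.25/SD recover it within
    3 SEs in nearly all replicates (scaled-down recovery simulation)."""
    from anthrorisk.simulate import ComponentEffect, GeneratorConfig, HazardSpec

    hits, n_rep = 0, 10
    for seed in range(300, 300 + n_rep):
        cfg = GeneratorConfig(
            n=4000, seed=seed,
            hazard=HazardSpec(components={"bmi": ComponentEffect("linear", slope=0.25)}),
        )
        cohort = generate_cohort(cfg)
        fit = fit_cox_linear(survival_frame(cohort, keep=("z_bmi",)), "z_bmi",
                             compute_metrics=False)
        se = np.sqrt(fit.covariance[0, 0])
        if abs(fit.coefficients[0] - 0.25) <= 3 * se:
            hits += 1
    assert hits >= n_rep - 1


def test_concordance_trivia():
    entry = np.zeros(3)
    exit_ = np.array([1.0, 2.0, 3.0])
    event = np.array([1, 1, 1])
    # perfect risk ordering: earlier death = higher predictor
    assert concordance_index(entry, exit_, event, [3.0, 2.0, 1.0]) == 1.0
    # constant predictor: all ties
    assert concordance_index(entry, exit_, event, [1.0, 1.0, 1.0]) == 0.5
    # exactly one discordant pair of three comparable
    assert concordance_index(entry, exit_, event, [3.0, 1.0, 2.0]) == pytest.approx(2.0 / 3.0)
    # reversal maps C -> 1 - C on tie-free data
    lp = np.array([0.3, -1.2, 0.8])
    c = concordance_index(entry, exit_, event, lp)
    assert concordance_index(entry, exit_, event, -lp) == pytest.approx(1.0 - c)


def _fit_stub(ll, df, m):
    return CoxFit(
        names=(), coefficients=np.zeros(1), covariance=np.eye(1),
        log_partial_likelihood=ll, null_log_partial_likelihood=ll - 1.0,
        df_eff=df, aic=-2 * ll + 2 * df, aicc=np.nan, n_events=m, n=m,
    )


def test_aicc_values():
    assert aicc(_fit_stub(-50.0, 0.0, 100)) == pytest.approx(100.0)
    assert aicc(_fit_stub(-100.0, 4.0, 100)) == pytest.approx(208.421, abs=1e-3)
    # converges to AIC as events grow
    vals = [aicc(_fit_stub(-100.0, 4.0, m)) for m in (50, 500, 5000)]
    assert vals[0] > vals[1] > vals[2] > 208.0
    with pytest.warns(UserWarning):
        assert aicc(_fit_stub(-100.0, 4.0, 5)) == np.inf


def test_delta_aic_table():
    fits = {"a": _fit_stub(-50.0, 0, 40), "b": _fit_stub(-51.5, 0, 40)}
    tab = delta_aic_table(fits)  # AICs {100, 103}
    assert list(tab["delta_i"]) == [0.0, 3.0]
    assert not tab["significantly_worse"].any()
    fits2 = {"a": _fit_stub(-25.0, 0, 40), "b": _fit_stub(-28.5, 0, 40)}  # {50, 57}
    tab2 = delta_aic_table(fits2)
    assert tab2.loc[tab2.predictor == "b", "significantly_worse"].item()
    # input order does not matter
    tab3 = delta_aic_table(dict(reversed(list(fits2.items()))))
    pd.testing.assert_frame_equal(tab2, tab3)
    with pytest.raises(ComparabilityError):
        delta_aic_table({"a": _fit_stub(-25.0, 0, 40), "b": _fit_stub(-25.0, 0, 39)})


def test_explained_variation():
    fit = _fit_stub(-490.0, 1, 400)
    null = _fit_stub(-500.0, 0, 400)
    assert explained_variation(fit, fit) == 0.0
    assert explained_variation(fit, null) == pytest.approx(0.04877, abs=1e-5)
    better = _fit_stub(-480.0, 1, 400)
    assert explained_variation(better, null) > explained_variation(fit, null)
    with pytest.warns(UserWarning):
        assert explained_variation(null, fit) == 0.0


def test_null_delta_vs_baseline_usually_small():
    """With a covariate independent of outcome, the linear model's AIC penalty
    rarely exceeds the delta > 6 significance threshold vs the baseline."""
    ok, n_rep = 0, 10
    for seed in range(400, 400 + n_rep):
        cohort = generate_cohort(default_config(n=2500, seed=seed))
        frame = survival_frame(cohort, keep=("z_height",))
        perm = np.random.default_rng(seed).permutation(len(frame))
        frame["z_perm"] = frame["z_height"].to_numpy()[perm]
        fits = {
            "None": fit_cox_baseline(frame, compute_metrics=False),
            "perm": fit_cox_linear(frame, "z_perm", compute_metrics=False),
        }
        tab = delta_aic_table(fits).set_index("predictor")
        if tab.loc["perm", "delta_i"] < 6 or tab.loc["None", "delta_i"] < 6:
            # either ordering is fine as long as neither is flagged far worse
            if max(tab["delta_i"]) < 6:
                ok += 1
    assert ok >= 9
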