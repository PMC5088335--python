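"""Independent brute-force oracles used by the test suite.

These deliberately mirror the *definitions* (exhaustive risk-set enumeration,
pair counting, explicit normal equations) rather than the package's
implementations, so agreement is a meaningful check.
"""

import numpy as np


def brute_partial_ll(entry, exit_, event, lp, weights=None):
    """Weighted Efron partial log-likelihood by exhaustive risk-set enumeration."""
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, bool)
    lp = np.asarray(lp, float)
    n = len(exit_)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    r = np.exp(lp)
    ll = 0.0
    for t in sorted(set(exit_[event])):
        D = [i for i in range(n) if event[i] and exit_[i] == t]
        R = [i for i in range(n) if entry[i] < t <= exit_[i]]
        d = len(D)
        wbar = sum(w[i] for i in D) / d
        S0R = sum(w[i] * r[i] for i in R)
        S0D = sum(w[i] * r[i] for i in D)
        ll += sum(w[i] * lp[i] for i in D)
        for ell in range(d):
            ll -= wbar * np.log(S0R - (ell / d) * S0D)
    return ll


def brute_concordance(entry, exit_, event, lp, weights=None):
    """Harrell C with delayed entry by explicit pair enumeration.

    Pair (i, j) is comparable when i dies at t and j is observed strictly
    beyond t; concordant when lp_i > lp_j; predictor ties count 1/2.
    Returns None when no pair is comparable.
    """
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, bool)
    lp = np.asarray(lp, float)
    n = len(exit_)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    num = den = 0.0
    for i in range(n):
        if not event[i]:
            continue
        t = exit_[i]
        for j in range(n):
            if j == i or not (entry[j] < t < exit_[j]):
                continue
            pw = w[i] * w[j]
            den += pw
            if lp[i] > lp[j]:
                num += pw
            elif lp[i] == lp[j]:
                num += 0.5 * pw
    return None if den == 0 else num / den


def brute_allometric_fit(height_cm, weight_kg, female, circumference_cm, weights=None):
    """Solve the 4x4 weighted normal equations of the log-log regression directly."""
    h = np.log(np.asarray(height_cm, float) / 100.0)
    wv = np.log(np.asarray(weight_kg, float))
    f = np.asarray(female, float)
    y = np.log(np.asarray(circumference_cm, float))
    n = len(y)
    wt = np.ones(n) if weights is None else np.asarray(weights, float)
    X = np.column_stack([np.ones(n), h, wv, f])
    XtW = X.T * wt
    return np.linalg.solve(XtW @ X, XtW @ y)


def gompertz_death_probability(t0, a, b, cap):
    """P(death within `cap` years | alive at age t0) under a pure Gompertz hazard."""
    if b > 0:
        lam = (a / b) * (np.exp(b * (t0 + cap)) - np.exp(b * t0))
    else:
        lam = a * cap
    return 1.0 - np.exp(-lam)
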