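"""Burg lattice estimator: examples, oracles and invariants."""

import numpy as np
import pytest

from emgburg import (BurgAR, burg_reflection, lattice_errors,
                     levinson_from_reflection, prediction_error_power,
                     simulate_ar, yule_walker)


def step_down(a):
    """Independent inverse (Levinson step-down) oracle: AR coefficients ->
    reflection coefficients."""
    a = np.asarray(a, dtype=float).copy()
    k = np.zeros(a.size)
    for m in range(a.size, 0, -1):
        km = a[m - 1]
        k[m - 1] = km
        if m > 1:
            prev = (a[: m - 1] - km * a[: m - 1][::-1]) / (1.0 - km**2)
            a = prev
    return k


def burg_by_stagewise_minimization(x, p):
    """Oracle: at each stage, find K_m by dense 1-D numerical minimisation
    of the summed forward+backward error power, independent of the
    closed-form ratio."""
    f = x.copy()
    b = x.copy()
    ks = []
    for _ in range(p):
        f_prev, b_prev = f[1:], b[:-1]

        def power(km):
            return float(np.sum((f_prev + km * b_prev) ** 2)
                         + np.sum((km * f_prev + b_prev) ** 2))

        # dense grid to locate the minimum, then an exact three-point
        # parabolic polish (the error power is quadratic in K)
        grid = np.linspace(-1.001, 1.001, 2001)
        vals = np.array([power(g) for g in grid])
        g = float(grid[int(np.argmin(vals))])
        h = 1e-2
        num = power(g + h) - power(g - h)
        den = power(g + h) - 2.0 * power(g) + power(g - h)
        km = g - 0.5 * h * num / den
        ks.append(km)
        f = f_prev + km * b_prev
        b = km * f_prev + b_prev
    return np.array(ks)


# ---------------------------------------------------------------------------
# pinned examples


def test_alternating_signal_k1_is_plus_one():
    x = np.tile([1.0, -1.0], 10)
    res = burg_reflection(x, order=1)
    assert res.k[0] == pytest.approx(1.0)
    # the normalised lag-1 autocorrelation of the same signal is -1
    r1 = np.dot(x[1:], x[:-1]) / np.dot(x[:-1], x[:-1])
    assert r1 == pytest.approx(-1.0)


def test_constant_signal_k1_magnitude_one():
    res = burg_reflection(np.full(16, 3.0), order=1)
    assert abs(res.k[0]) == pytest.approx(1.0)
    assert res.k[0] == pytest.approx(-1.0)  # one-step self-prediction


def test_scale_and_sign_invariance_of_k(rng):
    x = rng.standard_normal(400)
    k0 = burg_reflection(x, 6).k
    np.testing.assert_allclose(burg_reflection(3.7 * x, 6).k, k0, rtol=1e-12)
    np.testing.assert_allclose(burg_reflection(-x, 6).k, k0, rtol=1e-12)


# ---------------------------------------------------------------------------
# Levinson recursion


def test_levinson_single_stage():
    np.testing.assert_allclose(levinson_from_reflection([0.3]), [0.3])


def test_levinson_two_stage_closed_form():
    k1, k2 = 0.4, -0.25
    a = levinson_from_reflection([k1, k2])
    np.testing.assert_allclose(a, [k1 + k2 * k1, k2])


def test_levinson_roundtrip_with_stepdown_oracle(rng):
    for _ in range(20):
        k = rng.uniform(-0.95, 0.95, size=6)
        a = levinson_from_reflection(k)
        np.testing.assert_allclose(step_down(a), k, atol=1e-10)


def test_levinson_rejects_unstable():
    with pytest.raises(ValueError, match="unstable"):
        levinson_from_reflection([0.5, 1.2])


def test_final_stage_coefficient_equals_reflection(rng):
    x = rng.standard_normal(300)
    res = burg_reflection(x, 5)
    assert res.arcoefs[-1] == pytest.approx(res.k[-1])
    # the whole K vector is recoverable from the final AR coefficients
    np.testing.assert_allclose(step_down(res.arcoefs), res.k, atol=1e-10)


# ---------------------------------------------------------------------------
# lattice errors


def test_lattice_stage0_is_the_signal(rng):
    x = rng.standard_normal(50)
    state = lattice_errors(x, [], 0)
    np.testing.assert_array_equal(state.f, x)
    np.testing.assert_array_equal(state.b, x)


def test_lattice_stage1_closed_form(rng):
    x = rng.standard_normal(60)
    k1 = 0.37
    state = lattice_errors(x, [k1], 1)
    np.testing.assert_allclose(state.f, x[1:] + k1 * x[:-1], atol=1e-14)
    np.testing.assert_allclose(state.b, k1 * x[1:] + x[:-1], atol=1e-14)


def test_lattice_stage2_polynomial_expansion(rng):
    x = rng.standard_normal(60)
    k1, k2 = 0.3, -0.5
    state = lattice_errors(x, [k1, k2], 2)
    n = np.arange(2, 60)
    f2 = x[n] + k1 * x[n - 1] + k2 * (k1 * x[n - 1] + x[n - 2])
    b2 = k2 * (x[n] + k1 * x[n - 1]) + k1 * x[n - 1] + x[n - 2]
    np.testing.assert_allclose(state.f, f2, atol=1e-14)
    np.testing.assert_allclose(state.b, b2, atol=1e-14)


def test_lattice_rejects_stage_beyond_coefficients(rng):
    with pytest.raises(ValueError, match="exceeds"):
        lattice_errors(rng.standard_normal(20), [0.1], 2)


def test_error_power_stage0_is_twice_ssi(rng):
    x = rng.standard_normal(100)
    state = lattice_errors(x, [], 0)
    assert prediction_error_power(state) == pytest.approx(2.0 * np.sum(x**2))


def test_error_power_non_increasing_over_random_signals(rng):
    for _ in range(100):
        x = rng.standard_normal(rng.integers(30, 120))
        res = burg_reflection(x, 8)
        assert np.all(np.diff(res.eps) <= 1e-9 * res.eps[0])


def test_noise_free_ar1_first_stage_error_vanishes():
    # x[n] = -x[n-1] exactly: predictable forwards and backwards with the
    # same reflection coefficient, so the stage-1 error power vanishes
    x = np.tile([1.0, -1.0], 30)
    res = burg_reflection(x, 1)
    assert res.eps[1] <= 1e-12 * res.eps[0]


# ---------------------------------------------------------------------------
# oracle equivalence and cross-checks


def test_k_matches_stagewise_numerical_minimization(rng):
    for _ in range(10):
        n = int(rng.integers(16, 64))
        p = int(rng.integers(1, 5))
        x = rng.standard_normal(n)
        np.testing.assert_allclose(burg_reflection(x, p).k,
                                   burg_by_stagewise_minimization(x, p),
                                   atol=1e-8)


def test_matches_statsmodels_burg(rng):
    import statsmodels.api as sm
    x = rng.standard_normal(500)
    res = burg_reflection(x, 4)
    rho, sigma2 = sm.regression.linear_model.burg(x, order=4, demean=False)
    np.testing.assert_allclose(res.arcoefs_ar, rho, atol=1e-10)
    assert res.sigma2 == pytest.approx(float(sigma2), rel=0.05)


def test_reflection_bound_fuzz(rng):
    """|K_m| <= 1 over a battery of white-noise, AR and near-constant signals."""
    for i in range(300):
        kind = i % 3
        n = int(rng.integers(20, 200))
        if kind == 0:
            x = rng.standard_normal(n)
        elif kind == 1:
            x = simulate_ar(rng.uniform(-0.9, 0.9, size=3), n, rng)
        else:
            x = 5.0 + 1e-3 * rng.standard_normal(n)
        res = burg_reflection(x, order=min(10, n - 1))
        assert np.max(np.abs(res.k)) <= 1.0 + 1e-12


def test_parameter_recovery():
    """The generator's own class parameters are recovered from clean AR
    output at N = 3000 with mean RMSE below 0.02."""
    from emgburg import default_class_bank
    errs = []
    for ci, cp in enumerate(default_class_bank(p=4)):
        k_true = cp.k_true[0]
        for seed in range(5):
            x = simulate_ar(k_true, 3000, np.random.default_rng([seed, ci]))
            errs.append(np.sqrt(np.mean((burg_reflection(x, 4).k - k_true) ** 2)))
    assert np.mean(errs) < 0.02


def test_rejections():
    with pytest.raises(ValueError, match="order"):
        BurgAR(np.ones(5), order=10)
    with pytest.raises(ValueError, match="zero-energy"):
        burg_reflection(np.zeros(50), 2)


# ---------------------------------------------------------------------------
# Yule-Walker comparison estimator


def test_yule_walker_white_noise_coefficients_small(rng):
    x = rng.standard_normal(50_000)
    yw = yule_walker(x, 4)
    assert np.max(np.abs(yw.a)) < 5.0 / np.sqrt(x.size) * 3
    assert yw.r_hat[0] >= np.max(np.abs(yw.r_hat[1:]))
    assert yw.sigma_w2 > 0


def test_yule_walker_ar1_closed_form():
    # noise-free AR(1): phi = r(1)/r(0)
    phi = 0.7
    x = phi ** np.arange(2000)
    yw = yule_walker(x, 1)
    assert yw.a[0] == pytest.approx(yw.r_hat[1] / yw.r_hat[0], rel=1e-10)
    assert yw.a[0] == pytest.approx(phi, abs=0.01)


def test_burg_yule_walker_gaussian_agreement():
    """On long Gaussian AR(2) data the two estimators coincide to ~1%."""
    x = simulate_ar([0.5, -0.3], 100_000, np.random.default_rng(123))
    burg = burg_reflection(x, 2)
    yw = yule_walker(x, 2)
    np.testing.assert_allclose(burg.arcoefs_ar, yw.a, rtol=0.01)


def test_summary_mentions_order_and_coefficients(rng):
    res = burg_reflection(rng.standard_normal(200), 3)
    text = res.summary()
    assert "order: 3" in text
    assert f"{res.k[0]:.6f}" in text
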