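"""Statistics core: design matrices, OLS/REML fits, AICc, cascade selection,
contributions, time constants and binned t-tests, each against an
independent oracle."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from sideslip.models import (
    EQN_ROLL,
    ManeuverModel,
    ModelSpec,
    aicc,
    cascade_select,
    contribution_table,
    damping_time_constants,
    design_matrix,
    fit_linear,
    fit_mixed_random_intercept,
    roll_acceleration_check,
    updown_binned_ttests,
)

G = 980.665


def toy_table(n=40, seed=0, **overrides):
    """Minimal stroke table with independently drawn predictor columns."""
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame({
        "beta": rng.normal(0.0, 10.0, n),
        "y_dot": rng.normal(0.0, 20.0, n),
        "z_dot": rng.normal(0.0, 15.0, n),
        "alpha_LR": rng.normal(0.0, 5.0, n),
        "phi_p_LR": rng.normal(0.0, 3.0, n),
        "theta_p_LR": rng.normal(0.0, 2.0, n),
        "phi_LR": rng.normal(0.0, 3.0, n),
        "theta_LR": rng.normal(0.0, 3.0, n),
        "phi_p_bar_c": rng.normal(0.0, 4.0, n),
        "theta_p_bar_c": rng.normal(0.0, 3.0, n),
        "alpha_bar_c": rng.normal(0.0, 2.0, n),
        "drag_i": rng.normal(0.0, 5.0, n),
        "stroke": np.resize(["down", "up"], n),
        "moth_id": np.repeat([f"m{i}" for i in range(4)], int(np.ceil(n / 4)))[:n],
        "trial_id": np.repeat([f"t{i}" for i in range(8)], int(np.ceil(n / 8)))[:n],
    })
    tab["sgn_beta"] = np.sign(tab["beta"])
    tab["y_ddot"] = rng.normal(0.0, 10.0, n)
    tab["z_ddot"] = rng.normal(0.0, 10.0, n)
    tab["beta_dot"] = rng.normal(0.0, 50.0, n)
    tab["beta_ddot"] = rng.normal(0.0, 500.0, n)
    for k, v in overrides.items():
        tab[k] = v
    return tab


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def test_roll_transforms_at_zero_and_ninety():
    tab = toy_table(6, beta=np.array([0.0, 0.0, 90.0, 90.0, -30.0, 45.0]))
    tab["sgn_beta"] = np.sign(tab["beta"])
    spec = ModelSpec("y_ddot", ("g_sin_beta", "g_one_minus_cos_beta"))
    _, X, _ = design_matrix(tab, spec)
    assert X["g_sin_beta"].iloc[0] == 0.0
    assert X["g_one_minus_cos_beta"].iloc[1] == 0.0
    assert X["g_sin_beta"].iloc[2] == pytest.approx(980.665)
    assert X["g_sin_beta"].iloc[4] == pytest.approx(-G * 0.5)


def test_sign_multiplied_column_matches_hand_arithmetic():
    tab = toy_table(4,
                    beta=np.array([10.0, -5.0, 3.0, -8.0]),
                    phi_p_bar_c=np.array([1.0, 2.0, -3.0, 4.0]))
    tab["sgn_beta"] = np.sign(tab["beta"])
    _, X, _ = design_matrix(tab, ModelSpec("y_ddot", ("sgn_phi_p_bar_c",)))
    np.testing.assert_allclose(X["sgn_phi_p_bar_c"], [1.0, -2.0, -3.0, -4.0])


def test_unknown_term_error_lists_valid_terms():
    with pytest.raises(ValueError, match="alpha_LR"):
        ModelSpec("y_ddot", ("no_such_term",))


def test_missing_rows_dropped_and_counted():
    tab = toy_table(10)
    tab.loc[3, "y_dot"] = np.nan
    tab.loc[7, "y_ddot"] = np.nan
    y, X, dropped = design_matrix(tab, ModelSpec("y_ddot", ("y_dot",)))
    assert dropped == 2 and len(y) == 8


def test_roll_spec_refuses_intercept():
    with pytest.raises(ValueError, match="intercept"):
        ModelSpec("beta_dot", ("alpha_LR",), intercept=True)


# ---------------------------------------------------------------------------
# ordinary least squares
# ---------------------------------------------------------------------------


def test_exact_single_term_fit_recovers_unity():
    tab = toy_table(30, seed=1)
    tab["y_ddot"] = G * np.sin(np.deg2rad(tab["beta"]))
    res = fit_linear(tab, ModelSpec("y_ddot", ("g_sin_beta",)))
    assert res.params["g_sin_beta"] == pytest.approx(1.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)


def test_three_point_fit_matches_normal_equations():
    """Hand dataset solved by explicit normal equations."""
    tab = toy_table(3,
                    y_dot=np.array([1.0, 2.0, 4.0]),
                    phi_p_bar_c=np.array([0.5, -1.0, 2.0]),
                    y_ddot=np.array([3.0, 1.0, -2.0]))
    res = fit_linear(tab, ModelSpec("y_ddot", ("y_dot", "phi_p_bar_c")))
    X = np.column_stack([tab["y_dot"], tab["phi_p_bar_c"]])
    beta = np.linalg.solve(X.T @ X, X.T @ tab["y_ddot"].to_numpy())
    np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-10)


def test_null_pvalues_are_uniform():
    """Under a pure-noise response the coefficient p-value is uniform
    (KS test over 1000 seeded replicates)."""
    rng = np.random.default_rng(99)
    pvals = []
    x = rng.normal(size=15)
    for _ in range(1000):
        tab = toy_table(15, y_dot=x, y_ddot=rng.normal(size=15))
        res = fit_linear(tab, ModelSpec("y_ddot", ("y_dot",), intercept=True))
        pvals.append(res.pvalues["y_dot"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_collinear_columns_named():
    tab = toy_table(20)
    tab["phi_p_LR"] = 2.0 * tab["alpha_LR"]
    with pytest.raises(ValueError, match="alpha_LR"):
        fit_linear(tab, ModelSpec("beta_dot", ("alpha_LR", "phi_p_LR")))


# ---------------------------------------------------------------------------
# AICc
# ---------------------------------------------------------------------------


def test_aicc_hand_formula():
    # n=10, k=3, llf=-12.5: AICc = 25 + 6 + 2*3*4/6 = 35
    assert aicc(-12.5, 3, 10) == pytest.approx(35.0)


def test_aicc_correction_vanishes_for_large_n():
    assert aicc(0.0, 3, 10 ** 6) - 6.0 < 1e-3


def test_aicc_requires_degrees_of_freedom():
    with pytest.raises(ValueError):
        aicc(0.0, 9, 10)


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------


def grouped_table(n_groups=4, per=12, group_sd=50.0, noise_sd=15.0, seed=0):
    rng = np.random.default_rng(seed)
    n = n_groups * per
    tab = toy_table(n, seed=seed + 1)
    tab["moth_id"] = np.repeat([f"m{i}" for i in range(n_groups)], per)
    u = rng.normal(0.0, group_sd, n_groups)
    tab["y_ddot"] = (0.9 * G * np.sin(np.deg2rad(tab["beta"]))
                     - 1.5 * tab["y_dot"] + np.repeat(u, per)
                     + rng.normal(0.0, noise_sd, n))
    return tab


def test_zero_group_variance_matches_ols():
    tab = grouped_table(per=40, group_sd=0.0, seed=2)
    spec = ModelSpec("y_ddot", ("g_sin_beta", "y_dot"), intercept=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = fit_mixed_random_intercept(tab, spec, "moth_id")
    ols = fit_linear(tab, spec)
    for term in spec.terms:
        assert mixed.params[term] == pytest.approx(ols.params[term], rel=0.01)
    assert mixed.singular


def test_reml_variance_recovery():
    """Across replicates the REML random-intercept variance estimate is
    unbiased for a known 50 cm/s^2 intercept spread over 4 groups."""
    ests = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(60):
            tab = grouped_table(group_sd=50.0, seed=100 + rep)
            res = fit_mixed_random_intercept(
                tab, ModelSpec("y_ddot", ("g_sin_beta", "y_dot"),
                               intercept=True), "moth_id")
            ests.append(res.group_var)
    mean_sd = math.sqrt(np.mean(ests))
    assert mean_sd == pytest.approx(50.0, rel=0.30)


def test_reml_llf_matches_closed_form():
    """The reported REML log-likelihood equals the explicit restricted
    likelihood formula evaluated at the fitted variance components, and the
    fitted components maximise that formula on a surrounding grid."""
    tab = grouped_table(n_groups=2, per=8, group_sd=30.0, seed=5)
    spec = ModelSpec("y_ddot", ("g_sin_beta",), intercept=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_mixed_random_intercept(tab, spec, "moth_id")
    model = res.model
    X = np.column_stack([np.ones(res.nobs), model.exog["g_sin_beta"]])
    y = model.endog.to_numpy()
    groups = model.groups.to_numpy()
    labels = sorted(set(groups))
    Z = np.stack([(groups == lab).astype(float) for lab in labels], axis=1)
    n, p = X.shape

    def reml_llf(tau2, s2):
        V = s2 * np.eye(n) + tau2 * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        _, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XtViX)
        return -0.5 * ((n - p) * math.log(2 * math.pi) + ldV + ldX + r @ Vi @ r)

    tau2, s2 = res.group_var, res.scale
    assert reml_llf(tau2, s2) == pytest.approx(res.llf, abs=1e-6)
    # grid search around the optimum never beats it (beyond tolerance)
    best = reml_llf(tau2, s2)
    for ft in (0.5, 0.8, 1.25, 2.0):
        for fs in (0.5, 0.8, 1.25, 2.0):
            assert reml_llf(tau2 * ft, s2 * fs) <= best + 1e-6


def test_mixed_model_group_preconditions():
    tab = grouped_table()
    tab["moth_id"] = "only_one"
    with pytest.raises(ValueError, match="2 groups"):
        fit_mixed_random_intercept(
            tab, ModelSpec("y_ddot", ("y_dot",), intercept=True), "moth_id")


def test_updown_split_columns():
    tab = grouped_table(seed=9)
    spec = ModelSpec("beta_dot", ("alpha_LR", "theta_p_LR"),
                     updown_split=frozenset({"theta_p_LR"}))
    res = fit_linear(tab, spec)
    assert {"alpha_LR", "theta_p_LR__down", "theta_p_LR__up"} == set(res.params.index)


# ---------------------------------------------------------------------------
# cascade selection
# ---------------------------------------------------------------------------


def test_cascade_finds_single_active_term():
    """One strongly active term among three candidates: the true term is
    always selected, and each inactive term is admitted no more often than
    AICc's nominal acceptance rate for one useless parameter (~16%) plus a
    Monte-Carlo margin."""
    reps = 40
    true_hits = 0
    noise_accepts = 0
    for rep in range(reps):
        rng = np.random.default_rng(500 + rep)
        tab = toy_table(60, seed=600 + rep)
        tab["beta_dot"] = 12.0 * tab["alpha_LR"] + rng.normal(0, 10.0, 60)
        spec, _ = cascade_select(tab, "beta_dot",
                                 ("alpha_LR", "phi_p_LR", "theta_p_LR"),
                                 groups=())
        if "alpha_LR" in spec.terms:
            true_hits += 1
        noise_accepts += sum(t in spec.terms for t in ("phi_p_LR", "theta_p_LR"))
    assert true_hits >= 0.95 * reps
    rate = noise_accepts / (2 * reps)
    assert rate <= 0.157 + 3.0 * math.sqrt(0.157 * 0.843 / (2 * reps))


def test_cascade_null_selects_empty_for_roll():
    empties = 0
    reps = 20
    for rep in range(reps):
        tab = toy_table(50, seed=700 + rep)
        spec, _ = cascade_select(tab, "beta_dot",
                                 ("alpha_LR", "phi_p_LR", "theta_p_LR"),
                                 groups=())
        if spec.terms == ():
            empties += 1
    assert empties > reps / 2


def test_cascade_trace_records_decisions():
    tab = toy_table(60, seed=4)
    tab["beta_dot"] = 10.0 * tab["alpha_LR"] - 2.0 * tab["y_dot"]
    spec, trace = cascade_select(tab, "beta_dot",
                                 ("alpha_LR", "y_dot", "theta_p_LR"), groups=())
    steps = [t["step"] for t in trace]
    assert steps[0] == "significance order"
    assert steps[-1] == "selected"
    assert "alpha_LR" in spec.terms and "y_dot" in spec.terms


def test_cascade_needs_two_candidates():
    with pytest.raises(ValueError):
        cascade_select(toy_table(), "beta_dot", ("alpha_LR",))


# ---------------------------------------------------------------------------
# contributions and time constants
# ---------------------------------------------------------------------------


def test_contribution_single_term_is_total():
    tab = toy_table(30, seed=3)
    tab["beta_dot"] = 5.0 * tab["alpha_LR"]
    res = fit_linear(tab, ModelSpec("beta_dot", ("alpha_LR",)))
    contrib = contribution_table(res)
    assert contrib["alpha_LR"] == pytest.approx(100.0)


def test_contribution_equal_terms_split_evenly():
    n = 50
    rng = np.random.default_rng(8)
    a = rng.normal(0, 3.0, n)
    b = rng.permutation(a)  # same |x| distribution
    tab = toy_table(n, alpha_LR=a, phi_p_LR=b)
    tab["beta_dot"] = 2.0 * tab["alpha_LR"] + 2.0 * tab["phi_p_LR"]
    res = fit_linear(tab, ModelSpec("beta_dot", ("alpha_LR", "phi_p_LR")))
    contrib = contribution_table(res)
    assert contrib["alpha_LR"] == pytest.approx(50.0, abs=1e-6)
    assert contrib["phi_p_LR"] == pytest.approx(50.0, abs=1e-6)


def test_contribution_three_term_hand_case():
    tab = toy_table(8,
                    alpha_LR=np.resize([1.0, -1.0, 1.0, -1.0], 8),
                    phi_p_LR=np.resize([2.0, 2.0, -2.0, -2.0], 8),
                    y_dot=np.resize([4.0, -4.0, -4.0, 4.0], 8))
    tab["beta_dot"] = (3.0 * tab["alpha_LR"] + 1.0 * tab["phi_p_LR"]
                       + 0.5 * tab["y_dot"])
    res = fit_linear(tab, ModelSpec("beta_dot", ("alpha_LR", "phi_p_LR", "y_dot")))
    contrib = contribution_table(res)
    # weights: 3*1, 1*2, 0.5*4 -> 3:2:2
    assert contrib["alpha_LR"] == pytest.approx(100.0 * 3 / 7, abs=1e-6)
    assert contrib["phi_p_LR"] == pytest.approx(100.0 * 2 / 7, abs=1e-6)
    assert contrib["y_dot"] == pytest.approx(100.0 * 2 / 7, abs=1e-6)


def test_half_life_forced_case_and_ode_oracle():
    tab = toy_table(30, seed=6)
    tab["y_ddot"] = -math.log(2.0) * tab["y_dot"]
    res = fit_linear(tab, ModelSpec("y_ddot", ("y_dot",)))
    tc = damping_time_constants(res)["y_dot"]
    assert tc["half_life_s"] == pytest.approx(1.0, rel=1e-9)
    # ODE oracle: integrate v' = K v and time the halving
    K = tc["K"]
    sol = solve_ivp(lambda t, v: K * v, (0.0, 5.0), [1.0], dense_output=True,
                    rtol=1e-10, atol=1e-12)
    ts = np.linspace(0.0, 5.0, 200001)
    vs = sol.sol(ts)[0]
    t_half = ts[np.argmin(np.abs(vs - 0.5))]
    assert t_half == pytest.approx(tc["half_life_s"], rel=1e-3)


def test_nonnegative_damping_flagged():
    tab = toy_table(30, seed=7)
    tab["y_ddot"] = 0.5 * tab["y_dot"]
    res = fit_linear(tab, ModelSpec("y_ddot", ("y_dot",)))
    tc = damping_time_constants(res)["y_dot"]
    assert tc["flagged"] and not np.isfinite(tc["time_constant_s"])


# ---------------------------------------------------------------------------
# binned t-tests
# ---------------------------------------------------------------------------


def ttest_table(n=80, split=6.0, seed=0):
    """Rows with rightward/leftward rolls where the contralateral wing pitch
    exceeds the ipsilateral by ``split`` deg during high roll velocity."""
    rng = np.random.default_rng(seed)
    tab = toy_table(n, seed=seed + 1)
    bd = np.concatenate([rng.normal(0, 5.0, n // 2),
                         rng.choice([-1, 1], n - n // 2) * rng.uniform(80, 200, n - n // 2)])
    tab["beta_dot"] = rng.permutation(bd)
    base = 40.0
    alpha_L = np.full(n, base) + rng.normal(0, 2.0, n)
    alpha_R = np.full(n, base) + rng.normal(0, 2.0, n)
    high = np.abs(tab["beta_dot"]) > 40.0
    rolling_right = tab["beta_dot"] > 0
    # contralateral pitch up, ipsilateral down
    alpha_L[(high & rolling_right)] += split / 2.0
    alpha_R[(high & rolling_right)] -= split / 2.0
    alpha_L[(high & ~rolling_right)] -= split / 2.0
    alpha_R[(high & ~rolling_right)] += split / 2.0
    tab["alpha_L"], tab["alpha_R"] = alpha_L, alpha_R
    tab["phi_p_L"] = 100.0 + rng.normal(0, 2.0, n)
    tab["phi_p_R"] = 100.0 + rng.normal(0, 2.0, n)
    tab["theta_p_L"] = 30.0 + rng.normal(0, 2.0, n)
    tab["theta_p_R"] = 30.0 + rng.normal(0, 2.0, n)
    return tab


def test_binned_ttests_detect_pitch_split():
    """A commanded +/-3 deg ipsi/contra pitch split is significant in at
    least 90% of replicates at n=80 rows."""
    sig = 0
    reps = 40
    for rep in range(reps):
        rep_tab = ttest_table(seed=900 + rep)
        report = updown_binned_ttests(rep_tab)
        if report["alpha"]["ipsi_vs_contra"]["p"] < 0.05:
            sig += 1
    assert sig >= 0.9 * reps


def test_binned_ttest_statistic_matches_textbook_formula():
    tab = ttest_table(n=40, seed=42)
    report = updown_binned_ttests(tab)
    bd = tab["beta_dot"].to_numpy()
    thresh = np.quantile(np.abs(bd), 0.25)
    high = tab[np.abs(bd) > thresh]
    right = high["beta_dot"] > 0
    ipsi = np.where(right, high["alpha_R"], high["alpha_L"])
    contra = np.where(right, high["alpha_L"], high["alpha_R"])
    na, nb = len(ipsi), len(contra)
    sp2 = (((na - 1) * np.var(ipsi, ddof=1) + (nb - 1) * np.var(contra, ddof=1))
           / (na + nb - 2))
    t_hand = (np.mean(ipsi) - np.mean(contra)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    assert report["alpha"]["ipsi_vs_contra"]["t"] == pytest.approx(t_hand, rel=1e-9)


def test_binned_ttests_degenerate_input():
    tab = ttest_table(n=40, split=0.0, seed=1)
    tab["alpha_L"] = 40.0
    tab["alpha_R"] = 40.0
    with pytest.warns(RuntimeWarning, match="degenerate"):
        report = updown_binned_ttests(tab, measures=("alpha",))
    assert report["alpha"]["ipsi_vs_contra"]["p"] > 0.99


def test_binned_ttests_need_enough_rows():
    with pytest.raises(ValueError):
        updown_binned_ttests(ttest_table(n=10))


# ---------------------------------------------------------------------------
# roll first-order diagnostic
# ---------------------------------------------------------------------------


def test_roll_acceleration_check_discriminates():
    """Constructed beta_ddot proportional to alpha_LR (undamped toy) makes
    the acceleration model win; a velocity-driven table makes the velocity
    model win."""
    rng = np.random.default_rng(12)
    damped = toy_table(60, seed=13)
    damped["beta_dot"] = 12.0 * damped["alpha_LR"] + rng.normal(0, 8.0, 60)
    damped["beta_ddot"] = rng.normal(0, 500.0, 60)
    rep = roll_acceleration_check(damped)
    assert rep["first_order"]
    assert rep["r2_beta_dot"] > rep["r2_beta_ddot"]

    undamped = toy_table(60, seed=14)
    undamped["beta_ddot"] = 300.0 * undamped["alpha_LR"] + rng.normal(0, 100.0, 60)
    undamped["beta_dot"] = rng.normal(0, 50.0, 60)
    rep = roll_acceleration_check(undamped)
    assert not rep["first_order"]


def test_beta_ddot_from_differencing_oracle():
    """beta_ddot computed by applying the like-phase differencing operator
    to the beta_dot series equals the pipeline's own second derivative."""
    from sideslip.kinematics import wingbeat_derivatives

    f = 26.0
    t = np.arange(24) / (4.0 * f)
    beta = 30.0 * np.sin(2 * math.pi * 1.3 * t)
    d1 = wingbeat_derivatives(t, beta)
    d2 = wingbeat_derivatives(t, d1)
    # oracle: same stencil written out directly
    k = 4
    expect = np.full_like(d1, np.nan)
    for i in range(k, len(t) - k):
        expect[i] = (d1[i + k] - d1[i - k]) / (t[i + k] - t[i - k])
    m = np.isfinite(expect)
    np.testing.assert_allclose(d2[m], expect[m], rtol=1e-12)
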