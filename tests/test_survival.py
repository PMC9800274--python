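"""Exclusions, spline basis, Cox/Fine-Gray fitting and diagnostics."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vilpa
from vilpa import InputError, SplineSpec, rcs_basis
from vilpa.simulate import simulate_analysis_cohort
from vilpa.survival import (
    CoxDoseResponse,
    DoseResponseResults,
    FineGrayDoseResponse,
    apply_exclusions,
)


# --------------------------------------------------------------------------
# exclusions
# --------------------------------------------------------------------------


def _records(times, causes, **extra):
    df = pd.DataFrame({"participant_id": range(len(times)), "time_years": times, "cause": causes})
    for k, v in extra.items():
        df[k] = v
    return df


def test_landmark_removes_early_deaths_keeps_early_censoring():
    df = _records([1.5, 1.5, 3.0, 5.0], ["cvd", "censored", "cancer", "censored"])
    out, log = apply_exclusions(df, landmark_years=2.0, outcome="all_cause")
    assert log["n_removed_landmark"] == 1
    assert 0 not in out["participant_id"].tolist()  # death at 1.5 y removed
    assert 1 in out["participant_id"].tolist()  # censored at 1.5 y retained


def test_no_early_events_is_identity():
    df = _records([3.0, 4.0], ["cvd", "censored"], prevalent_cvd=[0, 0])
    out, log = apply_exclusions(df, outcome="all_cause")
    assert log["n_removed_landmark"] == 0 and log["n_removed_prevalent"] == 0
    pd.testing.assert_frame_equal(out, df)


def test_cause_specific_removes_prevalent_disease():
    df = _records([3.0, 4.0, 5.0], ["cvd", "censored", "censored"], prevalent_cvd=[0, 1, 0])
    out, log = apply_exclusions(df, outcome="cvd")
    assert log["n_removed_prevalent"] == 1
    assert 1 not in out["participant_id"].tolist()


def test_missing_prevalence_flag_is_input_error():
    df = _records([3.0, 4.0], ["cvd", "censored"])
    with pytest.raises(InputError, match="prevalent_cvd"):
        apply_exclusions(df, outcome="cvd")


# --------------------------------------------------------------------------
# restricted cubic spline basis
# --------------------------------------------------------------------------


def _textbook_rcs(x, t):
    """Independent transcription of the 3-knot natural-spline formula."""
    t1, t2, t3 = t
    out = np.zeros_like(np.asarray(x, dtype=float))
    for j, xi in enumerate(np.atleast_1d(x)):
        term = max(xi - t1, 0.0) ** 3
        term -= max(xi - t2, 0.0) ** 3 * (t3 - t1) / (t3 - t2)
        term += max(xi - t3, 0.0) ** 3 * (t2 - t1) / (t3 - t2)
        out[j] = term / (t3 - t1) ** 2
    return out


def test_rcs_zero_below_first_knot():
    spec = SplineSpec(knots=(1.0, 3.0, 7.0))
    x = np.linspace(-2, 1, 50)
    basis = rcs_basis(x, spec)
    np.testing.assert_array_equal(basis[:, 1], 0.0)
    np.testing.assert_array_equal(basis[:, 0], x)


def test_rcs_linear_beyond_last_knot():
    spec = SplineSpec(knots=(1.0, 3.0, 7.0))
    x = np.linspace(8, 20, 100)
    y = rcs_basis(x, spec)[:, 1]
    slopes = np.diff(y) / np.diff(x)
    np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)


def test_rcs_second_derivative_continuous_at_interior_knot():
    spec = SplineSpec(knots=(1.0, 3.0, 7.0))

    def gap(h):
        # left vs right finite-difference second derivative beside the knot
        f = lambda u: rcs_basis(np.array([u]), spec)[0, 1]
        d2 = lambda x0: (f(x0 + h) - 2 * f(x0) + f(x0 - h)) / h**2
        return d2(3.0 - 2 * h) - d2(3.0 + 2 * h)

    # the gap shrinks linearly in h (bounded third-derivative jump);
    # Richardson-extrapolating it to h -> 0 must give a continuous limit
    assert abs(2 * gap(1e-3) - gap(2e-3)) < 1e-6


def test_rcs_matches_textbook_formula_on_random_grid():
    rng = np.random.default_rng(0)
    spec = SplineSpec(knots=(0.5, 2.2, 6.1))
    x = rng.uniform(-1, 10, 200)
    np.testing.assert_allclose(rcs_basis(x, spec)[:, 1], _textbook_rcs(x, spec.knots), rtol=1e-12)


def test_rcs_rejects_nonincreasing_knots():
    with pytest.raises(InputError, match="increasing"):
        SplineSpec(knots=(1.0, 1.0, 2.0))


# --------------------------------------------------------------------------
# Cox fitting
# --------------------------------------------------------------------------


def _efron_log_pl(times, events, x, beta):
    """Brute-force Efron partial log-likelihood by risk-set enumeration."""
    ll = 0.0
    for t in sorted(set(times[events])):
        D = np.flatnonzero(events & (times == t))
        R = np.flatnonzero(times >= t)
        m = len(D)
        sum_d = x[D].sum()
        theta_R = np.exp(beta * x[R]).sum()
        theta_D = np.exp(beta * x[D]).sum()
        ll += beta * sum_d
        for l in range(m):
            ll -= np.log(theta_R - l / m * theta_D)
    return ll


def test_toy_partial_likelihood_matches_brute_force():
    times = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    events = np.array([True, True, True, False, True, False])
    x = np.array([0.5, -1.0, 2.0, 0.0, 1.0, -0.5])
    df = pd.DataFrame({"exposure": x, "time_years": times,
                       "cause": np.where(events, "cvd", "censored")})
    res = vilpa.fit_cox(df, "exposure", covariate_formula=None, spline=None)
    beta = float(res.params["exposure_lin"])
    assert res.llf == pytest.approx(_efron_log_pl(times, events, x, beta), abs=1e-8)
    # and the fitted beta maximises the brute-force likelihood
    for db in (-1e-3, 1e-3):
        assert _efron_log_pl(times, events, x, beta + db) < res.llf


def test_spline_cox_recovers_linear_truth():
    beta = -0.3
    df = simulate_analysis_cohort(5000, seed=42, beta=beta, baseline_hazard=0.025)
    res = vilpa.fit_cox(df, "exposure")
    x_med = float(np.median(df.loc[df["exposure"] > 0, "exposure"]))
    eta, se = res.log_hr(x_med)
    assert abs(eta[0] - beta * x_med) < 3 * se[0]


def test_null_exposure_rarely_gives_large_z():
    big_z = 0
    for seed in range(30):
        df = simulate_analysis_cohort(
            1200, seed=seed, beta=0.0, baseline_hazard=0.03, with_covariates=False
        )
        res = vilpa.fit_cox(df, "exposure", covariate_formula=None, spline=None)
        z = res.params["exposure_lin"] / np.sqrt(res.cov.iloc[0, 0])
        big_z += abs(z) >= 3
    assert big_z <= 1


def test_fewer_than_two_events_rejected():
    df = _records([3.0, 4.0, 5.0], ["cvd", "censored", "censored"], exposure=[1.0, 2.0, 3.0])
    with pytest.raises(InputError, match="events"):
        CoxDoseResponse(df, "exposure", covariate_formula=None, spline=None)


def test_constant_covariate_rejected():
    df = simulate_analysis_cohort(200, seed=1, baseline_hazard=0.1)
    df["flat"] = 1.0
    with pytest.raises(InputError, match="constant"):
        CoxDoseResponse(df, "exposure", covariate_formula="flat", spline=None)


def test_hr_invariant_to_exposure_rescaling():
    df = simulate_analysis_cohort(2000, seed=9, beta=-0.1, baseline_hazard=0.04)
    res1 = vilpa.fit_cox(df, "exposure", covariate_formula="age")
    df2 = df.assign(exposure=df["exposure"] * 2.0)
    res2 = vilpa.fit_cox(df2, "exposure", covariate_formula="age")
    x = float(np.median(df.loc[df["exposure"] > 0, "exposure"]))
    eta1, _ = res1.log_hr(x)
    eta2, _ = res2.log_hr(2.0 * x)  # same participants, same contrast
    assert abs(eta1[0] - eta2[0]) < 1e-8


def test_results_roundtrip_through_dict():
    df = simulate_analysis_cohort(800, seed=2, baseline_hazard=0.05)
    res = vilpa.fit_cox(df, "exposure")
    back = DoseResponseResults.from_dict(res.to_dict())
    grid = np.linspace(0, res.exposure_max, 20)
    np.testing.assert_allclose(res.log_hr(grid)[0], back.log_hr(grid)[0])
    np.testing.assert_allclose(res.log_hr(grid)[1], back.log_hr(grid)[1])


# --------------------------------------------------------------------------
# Fine-Gray
# --------------------------------------------------------------------------


def _fine_gray_cohort(n, seed, beta=0.5, p=0.6):
    """Simulate directly from a two-cause subdistribution model."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    eb = np.exp(beta * x)
    p1 = 1 - (1 - p) ** eb
    is1 = rng.random(n) < p1
    u = rng.random(n)
    t = np.empty(n)
    t[is1] = -np.log(1 - (1 - (1 - u[is1] * p1[is1]) ** (1 / eb[is1])) / p)
    t[~is1] = rng.exponential(1.0, (~is1).sum())
    c = rng.uniform(0.2, 4.0, n)
    return pd.DataFrame(
        {
            "exposure": x,
            "time_years": np.minimum(t, c) + 1e-9,
            "cause": np.where(t <= c, np.where(is1, "cvd", "cancer"), "censored"),
        }
    )


def test_fine_gray_recovers_subdistribution_effect():
    beta = 0.5
    df = _fine_gray_cohort(800, seed=3, beta=beta)
    res = vilpa.fit_fine_gray(df, "exposure", cause="cvd", covariate_formula=None, spline=None)
    se = float(np.sqrt(res.cov.iloc[0, 0]))
    assert abs(res.params["exposure_lin"] - beta) < 3 * se
    assert res.model_kind == "fine_gray"


def test_fine_gray_weights_are_valid_step_functions():
    df = _fine_gray_cohort(300, seed=5)
    model = FineGrayDoseResponse(df, "exposure", cause="cvd", covariate_formula=None, spline=None)
    long_df = model._expand()
    assert ((long_df["_w"] > 0) & (long_df["_w"] <= 1.0)).all()
    # weights non-increasing in time within each expanded subject
    for _, sub in long_df.groupby("_id"):
        w = sub.sort_values("_start")["_w"].to_numpy()
        assert (np.diff(w) <= 1e-12).all()
    # competing-event subjects never flagged as target events
    comp_ids = np.flatnonzero(model.competing)
    assert long_df.loc[long_df["_id"].isin(comp_ids), "_event"].sum() == 0


def test_fine_gray_matches_r_survival_finegray(tmp_path):
    df = _fine_gray_cohort(150, seed=11)
    res = vilpa.fit_fine_gray(df, "exposure", cause="cvd", covariate_formula=None, spline=None)
    csv = tmp_path / "fg.csv"
    df.assign(
        status=np.where(df["cause"] == "cvd", 1, np.where(df["cause"] == "cancer", 2, 0))
    ).to_csv(csv, index=False)
    script = tmp_path / "fg.R"
    script.write_text(
        "library(survival)\n"
        f"d <- read.csv('{csv}')\n"
        "d$status <- factor(d$status, 0:2, labels=c('censor','cvd','cancer'))\n"
        "fgd <- finegray(Surv(time_years, status) ~ ., data=d, etype='cvd')\n"
        "f <- coxph(Surv(fgstart, fgstop, fgstatus) ~ exposure, weight=fgwt,"
        " data=fgd, ties='efron')\n"
        "cat(sprintf('%.10f', coef(f)))\n"
    )
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=120
    )
    assert proc.returncode == 0, proc.stderr
    r_beta = float(proc.stdout.strip().split()[-1])
    assert abs(res.params["exposure_lin"] - r_beta) < 1e-6


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def test_wald_single_term_equals_squared_z():
    df = simulate_analysis_cohort(1500, seed=6, baseline_hazard=0.04)
    res = vilpa.fit_cox(df, "exposure")
    w = res.wald_nonlinearity()
    summ = res.summary()
    z = summ.loc["exposure_rcs1", "z"]
    assert w.df == 1
    assert w.statistic == pytest.approx(z**2, rel=1e-9)


def test_wald_detects_strong_quadratic_hazard():
    rng = np.random.default_rng(13)
    n = 4000
    x = rng.uniform(0, 5, n)
    eta = -0.6 * x + 0.12 * x**2
    t = rng.exponential(1.0 / (0.05 * np.exp(eta)))
    obs = np.minimum(t, 6.9)
    df = pd.DataFrame(
        {"exposure": x, "time_years": obs, "cause": np.where(t <= 6.9, "cvd", "censored")}
    )
    res = vilpa.fit_cox(df, "exposure", covariate_formula=None)
    assert res.wald_nonlinearity().p_value < 0.001


def test_wald_requires_nonlinear_term():
    df = simulate_analysis_cohort(500, seed=7, baseline_hazard=0.08)
    res = vilpa.fit_cox(df, "exposure", covariate_formula=None, spline=None)
    with pytest.raises(InputError, match="nonlinear"):
        res.wald_nonlinearity()


def test_ph_test_matches_independent_per_term_implementation():
    # lifelines implements the same per-term Grambsch-Therneau statistic
    from lifelines.statistics import proportional_hazard_test

    df = simulate_analysis_cohort(1000, seed=8, beta=-0.1, baseline_hazard=0.06)
    res = vilpa.fit_cox(df, "exposure", covariate_formula="age + confounder", spline=None)
    mine = res.ph_test(transform="rank")
    theirs = proportional_hazard_test(res._model, res._design, time_transform="rank")
    for term in mine.per_term.index:
        assert mine.per_term.loc[term, "statistic"] == pytest.approx(
            float(theirs.summary.loc[term, "test_statistic"]), rel=0.05, abs=0.05
        )


def test_ph_global_p_uniform_under_proportional_hazards():
    ps = []
    for seed in range(60):
        df = simulate_analysis_cohort(
            400, seed=1000 + seed, beta=-0.1, baseline_hazard=0.08, with_covariates=False
        )
        res = vilpa.fit_cox(df, "exposure", covariate_formula=None, spline=None)
        ps.append(res.ph_test().global_p)
    stat, p = stats.kstest(ps, "uniform")
    assert p > 0.01


def test_ph_test_detects_time_varying_effect():
    # effect reverses over time: piecewise-exponential with crossing hazards
    rng = np.random.default_rng(17)
    n = 5000
    x = rng.binomial(1, 0.5, n).astype(float)
    t_break = 1.0
    rate_early = 0.4 * np.exp(1.2 * x)
    rate_late = 0.4 * np.exp(-1.2 * x)
    t1 = rng.exponential(1 / rate_early)
    t = np.where(t1 < t_break, t1, t_break + rng.exponential(1 / rate_late))
    obs = np.minimum(t, 5.0)
    df = pd.DataFrame(
        {"exposure": x, "time_years": obs, "cause": np.where(t <= 5.0, "cvd", "censored")}
    )
    res = vilpa.fit_cox(df, "exposure", covariate_formula=None, spline=None)
    assert res.ph_test().global_p < 0.05


def test_ph_test_rejected_for_fine_gray_fit():
    df = _fine_gray_cohort(200, seed=4)
    res = vilpa.fit_fine_gray(df, "exposure", cause="cvd", covariate_formula=None, spline=None)
    with pytest.raises(InputError, match="Cox"):
        res.ph_test()
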