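"""Estimation workflow: regressions, identities, sweep-and-filter, recovery."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm

import thymoselect as ts
from thymoselect.estimation import (EmptyAcceptedSetError,
                                    InconsistentConfigError, fit_lineage_chain,
                                    fit_pooled_chain)


# ---------------------------------------------------------------- regression

@pytest.mark.parametrize("xcol,ycol", [("n1", "n2"), ("n2", "n3"),
                                       ("n4", "n2"), ("n8", "n4"), ("n8", "n3")])
def test_origin_regression_matches_statsmodels(cohort, xcol, ycol):
    """Slope and through-origin t-test p agree with an independent OLS fit."""
    res = ts.origin_regression(cohort[xcol], cohort[ycol])
    ols = sm.OLS(cohort[ycol].to_numpy(), cohort[xcol].to_numpy()).fit()
    assert res.slope == pytest.approx(ols.params[0], rel=1e-12)
    assert res.p_value == pytest.approx(ols.pvalues[0], rel=1e-9)


def test_origin_regression_closed_form_sum(cohort):
    """The slope equals the explicit ratio of sums evaluated by hand."""
    x = cohort["n1"].to_numpy()
    y = cohort["n2"].to_numpy()
    expected = sum(a * b for a, b in zip(x, y)) / sum(a * a for a in x)
    res = ts.origin_regression(x, y)
    assert res.slope == pytest.approx(expected, rel=1e-14)
    assert res.slope == pytest.approx(0.09166, abs=5e-5)
    # perturbing the slope increases the squared error (minimizer check)
    def sse(a):
        return ((y - a * x) ** 2).sum()
    assert sse(res.slope) < min(sse(res.slope * 1.001), sse(res.slope * 0.999))


def test_origin_regression_exact_proportionality():
    x = np.array([1.0, 2.0, 3.0])
    res = ts.origin_regression(x, 2 * x)
    assert res.slope == 2.0
    np.testing.assert_allclose(res.residuals, 0.0, atol=1e-14)


def test_origin_regression_rejects_degenerate_input():
    with pytest.raises(ValueError):
        ts.origin_regression([0.0, 0.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        ts.origin_regression([1.0], [1.0])


def test_sp_sum_slope_identity(cohort):
    """a5 = a4 + 1 whenever n3 = n4 + n8 row-wise."""
    a4 = ts.origin_regression(cohort["n8"], cohort["n4"]).slope
    a5 = ts.origin_regression(cohort["n8"], cohort["n3"]).slope
    assert a5 == pytest.approx(a4 + 1.0, abs=1e-10 + 1e-3)  # table rounding
    # and exactly on a synthetic cohort where the sum is exact
    spec = ts.SyntheticCohortSpec(seed=5)
    df = ts.generate_cohort(spec)
    a4s = ts.origin_regression(df["n8"], df["n4"]).slope
    a5s = ts.origin_regression(df["n8"], df["n3"]).slope
    assert a5s == pytest.approx(a4s + 1.0, abs=1e-12)


# --------------------------------------------------------------- pooled fit

def test_residence_time_closure(pooled_fit, lineage_fit):
    """Every estimated rate pair sums to the reciprocal residence time."""
    assert pooled_fit.phi1_ + pooled_fit.mu1_ == pytest.approx(1 / 2.5, rel=1e-14)
    assert pooled_fit.phi3_ + pooled_fit.mu3_ == pytest.approx(1 / 4.0, rel=1e-14)
    acc = pooled_fit.accepted_
    np.testing.assert_allclose(acc["phi2"] + acc["mu2"], 1 / 0.67, rtol=1e-14)
    assert lineage_fit.xi4_ + lineage_fit.mu4 == pytest.approx(1 / 4.0, rel=1e-14)
    assert lineage_fit.xi8_ + lineage_fit.mu8 == pytest.approx(1 / 4.0, rel=1e-14)


def test_accepted_sweep_satisfies_defining_relations(pooled_fit):
    """phi2 = a2 (phi3 + mu3 - lam3) holds to 1e-10 on every accepted row."""
    acc = pooled_fit.accepted_
    d3 = pooled_fit.phi3_ + pooled_fit.mu3_ - acc["lam3"]
    np.testing.assert_allclose(acc["phi2"], pooled_fit.a2_ * d3, rtol=1e-10)
    assert (acc["lam3"] >= 1 / 7 - 1e-12).all()
    assert (acc["lam3"] <= 1 / 4.0 + 1e-12).all()


def test_acceptance_boundary_location(cohort, pooled_fit):
    """The accept/reject boundary in lam3 lies in (0.22, 0.23)/day.

    Cross-checked by bisecting the 21-day SP deficit with a from-scratch RK4
    integration, independent of the estimator's filter implementation.
    """
    acc_max = pooled_fit.accepted_["lam3"].max()
    assert 0.22 < acc_max < 0.23

    stats = ts.cohort_stats(cohort)
    target = stats.mean_of("n3") - stats.sd_of("n3")

    def deficit(lam3):
        d3 = pooled_fit.phi3_ + pooled_fit.mu3_ - lam3
        phi2 = pooled_fit.a2_ * d3
        r = ts.PooledRates(phi=pooled_fit.phi_, phi1=pooled_fit.phi1_,
                           mu1=pooled_fit.mu1_, phi2=phi2, mu2=1 / 0.67 - phi2,
                           phi3=pooled_fit.phi3_, mu3=pooled_fit.mu3_, lam3=lam3)
        init = ts.CompartmentState.pooled(0.0, 0.0, 0.0, 0.0)
        traj = ts.rk4_simulate(r, init, t_end=21.0, dt=0.01)
        return traj["n3"].iloc[-1] - target

    lo, hi = 0.20, 0.249
    assert deficit(lo) > 0 > deficit(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if deficit(mid) > 0 else (lo, mid)
    grid_step = (0.25 - 1 / 7) / 99
    assert acc_max <= lo <= acc_max + grid_step


def test_acceptance_filter_examples(cohort, pooled_fit):
    stats = ts.cohort_stats(cohort)
    fast = dataclasses.replace(pooled_fit.to_rates(), lam3=1 / 7,
                               phi2=(p2 := pooled_fit.a2_ * (0.25 - 1 / 7)),
                               mu2=1 / 0.67 - p2)
    assert ts.acceptance_filter(fast, stats)
    marginal = dataclasses.replace(pooled_fit.to_rates(), lam3=0.25)
    assert not ts.acceptance_filter(marginal, stats)  # steady state gone


def test_unit_rescaling_equivariance(cohort):
    """Scaling counts and export flux by c scales phi by c, rates unchanged."""
    c = 137.0
    scaled = cohort.copy()
    for col in ("n1", "n2", "n3", "n4", "n8"):
        scaled[col] *= c
    cfg = ts.EstimationConfig(phi_out=2.5e6 * c)
    base = ts.estimate_pooled(cohort)
    resc = ts.estimate_pooled(scaled, cfg)
    assert resc.phi_ == pytest.approx(c * base.phi_, rel=1e-12)
    for attr in ("phi1_", "mu1_", "phi3_", "mu3_", "lambda3_", "phi2_", "mu2_"):
        assert getattr(resc, attr) == pytest.approx(getattr(base, attr), rel=1e-12)


def test_inconsistent_config_raises_named_identity(cohort):
    with pytest.raises(InconsistentConfigError, match="mu3"):
        ts.estimate_pooled(cohort, ts.EstimationConfig(phi_out=6e6))
    with pytest.raises(InconsistentConfigError, match="mu1"):
        ts.estimate_pooled(cohort, ts.EstimationConfig(tau1=12.0))


def test_empty_accepted_set_raises(cohort):
    # a 2-day horizon leaves every compartment far below mean - SD
    with pytest.raises(EmptyAcceptedSetError):
        ts.estimate_pooled(cohort, ts.EstimationConfig(t_acc=2.0))


def test_single_point_grid_is_usable(cohort):
    est = ts.estimate_pooled(cohort, ts.EstimationConfig(n_lambda3=1))
    assert est.n_accepted_ == 1
    assert est.lambda3_ == pytest.approx(1 / 7)


# -------------------------------------------------------------- lineage fit

def test_lineage_lambda_relations_per_row(cohort, lineage_fit):
    """Accepted rows satisfy the defining steady-state relations to 1e-10."""
    acc = lineage_fit.accepted_
    lam4 = 1 / 4.0 - lineage_fit.a3_ * acc["phi4"]
    np.testing.assert_allclose(acc["lam4"], lam4, rtol=1e-10)
    m1 = lineage_fit.pooled_.means_()
    lam8 = m1["lam3"] * lineage_fit.a5_ - acc["lam4"] * lineage_fit.a4_
    np.testing.assert_allclose(acc["lam8"], lam8, rtol=1e-10)
    np.testing.assert_allclose(acc["phi4"] + acc["phi8"], m1["phi2"], rtol=1e-12)
    for col in ("lam4", "lam8"):
        assert (acc[col] >= 1 / 7 - 1e-12).all()
        assert (acc[col] < 0.25).all()


def test_lineage_rejection_diagnostics(lineage_fit):
    rej = lineage_fit.rejection_counts_
    total = lineage_fit.fit_.n_candidates
    assert sum(rej.values()) + lineage_fit.n_accepted_ == total


def test_lambda4_regression_roundtrip(cohort, lineage_fit):
    """Given a3 and any phi4, lam4 solves a3 = (1/tau4 - lam4)/phi4."""
    a3 = lineage_fit.a3_
    acc = lineage_fit.accepted_
    lhs = (1 / 4.0 - acc["lam4"]) / acc["phi4"]
    np.testing.assert_allclose(lhs, a3, rtol=1e-10)


# ----------------------------------------------------------- recovery tests

# a ground truth inside the method's admissible region: proliferation times
# below 7 days in both lineages and SP relaxation fast enough that the truth
# itself satisfies the 21-day acceptance rule
RECOVERY_TRUTH = dataclasses.replace(ts.DEFAULT_TRUTH, lam4=0.18, lam8=0.16)


def _chain_inputs_for(df, cfg):
    stats = ts.cohort_stats(df)
    from thymoselect.estimation import PooledInputs
    return PooledInputs(
        tau1=cfg["tau1"], tau2=cfg["tau2"], tau3=cfg["tau3"],
        phi_out=cfg["phi_out"],
        a1=ts.origin_regression(df["n1"], df["n2"]).slope,
        a2=ts.origin_regression(df["n2"], df["n3"]).slope,
        nbar3=stats.mean_of("n3"), nbar1=stats.mean_of("n1")), stats


def test_noise_free_recovery_is_exact():
    """With zero noise the residence-identity rates are recovered exactly."""
    truth = RECOVERY_TRUTH
    cfgk = ts.matched_config_kwargs(truth)
    df = ts.generate_cohort(ts.SyntheticCohortSpec(
        truth=truth, n_mice=4, size_dispersion=0.0, noise_cv=0.0, seed=0))
    inputs, stats = _chain_inputs_for(df, cfgk)
    res = fit_pooled_chain(inputs, stats)
    star = ts.steady_state(truth)
    pooled_truth = ts.lineage_to_pooled(truth, star)
    assert res.phi == pytest.approx(truth.phi, rel=1e-6)
    assert res.phi1 == pytest.approx(truth.phi1, rel=1e-6)
    assert res.mu1 == pytest.approx(truth.mu1, rel=1e-6)
    assert res.phi3 == pytest.approx(pooled_truth.phi3, rel=1e-6)
    assert res.mu3 == pytest.approx(pooled_truth.mu3, rel=1e-6)


def test_noisy_recovery_within_tolerance():
    """CV <= 10% noise: phi1, mu1, phi within 10%; swept medullary
    proliferation means within 25% of a truth inside the admissible window."""
    truth = RECOVERY_TRUTH
    cfg = ts.EstimationConfig(**ts.matched_config_kwargs(truth))
    df = ts.generate_cohort(ts.SyntheticCohortSpec(
        truth=truth, n_mice=300, size_dispersion=0.4, noise_cv=0.1, seed=11))
    est = ts.estimate_lineage(df, cfg)
    pooled = est.pooled_
    assert pooled.phi_ == pytest.approx(truth.phi, rel=0.10)
    assert pooled.phi1_ == pytest.approx(truth.phi1, rel=0.10)
    assert pooled.mu1_ == pytest.approx(truth.mu1, rel=0.10)
    assert est.xi4_ == pytest.approx(truth.xi4, rel=1e-12)  # config-determined
    assert est.xi8_ == pytest.approx(truth.xi8, rel=1e-12)
    assert est.lambda4_ == pytest.approx(truth.lam4, rel=0.25)
    assert est.lambda8_ == pytest.approx(truth.lam8, rel=0.25)


def test_estimates_tighten_with_cohort_size():
    """Small fixed noise: the influx estimate converges toward the truth."""
    truth = RECOVERY_TRUTH
    cfg = ts.EstimationConfig(**ts.matched_config_kwargs(truth))
    errs = {}
    for n in (8, 100, 1000):
        df = ts.generate_cohort(ts.SyntheticCohortSpec(
            truth=truth, n_mice=n, size_dispersion=0.3, noise_cv=0.05, seed=3))
        est = ts.estimate_pooled(df, cfg)
        errs[n] = abs(est.phi_ - truth.phi) / truth.phi
    assert errs[1000] < 0.03
    assert errs[8] < 0.20
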