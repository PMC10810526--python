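"""VP change-detection observer: decision variable, biases, prediction, fit."""

import numpy as np
import pytest
from scipy import integrate

from presacc import vp_change as vpc
from presacc.circular import log_i0
from presacc.madc import ContingencyTable

from conftest import simulate_vp_table


def posterior_odds_oracle(x, y, kappa_x, kappa_y):
    """Numeric posterior odds of change vs no change for one location.

    Change: the two true (doubled) orientations differ by a uniform random
    angle; no change: they are equal, the common orientation uniform. The
    odds ratio equals p(x, y | change) / p(x, y | no change), each computed
    by direct integration of the von Mises likelihoods — independent of the
    Bessel-function identity used by the implementation.
    """
    def vm(z, mu, k):
        return np.exp(k * np.cos(z - mu) - np.log(2 * np.pi) - log_i0(k))

    def lik_change(theta):
        # marginal over the change angle is uniform: y's likelihood averages
        # over a uniform final orientation -> 1/(2 pi)
        return vm(x, theta, kappa_x) / (2 * np.pi)

    def lik_same(theta):
        return vm(x, theta, kappa_x) * vm(y, theta, kappa_y)

    num, _ = integrate.quad(lik_change, -np.pi, np.pi)
    den, _ = integrate.quad(lik_same, -np.pi, np.pi)
    return num / den


@pytest.mark.parametrize("kx,ky,dyx", [
    (5.0, 5.0, np.pi / 2), (2.0, 7.0, np.pi / 4), (1.0, 1.0, 3.0),
    (10.0, 3.0, 0.3),
])
def test_decision_variable_matches_integration_oracle(kx, ky, dyx):
    x = 0.4
    F = vpc.decision_variable(x, x + dyx, kx, ky)
    oracle = posterior_odds_oracle(x, x + dyx, kx, ky)
    assert F == pytest.approx(oracle, rel=1e-6)


def test_decision_variable_no_change_evidence_below_one():
    F = vpc.decision_variable(0.7, 0.7, 5.0, 5.0)
    from scipy.special import i0

    assert F == pytest.approx(i0(5.0) ** 2 / i0(10.0), rel=1e-9)
    assert F < 1.0


def test_decision_variable_symmetric_in_measurement_swap():
    a = vpc.decision_variable(0.2, 1.1, 3.0, 8.0)
    b = vpc.decision_variable(1.1, 0.2, 8.0, 3.0)
    assert a == pytest.approx(b, rel=1e-12)


def test_perceptual_bias_endpoints_and_wrap():
    assert vpc.apply_perceptual_bias(40.0, 120.0, 0.0) == pytest.approx(40.0)
    assert vpc.apply_perceptual_bias(40.0, 120.0, 1.0) == pytest.approx(120.0)
    # shortest arc across the wrap: midpoint of 170 and 10 is 0
    assert vpc.apply_perceptual_bias(170.0, 10.0, 0.5) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        vpc.apply_perceptual_bias(0.0, 10.0, 1.5)


def test_decide_rules():
    assert vpc.decide([0.5, 0.5, 0.5, 0.5], np.ones(4)) == 4
    assert vpc.decide([2.0, 0.5, 0.5, 0.5], np.ones(4)) == 0
    # lowering one threshold weakly increases that location's report rate
    rng = np.random.default_rng(0)
    F = rng.lognormal(0.0, 1.0, size=(10_000, 4))
    r_base = np.mean(np.asarray(vpc.decide(F, np.array([1.0, 1, 1, 1]))) == 0)
    r_low = np.mean(np.asarray(vpc.decide(F, np.array([0.5, 1, 1, 1]))) == 0)
    assert r_low >= r_base


def test_predicted_rows_are_distributions(both_biases_observer):
    pred = vpc.predict_response_distribution(both_biases_observer, 20.0, seed=0)
    assert np.allclose(pred.condensed.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(pred.full.sum(axis=1), 1.0, atol=1e-9)


def test_high_threshold_zero_angle_reports_no_change():
    p = vpc.VPChangeParams(variant="choice_bias", j_bar=1.0, eta_st=10.0,
                           eta_sa=10.0)
    pred = vpc.predict_response_distribution(p, 0.0, seed=0)
    assert np.all(pred.condensed[:, 2] > 0.99)


def test_full_bias_erases_change_signal():
    """With B = 1 the initial ST percept equals the final one, so the ST hit
    rate on change trials equals the ST false-alarm rate on no-change trials."""
    p = vpc.VPChangeParams(variant="perceptual_bias", j_bar=10.0, B=1.0)
    pred = vpc.predict_response_distribution(p, 30.0, seed=0)
    assert pred.condensed[0, 0] == pytest.approx(pred.condensed[2, 0],
                                                 abs=1e-12)


def test_prediction_consistent_with_generative_sampler(both_biases_observer):
    pred = vpc.predict_response_distribution(both_biases_observer, 20.0,
                                             n_xy=40_000, seed=0)
    rng = np.random.default_rng(1)
    n = 60_000
    for cond, sig in ((0, 0), (1, 1), (2, 4)):
        resp = vpc.sample_responses(both_biases_observer, np.full(n, sig),
                                    20.0, rng)
        p = np.bincount(resp, minlength=5) / n
        emp = np.array([p[0], p[1] + p[2] + p[3], p[4]])
        se = np.sqrt(emp * (1 - emp) / n) + np.sqrt(
            pred.condensed[cond] * (1 - pred.condensed[cond]) / 40_000)
        assert np.all(np.abs(emp - pred.condensed[cond]) < 4 * se + 0.01)


def test_aicc_closed_form():
    assert vpc.aicc(-500.0, 4, 100) == pytest.approx(
        1000 + 8 + 2 * 4 * 5 / 95.0)
    assert vpc.aicc(-500.0, 0, 100) == pytest.approx(1000.0)
    with pytest.raises(ValueError):
        vpc.aicc(-500.0, 4, 5)


def test_free_parameter_counts_by_variant():
    counts = {v: len(vpc.FREE_PARAMS[v]) for v in vpc.VARIANTS}
    assert counts == {"baseline": 1, "perceptual_bias": 2, "choice_bias": 3,
                      "both_biases": 4}


def test_fit_recovers_threshold_ordering(both_biases_observer):
    table = simulate_vp_table(both_biases_observer, 3000, 20.0, seed=42)
    fit = vpc.fit_variant(table, "both_biases", 20.0, seed=0)
    assert fit.params.eta_st < fit.params.eta_sa
    assert 0.1 < fit.params.B < 0.9


def test_fit_deterministic(both_biases_observer):
    table = simulate_vp_table(both_biases_observer, 1200, 20.0, seed=5)
    f1 = vpc.fit_variant(table, "baseline", 20.0, seed=3)
    f2 = vpc.fit_variant(table, "baseline", 20.0, seed=3)
    assert f1.params.j_bar == f2.params.j_bar
    assert f1.log_likelihood == f2.log_likelihood


def test_cross_validation_degenerate_split(both_biases_observer):
    """With identical folds, cvL equals the in-sample likelihood summed
    fold-wise."""
    table = simulate_vp_table(both_biases_observer, 1000, 20.0, seed=6)
    folds = [table.counts.copy(), table.counts.copy()]
    cvl = vpc.cross_validated_likelihood(folds, "baseline", 20.0, seed=0)
    fit = vpc.fit_variant(ContingencyTable(3 * table.counts // 1), "baseline",
                          20.0, seed=0)
    # each fold trains on the same counts, so the evaluation params coincide
    per_fold = vpc.evaluate_variant(
        vpc.fit_variant(ContingencyTable(folds[0]), "baseline", 20.0,
                        seed=0).params,
        ContingencyTable(folds[0]), 20.0, seed=0)
    assert cvl == pytest.approx(2 * per_fold, rel=1e-9)


def test_cross_validation_rejects_empty_session():
    with pytest.raises(ValueError):
        vpc.cross_validated_likelihood([np.zeros((5, 5))], "baseline", 20.0)
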