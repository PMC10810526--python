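"""Forward model, fitting and controls of the 4-ADC signal-detection model."""

import numpy as np
import pytest

from presacc import madc
from presacc.trials import build_contingency_table


def test_zero_parameter_observer_is_symmetric():
    """With d = t = 0 the no-change probability is Φ(0)⁴ = 0.0625 and the
    four change responses are exchangeable."""
    p = madc.response_probabilities(madc.MADCParams(d=np.zeros(4), t=np.zeros(4)))
    assert p[4, 4] == pytest.approx(0.0625, abs=1e-9)
    assert np.allclose(p[4, :4], p[4, 0])
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)


def test_infinite_thresholds_always_no_change():
    p = madc.response_probabilities(
        madc.MADCParams(d=np.ones(4), t=np.full(4, np.inf)))
    assert np.allclose(p[:, 4], 1.0)


def test_probabilities_match_monte_carlo_oracle():
    """Quadrature probabilities agree with brute-force simulation of the
    multivariate decision rule."""
    params = madc.MADCParams(d=[1.5, 0.0, 0.0, 0.0], t=[1.0, 1.0, 1.0, 1.0])
    exact = madc.response_probabilities(params)
    mc = madc.simulate_response_probabilities(
        params, 400_000, np.random.default_rng(0))
    assert np.abs(exact - mc).max() < 0.004


def test_permutation_equivariance():
    """Permuting location labels permutes rows and columns identically."""
    params = madc.MADCParams(d=[0.5, 1.0, 1.5, 2.0], t=[0.2, 0.4, 0.6, 0.8])
    perm = [2, 0, 3, 1]
    p_base = madc.response_probabilities(params)
    p_perm = madc.response_probabilities(
        madc.MADCParams(d=params.d[perm], t=params.t[perm]))
    full_perm = perm + [4]
    assert np.allclose(p_perm, p_base[np.ix_(full_perm, full_perm)], atol=1e-9)


def test_criterion_identity():
    params = madc.MADCParams(d=[1.1, 1.0, 1.0, 1.0], t=[0.61, 0.8, 0.8, 0.8])
    assert params.c[0] == pytest.approx(0.61 - 1.1 / 2)  # 0.06
    assert np.allclose(params.c, params.t - params.d / 2)


def test_fit_recovers_generating_parameters():
    true = madc.MADCParams(d=[1.1, 1.15, 1.15, 1.15],
                           t=[0.61, 0.815, 0.815, 0.815])
    probs = madc.response_probabilities(true)
    rng = np.random.default_rng(2)
    counts = np.vstack([rng.multinomial(1500, row) for row in probs])
    fit, ll = madc.fit_madc(madc.ContingencyTable(counts))
    assert np.abs(fit.d - true.d).max() < 0.15
    assert np.abs(fit.c - true.c).max() < 0.10
    assert np.allclose(fit.c, fit.t - fit.d / 2)
    assert np.isfinite(ll)


def test_fit_null_observer():
    true = madc.MADCParams(d=np.zeros(4), t=np.full(4, 0.8))
    probs = madc.response_probabilities(true)
    rng = np.random.default_rng(3)
    counts = np.vstack([rng.multinomial(1200, row) for row in probs])
    fit, _ = madc.fit_madc(madc.ContingencyTable(counts))
    assert np.all(fit.d < 0.15)


def test_1d_sdt_closed_form():
    """H = 0.69, FA = 0.31 gives d′ ≈ 0.99 and c ≈ 0 by the inverse-normal
    formula (log-linear correction keeps it within rounding)."""
    counts = np.zeros((5, 5))
    counts[0, 0], counts[0, 4] = 690, 310  # hits, misses
    counts[4, 0], counts[4, 4] = 310, 690  # FAs, CRs
    d, c = madc.fit_1d_sdt_no_mislocalization(madc.ContingencyTable(counts))[0]
    assert d == pytest.approx(0.99, abs=0.02)
    assert c == pytest.approx(0.0, abs=0.01)


def test_1d_sdt_null_when_h_equals_fa():
    counts = np.zeros((5, 5))
    counts[0, 0], counts[0, 4] = 500, 500
    counts[4, 0], counts[4, 4] = 500, 500
    d, _ = madc.fit_1d_sdt_no_mislocalization(madc.ContingencyTable(counts))[0]
    assert d == pytest.approx(0.0, abs=1e-9)


def test_gof_rejects_gross_misfit():
    true = madc.MADCParams(d=[1.2] * 4, t=[0.8] * 4)
    probs = madc.response_probabilities(true)
    rng = np.random.default_rng(4)
    counts = np.vstack([rng.multinomial(800, row) for row in probs])
    swapped = counts.copy()
    swapped[:4, [0, 4]] = swapped[:4, [4, 0]]  # swap hit and miss columns
    p = madc.gof_randomization(madc.ContingencyTable(swapped), true,
                               n_rand=200, seed=0)
    assert p < 0.01


def test_gof_calibrated_for_true_model():
    true = madc.MADCParams(d=[1.2] * 4, t=[0.8] * 4)
    probs = madc.response_probabilities(true)
    rng = np.random.default_rng(5)
    pvals = []
    for _ in range(20):
        counts = np.vstack([rng.multinomial(400, row) for row in probs])
        pvals.append(madc.gof_randomization(madc.ContingencyTable(counts),
                                            true, n_rand=99,
                                            seed=int(rng.integers(2**31))))
    assert 0.2 < np.median(pvals) < 0.9


def test_temporal_windows_and_sliding_bookkeeping(detection_session):
    fits = madc.temporal_binned_params(detection_session)
    assert set(fits) == {-175.0, -125.0, -75.0, -25.0}
    done = {c: f for c, f in fits.items() if f is not None}
    assert done, "at least one window should be populated"
    # stationary observer: d estimates agree across windows within noise
    d_tow = [f[0].d[0] for f in done.values()]
    assert np.ptp(d_tow) < 1.2

    centers, toward, away = madc.sliding_hit_fa_timecourse(detection_session)
    assert centers[0] == -200.0 and centers[-1] == 50.0
    # brute-force re-count of one window
    mid = len(centers) // 2
    c = centers[mid]
    lat = detection_session["change_onset_vs_saccade_ms"]
    sub = detection_session[(lat >= c - 25.0) & (lat < c + 25.0)]
    from presacc.trials import response_to_relative

    rel = response_to_relative(sub["cue_location"], sub["response"])
    ch = sub["change_location"].to_numpy()
    expected = (np.mean(rel[ch == "cued"] == "cued")
                + np.mean(rel[ch == "none"] == "cued"))
    assert toward[mid] == pytest.approx(expected, abs=1e-12)


def test_psychometric_fit_recovery():
    angles = np.array([10.0, 25.0, 40.0, 55.0])
    rng = np.random.default_rng(6)

    def sigmoid(x, a, m, s):
        return a / (1.0 + np.exp(-(x - m) / s))

    rates = rng.binomial(200, sigmoid(angles, 0.9, 25.0, 8.0)) / 200
    a, m, s, mono = madc.psychometric_fit(angles, rates)
    assert m == pytest.approx(25.0, abs=3.0)
    assert mono


def test_psychometric_flat_rates_give_flat_curve():
    a, m, s, _ = madc.psychometric_fit([10, 25, 40, 55], [0.5] * 4)
    fitted = a / (1.0 + np.exp(-(np.array([10.0, 55.0]) - m) / s))
    assert abs(fitted[1] - fitted[0]) < 0.05


def test_contingency_table_from_trials_matches_fit_path(detection_session):
    table = build_contingency_table(detection_session)
    assert table.total == len(detection_session)
    row_totals = table.counts.sum(axis=1)
    for i, klass in enumerate(("cued", "opposite", "ipsilateral",
                               "contralateral", "none")):
        assert row_totals[i] == (detection_session["change_location"]
                                 == klass).sum()
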