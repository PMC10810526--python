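"""Permutation tests, Bayes factors, Holm correction and the dip test."""

import numpy as np
import pytest
from scipy import integrate
from scipy.optimize import linprog

from presacc import stats as st


def test_permutation_identical_pairs_gives_p_one():
    res = st.location_permutation_test([1.0, 2.0, 3.0, 4.0],
                                       [1.0, 2.0, 3.0, 4.0])
    assert res.p_value == 1.0
    assert res.observed == 0.0


def test_permutation_exhaustive_for_small_samples():
    res = st.location_permutation_test([2.0, 2.1, 1.9, 2.2, 2.0],
                                       [1.0, 1.2, 0.9, 1.1, 1.0])
    assert res.exact
    assert res.p_value == pytest.approx(2 / 32)  # only ±all-signs as extreme


def test_permutation_reproducible_with_seed():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0.3, 1, 20), rng.normal(0, 1, 20)
    r1 = st.location_permutation_test(a, b, seed=9)
    r2 = st.location_permutation_test(a, b, seed=9)
    assert r1.p_value == r2.p_value
    assert r1.p_value >= 1.0 / (r1.n_shuffles + 1)


def test_cluster_permutation_finds_injected_effect_and_not_noise():
    rng = np.random.default_rng(1)
    noise = rng.normal(0, 1, size=(10, 30))
    assert all(c.p_value > 0.05
               for c in st.cluster_permutation_timecourse(noise, 500, seed=2))
    effect = noise.copy()
    effect[:, 10:15] += 1.5
    clusters = st.cluster_permutation_timecourse(effect, 500, seed=2)
    sig = [c for c in clusters if c.p_value <= 0.05]
    assert sig and any(c.start <= 10 and c.stop >= 14 for c in sig)


def test_cluster_permutation_empty_when_subthreshold():
    flat = np.random.default_rng(3).normal(0, 1, size=(8, 20)) * 0.01
    assert st.cluster_permutation_timecourse(flat, 200, seed=0) == []


def rouder_bf_oracle(t, n, r=np.sqrt(2) / 2):
    """JZS BF by the g-prior integral (independent of the nct route)."""
    nu = n - 1

    def integrand(g):
        return ((1 + n * g * r**2) ** -0.5
                * (1 + t**2 / ((1 + n * g * r**2) * nu)) ** (-(nu + 1) / 2)
                * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g)))

    num, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return num / den


@pytest.mark.parametrize("t,n", [(0.0, 10), (1.5, 8), (2.5, 12), (4.0, 20),
                                 (-2.0, 15)])
def test_jzs_matches_g_prior_oracle(t, n):
    assert st.jzs_bf_from_t(t, n) == pytest.approx(rouder_bf_oracle(t, n),
                                                   rel=0.01)


def test_jzs_null_favoring_at_t_zero_and_growth():
    assert st.jzs_bf_from_t(0.0, 12) < 1.0
    bfs = [st.jzs_bf_from_t(t, 12) for t in (0.0, 2.0, 4.0, 8.0)]
    assert np.all(np.diff(bfs) > 0)


def test_one_tailed_doubles_in_the_supported_direction():
    two = st.jzs_bf_from_t(3.0, 10, tail="two")
    one = st.jzs_bf_from_t(3.0, 10, tail="one")
    assert two < one < 2.0 * two + 1e-9


def test_sequential_bf_final_matches_full_sample():
    rng = np.random.default_rng(4)
    d = rng.normal(0.8, 1.0, 12)
    seq = st.sequential_bf(d)
    assert len(seq) == 11
    assert seq[-1] == pytest.approx(st.jzs_bayes_factor(d), rel=1e-9)


def test_holm_adjustment_examples_and_monotonicity():
    assert np.allclose(st.holm_correction([0.01, 0.04, 0.03]),
                       [0.03, 0.06, 0.06])
    assert st.holm_correction([0.2]) == pytest.approx([0.2])
    rng = np.random.default_rng(5)
    p = rng.uniform(size=8)
    adj = st.holm_correction(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    # adjusted values are ordered like the raw p-values
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)


# --- dip test ---------------------------------------------------------------


def lp_dip_oracle(sample, tol=1e-5):
    """Brute-force dip: bisection over d with an LP feasibility check per
    candidate mode knot (values + left limit as variables, convexity /
    concavity / monotonicity as linear constraints)."""
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    xs, idx, counts = np.unique(x, return_index=True, return_counts=True)
    if len(xs) == 1:
        return 0.0
    a_val, b_val = idx / n, (idx + counts) / n

    def mode_feasible(lo, hi, a_band, b_band, k):
        m = len(xs)
        nv = m + 1  # g_0..g_{m-1}, a (left limit at the mode)
        A_ub, b_ub = [], []

        def vi(j):
            return nv - 1 if j == k else j

        pre = list(range(k + 1))
        for t in range(1, len(pre) - 1):
            i0, i1, i2 = pre[t - 1], pre[t], pre[t + 1]
            h1, h2 = xs[i1] - xs[i0], xs[i2] - xs[i1]
            row = np.zeros(nv)
            row[vi(i0)] += 1 / h1
            row[vi(i1)] -= 1 / h1 + 1 / h2
            row[vi(i2)] += 1 / h2
            A_ub.append(-row)
            b_ub.append(0.0)
        suf = list(range(k, m))
        for t in range(1, len(suf) - 1):
            i0, i1, i2 = suf[t - 1], suf[t], suf[t + 1]
            h1, h2 = xs[i1] - xs[i0], xs[i2] - xs[i1]
            row = np.zeros(nv)
            row[i0] += 1 / h1
            row[i1] -= 1 / h1 + 1 / h2
            row[i2] += 1 / h2
            A_ub.append(row)
            b_ub.append(0.0)
        for seq, idx_fn in ((pre, vi), (suf, lambda j: j)):
            for t in range(len(seq) - 1):
                row = np.zeros(nv)
                row[idx_fn(seq[t])] = 1
                row[idx_fn(seq[t + 1])] -= 1
                A_ub.append(row)
                b_ub.append(0.0)
        row = np.zeros(nv)
        row[nv - 1] = 1
        row[k] = -1
        A_ub.append(row)
        b_ub.append(0.0)
        bounds = [(lo[j], hi[j]) if j != k else b_band for j in range(m)]
        bounds.append(a_band)
        if any(b[0] > b[1] + 1e-12 for b in bounds):
            return False
        res = linprog(np.zeros(nv), A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=bounds, method="highs")
        return res.success

    def feasible(d):
        lo = np.clip(b_val - d, 0, 1)
        hi = np.clip(a_val + d, 0, 1)
        for k in range(len(xs)):
            if mode_feasible(lo, hi,
                             (max(a_val[k] - d, 0), min(a_val[k] + d, 1)),
                             (max(b_val[k] - d, 0), min(b_val[k] + d, 1)), k):
                return True
        return False

    lo_d, hi_d = 0.0, 0.5
    while hi_d - lo_d > tol:
        mid = (lo_d + hi_d) / 2
        if feasible(mid):
            hi_d = mid
        else:
            lo_d = mid
    return hi_d


def test_dip_matches_lp_oracle_on_small_samples():
    rng = np.random.default_rng(6)
    samples = [
        np.repeat([0.0, 1.0], 5),                       # two point masses
        rng.uniform(size=15),
        rng.normal(size=18),
        np.concatenate([rng.normal(-2, 0.3, 8), rng.normal(2, 0.3, 8)]),
        np.round(rng.uniform(0, 1, 14), 1),             # heavy ties
    ]
    for s in samples:
        assert st.dip_statistic(s) == pytest.approx(lp_dip_oracle(s),
                                                    abs=2e-4)


def test_dip_point_masses_reach_quarter():
    assert st.dip_statistic(np.repeat([0.0, 1.0], 10)) == pytest.approx(
        0.25, abs=1e-4)


def test_dip_test_rejects_strong_bimodality():
    rng = np.random.default_rng(7)
    sample = np.concatenate([rng.normal(-3, 0.3, 100), rng.normal(3, 0.3, 100)])
    d, p = st.dip_test(sample, n_boot=199, seed=0)
    assert p < 0.01


def test_dip_test_accepts_unimodal():
    rng = np.random.default_rng(8)
    d, p = st.dip_test(rng.normal(size=150), n_boot=99, seed=0)
    assert p > 0.10


def test_dip_bootstrap_calibration_spread():
    """Under the uniform null, bootstrap p-values spread over (0, 1] rather
    than piling near 0 or 1."""
    rng = np.random.default_rng(9)
    pvals = [st.dip_test(rng.uniform(size=40), n_boot=99,
                         seed=int(rng.integers(2**31)))[1]
             for _ in range(15)]
    assert min(pvals) < 0.5 < max(pvals)
    assert np.mean([p <= 0.2 for p in pvals]) < 0.6


def test_kruskal_and_wilcoxon_delegation():
    rng = np.random.default_rng(10)
    h, p = st.kruskal_wallis(rng.normal(size=12), rng.normal(size=12),
                             rng.normal(size=12))
    assert 0 <= p <= 1
    w, pw = st.wilcoxon_signed_rank(rng.normal(0.8, 1, 15))
    assert 0 <= pw <= 1
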