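"""Inferential toolkit: permutation tests, cluster-based permutation over
time courses, JZS Bayes factors with sequential analysis, Bonferroni–Holm
correction, and Hartigan's dip test of unimodality.

Permutation p-values use add-one smoothing, p = (b + 1)/(m + 1), except when
the arrangement space is small enough (≤ 2¹⁵) to enumerate exhaustively, in
which case the exact fraction is returned. Kruskal–Wallis, Wilcoxon and
Mann–Whitney comparisons are delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats as sps
from statsmodels.stats.multitest import multipletests

EXHAUSTIVE_LIMIT = 2**15


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    null_mean: float
    null_sd: float
    n_shuffles: int
    seed: int | None
    exact: bool = False


def location_permutation_test(toward_values, away_values, n_shuffles: int = 1000,
                              seed: int = 0, alternative: str = "two-sided"
                              ) -> PermutationResult:
    """Paired permutation test of toward − away by shuffling location labels.

    Shuffling toward/away labels within a participant flips the sign of that
    participant's difference; the null distribution is the mean difference
    under random (or, for small samples, all 2ⁿ) sign assignments.
    """
    toward = np.asarray(toward_values, dtype=float)
    away = np.asarray(away_values, dtype=float)
    if toward.shape != away.shape:
        raise ValueError("paired samples must have equal length")
    if len(toward) < 3:
        import warnings

        warnings.warn("fewer than 3 pairs: permutation test is very coarse",
                      stacklevel=2)
    diffs = toward - away
    observed = float(diffs.mean())
    n = len(diffs)
    if 2**n <= EXHAUSTIVE_LIMIT:
        signs = np.array(np.meshgrid(*[[1.0, -1.0]] * n)).reshape(n, -1).T
        null = signs @ diffs / n
        exact = True
        m = len(null)
        b = _count_extreme(null, observed, alternative)
        p = b / m
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_shuffles, n))
        null = signs @ diffs / n
        exact = False
        b = _count_extreme(null, observed, alternative)
        p = (b + 1) / (n_shuffles + 1)
    return PermutationResult(observed=observed, p_value=float(min(p, 1.0)),
                             null_mean=float(null.mean()),
                             null_sd=float(null.std()),
                             n_shuffles=len(null), seed=seed, exact=exact)


def _count_extreme(null, observed, alternative):
    if alternative == "two-sided":
        return int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    if alternative == "greater":
        return int(np.sum(null >= observed - 1e-12))
    if alternative == "less":
        return int(np.sum(null <= observed + 1e-12))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class Cluster:
    start: int
    stop: int  # inclusive bin indices
    mass: float
    p_value: float


def cluster_permutation_timecourse(series_by_participant, n_shuffles: int = 1000,
                                   seed: int = 0, alpha: float = 0.05,
                                   cluster_alpha: float = 0.05):
    """Cluster-based permutation test of a participants × time-bins array
    against zero.

    Per-bin one-sample t-values above the two-sided ``cluster_alpha`` critical
    value form candidate clusters of contiguous same-sign bins; the cluster
    statistic is the summed t (mass), tested against the max-cluster-mass
    distribution under participant-wise sign flips. Returns all candidate
    clusters; callers filter on ``p_value <= alpha``.
    """
    data = np.asarray(series_by_participant, dtype=float)
    n_sub, n_bins = data.shape
    rng = np.random.default_rng(seed)
    t_crit = sps.t.ppf(1.0 - cluster_alpha / 2.0, df=n_sub - 1)

    def t_values(d):
        sd = d.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return d.mean(axis=0) / (sd / np.sqrt(n_sub))

    def clusters_of(tv):
        out = []
        i = 0
        while i < n_bins:
            if abs(tv[i]) > t_crit:
                sign = np.sign(tv[i])
                j = i
                while j + 1 < n_bins and abs(tv[j + 1]) > t_crit \
                        and np.sign(tv[j + 1]) == sign:
                    j += 1
                out.append((i, j, float(tv[i:j + 1].sum())))
                i = j + 1
            else:
                i += 1
        return out

    obs_clusters = clusters_of(t_values(data))
    if not obs_clusters:
        return []
    null_max = np.zeros(n_shuffles)
    for s in range(n_shuffles):
        flips = rng.choice([1.0, -1.0], size=(n_sub, 1))
        cl = clusters_of(t_values(data * flips))
        if cl:
            null_max[s] = max(abs(m) for _, _, m in cl)
    results = []
    for start, stop, mass in obs_clusters:
        b = int(np.sum(null_max >= abs(mass) - 1e-12))
        results.append(Cluster(start=start, stop=stop, mass=mass,
                               p_value=(b + 1) / (n_shuffles + 1)))
    return results


def jzs_bayes_factor(differences, tail: str = "two",
                     prior_scale: float = np.sqrt(2) / 2.0) -> float:
    """JZS Bayes factor BF₁₀ for a one-sample (paired) t-test.

    Integrates the noncentral-t likelihood over a Cauchy(0, ``prior_scale``)
    prior on the standardized effect size δ; ``tail='one'`` restricts (and
    renormalizes) the prior to δ > 0. BF > 3 (or > 10) is conventionally read
    as substantial (strong) evidence for the effect.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    return jzs_bf_from_t(t, n, tail=tail, prior_scale=prior_scale)


def jzs_bf_from_t(t: float, n: int, tail: str = "two",
                  prior_scale: float = np.sqrt(2) / 2.0) -> float:
    nu = n - 1

    def integrand(delta):
        return sps.nct.pdf(t, nu, delta * np.sqrt(n)) * \
            sps.cauchy.pdf(delta, scale=prior_scale)

    if tail == "two":
        m1, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    elif tail == "one":
        m1, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        m1 *= 2.0  # half-Cauchy renormalization
    else:
        raise ValueError("tail must be 'one' or 'two'")
    m0 = sps.t.pdf(t, nu)
    return float(m1 / m0)


def sequential_bf(differences_ordered, tail: str = "two",
                  prior_scale: float = np.sqrt(2) / 2.0) -> np.ndarray:
    """BF₁₀ recomputed at each cumulative sample size from 2 upward."""
    d = np.asarray(differences_ordered, dtype=float)
    out = []
    for n in range(2, len(d) + 1):
        if d[:n].std(ddof=1) == 0:
            out.append(np.nan)
        else:
            out.append(jzs_bayes_factor(d[:n], tail=tail,
                                        prior_scale=prior_scale))
    return np.asarray(out)


def holm_correction(p_values) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Hartigan's dip
# ---------------------------------------------------------------------------
# The dip of an empirical CDF F_n is min_G sup|F_n - G| over unimodal CDFs G
# (convex up to a mode m, concave after it, an atom allowed at the mode).
# |F_n - G| <= d constrains, at each distinct sorted value with original
# 0-based indices i_first..i_last, the CDF value to
#     b in [(i_last+1)/n - d, (i_last+1)/n + d]
# and its left limit to
#     a in [i_first/n - d, i_first/n + d],
# both clipped to [0, 1]; away from the mode a = b, so the working band is
# the intersection of the two.  Feasibility at tolerance d holds iff some
# knot k can act as the mode: a nondecreasing convex function threads the
# bands left of k and ends inside k's left-limit band at a value a, a
# nondecreasing concave function threads the bands right of k and starts
# inside k's value band at b, and a <= b (a jump up at the mode is an atom).
#
# Two exact facts reduce this to hull geometry.  (i) Convex threading of
# bands [L, U] is feasible iff the greatest convex minorant of the U-points
# clears every L (it is then the pointwise-highest monotone thread).
# (ii) The lowest value a convex monotone thread can reach just right of its
# bands is max(L_j, lines through (x_i, U_i) and (x_j, L_j) for pairs with
# U_i < L_j, extrapolated): the three-point convexity inequality forces each
# of these bounds, and their pointwise maximum is itself a valid thread.
# The end-value interval on the convex side is therefore [minP, a_hi], the
# start-value interval on the concave side (by mirror symmetry) is
# [b_lo, maxS], and the mode works iff both are nonempty and minP <= maxS.
# The dip itself is found by bisection on d.


def _gcm(xs, y):
    """Greatest convex minorant of points (xs, y): hull values at xs."""
    m = len(xs)
    hull = [0]
    for j in range(1, m):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (y[j] - y[b]) * (xs[b] - xs[a]) <= (y[b] - y[a]) * (xs[j] - xs[b]):
                hull.pop()
            else:
                break
        hull.append(j)
    out = np.empty(m)
    for a, b in zip(hull[:-1], hull[1:]):
        t = (xs[a:b + 1] - xs[a]) / (xs[b] - xs[a]) if xs[b] > xs[a] else 0.0
        out[a:b + 1] = y[a] + t * (y[b] - y[a])
    out[hull[-1]] = y[hull[-1]]
    return out


def _convex_feasible(xs, lo, hi, tol=1e-12) -> bool:
    """Can a nondecreasing convex function pass through every band
    [lo_j, hi_j]?  (Bands are assumed monotone, as the CDF bands are.)"""
    if np.any(lo > hi + tol):
        return False
    if len(xs) <= 1:
        return True
    return not np.any(_gcm(xs, hi) < lo - tol)


def _prefix_feasible_flags(xs, lo, hi, tol=1e-12):
    """flags[k] = a convex thread exists through bands 0..k-1 (monotone in k,
    located by binary search)."""
    m = len(xs)
    lo_k, hi_k = 0, m  # prefix length: feasible at lo_k, unknown above
    if _convex_feasible(xs, lo, hi, tol):
        lo_k = m
    while hi_k - lo_k > 1:
        mid = (lo_k + hi_k) // 2
        if _convex_feasible(xs[:mid], lo[:mid], hi[:mid], tol):
            lo_k = mid
        else:
            hi_k = mid
    flags = np.zeros(m + 1, dtype=bool)
    flags[:lo_k + 1] = True
    return flags


def _prefix_min_end(xs, lo, hi):
    """pmin[k]: lowest value reachable at x_k by a monotone convex thread
    through bands 0..k-1 (-inf where unconstrained)."""
    m = len(xs)
    pmin = np.full(m, -np.inf)
    slopes = np.empty(m)
    icpts = np.empty(m)
    nlines = 0
    max_l = -np.inf
    for k in range(m):
        if k > 0:
            v = max_l
            if nlines:
                v = max(v, float(np.max(slopes[:nlines] * xs[k]
                                        + icpts[:nlines])))
            pmin[k] = v
        if k >= 1:
            s = float(np.max((lo[k] - hi[:k]) / (xs[k] - xs[:k])))
            if s > 0:  # steepest line from an earlier upper bound up to L_k
                slopes[nlines] = s
                icpts[nlines] = lo[k] - s * xs[k]
                nlines += 1
        max_l = max(max_l, lo[k])
    return pmin


def _dip_feasible(xs, a_val, b_val, d, tol=1e-12) -> bool:
    lo = np.clip(b_val - d, 0.0, 1.0)
    hi = np.clip(a_val + d, 0.0, 1.0)
    a_lo, a_hi = np.clip(a_val - d, 0.0, 1.0), np.clip(a_val + d, 0.0, 1.0)
    b_lo, b_hi = np.clip(b_val - d, 0.0, 1.0), np.clip(b_val + d, 0.0, 1.0)
    pre_ok = _prefix_feasible_flags(xs, lo, hi, tol)[:-1]
    pmin = _prefix_min_end(xs, lo, hi)
    # suffix side via the mirror transform (reverse x, negate values)
    xs_m, lo_m, hi_m = -xs[::-1], -hi[::-1], -lo[::-1]
    suf_ok = _prefix_feasible_flags(xs_m, lo_m, hi_m, tol)[:-1][::-1]
    smax = -_prefix_min_end(xs_m, lo_m, hi_m)[::-1]
    min_p = np.maximum(pmin, a_lo)
    max_s = np.minimum(smax, b_hi)
    ok = (pre_ok & suf_ok & (min_p <= a_hi + tol) & (max_s >= b_lo - tol)
          & (min_p <= max_s + tol))
    return bool(ok.any())


def dip_statistic(sample, tol: float = 1e-6) -> float:
    """Hartigan's dip statistic: the smallest sup-distance between the
    empirical CDF and the set of unimodal CDFs (bisection on the distance)."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 2:
        return 0.0
    xs, idx, counts = np.unique(x, return_index=True, return_counts=True)
    if len(xs) == 1:
        return 0.0
    a_val = idx / n
    b_val = (idx + counts) / n
    lo_d, hi_d = 0.0, 0.5
    while hi_d - lo_d > tol:
        mid = 0.5 * (lo_d + hi_d)
        if _dip_feasible(xs, a_val, b_val, mid):
            hi_d = mid
        else:
            lo_d = mid
    return float(hi_d)


def dip_test(sample, n_boot: int = 1000, seed: int = 0):
    """Dip statistic with a bootstrap p-value against the uniform null.

    The null distribution is the dip of uniform samples of the same size
    (the standard calibration for Hartigan's test); p uses add-one smoothing.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 10:
        raise ValueError("dip test needs at least 10 observations")
    obs = dip_statistic(sample, tol=1e-5)
    rng = np.random.default_rng(seed)
    boots = np.array([dip_statistic(rng.uniform(size=len(sample)), tol=1e-5)
                      for _ in range(n_boot)])
    p = (int(np.sum(boots >= obs - 1e-15)) + 1) / (n_boot + 1)
    return obs, float(p)


def kruskal_wallis(*groups):
    """Kruskal–Wallis H and p (scipy delegation)."""
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a, b=None):
    """Two-tailed Wilcoxon signed-rank test (scipy delegation)."""
    res = sps.wilcoxon(a, b) if b is not None else sps.wilcoxon(a)
    return float(res.statistic), float(res.pvalue)
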