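"""Multidimensional signal detection (4-ADC) model of change detection/localization.

The observer monitors four locations. On a change-at-``i`` trial the decision
variable at location ``k`` is Gaussian with unit variance and mean ``d_i`` if
``k == i`` else 0; each location has a threshold ``t_k``. The observer reports
the location whose decision variable exceeds its threshold by the largest
margin, or "no change" if none does. The criterion measure of choice bias is
``c = t − d′/2`` per location.

Response probabilities reduce to one-dimensional integrals over the maximal
threshold-exceedance ``z``:

    P(respond j | signal i) = ∫₀^∞ φ(z − μ_j) Π_{k≠j} Φ(z − μ_k) dz
    P(no change | signal i) = Π_k Φ(−μ_k),   μ_k = d_i·[k=i] − t_k
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

N_LOC = 4
LOCATION_LABELS = ("cued", "opposite", "ipsilateral", "contralateral")
RESPONSE_LABELS = LOCATION_LABELS + ("no_change",)

# Gauss-Legendre nodes for the exceedance integral on (0, hi)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)

D_BOUNDS = (0.0, 5.0)
T_BOUNDS = (-3.0, 5.0)


@dataclass
class MADCParams:
    """Sensitivities d′ and thresholds t per location; criteria are c = t − d′/2."""

    d: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.d.shape != (N_LOC,) or self.t.shape != (N_LOC,):
            raise ValueError("d and t must be 4-vectors")
        if np.any(np.isnan(self.d)) or np.any(np.isnan(self.t)) or \
                np.any(np.isinf(self.d)):
            raise ValueError("non-finite m-ADC parameters")
        # +inf thresholds are allowed: the degenerate always-"no change" observer
        if np.any(self.d < 0):
            raise ValueError("sensitivities must be non-negative")

    @property
    def c(self) -> np.ndarray:
        return self.t - self.d / 2.0


@dataclass
class ContingencyTable:
    """5×5 stimulus-by-response counts, rows/columns ordered
    (cued, opposite, ipsilateral, contralateral, no-change) relative to the cue."""

    counts: np.ndarray
    row_labels: tuple = field(default=RESPONSE_LABELS, init=False)
    col_labels: tuple = field(default=RESPONSE_LABELS, init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (5, 5):
            raise ValueError("contingency table must be 5x5")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _row_means(params: MADCParams, signal: int | None) -> np.ndarray:
    mu = -params.t.copy()
    if signal is not None:
        mu[signal] += params.d[signal]
    return mu


def _row_probabilities(mu: np.ndarray) -> np.ndarray:
    """P(each of 5 responses) for decision-variable means ``mu`` (4,)."""
    finite = mu[np.isfinite(mu)]
    hi = max(float(finite.max()) + 9.0, 9.0) if finite.size else 9.0
    z = 0.5 * hi * (_GL_NODES + 1.0)
    w = 0.5 * hi * _GL_WEIGHTS
    zm = z[:, None] - mu[None, :]
    cdf = stats.norm.cdf(zm)
    pdf = stats.norm.pdf(zm)
    out = np.empty(5)
    for j in range(N_LOC):
        others = np.prod(np.delete(cdf, j, axis=1), axis=1)
        out[j] = np.sum(w * pdf[:, j] * others)
    out[N_LOC] = np.prod(stats.norm.cdf(-mu))
    return out


def response_probabilities(params: MADCParams) -> np.ndarray:
    """5×5 response-probability matrix; row i = change at location i, row 5 = no change."""
    rows = [_row_probabilities(_row_means(params, i)) for i in range(N_LOC)]
    rows.append(_row_probabilities(_row_means(params, None)))
    return np.vstack(rows)


def simulate_response_probabilities(params: MADCParams, n_draws: int,
                                    rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo version of :func:`response_probabilities` (independent oracle
    for testing, and the generative engine for synthetic m-ADC observers)."""
    out = np.empty((5, 5))
    for i in range(5):
        signal = i if i < N_LOC else None
        mu = _row_means(params, signal)
        zs = rng.standard_normal((n_draws, N_LOC)) + mu
        out[i] = _tally_decisions(zs)
    return out


def _tally_decisions(z_excess: np.ndarray) -> np.ndarray:
    """Tally the 5 responses for threshold-exceedance draws (n, 4)."""
    best = np.argmax(z_excess, axis=1)
    exceeded = z_excess[np.arange(len(z_excess)), best] > 0
    counts = np.bincount(np.where(exceeded, best, N_LOC), minlength=5)
    return counts / len(z_excess)


def sample_madc_responses(params: MADCParams, signals: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw one response (0..3 location, 4 = no change) per trial.

    ``signals``: per-trial change location 0..3 or 4 for no-change trials.
    """
    signals = np.asarray(signals)
    z = rng.standard_normal((len(signals), N_LOC)) - params.t
    is_change = signals < N_LOC
    z[np.arange(len(signals))[is_change], signals[is_change]] += params.d[
        signals[is_change]
    ]
    best = np.argmax(z, axis=1)
    exceeded = z[np.arange(len(signals)), best] > 0
    return np.where(exceeded, best, N_LOC)


def _neg_log_likelihood(theta: np.ndarray, counts: np.ndarray) -> float:
    params = MADCParams(d=np.maximum(theta[:N_LOC], 0.0), t=theta[N_LOC:])
    p = np.clip(response_probabilities(params), 1e-12, 1.0)
    return float(-np.sum(counts * np.log(p)))


def _moment_start(counts: np.ndarray) -> np.ndarray:
    """1-D SDT estimates per location as a multistart anchor."""
    d0 = np.empty(N_LOC)
    t0 = np.empty(N_LOC)
    for loc, (dp, c) in enumerate(fit_1d_sdt_no_mislocalization(
            ContingencyTable(counts))):
        d0[loc] = np.clip(dp, *D_BOUNDS)
        t0[loc] = np.clip(c + dp / 2.0, *T_BOUNDS)
    return np.concatenate([d0, t0])


def fit_madc(table: ContingencyTable) -> tuple[MADCParams, float]:
    """Maximum-likelihood m-ADC fit of a 5×5 contingency table.

    Bounded L-BFGS-B from a deterministic 5-point multistart schedule; the best
    likelihood wins, making the fit reproducible. Returns (params, log-likelihood).
    """
    counts = table.counts
    if table.total < 25:
        raise ValueError("table total below identifiability floor (25 trials)")
    if np.any(counts.sum(axis=1) == 0):
        import warnings

        warnings.warn("degenerate contingency table: empty stimulus row", stacklevel=2)
    starts = [_moment_start(counts)]
    for d0, t0 in [(1.0, 0.5), (0.5, 1.0), (2.0, 1.0), (1.5, 0.0)]:
        starts.append(np.concatenate([np.full(N_LOC, d0), np.full(N_LOC, t0)]))
    bounds = [D_BOUNDS] * N_LOC + [T_BOUNDS] * N_LOC
    best = None
    for x0 in starts:
        res = optimize.minimize(_neg_log_likelihood, x0, args=(counts,),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    params = MADCParams(d=best.x[:N_LOC], t=best.x[N_LOC:])
    return params, -float(best.fun)


def fit_1d_sdt_no_mislocalization(table: ContingencyTable) -> list[tuple[float, float]]:
    """Per-location yes/no (d′, c) after dropping mislocalization cells.

    Only hits, misses, false alarms and correct rejections enter; zero or unit
    rates are handled with the log-linear (add 0.5) correction.
    """
    counts = table.counts
    out = []
    for loc in range(N_LOC):
        h, m = counts[loc, loc], counts[loc, N_LOC]
        f, r = counts[N_LOC, loc], counts[N_LOC, N_LOC]
        hr = (h + 0.5) / (h + m + 1.0)
        fr = (f + 0.5) / (f + r + 1.0)
        zh, zf = stats.norm.ppf(hr), stats.norm.ppf(fr)
        out.append((zh - zf, -(zh + zf) / 2.0))
    return out


def chi_squared_statistic(counts: np.ndarray, probs: np.ndarray) -> float:
    expected = counts.sum(axis=1, keepdims=True) * probs
    expected = np.maximum(expected, 1e-6)
    return float(np.sum((counts - expected) ** 2 / expected))


def gof_randomization(table: ContingencyTable, params: MADCParams,
                      n_rand: int = 1000, seed: int = 0) -> float:
    """Parametric-bootstrap goodness of fit: p = P(χ²_sim ≥ χ²_obs) under the
    fitted model, with add-one smoothing."""
    if n_rand < 100:
        import warnings

        warnings.warn("n_rand < 100 gives a coarse GOF p-value", stacklevel=2)
    probs = response_probabilities(params)
    obs = chi_squared_statistic(table.counts, probs)
    rng = np.random.default_rng(seed)
    row_totals = table.counts.sum(axis=1).astype(int)
    exceed = 0
    for _ in range(n_rand):
        sim = np.vstack([rng.multinomial(n, p) for n, p in zip(row_totals, probs)])
        if chi_squared_statistic(sim, probs) >= obs:
            exceed += 1
    return (exceed + 1) / (n_rand + 1)


def temporal_binned_params(trials, window_centers=(-175.0, -125.0, -75.0, -25.0),
                           width: float = 50.0):
    """m-ADC fits in saccade-locked time windows.

    Windows are half-open ``[center − width/2, center + width/2)`` on the
    change-event-to-saccade-onset latency. Empty windows are skipped and
    reported as ``None``.
    """
    from .trials import build_contingency_table

    lat = trials["change_onset_vs_saccade_ms"].to_numpy(dtype=float)
    fits = {}
    for center in window_centers:
        mask = (lat >= center - width / 2.0) & (lat < center + width / 2.0)
        sub = trials[mask]
        if len(sub) < 25:
            fits[center] = None
            continue
        params, ll = fit_madc(build_contingency_table(sub))
        fits[center] = (params, ll)
    return fits


def sliding_hit_fa_timecourse(trials, width: float = 50.0, shift: float = 5.0,
                              span: tuple[float, float] = (-200.0, 50.0)):
    """Hit+FA rate per overlapping saccade-locked window, split ST vs SA.

    Returns (window centers, toward series, away series); windows with no
    eligible trials yield NaN.
    """
    from .trials import response_to_relative

    lat = trials["change_onset_vs_saccade_ms"].to_numpy(dtype=float)
    change = trials["change_location"].to_numpy()
    resp = response_to_relative(trials["cue_location"], trials["response"])
    centers = np.arange(span[0], span[1] + 1e-9, shift)
    toward = np.full(len(centers), np.nan)
    away = np.full(len(centers), np.nan)
    sa_classes = ("opposite", "ipsilateral", "contralateral")
    for i, c in enumerate(centers):
        m = (lat >= c - width / 2.0) & (lat < c + width / 2.0)
        if not m.any():
            continue
        ch, rs = change[m], resp[m]
        toward[i] = _hit_fa_sum(ch, rs, "cued")
        vals = [_hit_fa_sum(ch, rs, klass) for klass in sa_classes]
        vals = [v for v in vals if not np.isnan(v)]
        away[i] = np.mean(vals) if vals else np.nan
    return centers, toward, away


def _hit_fa_sum(change, rel_resp, klass):
    is_sig = change == klass
    is_noise = change == "none"
    hit = np.mean(rel_resp[is_sig] == klass) if is_sig.any() else np.nan
    fa = np.mean(rel_resp[is_noise] == klass) if is_noise.any() else np.nan
    if np.isnan(hit) or np.isnan(fa):
        return np.nan
    return hit + fa


def psychometric_fit(angles, hit_rates):
    """Three-parameter sigmoid fit of hit rate vs change angle.

    rate(θ) = a / (1 + exp(−(θ − m)/s)): asymptote a, midpoint m, slope 1/s.
    Returns (a, m, s, monotone_flag); the flag is False when the observed rates
    are grossly non-monotone (fit still returned).
    """
    angles = np.asarray(angles, dtype=float)
    rates = np.asarray(hit_rates, dtype=float)
    if len(angles) < 3:
        raise ValueError("need at least 3 angle levels")

    def sigmoid(x, a, m, s):
        return a / (1.0 + np.exp(-(x - m) / s))

    p0 = (max(rates.max(), 0.1), float(np.median(angles)), 10.0)
    popt, _ = optimize.curve_fit(
        sigmoid, angles, rates, p0=p0,
        bounds=([0.0, 0.0, 0.1], [1.0, 180.0, 1e4]), maxfev=20000)
    order = np.argsort(angles)
    monotone = bool(np.all(np.diff(rates[order]) >= -0.15))
    return float(popt[0]), float(popt[1]), float(popt[2]), monotone
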