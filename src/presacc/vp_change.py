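"""Variable-precision Bayesian observer for change detection & localization.

On each trial the observer holds noisy von Mises measurements x (initial set)
and y (final set) of the four stimuli, with per-item precisions drawn from
gamma distributions. The posterior odds of change vs no-change at location l
is proportional to

    F(l) = I₀(κ_x)·I₀(κ_y) / I₀(√(κ_x² + κ_y² + 2 κ_x κ_y cos(y − x)))

with all angles on the doubled-orientation circle. The observer reports "no
change" unless F(l) exceeds the decision threshold η_l somewhere, else the
location maximizing F(l) − η_l.

Four variants:

==============  ==========================================  ====
variant         free parameters                              k
==============  ==========================================  ====
baseline        J̄                                            1
perceptual_bias J̄, B (recency weight at the saccade target)  2
choice_bias     J̄, η_ST, η_SA                                3
both_biases     J̄, B, η_ST, η_SA                             4
==============  ==========================================  ====

The final-set precision at the saccade target is a fixed multiple (default 6)
of J̄ and the gamma scale τ is fixed (default 13), both imported from the
estimation-task fit. Response distributions are predicted by Monte-Carlo
simulation with common random numbers, and fitted to 3×3 (ST / pooled-SA /
no-change) multinomial counts by generalized pattern search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circular import default_vm_sampler, log_i0
from .madc import ContingencyTable

VARIANTS = ("baseline", "perceptual_bias", "choice_bias", "both_biases")
FREE_PARAMS = {
    "baseline": ("j_bar",),
    "perceptual_bias": ("j_bar", "B"),
    "choice_bias": ("j_bar", "eta_st", "eta_sa"),
    "both_biases": ("j_bar", "B", "eta_st", "eta_sa"),
}
PARAM_BOUNDS = {"j_bar": (0.05, 50.0), "B": (0.0, 1.0),
                "eta_st": (0.01, 10.0), "eta_sa": (0.01, 10.0)}
LOG_SCALED = {"j_bar": True, "B": False, "eta_st": True, "eta_sa": True}


@dataclass
class VPChangeParams:
    """One variant's parameter vector; fixed fields default to the paper-level
    constraints (η = 1, no perceptual bias)."""

    variant: str
    j_bar: float
    B: float = 0.0
    eta_st: float = 1.0
    eta_sa: float = 1.0
    final_st_precision_ratio: float = 6.0
    tau: float = 13.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.B <= 1.0:
            raise ValueError("B must lie in [0, 1]")
        if self.j_bar <= 0 or self.eta_st <= 0 or self.eta_sa <= 0 or self.tau <= 0:
            raise ValueError("j_bar, eta and tau must be positive")

    @property
    def k_free(self) -> int:
        return len(FREE_PARAMS[self.variant])

    @property
    def eta(self) -> np.ndarray:
        return np.array([self.eta_st, self.eta_sa, self.eta_sa, self.eta_sa])


def decision_variable(x, y, kappa_x, kappa_y):
    """Posterior-odds decision variable F (change vs no change) for doubled-
    circle measurements x, y; log-Bessel guarded against overflow."""
    kappa_x = np.asarray(kappa_x, dtype=float)
    kappa_y = np.asarray(kappa_y, dtype=float)
    if np.any(kappa_x <= 0) or np.any(kappa_y <= 0):
        raise ValueError("concentrations must be positive")
    return np.exp(np.minimum(log_decision_variable(x, y, kappa_x, kappa_y), 500.0))


def log_decision_variable(x, y, kappa_x, kappa_y):
    delta = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    resultant = np.sqrt(kappa_x**2 + kappa_y**2
                        + 2.0 * kappa_x * kappa_y * np.cos(delta))
    return log_i0(kappa_x) + log_i0(kappa_y) - log_i0(resultant)


def apply_perceptual_bias(x_st, y_st, B):
    """Recency-biased initial-ST measurement: interpolate from x toward y by
    weight B along the shortest arc (orientation degrees)."""
    from .circular import circ_interp_ori

    if np.any((np.asarray(B) < 0) | (np.asarray(B) > 1)):
        raise ValueError("B must lie in [0, 1]")
    return circ_interp_ori(x_st, y_st, B)


def _bias_doubled(x, y, B):
    # same interpolation on the doubled circle (radians)
    d = np.mod(y - x + np.pi, 2 * np.pi) - np.pi
    return x + B * d


def decide(F, eta, rng: np.random.Generator | None = None):
    """Response for decision variables F (..., 4): 4 = no change if no
    F_l > η_l, else argmax of F − η. Exact ties broken at random (seeded)."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    margins = F - np.asarray(eta, dtype=float)
    best = np.argmax(margins, axis=1)
    top = margins[np.arange(len(margins)), best]
    resp = np.where(top > 0, best, 4)
    ties = (margins == top[:, None]).sum(axis=1) > 1
    if ties.any():
        rng = rng or np.random.default_rng(0)
        for i in np.flatnonzero(ties & (top > 0)):
            resp[i] = rng.choice(np.flatnonzero(margins[i] == top[i]))
    return resp if resp.shape[0] > 1 else int(resp[0])


@dataclass
class MonteCarloDraws:
    """Fixed uniforms reused across likelihood evaluations (common random
    numbers): gamma quantiles for J and von Mises quantiles for x, y."""

    n_J: int = 1000
    n_xy: int = 4800
    seed: int = 0
    u_J: np.ndarray = field(init=False)
    u_x: np.ndarray = field(init=False)
    u_y: np.ndarray = field(init=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        uj = rng.uniform(size=(self.n_J, 8))
        reps = int(np.ceil(self.n_xy / self.n_J))
        self.u_J = np.tile(uj, (reps, 1))[: self.n_xy]
        self.u_x = rng.uniform(size=(self.n_xy, 4))
        self.u_y = rng.uniform(size=(self.n_xy, 4))


_U_GRID = np.concatenate([[1e-7], np.linspace(5e-4, 1 - 5e-4, 254), [1 - 1e-7]])


def _gamma_ppf_interp(u: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma quantiles via a 256-point monotone interpolation table (keeps the
    per-evaluation cost low while staying smooth in the parameters)."""
    q = stats.gamma.ppf(_U_GRID, a=shape, scale=scale)
    return np.interp(u, _U_GRID, q)


@dataclass
class PredictedResponseTable:
    """Monte-Carlo response probabilities: condensed 3×3 (ST / pooled SA /
    no-change) and expanded symmetric 5×5 rows summing to 1."""

    condensed: np.ndarray
    full: np.ndarray
    n_xy: int
    seed: int


def predict_response_distribution(params: VPChangeParams, delta_theta: float,
                                  n_J: int = 1000, n_xy: int = 4800,
                                  seed: int = 0,
                                  draws: MonteCarloDraws | None = None
                                  ) -> PredictedResponseTable:
    """Predicted response distribution for conditions (change at ST, change at
    an SA location, no change) at change angle ``delta_theta`` (orientation
    degrees)."""
    if draws is None:
        draws = MonteCarloDraws(n_J=n_J, n_xy=n_xy, seed=seed)
    from .vp_estimation import kappa_interp

    sampler = default_vm_sampler()
    tau = params.tau
    shape_lo = params.j_bar / tau
    shape_hi = params.final_st_precision_ratio * params.j_bar / tau
    # per-trial precisions: streams 0..3 initial set, 4..7 final set;
    # one quantile table per distinct gamma shape (final ST is stream 4)
    q_lo = stats.gamma.ppf(_U_GRID, a=shape_lo, scale=tau)
    q_hi = stats.gamma.ppf(_U_GRID, a=shape_hi, scale=tau)
    J = np.empty((draws.n_xy, 8))
    for s in range(8):
        J[:, s] = np.interp(draws.u_J[:, s], _U_GRID,
                            q_hi if s == 4 else q_lo)
    kappa = np.maximum(kappa_interp(J), 1e-3)
    kx, ky = kappa[:, :4], kappa[:, 4:]
    x = sampler.sample(draws.u_x, kx)  # centered on theta_i = 0
    y_noise = sampler.sample(draws.u_y, ky)
    d2 = 2.0 * np.deg2rad(delta_theta)  # doubled-circle change angle

    # only six distinct (location, condition) evidence columns are needed:
    # loc 0 with unshifted/shifted final set (x0 biased toward that y0),
    # loc 1 unshifted/shifted, locs 2-3 unshifted.
    li0 = log_i0(kx) + log_i0(ky)

    def logF_col(loc, y_col, biased):
        x_col = _bias_doubled(x[:, loc], y_col, params.B) if biased \
            else x[:, loc]
        res = np.sqrt(kx[:, loc] ** 2 + ky[:, loc] ** 2
                      + 2.0 * kx[:, loc] * ky[:, loc] * np.cos(y_col - x_col))
        return li0[:, loc] - log_i0(res)

    bias0 = params.B > 0
    f0_plain = logF_col(0, y_noise[:, 0], bias0)
    f0_shift = logF_col(0, y_noise[:, 0] + d2, bias0)
    f1_plain = logF_col(1, y_noise[:, 1], False)
    f1_shift = logF_col(1, y_noise[:, 1] + d2, False)
    f2 = logF_col(2, y_noise[:, 2], False)
    f3 = logF_col(3, y_noise[:, 3], False)

    condensed = np.empty((3, 3))
    full = np.zeros((5, 5))
    for cond, (c0, c1) in enumerate(((f0_shift, f1_plain),
                                     (f0_plain, f1_shift),
                                     (f0_plain, f1_plain))):
        logF = np.column_stack([c0, c1, f2, f3])
        margins = np.exp(np.minimum(logF, 500.0)) - params.eta[None, :]
        best = np.argmax(margins, axis=1)
        top = margins[np.arange(len(margins)), best]
        resp = np.where(top > 0, best, 4)
        p = np.bincount(resp, minlength=5) / len(resp)
        condensed[cond] = [p[0], p[1] + p[2] + p[3], p[4]]
        if cond == 0:
            full[0] = [p[0], p[1], p[2], p[3], p[4]]
        elif cond == 1:
            other = (p[2] + p[3]) / 2.0
            for r in (1, 2, 3):  # symmetric SA rows: hit at r, misloc elsewhere
                row = np.full(5, other)
                row[0], row[r], row[4] = p[0], p[1], p[4]
                full[r] = row
        else:
            full[4] = [p[0], p[1], p[2], p[3], p[4]]
    return PredictedResponseTable(condensed=condensed, full=full,
                                  n_xy=draws.n_xy, seed=draws.seed)


def condense_table(table: ContingencyTable) -> np.ndarray:
    """Collapse a 5×5 contingency table to 3×3 by pooling the SA rows/columns."""
    c = table.counts
    def pool(row):
        return np.array([row[0], row[1] + row[2] + row[3], row[4]])
    return np.vstack([pool(c[0]), pool(c[1] + c[2] + c[3]), pool(c[4])])


def multinomial_ll(counts3: np.ndarray, probs3: np.ndarray) -> float:
    return float(np.sum(counts3 * np.log(np.clip(probs3, 1e-12, 1.0))))


@dataclass
class VPChangeFit:
    variant: str
    params: VPChangeParams
    log_likelihood: float
    aicc: float
    n_trials: int
    boundary_flag: bool = False
    restarted: bool = False


def _theta_to_params(theta, variant, fixed: dict) -> VPChangeParams:
    kw = dict(variant=variant, j_bar=1.0, **fixed)
    for name, z in zip(FREE_PARAMS[variant], theta):
        lo, hi = PARAM_BOUNDS[name]
        if LOG_SCALED[name]:
            kw[name] = float(np.exp(np.log(lo) + z * (np.log(hi) - np.log(lo))))
        else:
            kw[name] = float(lo + z * (hi - lo))
    return VPChangeParams(**kw)


def _pattern_search(objective, x0, mesh0=0.25, contraction=0.5, mesh_tol=1e-3,
                    max_evals=2000):
    """Coordinate generalized pattern search on the unit cube.

    Polls ±mesh along each coordinate, moves to the best improving point,
    otherwise contracts the mesh; stops when the mesh falls below ``mesh_tol``.
    Deterministic given the starting point.
    """
    x = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    fx = objective(x)
    mesh = mesh0
    evals = 1
    while mesh >= mesh_tol and evals < max_evals:
        best_x, best_f = None, fx
        for i in range(len(x)):
            for sign in (+1.0, -1.0):
                cand = x.copy()
                cand[i] = np.clip(cand[i] + sign * mesh, 0.0, 1.0)
                if cand[i] == x[i]:
                    continue
                f = objective(cand)
                evals += 1
                if f < best_f:
                    best_x, best_f = cand, f
        if best_x is None:
            mesh *= contraction
        else:
            x, fx = best_x, best_f
    return x, fx


# deterministic multistart schedule; for the threshold variants the starts
# seed both threshold orderings (eta_st < eta_sa and the reverse) because the
# perceptual and choice biases partially mimic one another at the ST location
_START_POINTS = {
    1: [np.array([0.5]), np.array([0.8])],
    2: [np.array([0.5, 0.3]), np.array([0.8, 0.1])],
    3: [np.array([0.65, 0.49, 0.59]), np.array([0.8, 0.67, 0.67]),
        np.array([0.65, 0.59, 0.49])],
    4: [np.array([0.65, 0.3, 0.49, 0.59]), np.array([0.8, 0.1, 0.67, 0.67]),
        np.array([0.65, 0.5, 0.59, 0.49])],
}
# documented extra initial condition used when a fit lands on the cube boundary
_EXTRA_START = {1: np.array([0.3]), 2: np.array([0.3, 0.6]),
                3: np.array([0.3, 0.4, 0.8]), 4: np.array([0.3, 0.6, 0.4, 0.8])}


def fit_variant(table: ContingencyTable | np.ndarray, variant: str,
                delta_theta: float, final_st_precision_ratio: float = 6.0,
                tau: float = 13.0, n_J: int = 1000, n_xy: int = 4800,
                seed: int = 0, mesh_tol: float = 1e-3) -> VPChangeFit:
    """Multinomial ML fit of one VP variant to a contingency table.

    Deterministic given ``seed``: one fixed set of Monte-Carlo uniforms is
    reused across all parameter evaluations. A fit stuck on a parameter-cube
    boundary is restarted once from the documented extra initial condition.
    """
    counts3 = condense_table(table) if isinstance(table, ContingencyTable) \
        else np.asarray(table, dtype=float)
    draws = MonteCarloDraws(n_J=n_J, n_xy=n_xy, seed=seed)
    fixed = {"final_st_precision_ratio": final_st_precision_ratio, "tau": tau}

    def objective(z):
        p = _theta_to_params(z, variant, fixed)
        pred = predict_response_distribution(p, delta_theta, draws=draws)
        return -multinomial_ll(counts3, pred.condensed)

    k = len(FREE_PARAMS[variant])
    x, fx = None, np.inf
    for x0 in _START_POINTS[k]:
        xi, fi = _pattern_search(objective, x0, mesh_tol=mesh_tol)
        if fi < fx:
            x, fx = xi, fi
    restarted = False
    if np.any((x <= 1e-9) | (x >= 1 - 1e-9)):
        x2, f2 = _pattern_search(objective, _EXTRA_START[k], mesh_tol=mesh_tol)
        restarted = True
        if f2 < fx:
            x, fx = x2, f2
    params = _theta_to_params(x, variant, fixed)
    n = int(counts3.sum())
    return VPChangeFit(variant=variant, params=params, log_likelihood=-fx,
                       aicc=aicc(-fx, k, n), n_trials=n,
                       boundary_flag=bool(np.any((x <= 1e-9) | (x >= 1 - 1e-9))),
                       restarted=restarted)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion −2logL + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def evaluate_variant(params: VPChangeParams, table, delta_theta: float,
                     n_J: int = 1000, n_xy: int = 4800, seed: int = 0) -> float:
    """Multinomial log-likelihood of ``table`` under fixed parameters."""
    counts3 = condense_table(table) if isinstance(table, ContingencyTable) \
        else np.asarray(table, dtype=float)
    pred = predict_response_distribution(params, delta_theta, n_J=n_J,
                                         n_xy=n_xy, seed=seed)
    return multinomial_ll(counts3, pred.condensed)


def cross_validated_likelihood(session_tables, variant: str, delta_theta: float,
                               **fit_kwargs) -> float:
    """Leave-session-out cross-validated log-likelihood.

    For each fold the variant is fitted on the pooled held-in sessions and its
    predicted distribution scored on the held-out session; fold scores sum.
    """
    tables = [t.counts if isinstance(t, ContingencyTable) else np.asarray(t)
              for t in session_tables]
    if len(tables) < 2:
        raise ValueError("cross-validation needs at least 2 sessions")
    if any(t.sum() == 0 for t in tables):
        raise ValueError("a session has zero trials")
    total = 0.0
    for held_out in range(len(tables)):
        train = sum(t for i, t in enumerate(tables) if i != held_out)
        fit = fit_variant(ContingencyTable(train), variant, delta_theta,
                          **fit_kwargs)
        total += evaluate_variant(fit.params, ContingencyTable(tables[held_out]),
                                  delta_theta,
                                  n_J=fit_kwargs.get("n_J", 1000),
                                  n_xy=fit_kwargs.get("n_xy", 4800),
                                  seed=fit_kwargs.get("seed", 0))
    return float(total)


def sample_responses(params: VPChangeParams, signals: np.ndarray,
                     delta_theta: float, rng: np.random.Generator) -> np.ndarray:
    """Generative draws for synthetic observers: one response (0 = ST, 1..3 SA,
    4 = no change) per trial; ``signals`` gives the change location (4 = none)."""
    from .vp_estimation import kappa_interp as kappa_from_J

    signals = np.asarray(signals)
    n = len(signals)
    tau = params.tau
    J = np.empty((n, 8))
    shape_lo = params.j_bar / tau
    shape_hi = params.final_st_precision_ratio * params.j_bar / tau
    for s in range(8):
        J[:, s] = rng.gamma(shape=shape_hi if s == 4 else shape_lo, scale=tau,
                            size=n)
    kappa = np.maximum(kappa_from_J(J), 1e-3)
    kx, ky = kappa[:, :4], kappa[:, 4:]
    x = rng.vonmises(0.0, kx)
    y = rng.vonmises(0.0, ky)
    d2 = 2.0 * np.deg2rad(delta_theta)
    is_change = signals < 4
    y[np.arange(n)[is_change], signals[is_change]] += d2
    if params.B > 0:
        x[:, 0] = _bias_doubled(x[:, 0], y[:, 0], params.B)
    logF = log_decision_variable(x, y, kx, ky)
    margins = np.exp(np.minimum(logF, 500.0)) - params.eta[None, :]
    best = np.argmax(margins, axis=1)
    top = margins[np.arange(n), best]
    return np.where(top > 0, best, 4)
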