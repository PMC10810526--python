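"""Circular helpers for orientation (180°-periodic) and doubled-angle statistics.

Gabor orientations live on [0, 180); all circular statistics double the angles
onto the full 360° circle, operate there, and transform back. Signed
orientation differences live on (−90, 90] with the ±90° tie resolved to +90.
"""

from __future__ import annotations

import numpy as np
from scipy import special

ORI_PERIOD = 180.0


def wrap_orientation(theta):
    """Wrap angles (degrees) into the orientation domain [0, 180)."""
    return np.mod(theta, ORI_PERIOD)


def signed_ori_diff(a, b):
    """Minimal signed difference a − b (degrees) on the orientation circle.

    Returns values in (−90, 90]; an exact 90° separation maps to +90.
    """
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), ORI_PERIOD)
    # d in [0, 180): fold the upper half to negative differences, keep 90 -> +90
    d = np.where(d > 90.0, d - ORI_PERIOD, d)
    return d if d.ndim else float(d)


def circ_interp_ori(x, y, w):
    """Interpolate from orientation x toward y by weight w along the shortest arc.

    w = 0 returns x, w = 1 returns y. At the antipodal tie (|x − y| = 90°) the
    +90 branch of ``signed_ori_diff`` fixes the arc deterministically.
    """
    d = signed_ori_diff(y, x)
    return wrap_orientation(np.asarray(x, dtype=float) + np.asarray(w) * d)


def circ_mean_resultant(angles_deg, period=ORI_PERIOD):
    """(circular mean in degrees, mean resultant length) after doubling to 360°."""
    a = np.asarray(angles_deg, dtype=float) * (2.0 * np.pi / period)
    z = np.exp(1j * a).mean()
    mean = np.angle(z) * (period / (2.0 * np.pi))
    return float(np.mod(mean + period / 2.0, period) - period / 2.0), float(np.abs(z))


def circ_sd(angles_deg, period=ORI_PERIOD):
    """Non-parametric circular standard deviation sqrt(−2 ln R̄), in radians
    of the doubled (360°) circle."""
    _, rbar = circ_mean_resultant(angles_deg, period=period)
    rbar = min(max(rbar, 1e-300), 1.0)
    return float(np.sqrt(max(-2.0 * np.log(rbar), 0.0)))


def log_i0(kappa):
    """log I₀(κ), overflow-safe."""
    kappa = np.asarray(kappa, dtype=float)
    return np.log(special.i0e(kappa)) + kappa


def vm_a(kappa):
    """Mean resultant length A(κ) = I₁(κ)/I₀(κ) of a von Mises distribution."""
    kappa = np.asarray(kappa, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = special.i1e(kappa) / special.i0e(kappa)
    return np.where(kappa == 0.0, 0.0, r)


class VonMisesSampler:
    """Inverse-CDF von Mises sampler on a (log κ, u) interpolation table.

    Mapping fixed uniforms through the inverse CDF keeps draws common across
    parameter values, so Monte-Carlo likelihoods vary smoothly with κ — the
    common-random-numbers device the observer fits rely on.
    """

    def __init__(self, kappa_min=1e-3, kappa_max=2000.0, n_kappa=256, n_angle=2048):
        self.kappa_grid = np.geomspace(kappa_min, kappa_max, n_kappa)
        self._log_kappa = np.log(self.kappa_grid)
        theta = np.linspace(-np.pi, np.pi, n_angle + 1)  # radians, full circle
        mid = 0.5 * (theta[:-1] + theta[1:])
        # CDF of VM(0, kappa) at the grid edges, per kappa row
        logpdf = self.kappa_grid[:, None] * np.cos(mid[None, :]) - (
            np.log(2 * np.pi) + log_i0(self.kappa_grid)[:, None]
        )
        pdf = np.exp(logpdf)
        cdf = np.concatenate(
            [np.zeros((len(self.kappa_grid), 1)), np.cumsum(pdf, axis=1)], axis=1
        ) * (theta[1] - theta[0])
        cdf /= cdf[:, -1:]
        # invert onto a fixed u grid
        self.u_grid = np.linspace(0.0, 1.0, 1025)
        self._inv = np.empty((len(self.kappa_grid), len(self.u_grid)))
        for i in range(len(self.kappa_grid)):
            self._inv[i] = np.interp(self.u_grid, cdf[i], theta)

    def sample(self, u, kappa):
        """VM(0, κ) deviates (radians) for uniforms ``u``; bilinear in (log κ, u)."""
        u = np.asarray(u, dtype=float)
        kappa = np.broadcast_to(np.asarray(kappa, dtype=float), u.shape)
        lk = np.clip(np.log(np.maximum(kappa, self.kappa_grid[0])),
                     self._log_kappa[0], self._log_kappa[-1])
        ik = np.clip(np.searchsorted(self._log_kappa, lk) - 1, 0, len(self.kappa_grid) - 2)
        wk = (lk - self._log_kappa[ik]) / (self._log_kappa[ik + 1] - self._log_kappa[ik])
        iu = np.clip(np.searchsorted(self.u_grid, u) - 1, 0, len(self.u_grid) - 2)
        wu = (u - self.u_grid[iu]) / (self.u_grid[iu + 1] - self.u_grid[iu])
        v00 = self._inv[ik, iu]
        v01 = self._inv[ik, iu + 1]
        v10 = self._inv[ik + 1, iu]
        v11 = self._inv[ik + 1, iu + 1]
        return (1 - wk) * ((1 - wu) * v00 + wu * v01) + wk * ((1 - wu) * v10 + wu * v11)


_SAMPLER: VonMisesSampler | None = None


def default_vm_sampler() -> VonMisesSampler:
    global _SAMPLER
    if _SAMPLER is None:
        _SAMPLER = VonMisesSampler()
    return _SAMPLER
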