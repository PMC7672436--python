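"""Gaussian-process integration of mean-force grids.

The latent free energy f is a GP with an anisotropic product kernel
(squared-exponential per dimension; the wrapped/periodic variant on periodic
dimensions).  The observations are the per-bin mean forces, treated as noisy
derivative observations -df/dx at the bin centers with noise variance
var * g / n.  Hyperparameters maximize the log marginal likelihood with an
analytic gradient; the posterior mean of f on the bin centers is the
integrated surface and the posterior standard deviation of
f(x) - f(x_min) gives the error band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError
from scipy.optimize import minimize

from .grids import GridSpec, MeanForceGrid
from .surface import FESurface, reference_to_min
from ..errors import ConditioningError, ContractError

__all__ = ["GPRModel", "fit_gpr", "integrate_gpr"]

_JITTER_LADDER = (1e-10, 1e-9, 1e-8, 1e-7, 1e-6)


# --------------------------------------------------------------------------
# per-dimension kernel factors and their derivatives

def _factor_se(u, ell):
    """SE factor: k(u)=exp(-u^2/2l^2); returns k, k', k'' and d/dlog(l) of each."""
    r2 = (u / ell) ** 2
    k = np.exp(-0.5 * r2)
    k1 = -(u / ell ** 2) * k
    k2 = (r2 - 1.0) / ell ** 2 * k
    dk = k * r2
    dk1 = k * (u / ell ** 2) * (2.0 - r2)
    dk2 = k * (r2 * r2 - 5.0 * r2 + 2.0) / ell ** 2
    return k, k1, k2, dk, dk1, dk2


def _factor_periodic(u, ell, period):
    """Wrapped kernel factor exp(-(1-cos(2 pi u/P))/l^2) and derivatives."""
    w = 2.0 * np.pi / period
    th = w * u
    c, s = np.cos(th), np.sin(th)
    q = (1.0 - c) / ell ** 2
    k = np.exp(-q)
    k1 = -(w * s / ell ** 2) * k
    k2 = (-(w ** 2) * c / ell ** 2 + (w * s / ell ** 2) ** 2) * k
    dk = 2.0 * q * k
    dk1 = (2.0 * w * s / ell ** 2) * k + k1 * 2.0 * q
    dk2 = (2.0 * (w ** 2) * c / ell ** 2 - 4.0 * (w * s) ** 2 / ell ** 4) * k \
        + k2 * 2.0 * q
    return k, k1, k2, dk, dk1, dk2


def _factors(U, ells, periodic, periods):
    out = []
    for d in range(len(ells)):
        if periodic[d]:
            out.append(_factor_periodic(U[d], ells[d], periods[d]))
        else:
            out.append(_factor_se(U[d], ells[d]))
    return out


def _grad_kernel_blocks(U, ells, periodic, periods, want_grads=True):
    """Unit-signal gradient-gradient kernel and d/dlog(ell_c) blocks.

    Returns (K, [dK_dlog_ell_c ...]) where K has shape (d*m, d*m) with
    component-major block ordering.
    """
    d = len(ells)
    m = U[0].shape[0]
    fac = _factors(U, ells, periodic, periods)
    K = np.empty((d * m, d * m))
    dKs = [np.empty((d * m, d * m)) for _ in range(d)] if want_grads else []
    for a in range(d):
        for b in range(d):
            if a == b:
                rest = np.ones((m, m))
                for c in range(d):
                    if c != a:
                        rest = rest * fac[c][0]
                blk = -fac[a][2] * rest
            else:
                rest = np.ones((m, m))
                for c in range(d):
                    if c not in (a, b):
                        rest = rest * fac[c][0]
                blk = -fac[a][1] * fac[b][1] * rest
            K[a * m:(a + 1) * m, b * m:(b + 1) * m] = blk
            if want_grads:
                for c in range(d):
                    # product-rule derivative of the block w.r.t. log ell_c
                    terms = []
                    for e in range(d):
                        if a == b:
                            part = fac[e][5] if e == a else fac[e][3]
                            base = fac[e][2] if e == a else fac[e][0]
                        else:
                            part = fac[e][4] if e in (a, b) else fac[e][3]
                            base = fac[e][1] if e in (a, b) else fac[e][0]
                        terms.append((part, base))
                    prod = terms[c][0]
                    for e in range(d):
                        if e != c:
                            prod = prod * terms[e][1]
                    dKs[c][a * m:(a + 1) * m, b * m:(b + 1) * m] = -prod
    return K, dKs


def _cross_kernel(Xe, Xo, ells, periodic, periods):
    """Unit-signal cov(f(xe), -grad-obs at xo): shape (ne, d*m)."""
    d = len(ells)
    m = Xo.shape[0]
    ne = Xe.shape[0]
    U = [Xe[:, c][:, None] - Xo[:, c][None, :] for c in range(d)]
    fac = _factors(U, ells, periodic, periods)
    Kc = np.empty((ne, d * m))
    for b in range(d):
        rest = np.ones((ne, m))
        for c in range(d):
            if c != b:
                rest = rest * fac[c][0]
        Kc[:, b * m:(b + 1) * m] = -fac[b][1] * rest
    return Kc


# --------------------------------------------------------------------------

@dataclass
class GPRModel:
    """Fitted derivative-observation GP over a mean-force grid."""

    spec: GridSpec
    obs_idx: np.ndarray          # flat bin indices of observed bins
    X: np.ndarray                # (m, d) observed bin centers
    y: np.ndarray                # (d*m,) stacked gradient observations
    noise: np.ndarray            # (d*m,) per-observation noise variances
    signal_var: float
    length_scales: np.ndarray
    log_marginal_likelihood: float
    jitter: float
    _chol: tuple = field(repr=False, default=None)
    _alpha: np.ndarray = field(repr=False, default=None)

    @property
    def periods(self):
        return np.array(self.spec.maxs) - np.array(self.spec.mins)

    def _diff_mats(self):
        d = self.spec.dims
        U = [self.X[:, c][:, None] - self.X[:, c][None, :] for c in range(d)]
        if any(self.spec.periodic):
            return U
        return U

    def lml_and_grad(self, theta: np.ndarray):
        """Log marginal likelihood and its gradient at theta.

        theta = [log signal_var, log ell_1, ..., log ell_d].
        """
        d = self.spec.dims
        sf2 = float(np.exp(theta[0]))
        ells = np.exp(theta[1:1 + d])
        U = self._diff_mats()
        Ku, dKu = _grad_kernel_blocks(U, ells, self.spec.periodic, self.periods)
        n = Ku.shape[0]
        K = sf2 * Ku + np.diag(self.noise)
        L = None
        for jit in _JITTER_LADDER:
            try:
                L = cholesky(K + jit * sf2 * np.eye(n), lower=True)
                break
            except LinAlgError:
                L = None
        if L is None:
            return -1e12, np.zeros_like(theta)
        alpha = cho_solve((L, True), self.y)
        lml = (-0.5 * self.y @ alpha - np.log(np.diag(L)).sum()
               - 0.5 * n * np.log(2.0 * np.pi))
        Kinv = cho_solve((L, True), np.eye(n))
        W = np.outer(alpha, alpha) - Kinv
        grad = np.empty_like(theta)
        grad[0] = 0.5 * np.sum(W * (sf2 * Ku + jit * sf2 * np.eye(n)))
        for c in range(d):
            grad[1 + c] = 0.5 * np.sum(W * (sf2 * dKu[c]))
        return float(lml), grad

    def refit(self, theta: np.ndarray) -> None:
        """Recompute the Cholesky/alpha cache at the given hyperparameters."""
        d = self.spec.dims
        self.signal_var = float(np.exp(theta[0]))
        self.length_scales = np.exp(theta[1:1 + d])
        U = self._diff_mats()
        Ku, _ = _grad_kernel_blocks(U, self.length_scales, self.spec.periodic,
                                    self.periods, want_grads=False)
        n = Ku.shape[0]
        K = self.signal_var * Ku + np.diag(self.noise)
        for jit in _JITTER_LADDER:
            try:
                L = cholesky(K + jit * self.signal_var * np.eye(n), lower=True)
                self.jitter = jit
                break
            except LinAlgError:
                L = None
        if L is None:
            raise ConditioningError(
                f"covariance not PSD even at jitter {_JITTER_LADDER[-1]:g}")
        self._chol = (L, True)
        self._alpha = cho_solve(self._chol, self.y)
        self.log_marginal_likelihood, _ = self.lml_and_grad(theta)


def fit_gpr(grid: MeanForceGrid, n_restarts: int = 2, maxiter: int = 60,
            noise_floor: float = 1e-10, optimize: bool = True,
            theta0: np.ndarray | None = None,
            min_obs_count: int = 2) -> GPRModel:
    """Fit GP hyperparameters to a mean-force grid by maximizing the LML.

    Observed bins are those with at least ``min_obs_count`` samples (2 are
    needed for a noise estimate; more suppresses unreliable stray bins).
    The optimizer is multi-start L-BFGS-B on (log signal variance, log
    length scales).
    """
    spec = grid.spec
    d = spec.dims
    obs = np.flatnonzero(grid.count >= max(min_obs_count, 2))
    if obs.size < 10:
        raise ContractError("need at least 10 sampled bins to fit a GP")
    centers = grid.centroids().T[obs]
    # gradient of G = minus the mean force
    y = (-grid.mean[:, obs]).reshape(d * obs.size)
    noise = grid.sem2()[:, obs].reshape(d * obs.size)
    noise = np.maximum(noise, noise_floor)

    model = GPRModel(spec=spec, obs_idx=obs, X=centers, y=y, noise=noise,
                     signal_var=1.0, length_scales=np.ones(d),
                     log_marginal_likelihood=-np.inf, jitter=0.0)

    span = np.array(spec.maxs) - np.array(spec.mins)
    ell0 = span / 6.0
    sf2_0 = max(float(np.var(y)) * float(np.mean(ell0 ** 2)), 1e-6)
    if theta0 is None:
        theta0 = np.concatenate([[np.log(sf2_0)], np.log(ell0)])
    lo = np.concatenate([[np.log(sf2_0) - 12.0], np.log(spec.widths * 0.5)])
    hi = np.concatenate([[np.log(sf2_0) + 12.0], np.log(span * 3.0)])
    bounds = list(zip(lo, hi))

    if not optimize:
        model.refit(theta0)
        return model

    starts = [theta0]
    scales = [0.5, 2.0, 4.0, 0.25]
    for i in range(max(0, n_restarts - 1)):
        t = theta0.copy()
        t[1:] += np.log(scales[i % len(scales)])
        starts.append(t)

    best = None
    for t0 in starts:
        res = minimize(lambda t: tuple(-v for v in model.lml_and_grad(t)),
                       np.clip(t0, lo, hi), jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": maxiter})
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res.x)
    model.refit(best[1])
    return model


def integrate_gpr(grid: MeanForceGrid, model: GPRModel,
                  mask_threshold: float = 10.0,
                  stderr_sigmas: float = 3.0) -> FESurface:
    """Posterior mean free energy on the grid, referenced to its minimum.

    The standard error of each bin is ``stderr_sigmas`` times the posterior
    standard deviation of f(x) - f(x_min), so the error vanishes at the
    reference minimum and grows away from it.
    """
    if model._chol is None:
        model.refit(np.concatenate([[np.log(model.signal_var)],
                                    np.log(model.length_scales)]))
    spec = grid.spec
    Xe = spec.center_grid()
    Kc = model.signal_var * _cross_kernel(
        Xe, model.X, model.length_scales, spec.periodic, model.periods)
    mean = Kc @ model._alpha
    mask = grid.n_effective < mask_threshold
    if mask.all():
        raise ContractError("all bins below the sampling threshold")

    V = cho_solve(model._chol, Kc.T)           # (d*m, nb)
    var_self = model.signal_var - np.einsum("ij,ji->i", Kc, V)
    imin = int(np.flatnonzero(~mask)[np.argmin(mean[~mask])])
    # cov(f(x), f(x_min)) given the derivative observations
    u = [Xe[:, c][:, None] - Xe[imin, c][None, None] for c in range(spec.dims)]
    fac = _factors(u, model.length_scales, spec.periodic, model.periods)
    k_xmin = model.signal_var * np.ones(Xe.shape[0])
    for c in range(spec.dims):
        k_xmin = k_xmin * fac[c][0][:, 0]
    cov_with_min = k_xmin - Kc @ V[:, imin]
    var_diff = np.maximum(var_self + var_self[imin] - 2.0 * cov_with_min, 0.0)
    stderr = stderr_sigmas * np.sqrt(var_diff)
    surf = FESurface(spec, mean, stderr, mask)
    return reference_to_min(surf)
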