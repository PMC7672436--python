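"""Statistical inefficiency of correlated sample series."""

from __future__ import annotations

import numpy as np
from statsmodels.tsa.stattools import acf

from ..errors import ContractError

__all__ = ["statistical_inefficiency", "blocking_inefficiency",
           "residual_inefficiency"]


def statistical_inefficiency(series: np.ndarray, method: str = "iact") -> float:
    """Inefficiency g >= 1: the factor reducing the effective sample size.

    ``iact`` integrates the normalized autocorrelation function, truncated at
    its first negative lag (g = 1 + 2 sum rho_t).  ``blocking`` uses the
    Flyvbjerg-Petersen block-averaging estimate as a cross-check.
    A constant series returns 1 by convention.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 4:
        raise ContractError("series too short for inefficiency estimation")
    if np.ptp(x) == 0.0:
        return 1.0
    if method == "blocking":
        return blocking_inefficiency(x)
    if method != "iact":
        raise ContractError(f"unknown method {method!r}")
    nlags = min(x.size // 2, 20000)
    rho = acf(x, nlags=nlags, fft=True)
    s = 0.0
    for t in range(1, len(rho)):
        if rho[t] <= 0.0:
            break
        s += rho[t]
    return max(1.0, 1.0 + 2.0 * s)


def residual_inefficiency(values: np.ndarray, forces: np.ndarray,
                          spec) -> float:
    """Inefficiency of the within-bin force fluctuations of one walker.

    The slowly varying part of an instantaneous-force series follows the
    walker's drift across bins; for the error of per-bin mean forces only
    the residual fluctuation around the bin means is relevant.  Returns the
    largest IACT-based inefficiency over the force components.
    """
    from .grids import accumulate

    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    forces = np.atleast_2d(np.asarray(forces, dtype=float).T).T
    binned = accumulate(values, forces, spec)
    idx = spec.flat_index(values)
    ok = idx >= 0
    res = forces[ok] - binned.mean[:, idx[ok]].T
    return max(statistical_inefficiency(res[:, d])
               for d in range(res.shape[1]))


def blocking_inefficiency(series: np.ndarray, min_blocks: int = 20) -> float:
    """Flyvbjerg-Petersen blocking estimate of the inefficiency."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 4:
        raise ContractError("series too short for blocking analysis")
    var0 = x.var(ddof=1)
    if var0 == 0.0:
        return 1.0
    best = 1.0
    b = 1
    while x.size // (2 * b) >= min_blocks:
        b *= 2
        nb = x.size // b
        means = x[:nb * b].reshape(nb, b).mean(axis=1)
        g = b * means.var(ddof=1) / var0
        best = max(best, g)
    return max(1.0, best)
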