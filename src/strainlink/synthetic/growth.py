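"""Closed-form logistic population growth.

The generative model is the density-dependent ODE

    dN/dt = N * (mu + alpha * N)

whose short-interval linearization is the per-capita growth-rate
regression pcgr = mu + alpha * N_start fitted downstream. Using the
closed form keeps parameter recovery well-posed and cheap.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["grow_population"]


def grow_population(mu: float, alpha: float, n0, dt):
    """Propagate density under dN/dt = N(mu + alpha N) for ``dt`` days.

    Parameters
    ----------
    mu : float
        Intrinsic (low-density) per-capita growth rate, per day.
    alpha : float
        Conspecific interaction coefficient, per day per (cells/mL).
        Negative values give self-limitation with carrying capacity
        K = -mu/alpha; ``alpha == 0`` reduces to pure exponential growth.
    n0 : float or array
        Starting density, cells/mL. Must be > 0.
    dt : float or array
        Elapsed time, days. Must be >= 0.

    Returns
    -------
    float or ndarray
        N(dt), same shape as the broadcast of ``n0`` and ``dt``.
    """
    mu = float(mu)
    alpha = float(alpha)
    n0 = np.asarray(n0, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if not (math.isfinite(mu) and math.isfinite(alpha)):
        raise ValueError("mu and alpha must be finite")
    if not np.all(np.isfinite(n0)) or not np.all(np.isfinite(dt)):
        raise ValueError("n0 and dt must be finite")
    if np.any(n0 <= 0):
        raise ValueError("starting density must be positive")
    if np.any(dt < 0):
        raise ValueError("dt must be non-negative")

    if alpha == 0.0:
        out = n0 * np.exp(mu * dt)
    elif mu == 0.0:
        # dN/dt = alpha N^2  ->  N(t) = n0 / (1 - alpha n0 t)
        denom = 1.0 - alpha * n0 * dt
        if np.any(denom <= 0):
            raise OverflowError("population diverges within dt (mu=0, alpha>0)")
        out = n0 / denom
    else:
        # N(t) = K N0 e^{mu t} / (K + N0 (e^{mu t} - 1)), K = -mu/alpha
        k = -mu / alpha
        growth = np.exp(mu * dt)
        denom = k + n0 * (growth - 1.0)
        if np.any(denom <= 0):
            raise OverflowError("population diverges within dt (positive density dependence)")
        out = k * n0 * growth / denom
    return out if out.ndim else float(out)
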