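"""Exact exponential convolution of piecewise-linear signals.

The workhorse of both the phantom simulator and the kinetic forward model:

    y(t) = integral_0^t c(s) * exp(-k (t - s)) ds

evaluated at every node of the grid carrying ``c``. For a piecewise-linear
``c`` the per-segment integral has a closed form, so the node values are exact
up to floating point; the recursion y[i+1] = E_i y[i] + I_i is run through
``scipy.signal.lfilter`` on uniform grids (O(n), compiled) and a plain loop
otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

__all__ = ["expconv_pl"]

_SMALL_KD = 1e-8


def expconv_pl(t: np.ndarray, c: np.ndarray, k: float) -> np.ndarray:
    """Convolution of piecewise-linear ``c(t)`` with ``exp(-k t)`` on grid ``t``.

    Parameters
    ----------
    t : strictly increasing time grid (s).
    c : signal values at the grid nodes.
    k : nonnegative decay rate (s^-1); ``k = 0`` reduces to the running
        trapezoidal integral of ``c``.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if k < 0:
        raise ValueError(f"rate k must be nonnegative, got {k}")
    dt = np.diff(t)
    kd = k * dt
    E = np.exp(-kd)
    dc = c[1:] - c[:-1]
    # I_i = int_{t_i}^{t_{i+1}} c(s) exp(-k (t_{i+1} - s)) ds, c linear on segment
    I = np.empty_like(dt)
    big = kd > _SMALL_KD
    if np.any(big):
        w0 = (1.0 - E[big]) / k          # int exp(-k (t1 - s)) ds
        I[big] = c[:-1][big] * w0 + dc[big] * (dt[big] - w0) / kd[big]
    if np.any(~big):
        # k*dt -> 0 limit: plain trapezoid of the segment
        sm = ~big
        I[sm] = 0.5 * dt[sm] * (c[:-1][sm] + c[1:][sm])

    y = np.empty_like(c)
    y[0] = 0.0
    if dt.size and np.allclose(dt, dt[0], rtol=1e-10, atol=0.0):
        # uniform grid: y[i+1] = E0 * y[i] + I[i] is a first-order IIR filter
        y[1:] = lfilter([1.0], [1.0, -float(E[0])], I)
    else:
        acc = 0.0
        for i in range(dt.size):
            acc = E[i] * acc + I[i]
            y[i + 1] = acc
    return y
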