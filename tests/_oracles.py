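"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own integration code paths: the
alpha-integral is evaluated with dense trapezoid quadrature and the
kernel discretisation is recomputed from first principles (per-axis
normal CDF differences over cell edges).
"""

import math

import numpy as np
from scipy.special import ndtr


def brute_force_bb_2d(steps, grid, sigma2=0.14, n_nodes=10_001):
    """Trapezoid integration of the Brownian-bridge alpha-mixture.

    Same variance floor (cell^2/12) as the model definition, but no
    kernel truncation and dense alpha nodes.
    """
    xe = grid.origin[0] + np.arange(grid.shape[0] + 1) * grid.cell
    ye = grid.origin[1] + np.arange(grid.shape[1] + 1) * grid.cell
    mass = np.zeros(grid.shape)
    floor = grid.cell**2 / 12.0
    a = np.linspace(0.0, 1.0, n_nodes)
    w = np.full(n_nodes, 1.0 / (n_nodes - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    for _, s in steps.iterrows():
        dt = float(s["dt"])
        for aj, wj in zip(a, w):
            mux = (1 - aj) * s["x0"] + aj * s["x1"]
            muy = (1 - aj) * s["y0"] + aj * s["y1"]
            sd = math.sqrt(max(aj * (1 - aj) * dt * sigma2, floor))
            gx = np.diff(ndtr((xe - mux) / sd))
            gy = np.diff(ndtr((ye - muy) / sd))
            mass += dt * wj * np.outer(gx, gy)
    return mass / mass.sum()


def km_by_ecdf(durations):
    """1 - empirical CDF at each distinct time (valid with no censoring)."""
    durations = np.sort(np.asarray(durations, dtype=float))
    times = np.unique(durations)
    n = len(durations)
    return times, 1.0 - np.searchsorted(durations, times, side="right") / n


def ols_line(x, y):
    """Closed-form normal-equation least squares (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    return slope, y.mean() - slope * x.mean()
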