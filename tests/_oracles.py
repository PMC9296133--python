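"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the FRAP oracle is an
exhaustive grid search over (A, tau) rather than a gradient-based fit.
"""

import numpy as np

# the A grid spans the fit bounds; the tau grid spans the same five decades
# the fitter multistarts over
A_GRID = np.linspace(0.0, 1.5, 200)
TAU_GRID = np.logspace(-4, 1, 200)


def grid_search_frap(t, y, a_grid=A_GRID, tau_grid=TAU_GRID):
    """Exhaustive least-squares over a parameter grid.

    Returns (a_best, tau_best, rss_best).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    decay = 1.0 - np.exp(-np.outer(tau_grid, t))          # (Ntau, T)
    pred = a_grid[:, None, None] * decay[None, :, :]      # (Na, Ntau, T)
    rss = ((pred - y[None, None, :]) ** 2).sum(axis=-1)
    i, j = np.unravel_index(int(rss.argmin()), rss.shape)
    return float(a_grid[i]), float(tau_grid[j]), float(rss[i, j])
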