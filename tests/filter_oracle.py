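"""Brute-force discretised forward filter, independent of the package.

Implements the fixed-volatility reduction of the reward-probability
filter with explicit transition-matrix enumeration and plain Python
loops, for cross-checking the package's vectorised implementation.
"""

import numpy as np
from scipy.stats import beta as beta_dist


def transition_matrix(r_grid, step_var):
    """T[s, r] = p(r' = r_grid[s] | r = r_grid[r]), column-normalised."""
    n = len(r_grid)
    T = np.zeros((n, n))
    for j in range(n):
        m = r_grid[j]
        cap = m * (1.0 - m)
        var = min(step_var, 0.9 * cap)
        nu = cap / var - 1.0
        a, b = m * nu, (1.0 - m) * nu
        for i in range(n):
            T[i, j] = beta_dist.pdf(r_grid[i], a, b)
        T[:, j] /= T[:, j].sum()
    return T


def forward_filter(r_grid, step_var, outcomes):
    """Posterior-mean trajectory of a Bernoulli HMM on the r grid.

    Returns the pre-outcome E[r] before each observation, starting from
    a uniform prior, with a predict step before every update.
    """
    n = len(r_grid)
    T = transition_matrix(r_grid, step_var)
    p = np.full(n, 1.0 / n)
    means = []
    for o in outcomes:
        means.append(float(np.dot(p, r_grid)))
        p = T @ p
        lik = r_grid if o == 1 else 1.0 - r_grid
        p = p * lik
        p = p / p.sum()
    return np.array(means), p


def predict_only(r_grid, step_var, p):
    T = transition_matrix(r_grid, step_var)
    q = T @ p
    return q / q.sum()
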