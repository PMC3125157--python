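"""Grid-based Bayesian filtering of drifting reward probabilities.

Each bandit option pays off with a reward probability that follows a
beta-distributed random walk whose step variance is itself allowed to
drift.  The learner tracks, per option, a joint posterior over

* ``r`` — the option's current reward probability,
* ``v`` — the log step-variance of the probability walk (the volatility),
* ``k`` — the standard deviation of the random walk followed by ``v``
  in log space (how quickly the volatility itself can change).

One filter step per trial and option consists of (a) pushing the joint
density through the transition kernels (a beta kernel in ``r`` whose
variance is set by ``v``, and a Gaussian kernel in ``v`` whose scale is
set by ``k``), (b) multiplying in the Bernoulli likelihood of that
option's observed outcome, and (c) renormalising.  Options are
statistically independent, so each carries its own joint density.

Two learner variants are exposed through :func:`run_learner`:

``optimal``
    updates every option with its revealed outcome on every trial
    (the task reveals all three outcomes eventually on each trial);
``experiential``
    updates only the options the agent actually chose; the beliefs
    about unchosen options still diffuse (:func:`propagate_without_observation`)
    but receive no likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import stats

__all__ = [
    "GridSpec",
    "BeliefState",
    "ProbabilityEstimates",
    "init_belief",
    "update_belief",
    "propagate_without_observation",
    "run_learner",
]

#: safety factor applied when a requested beta variance is infeasible for
#: its mean; keeps both beta shape parameters strictly positive
_VAR_CLIP = 0.9


@dataclass(frozen=True)
class GridSpec:
    """Discretisation of the (r, v, k) space.

    Parameters
    ----------
    r_points : int
        Number of grid points for the reward probability ``r``; points are
        bin midpoints of an even partition of ``r_range``.
    v_points : int
        Number of grid points for the log step-variance ``v``, evenly
        spaced on ``log_var_range``.
    k_points : int
        Number of grid points for the volatility-trend scale ``k``, evenly
        spaced in log space on ``log_k_range``.
    n_options : int
        Number of independent options tracked side by side.

    A single-point ``v`` (and ``k``) grid is supported and reduces the
    filter to a fixed-volatility forward filter on the ``r`` grid.
    """

    r_points: int = 50
    v_points: int = 30
    k_points: int = 15
    r_range: tuple[float, float] = (0.01, 0.99)
    log_var_range: tuple[float, float] = (math.log(5e-5), math.log(5e-2))
    log_k_range: tuple[float, float] = (math.log(0.02), math.log(2.0))
    n_options: int = 3

    def __post_init__(self) -> None:
        if self.r_points < 2:
            raise ValueError("r_points must be >= 2")
        if self.v_points < 1 or self.k_points < 1:
            raise ValueError("v_points and k_points must be >= 1")
        if self.n_options < 1:
            raise ValueError("n_options must be >= 1")
        lo, hi = self.r_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("r_range must lie strictly inside (0, 1)")

    @property
    def r_grid(self) -> np.ndarray:
        # midpoints of an even partition of a fixed interior support, so
        # refining the grid does not move the boundary bins toward 0/1
        lo, hi = self.r_range
        n = self.r_points
        return lo + (np.arange(n) + 0.5) * (hi - lo) / n

    @property
    def v_grid(self) -> np.ndarray:
        return np.linspace(*self.log_var_range, self.v_points)

    @property
    def k_grid(self) -> np.ndarray:
        lo, hi = self.log_k_range
        return np.exp(np.linspace(lo, hi, self.k_points))


def _beta_ab(mean: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape parameters of a beta distribution from mean/variance.

    Variances at or above the feasible maximum ``mean * (1 - mean)`` are
    clipped to ``_VAR_CLIP`` times that maximum.
    """
    mean = np.asarray(mean, dtype=float)
    cap = mean * (1.0 - mean)
    var = np.minimum(np.asarray(var, dtype=float), _VAR_CLIP * cap)
    nu = cap / var - 1.0
    return mean * nu, (1.0 - mean) * nu


class _Kernels:
    """Precomputed, column-normalised transition tensors for one grid."""

    def __init__(self, grid: GridSpec):
        r = grid.r_grid
        v = grid.v_grid
        k = grid.k_grid
        nr, nv, nk = grid.r_points, grid.v_points, grid.k_points

        # T_r[s, r, w] = p(r' = r_s | r = r_r, variance exp(v_w))
        mean = r[None, :, None]
        var = np.exp(v)[None, None, :]
        a, b = _beta_ab(np.broadcast_to(mean, (1, nr, nv)),
                        np.broadcast_to(var, (1, nr, nv)))
        t_r = stats.beta.pdf(r[:, None, None], a, b)
        t_r /= t_r.sum(axis=0, keepdims=True)

        # T_v[w, v, k] = p(v' = v_w | v = v_v, scale k_k); degenerate
        # one-point grids get the identity kernel.
        if nv == 1:
            t_v = np.ones((1, 1, nk))
        else:
            t_v = stats.norm.pdf(v[:, None, None], v[None, :, None],
                                 k[None, None, :])
            t_v /= t_v.sum(axis=0, keepdims=True)

        self.t_r = np.ascontiguousarray(t_r)
        # (k, v, w) layout for the batched matmul in _diffuse
        self.t_v_kvw = np.ascontiguousarray(t_v.transpose(2, 1, 0))
        # (w, s, r) layout
        self.t_r_wsr = np.ascontiguousarray(t_r.transpose(2, 0, 1))
        self.grid = grid


_KERNEL_CACHE: dict[GridSpec, _Kernels] = {}


def _kernels(grid: GridSpec) -> _Kernels:
    kern = _KERNEL_CACHE.get(grid)
    if kern is None:
        kern = _KERNEL_CACHE[grid] = _Kernels(grid)
    return kern


@dataclass
class BeliefState:
    """Joint posterior densities over the (r, v, k) grid, one per option.

    ``density`` has shape ``(n_options, r_points, v_points, k_points)`` and
    each option's slice sums to 1.
    """

    grid: GridSpec
    density: np.ndarray
    trial_index: int = 0

    def copy(self) -> "BeliefState":
        return BeliefState(self.grid, self.density.copy(), self.trial_index)

    def expected_probability(self) -> np.ndarray:
        """Posterior mean reward probability E[r], one value per option."""
        r = self.grid.r_grid
        return np.einsum("orvk,r->o", self.density, r)

    def r_marginal(self) -> np.ndarray:
        """Marginal posterior over r, shape (n_options, r_points)."""
        return self.density.sum(axis=(2, 3))

    def r_variance(self) -> np.ndarray:
        r = self.grid.r_grid
        m = self.expected_probability()
        return np.einsum("orvk,r->o", self.density, r**2) - m**2


@dataclass
class ProbabilityEstimates:
    """Pre-outcome expected reward probabilities, trials x options.

    Row ``i`` is the learner's estimate *before* any of trial ``i``'s
    outcomes are seen, so it depends only on feedback from trials < i.
    """

    p_hat: np.ndarray
    variant: str = "optimal"

    @property
    def n_trials(self) -> int:
        return self.p_hat.shape[0]

    def to_frame(self):
        import pandas as pd

        n, m = self.p_hat.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(np.arange(1, n + 1), m),
                "option": np.tile(np.arange(1, m + 1), n),
                "p_hat": self.p_hat.ravel(),
            }
        )


def init_belief(grid: GridSpec) -> BeliefState:
    """Uniform joint prior on the grid for every option.

    The r grid is symmetric about 0.5, so the prior mean of ``r`` is
    exactly 0.5.
    """
    n_cells = grid.r_points * grid.v_points * grid.k_points
    density = np.full(
        (grid.n_options, grid.r_points, grid.v_points, grid.k_points),
        1.0 / n_cells,
    )
    return BeliefState(grid, density, trial_index=0)


def _diffuse(density: np.ndarray, kern: _Kernels) -> np.ndarray:
    """One transition (predict) step for a stack of option densities."""
    b, nr, nv, nk = density.shape
    # volatility walk: contract v -> w for each k
    d2 = density.transpose(3, 0, 1, 2).reshape(nk, b * nr, nv)
    e = d2 @ kern.t_v_kvw  # (nk, b*nr, nw)
    e = e.reshape(nk, b, nr, nv).transpose(1, 2, 3, 0)  # (b, r, w, k)
    # probability walk: contract r -> s for each w
    e2 = e.transpose(2, 1, 0, 3).reshape(nv, nr, b * nk)
    f = kern.t_r_wsr @ e2  # (nw, s, b*nk)
    f = f.reshape(nv, nr, b, nk).transpose(2, 1, 0, 3)  # (b, s, w, k)
    return np.ascontiguousarray(f)


def _apply_likelihood(density: np.ndarray, r_grid: np.ndarray,
                      outcome: int) -> np.ndarray:
    lik = r_grid if outcome == 1 else 1.0 - r_grid
    out = density * lik[None, :, None, None]
    out /= out.sum(axis=(1, 2, 3), keepdims=True)
    return out


def update_belief(belief: BeliefState, option: int, outcome: int) -> BeliefState:
    """One predict-and-update filter step for a single option.

    Diffuses that option's joint density one trial forward and multiplies
    in the Bernoulli likelihood of ``outcome`` (0 or 1).  Other options'
    densities are untouched.  Returns a new :class:`BeliefState`.
    """
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    kern = _kernels(belief.grid)
    density = belief.density.copy()
    d = _diffuse(density[option:option + 1], kern)
    density[option:option + 1] = _apply_likelihood(d, belief.grid.r_grid,
                                                   outcome)
    return BeliefState(belief.grid, density, belief.trial_index)


def propagate_without_observation(belief: BeliefState, option: int) -> BeliefState:
    """Predict-only step: diffusion without likelihood, renormalised."""
    kern = _kernels(belief.grid)
    density = belief.density.copy()
    d = _diffuse(density[option:option + 1], kern)
    d /= d.sum(axis=(1, 2, 3), keepdims=True)
    density[option:option + 1] = d
    return BeliefState(belief.grid, density, belief.trial_index)


def _step_all(density: np.ndarray, kern: _Kernels, outcomes, observed) -> np.ndarray:
    """In-place style trial step for all options at once (fast path).

    ``outcomes`` is a length-n_options integer array; ``observed`` a boolean
    mask saying which options receive their likelihood.
    """
    d = _diffuse(density, kern)
    r = kern.grid.r_grid
    lik = np.where(observed[:, None],
                   np.where(outcomes[:, None] == 1, r[None, :], 1 - r[None, :]),
                   1.0)
    d *= lik[:, :, None, None]
    d /= d.sum(axis=(1, 2, 3), keepdims=True)
    return d


def run_learner(session, variant: str = "optimal",
                grid: GridSpec | None = None) -> ProbabilityEstimates:
    """Filter a whole session and emit pre-outcome probability estimates.

    Parameters
    ----------
    session : pandas.DataFrame
        Completed session table (see :mod:`cfbandit.task`); must contain
        ``outcome_1..3``, ``first_choice``, ``condition`` and (for
        conditions 2-3) ``second_choice``.
    variant : {"optimal", "experiential"}
        ``optimal`` feeds every option's revealed outcome to the filter;
        ``experiential`` feeds only the outcomes of options the agent
        chose (first choice always, second choice in conditions 2-3) and
        lets the other beliefs diffuse unobserved.
    grid : GridSpec, optional
        Discretisation; defaults to :class:`GridSpec` defaults.

    Returns
    -------
    ProbabilityEstimates
        ``p_hat[i, s]`` is E[r] for option ``s`` before trial ``i``'s
        outcomes.
    """
    if variant not in ("optimal", "experiential"):
        raise ValueError(f"unknown learner variant {variant!r}")
    if grid is None:
        grid = GridSpec()
    kern = _kernels(grid)

    n_trials = len(session)
    conditions = np.asarray(session["condition"], dtype=int)
    first_choice = np.asarray(session["first_choice"], dtype=int)
    outcomes = np.column_stack(
        [np.asarray(session[f"outcome_{s}"]) for s in range(1, grid.n_options + 1)]
    )
    if np.any(~np.isin(outcomes, (0, 1))):
        bad = int(np.where(np.any(~np.isin(outcomes, (0, 1)), axis=1))[0][0])
        raise ValueError(f"missing or invalid outcome on trial {bad + 1}")
    outcomes = outcomes.astype(int)
    second_choice = session["second_choice"] if "second_choice" in session else None

    density = init_belief(grid).density
    p_hat = np.empty((n_trials, grid.n_options))
    r = grid.r_grid
    for i in range(n_trials):
        p_hat[i] = np.einsum("orvk,r->o", density, r)
        if variant == "optimal":
            observed = np.ones(grid.n_options, dtype=bool)
        else:
            observed = np.zeros(grid.n_options, dtype=bool)
            observed[first_choice[i] - 1] = True
            if conditions[i] in (2, 3):
                sc = second_choice.iloc[i]
                if sc is None or (isinstance(sc, float) and np.isnan(sc)):
                    raise ValueError(f"missing second choice on trial {i + 1}")
                observed[int(sc) - 1] = True
        density = _step_all(density, kern, outcomes[i], observed)
    return ProbabilityEstimates(p_hat=p_hat, variant=variant)
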