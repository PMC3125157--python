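"""Per-participant maximum-likelihood fitting and BIC model comparison.

The model zoo couples one of four learning rules to the three-parameter
softmax choice model of :mod:`cfbandit.choice`:

================  ===============================================  ==
name              probability estimates                            k
================  ===============================================  ==
optimal_bayes     Bayesian filter updating every option             3
experiential_bayes Bayesian filter updating chosen options only     3
rw_single         delta rule, one learning rate                     4
rw_dual           delta rule, separate chosen/unchosen rates        5
================  ===============================================  ==

``k`` counts free parameters (beta, lambda, gamma plus any learning
rates).  Fitting follows the statsmodels idiom: build a
:class:`SoftmaxChoiceModel` from a session table, call
:meth:`~SoftmaxChoiceModel.fit`, inspect the returned
:class:`SoftmaxChoiceResults` (params, llf, bic, summary()).  BIC uses
n = 180, the number of first-decision trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .choice import ChoiceParams, _second_decision_arrays, subjective_values
from .learner import GridSpec, ProbabilityEstimates, run_learner

__all__ = [
    "RWParams",
    "rescorla_wagner_estimates",
    "compute_bic",
    "SoftmaxChoiceModel",
    "SoftmaxChoiceResults",
    "fit_participant",
    "compare_models",
    "MODEL_NAMES",
]

MODEL_NAMES = ("optimal_bayes", "experiential_bayes", "rw_single", "rw_dual")
_N_PARAMS = {"optimal_bayes": 3, "experiential_bayes": 3,
             "rw_single": 4, "rw_dual": 5}
WEIGHT_BOUNDS = (-50.0, 50.0)
RATE_BOUNDS = (0.0, 1.0)
#: BIC sample size: number of first-decision trials
BIC_N = 180


@dataclass(frozen=True)
class RWParams:
    """Delta-rule learning rates; the single-rate variant ties them."""

    alpha_chosen: float
    alpha_unchosen: float
    initial_estimate: float = 0.5

    def __post_init__(self):
        for a in (self.alpha_chosen, self.alpha_unchosen):
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"learning rate {a} outside [0, 1]")


def rescorla_wagner_estimates(session, params: RWParams) -> ProbabilityEstimates:
    """Pre-outcome delta-rule estimates for every option and trial.

    Each revealed outcome updates its option's estimate by
    ``p += alpha * (outcome - p)``, with ``alpha_chosen`` for options the
    agent chose at either decision phase of the trial and
    ``alpha_unchosen`` for the others.  Row ``i`` of the result is the
    state before trial ``i``'s updates.
    """
    outcomes = np.column_stack(
        [session[f"outcome_{s}"] for s in (1, 2, 3)]).astype(float)
    chosen = _chosen_mask(session)
    alphas = np.where(chosen, params.alpha_chosen, params.alpha_unchosen)
    p_hat = _rw_recursion(outcomes, alphas, params.initial_estimate)
    return ProbabilityEstimates(p_hat=p_hat, variant="rescorla_wagner")


def _rw_recursion(outcomes: np.ndarray, alphas: np.ndarray,
                  p0: float) -> np.ndarray:
    """Pre-outcome states of ``p <- p + alpha * (outcome - p)``.

    Solved in closed form via cumulative products of (1 - alpha) when the
    retention factors are safely away from zero, else by direct
    iteration (large rates make the products underflow).
    """
    n = outcomes.shape[0]
    p_hat = np.empty_like(outcomes)
    retain = 1.0 - alphas
    if retain.min() < 0.05:
        est = np.full(outcomes.shape[1], p0)
        for i in range(n):
            p_hat[i] = est
            est = est + alphas[i] * (outcomes[i] - est)
        return p_hat
    cum = np.cumprod(retain, axis=0)           # A_i = prod_{j<=i} (1-a_j)
    drive = np.cumsum(alphas * outcomes / cum, axis=0)
    p_hat[0] = p0
    p_hat[1:] = cum[:-1] * (p0 + drive[:-1])
    return p_hat


def _chosen_mask(session) -> np.ndarray:
    """(n, 3) mask of options chosen at either phase of each trial."""
    n = len(session)
    fc = np.asarray(session["first_choice"], dtype=int)
    mask = np.zeros((n, 3), dtype=bool)
    mask[np.arange(n), fc - 1] = True
    if "second_choice" in session:
        sc = np.asarray(session["second_choice"], dtype=float)
        has = ~np.isnan(sc)
        mask[np.flatnonzero(has), sc[has].astype(int) - 1] = True
    return mask


def compute_bic(logL: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, -2 logL + k ln n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * logL + k * np.log(n)


class _LikelihoodData:
    """Session quantities hoisted out of the likelihood inner loop."""

    def __init__(self, session, include_second: bool, cond3_magnitude: int):
        self.n = len(session)
        self.mags = np.column_stack(
            [session[f"mag_{s}"] for s in (1, 2, 3)]).astype(float)
        self.fc = np.asarray(session["first_choice"], dtype=int)
        self.include_second = include_second
        if include_second:
            (self.rows, self.opts, self.mags2,
             self.chosen_col) = _second_decision_arrays(session, cond3_magnitude)
        self.n_first = self.n
        self.n_second = len(self.rows) if include_second else 0

    def loglike(self, p_hat: np.ndarray, params: ChoiceParams) -> float:
        v1 = subjective_values(p_hat, self.mags, params)
        ll = float(np.sum(v1[np.arange(self.n), self.fc - 1]
                          - logsumexp(v1, axis=1)))
        if self.include_second:
            p2 = np.take_along_axis(p_hat[self.rows], self.opts - 1, axis=1)
            v2 = subjective_values(p2, self.mags2, params)
            ll += float(np.sum(v2[np.arange(len(self.rows)), self.chosen_col]
                               - logsumexp(v2, axis=1)))
        return ll

    @property
    def chance_loglike(self) -> float:
        return self.n_first * np.log(1 / 3) + self.n_second * np.log(1 / 2)


class SoftmaxChoiceModel:
    """Softmax subjective-value choice model for one participant's session.

    Parameters
    ----------
    session : pandas.DataFrame
        Completed session table (choices and all outcomes present).
    model : str
        One of ``MODEL_NAMES``; selects the learning rule that produces
        the reward-probability estimates entering the subjective values.
    grid : GridSpec, optional
        Discretisation for the Bayesian learners.
    estimates : ProbabilityEstimates, optional
        Precomputed estimates for the Bayesian models (skips re-running
        the filter; ignored for delta-rule models, whose estimates depend
        on the fitted rates).
    include_second : bool
        Whether second-decision choices enter the likelihood (default
        True; BIC's n is unaffected).
    """

    def __init__(self, session, model: str = "optimal_bayes",
                 grid: GridSpec | None = None,
                 estimates: ProbabilityEstimates | None = None,
                 include_second: bool = True, cond3_magnitude: int = 50):
        if model not in MODEL_NAMES:
            raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
        self.session = session
        self.model_name = model
        self.grid = grid
        self.k = _N_PARAMS[model]
        self._data = _LikelihoodData(session, include_second, cond3_magnitude)
        self._bayes = model in ("optimal_bayes", "experiential_bayes")
        if self._bayes:
            if estimates is None:
                variant = "optimal" if model == "optimal_bayes" else "experiential"
                estimates = run_learner(session, variant=variant, grid=grid)
            self._estimates = estimates
        else:
            self._estimates = None
            self._rw_outcomes = np.column_stack(
                [session[f"outcome_{s}"] for s in (1, 2, 3)]).astype(float)
            self._rw_alpha_sel = np.where(_chosen_mask(session), 0, 1)
        self.param_names = (["beta", "lambda", "gamma"]
                            + {3: [], 4: ["alpha"],
                               5: ["alpha_chosen", "alpha_unchosen"]}[self.k])

    # -- likelihood ---------------------------------------------------
    def _p_hat(self, theta: np.ndarray) -> np.ndarray:
        if self._bayes:
            return self._estimates.p_hat
        rates = ((theta[3], theta[3]) if self.k == 4
                 else (theta[3], theta[4]))
        alphas = np.asarray(rates)[self._rw_alpha_sel]
        return _rw_recursion(self._rw_outcomes, alphas, 0.5)

    def loglike(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        params = ChoiceParams(*theta[:3])
        return self._data.loglike(self._p_hat(theta), params)

    # -- fitting ------------------------------------------------------
    def fit(self, n_restarts: int = 10, seed: int = 0,
            maxfev: int = 4000) -> "SoftmaxChoiceResults":
        """Maximise the likelihood by multi-restart Nelder-Mead.

        Restart starting points are drawn from a seeded generator
        (weights uniform on [-8, 8], rates uniform on [0.05, 0.95]);
        weights are box-constrained to [-50, 50] and rates to [0, 1].
        Raises ``RuntimeError`` if no restart converges.
        """
        rng = np.random.default_rng(seed)
        bounds = [WEIGHT_BOUNDS] * 3 + [RATE_BOUNDS] * (self.k - 3)

        def objective(theta):
            return -self.loglike(theta)

        best = None
        n_ok = 0
        for _ in range(n_restarts):
            x0 = np.concatenate([rng.uniform(-8, 8, size=3),
                                 rng.uniform(0.05, 0.95, size=self.k - 3)])
            res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                    bounds=bounds,
                                    options={"maxfev": maxfev,
                                             "xatol": 1e-5, "fatol": 1e-7})
            n_ok += bool(res.success)
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(
                f"all {n_restarts} restarts failed to converge for model "
                f"{self.model_name}")
        llf = -float(best.fun)
        return SoftmaxChoiceResults(
            model=self, params=pd.Series(best.x, index=self.param_names),
            llf=llf, n_restarts=n_restarts, n_converged=n_ok,
            converged=True)


class SoftmaxChoiceResults:
    """Fit results: parameter estimates, likelihood, BIC, uncertainties.

    Attributes mirror statsmodels results where sensible: ``params``
    (pandas Series), ``llf``, ``bic``, ``bse`` (numerical-Hessian
    standard errors, NaN where the Hessian is not positive definite at
    the optimum, e.g. on a bound).
    """

    def __init__(self, model: SoftmaxChoiceModel, params: pd.Series,
                 llf: float, n_restarts: int, n_converged: int,
                 converged: bool):
        self.model = model
        self.model_name = model.model_name
        self.params = params
        self.llf = llf
        self.k = model.k
        self.nobs = BIC_N
        self.bic = compute_bic(llf, self.k, self.nobs)
        self.n_restarts = n_restarts
        self.n_converged = n_converged
        self.converged = converged
        self.n_first = model._data.n_first
        self.n_second = model._data.n_second
        self._bse = None

    @property
    def log_likelihood(self) -> float:
        return self.llf

    @property
    def chance_llf(self) -> float:
        return float(self.model._data.chance_loglike)

    @property
    def bse(self) -> pd.Series:
        """Standard errors from the inverse numerical Hessian of -logL."""
        if self._bse is None:
            from statsmodels.tools.numdiff import approx_hess1

            theta = self.params.to_numpy()
            hess = approx_hess1(theta, lambda t: -self.model.loglike(t))
            se = np.full(self.k, np.nan)
            try:
                cov = np.linalg.inv(hess)
                diag = np.diag(cov)
                se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
            except np.linalg.LinAlgError:
                pass
            self._bse = pd.Series(se, index=self.params.index)
        return self._bse

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "params": self.params.to_dict(),
            "log_likelihood": self.llf,
            "k": self.k,
            "n": self.nobs,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            "Softmax choice model fit",
            "=" * 46,
            f"model:          {self.model_name}",
            f"log-likelihood: {self.llf:.2f}",
            f"BIC (n={self.nobs}):   {self.bic:.1f}",
            f"decisions:      {self.n_first} first + {self.n_second} second",
            f"restarts:       {self.n_converged}/{self.n_restarts} converged",
            "-" * 46,
            f"{'param':<16}{'estimate':>12}{'std err':>12}",
        ]
        bse = self.bse
        for name in self.params.index:
            lines.append(f"{name:<16}{self.params[name]:>12.4f}"
                         f"{bse[name]:>12.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)


def fit_participant(session, model_name: str, n_restarts: int = 10,
                    seed: int = 0, grid: GridSpec | None = None,
                    estimates: ProbabilityEstimates | None = None,
                    include_second: bool = True) -> SoftmaxChoiceResults:
    """Fit one model to one participant's session (convenience wrapper)."""
    model = SoftmaxChoiceModel(session, model=model_name, grid=grid,
                               estimates=estimates,
                               include_second=include_second)
    return model.fit(n_restarts=n_restarts, seed=seed)


def fit_cohort(sessions, model_names=("optimal_bayes", "experiential_bayes"),
               n_restarts: int = 10, seed: int = 0,
               grid: GridSpec | None = None) -> dict[str, list[SoftmaxChoiceResults]]:
    """Fit several models to every session of a cohort.

    Runs each Bayesian learner variant once per session and shares the
    estimates across the fits that need them.  Returns the mapping
    expected by :func:`compare_models`.
    """
    rng = np.random.default_rng(seed)
    fits: dict[str, list[SoftmaxChoiceResults]] = {m: [] for m in model_names}
    for session in sessions:
        fit_seed = int(rng.integers(2**31))
        cache = {}
        for name in model_names:
            est = None
            if name in ("optimal_bayes", "experiential_bayes"):
                variant = "optimal" if name == "optimal_bayes" else "experiential"
                if variant not in cache:
                    cache[variant] = run_learner(session, variant=variant,
                                                 grid=grid)
                est = cache[variant]
            fits[name].append(fit_participant(
                session, name, n_restarts=n_restarts, seed=fit_seed,
                grid=grid, estimates=est))
    return fits


def compare_models(fits: dict[str, list[SoftmaxChoiceResults]]) -> "ModelComparison":
    """Group-level model comparison across participants.

    ``fits`` maps model name to a list of per-participant results, all
    over the same participants in the same order.  Returns a
    :class:`ModelComparison` with group-summed log-likelihood and BIC per
    model (plus a ``chance`` baseline with k = 0) and the per-participant
    counterfactual learning index
    ``llf(optimal_bayes) - llf(experiential_bayes)``.
    """
    sizes = {name: len(res) for name, res in fits.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"participant sets differ across models: {sizes}")
    n_participants = next(iter(sizes.values()))

    rows = []
    for name, results in fits.items():
        llf = sum(r.llf for r in results)
        k = results[0].k
        bic = sum(r.bic for r in results)
        rows.append({"model": name, "k": k, "log_likelihood": llf,
                     "bic": bic})
    any_model = next(iter(fits.values()))
    chance = sum(r.chance_llf for r in any_model)
    rows.append({"model": "chance", "k": 0, "log_likelihood": chance,
                 "bic": sum(compute_bic(r.chance_llf, 0, r.nobs)
                            for r in any_model)})
    table = (pd.DataFrame(rows).sort_values("bic").reset_index(drop=True))
    table["rank"] = np.arange(1, len(table) + 1)

    index = None
    if "optimal_bayes" in fits and "experiential_bayes" in fits:
        index = np.array([o.llf - e.llf
                          for o, e in zip(fits["optimal_bayes"],
                                          fits["experiential_bayes"])])
    return ModelComparison(table=table,
                           counterfactual_learning_index=index,
                           n_participants=n_participants)


@dataclass
class ModelComparison:
    """Comparison table (ranked by group BIC, lower is better) plus the
    per-participant counterfactual learning index."""

    table: pd.DataFrame
    counterfactual_learning_index: np.ndarray | None
    n_participants: int

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model"])

    def summary(self) -> str:
        out = [f"Model comparison over {self.n_participants} participants",
               self.table.to_string(index=False,
                                    float_format=lambda x: f"{x:,.1f}")]
        if self.counterfactual_learning_index is not None:
            cli = self.counterfactual_learning_index
            out.append(f"counterfactual learning index: mean "
                       f"{cli.mean():.2f} (sd {cli.std(ddof=1):.2f})")
        return "\n".join(out)
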