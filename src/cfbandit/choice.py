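"""Subjective value and softmax choice rule, with session log-likelihood.

The subjective value of an option combines its estimated reward
probability ``p`` and displayed reward magnitude ``m`` (an integer in
1..100, rescaled to ``m/100`` so all terms share scale) through three
participant-specific weights:

    V = beta * p + lambda * (m/100) + gamma * p * (m/100)

Choices are modelled as a softmax over the subjective values of the
options available at that decision: all three options at a first
decision, the two previously unchosen options at a second decision.
There is no separate inverse-temperature parameter; the overall scale of
the weights plays that role, so the model has exactly three free
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ChoiceParams",
    "subjective_value",
    "subjective_values",
    "choice_probabilities",
    "session_log_likelihood",
    "second_phase_options",
]

MAGNITUDE_SCALE = 100.0


@dataclass(frozen=True)
class ChoiceParams:
    """Weights on probability (beta), magnitude (lam) and their product (gamma)."""

    beta: float
    lam: float
    gamma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.beta, self.lam, self.gamma], dtype=float)

    def to_json(self) -> str:
        return json.dumps({"beta": self.beta, "lambda": self.lam,
                           "gamma": self.gamma})

    @classmethod
    def from_json(cls, text: str) -> "ChoiceParams":
        d = json.loads(text)
        return cls(beta=d["beta"], lam=d["lambda"], gamma=d["gamma"])


def subjective_value(p: float, m: float, params: ChoiceParams) -> float:
    """Subjective value of a single option (see module docstring)."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"reward probability must lie in (0,1), got {p}")
    m_t = m / MAGNITUDE_SCALE
    return params.beta * p + params.lam * m_t + params.gamma * p * m_t


def subjective_values(p, m, params: ChoiceParams) -> np.ndarray:
    """Vectorised subjective values for arrays of probabilities/magnitudes."""
    p = np.asarray(p, dtype=float)
    m_t = np.asarray(m, dtype=float) / MAGNITUDE_SCALE
    return params.beta * p + params.lam * m_t + params.gamma * p * m_t


def choice_probabilities(values) -> np.ndarray:
    """Softmax over the available options, computed with max-subtraction."""
    v = np.asarray(values, dtype=float)
    v = v - v.max(axis=-1, keepdims=True)
    e = np.exp(v)
    return e / e.sum(axis=-1, keepdims=True)


def second_phase_options(condition: int, first_choice: int,
                         magnitudes, cond3_magnitude: int = 50):
    """Options and magnitudes in play at the second decision of a trial.

    Returns ``(option_ids, magnitudes)`` for the two options not taken at
    the first decision; in condition 2 the first-phase magnitudes carry
    over, in condition 3 both are replaced by ``cond3_magnitude``.
    Condition 1 has no second decision.
    """
    if condition == 1:
        raise ValueError("condition 1 trials have no second decision")
    options = [s for s in (1, 2, 3) if s != first_choice]
    if condition == 2:
        mags = [magnitudes[s - 1] for s in options]
    elif condition == 3:
        mags = [cond3_magnitude, cond3_magnitude]
    else:
        raise ValueError(f"unknown condition {condition}")
    return options, mags


def _second_decision_arrays(session, cond3_magnitude: int = 50):
    """Vectorised second-decision structure for conditions 2-3.

    Returns (trial_rows, option_ids (m,2), magnitudes (m,2), chosen_col (m,))
    where ``chosen_col`` indexes into the 2-option set.
    """
    cond = np.asarray(session["condition"], dtype=int)
    rows = np.flatnonzero(cond != 1)
    fc = np.asarray(session["first_choice"], dtype=int)[rows]
    sc = np.asarray(session["second_choice"], dtype=float)[rows]
    if np.any(np.isnan(sc)):
        bad = rows[np.flatnonzero(np.isnan(sc))[0]]
        raise ValueError(f"missing second choice on trial {bad + 1}")
    sc = sc.astype(int)
    all_opts = np.array([1, 2, 3])
    opts = np.stack([np.delete(all_opts, f - 1) for f in fc])  # (m, 2)
    mags_all = np.column_stack([session[f"mag_{s}"] for s in (1, 2, 3)])[rows]
    mags = np.take_along_axis(mags_all, opts - 1, axis=1).astype(float)
    mags[cond[rows] == 3] = float(cond3_magnitude)
    chosen_col = np.where(opts[:, 0] == sc, 0, 1)
    if np.any(opts[np.arange(len(rows)), chosen_col] != sc):
        raise ValueError("second choice equals first choice on some trial")
    return rows, opts, mags, chosen_col


def session_log_likelihood(session, estimates, params: ChoiceParams,
                           include_second: bool = True,
                           cond3_magnitude: int = 50) -> float:
    """Log-likelihood of all recorded choices under the softmax model.

    Sums the log softmax probability of the chosen option over every
    first decision (three options) and, when ``include_second``, every
    second decision in conditions 2-3 (two options).  ``estimates`` must
    supply pre-outcome reward-probability estimates aligned to the
    session (one row per trial, one column per option).
    """
    p_hat = np.asarray(estimates.p_hat if hasattr(estimates, "p_hat")
                       else estimates, dtype=float)
    n = len(session)
    if p_hat.shape != (n, 3):
        raise ValueError(
            f"estimates shape {p_hat.shape} does not match session with "
            f"{n} trials x 3 options")

    mags = np.column_stack([session[f"mag_{s}"] for s in (1, 2, 3)]).astype(float)
    fc = np.asarray(session["first_choice"], dtype=int)
    v1 = subjective_values(p_hat, mags, params)
    ll = float(np.sum(v1[np.arange(n), fc - 1] - logsumexp(v1, axis=1)))

    if include_second:
        rows, opts, mags2, chosen_col = _second_decision_arrays(
            session, cond3_magnitude)
        p2 = np.take_along_axis(p_hat[rows], opts - 1, axis=1)
        v2 = subjective_values(p2, mags2, params)
        ll += float(np.sum(v2[np.arange(len(rows)), chosen_col]
                           - logsumexp(v2, axis=1)))
    return ll
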