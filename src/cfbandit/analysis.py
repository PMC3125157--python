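"""Group behavioural statistics for the three-option bandit.

All group tests are random effects: a statistic is computed per
participant and then tested across participants (one-sample or paired
t-test, df = participants - 1).  "Optimal choice" always means choosing
the option with the highest expected value (estimated reward probability
times displayed magnitude) at the first decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "OptionRanking",
    "RegressionReport",
    "rank_options",
    "optimal_choice_regression",
    "cross_correlation_matrix",
    "switch_adaptation_analysis",
]


@dataclass
class OptionRanking:
    """Per-trial option orderings (best to worst), with tie flags.

    ``ev_order`` ranks all three options by expected value p_hat * m;
    ``prob_order`` ranks by estimated reward probability alone.  Ties are
    broken toward the lower option id and flagged.
    """

    ev_order: np.ndarray       # (n_trials, 3) option ids, best first
    prob_order: np.ndarray     # (n_trials, 3)
    ev_tie: np.ndarray         # (n_trials,) bool
    prob_tie: np.ndarray

    @property
    def ev_best(self) -> np.ndarray:
        return self.ev_order[:, 0]


def _rank_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending argsort per row with lower-id tie-break, plus tie flag."""
    n = values.shape[0]
    ids = np.broadcast_to(np.arange(values.shape[1]), values.shape)
    order = np.lexsort((ids, -values), axis=1)
    srt = np.sort(values, axis=1)
    tie = np.any(np.diff(srt, axis=1) == 0, axis=1)
    return order + 1, tie


def rank_options(estimates, session) -> OptionRanking:
    """Rank options per trial by expected value and by probability."""
    p_hat = np.asarray(estimates.p_hat if hasattr(estimates, "p_hat")
                       else estimates, dtype=float)
    mags = np.column_stack([session[f"mag_{s}"] for s in (1, 2, 3)]).astype(float)
    ev_order, ev_tie = _rank_rows(p_hat * mags)
    prob_order, prob_tie = _rank_rows(p_hat)
    return OptionRanking(ev_order=ev_order, prob_order=prob_order,
                         ev_tie=ev_tie, prob_tie=prob_tie)


@dataclass
class RegressionReport:
    """Per-participant logistic coefficients and their group t-tests."""

    coefs: pd.DataFrame        # participants x regressors
    group: pd.DataFrame        # mean, t, p (two- and one-sided), per regressor
    df: int                    # degrees of freedom of the group tests
    ridge_flags: np.ndarray    # participants where a ridge refit was needed


def _fit_logistic(y: np.ndarray, X: np.ndarray, ridge_alpha: float = 1e-3):
    """Logistic fit with a ridge fallback on (quasi-)separation.

    Returns (coefficients excluding intercept, ridge_used).
    """
    Xc = sm.add_constant(X, has_constant="add")
    try:
        if y.min() == y.max():
            raise ValueError("constant response")
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 20:
            return np.asarray(res.params)[1:], False
    except Exception:
        pass
    res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit_regularized(
        alpha=ridge_alpha, L1_wt=0.0)
    return np.asarray(res.params)[1:], True


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def optimal_choice_regression(sessions, estimates_list,
                              include_lagged_magnitudes: bool = False
                              ) -> RegressionReport:
    """Logistic regression of optimal first choices, tested across the group.

    Per participant, the indicator "chose the EV-best option" is
    regressed (after per-participant standardisation of regressors) on
    the estimated reward probability and displayed magnitude of the
    EV-ranked best, mid and worst options, optionally plus the previous
    trial's three magnitudes (ranked on the previous trial).  Group
    inference is a one-sample t-test per coefficient across participants.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two participants for group tests")
    names = [f"{var}_{role}" for var in ("prob", "mag")
             for role in ("best", "mid", "worst")]
    if include_lagged_magnitudes:
        names += [f"mag_{role}_prev" for role in ("best", "mid", "worst")]

    rows, flags = [], []
    for session, estimates in zip(sessions, estimates_list):
        ranking = rank_options(estimates, session)
        p_hat = np.asarray(estimates.p_hat, dtype=float)
        mags = np.column_stack(
            [session[f"mag_{s}"] for s in (1, 2, 3)]).astype(float)
        n = len(session)
        idx = ranking.ev_order - 1                      # (n, 3) best..worst
        tr = np.arange(n)[:, None]
        X = np.column_stack([p_hat[tr, idx], mags[tr, idx]])
        y = (np.asarray(session["first_choice"], dtype=int)
             == ranking.ev_best).astype(float)
        if include_lagged_magnitudes:
            prev_mags = mags[tr, idx][:-1]              # prev trial, prev ranking
            X = np.column_stack([X[1:], prev_mags])
            y = y[1:]
        coef, used_ridge = _fit_logistic(y, _zscore(X))
        rows.append(coef)
        flags.append(used_ridge)

    coefs = pd.DataFrame(rows, columns=names)
    t, p_two = stats.ttest_1samp(coefs.to_numpy(), 0.0, axis=0)
    mean = coefs.mean(axis=0).to_numpy()
    p_one = np.where(t > 0, p_two / 2, 1 - p_two / 2)
    group = pd.DataFrame({"mean": mean, "t": t, "p_two_sided": p_two,
                          "p_one_sided_positive": p_one}, index=names)
    return RegressionReport(coefs=coefs, group=group,
                            df=len(sessions) - 1,
                            ridge_flags=np.asarray(flags))


CROSS_CORR_LABELS = [f"{var}_{role}" for var in ("prob", "ev", "mag")
                     for role in ("chosen", "next_best", "worst")]


def cross_correlation_matrix(sessions, estimates_list) -> pd.DataFrame:
    """Mean 9x9 Pearson correlation matrix across participants.

    The nine trialwise series are reward probability, expected value and
    magnitude of the chosen option and of the two unchosen options ranked
    by estimated reward probability (next best / worst).  Per-participant
    matrices are averaged; undefined correlations (zero-variance series)
    are left missing for that participant.
    """
    mats = []
    for session, estimates in zip(sessions, estimates_list):
        p_hat = np.asarray(estimates.p_hat, dtype=float)
        mags = np.column_stack(
            [session[f"mag_{s}"] for s in (1, 2, 3)]).astype(float)
        n = len(session)
        fc = np.asarray(session["first_choice"], dtype=int) - 1
        tr = np.arange(n)
        unchosen = np.stack([np.delete(np.arange(3), f) for f in fc])
        un_p = p_hat[tr[:, None], unchosen]
        order = np.argsort(-un_p, axis=1)
        ranked = np.take_along_axis(unchosen, order, axis=1)
        roles = np.column_stack([fc, ranked])            # chosen, next, worst
        cols = np.column_stack([
            p_hat[tr[:, None], roles],
            (p_hat * mags)[tr[:, None], roles],
            mags[tr[:, None], roles],
        ])
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(cols.T)
        mats.append(c)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries
        mean = np.nanmean(np.stack(mats), axis=0)
    return pd.DataFrame(mean, index=CROSS_CORR_LABELS,
                        columns=CROSS_CORR_LABELS)


@dataclass
class SwitchAdaptationResult:
    """Adaptation frequencies to the previously best vs worst unchosen
    option on trials where that option has become EV-optimal."""

    per_participant: pd.DataFrame
    t: float
    p_two_sided: float
    p_one_sided: float
    df: int
    n_skipped: int
    matched_dv_best: np.ndarray     # pooled |EV margin| in matched sets
    matched_dv_worst: np.ndarray


def switch_adaptation_analysis(sessions, estimates_list, n_bins: int = 10,
                               seed: int = 0) -> SwitchAdaptationResult:
    """Do people switch to the previously best pending option more readily?

    For consecutive trial pairs (t, t+1): rank the two options unchosen
    at trial t by estimated reward probability.  Where the previously
    best (resp. worst) unchosen option is EV-optimal on trial t+1, an
    adaptation is choosing it at t+1.  The two trial sets are matched on
    the EV margin |EV(best) - EV(runner-up)| at t+1 by equal-width
    binning and seeded subsampling of the larger set per bin, then the
    per-participant matched frequencies are compared by paired t-test.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pooled_a, pooled_b = [], []
    n_skipped = 0
    for session, estimates in zip(sessions, estimates_list):
        ranking = rank_options(estimates, session)
        p_hat = np.asarray(estimates.p_hat, dtype=float)
        mags = np.column_stack(
            [session[f"mag_{s}"] for s in (1, 2, 3)]).astype(float)
        ev = p_hat * mags
        n = len(session)
        fc = np.asarray(session["first_choice"], dtype=int)
        tr = np.arange(n)
        unchosen = np.stack([np.delete(np.arange(3), f - 1) for f in fc]) + 1
        un_p = np.take_along_axis(p_hat, unchosen - 1, axis=1)
        best_un = np.where(un_p[:, 0] >= un_p[:, 1], unchosen[:, 0],
                           unchosen[:, 1])
        worst_un = np.where(un_p[:, 0] >= un_p[:, 1], unchosen[:, 1],
                            unchosen[:, 0])

        nxt_best = ranking.ev_best[1:]
        ev_sorted = np.sort(ev, axis=1)
        margin = (ev_sorted[:, 2] - ev_sorted[:, 1])[1:]
        adapted = (fc[1:] == nxt_best)
        case_a = best_un[:-1] == nxt_best
        case_b = worst_un[:-1] == nxt_best

        freq_a_raw = adapted[case_a].mean() if case_a.any() else np.nan
        freq_b_raw = adapted[case_b].mean() if case_b.any() else np.nan

        # EV-margin matching by equal-width bins over the pooled range
        dv = margin
        pool = np.concatenate([dv[case_a], dv[case_b]])
        if len(dv[case_a]) == 0 or len(dv[case_b]) == 0:
            n_skipped += 1
            rows.append({"freq_best_raw": freq_a_raw,
                         "freq_worst_raw": freq_b_raw,
                         "freq_best_matched": np.nan,
                         "freq_worst_matched": np.nan})
            continue
        edges = np.linspace(pool.min(), pool.max() + 1e-12, n_bins + 1)
        keep_a, keep_b = [], []
        ia, ib = np.flatnonzero(case_a), np.flatnonzero(case_b)
        bin_a = np.digitize(dv[case_a], edges) - 1
        bin_b = np.digitize(dv[case_b], edges) - 1
        for b in range(n_bins):
            sel_a, sel_b = ia[bin_a == b], ib[bin_b == b]
            m = min(len(sel_a), len(sel_b))
            if m == 0:
                continue
            keep_a.append(rng.choice(sel_a, size=m, replace=False))
            keep_b.append(rng.choice(sel_b, size=m, replace=False))
        if not keep_a:
            n_skipped += 1
            rows.append({"freq_best_raw": freq_a_raw,
                         "freq_worst_raw": freq_b_raw,
                         "freq_best_matched": np.nan,
                         "freq_worst_matched": np.nan})
            continue
        keep_a = np.concatenate(keep_a)
        keep_b = np.concatenate(keep_b)
        pooled_a.append(dv[keep_a])
        pooled_b.append(dv[keep_b])
        rows.append({"freq_best_raw": freq_a_raw,
                     "freq_worst_raw": freq_b_raw,
                     "freq_best_matched": adapted[keep_a].mean(),
                     "freq_worst_matched": adapted[keep_b].mean()})

    per = pd.DataFrame(rows)
    ok = per.dropna(subset=["freq_best_matched", "freq_worst_matched"])
    diff = (ok["freq_best_matched"] - ok["freq_worst_matched"]).to_numpy()
    if len(diff) >= 2 and np.ptp(diff) > 0:
        t, p_two = stats.ttest_1samp(diff, 0.0)
    else:
        t, p_two = (0.0, 1.0) if len(diff) and np.allclose(diff, 0) else (np.nan, np.nan)
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    return SwitchAdaptationResult(
        per_participant=per, t=float(t), p_two_sided=float(p_two),
        p_one_sided=float(p_one), df=len(ok) - 1, n_skipped=n_skipped,
        matched_dv_best=(np.concatenate(pooled_a) if pooled_a
                         else np.empty(0)),
        matched_dv_worst=(np.concatenate(pooled_b) if pooled_b
                          else np.empty(0)))
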