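"""Model-derived trialwise regressors and the convolved fMRI design matrix.

The trialwise quantities are the estimated reward probabilities of the
chosen / best-unchosen / worst-unchosen options (under a model-based
ranking in conditions 1-2 and a participant-choice-based ranking in
condition 3), signed prediction errors for chosen and unchosen outcomes
(outcome minus the same trial's pre-outcome estimate, so every PE lies
in [-1, 1]), and a regret signal defined purely on delivered magnitudes.

The design matrix places stick events at phase onsets, multiplies each
parametric modulator into its phase's events after mean-centering within
that event set, convolves with a canonical double-gamma haemodynamic
response (peak 6 s, undershoot 16 s) and samples at the TR.  Six motion
columns are emitted as zero placeholders, giving 24 columns in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .choice import second_phase_options

__all__ = [
    "build_regressor_set",
    "prediction_errors",
    "regret_signal",
    "build_design_matrix",
    "synthetic_bold_recovery",
    "hrf_double_gamma",
    "convolve_events",
    "write_events_tsv",
    "DesignMatrix",
]


def _roles(session, p_hat, cond3_magnitude=50):
    """Chosen / best-unchosen / worst-unchosen option ids per trial.

    Unchosen options are ranked by estimated reward probability
    (model-based).  The participant-choice ranking takes the option
    chosen at the second decision as the best unchosen (conditions 2-3).
    """
    n = len(session)
    fc = np.asarray(session["first_choice"], dtype=int)
    cond = np.asarray(session["condition"], dtype=int)
    unchosen = np.stack([np.delete(np.array([1, 2, 3]), f - 1) for f in fc])
    un_p = np.take_along_axis(p_hat, unchosen - 1, axis=1)
    first_best = un_p[:, 0] >= un_p[:, 1]
    best_model = np.where(first_best, unchosen[:, 0], unchosen[:, 1])
    worst_model = np.where(first_best, unchosen[:, 1], unchosen[:, 0])

    best_choice = np.full(n, np.nan)
    worst_choice = np.full(n, np.nan)
    if "second_choice" in session:
        sc = np.asarray(session["second_choice"], dtype=float)
        has = ~np.isnan(sc)
        sci = sc[has].astype(int)
        other = unchosen[has]
        best_choice[has] = sci
        worst_choice[has] = np.where(other[:, 0] == sci, other[:, 1],
                                     other[:, 0])
    return fc, best_model, worst_model, best_choice, worst_choice


def build_regressor_set(session, estimates, cond3_magnitude: int = 50
                        ) -> pd.DataFrame:
    """All trialwise model-derived regressors for one session.

    Requires a completed session (choices and all three outcomes) and
    pre-outcome probability estimates aligned to it.
    """
    p_hat = np.asarray(estimates.p_hat if hasattr(estimates, "p_hat")
                       else estimates, dtype=float)
    n = len(session)
    if p_hat.shape != (n, 3):
        raise ValueError("estimates misaligned with session")
    outcomes = np.column_stack(
        [session[f"outcome_{s}"] for s in (1, 2, 3)]).astype(float)
    if np.any(~np.isin(outcomes, (0.0, 1.0))):
        raise ValueError("session has missing outcomes")
    mags = np.column_stack(
        [session[f"mag_{s}"] for s in (1, 2, 3)]).astype(float)
    cond = np.asarray(session["condition"], dtype=int)
    tr = np.arange(n)
    fc, best_m, worst_m, best_c, worst_c = _roles(session, p_hat,
                                                  cond3_magnitude)

    def take(arr, ids):
        ids = np.asarray(ids, dtype=float)
        out = np.full(n, np.nan)
        has = ~np.isnan(ids)
        out[has] = arr[tr[has], ids[has].astype(int) - 1]
        return out

    df = pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "condition": cond,
        "chosen_p": take(p_hat, fc),
        "best_unchosen_p_model": take(p_hat, best_m),
        "worst_unchosen_p_model": take(p_hat, worst_m),
        "best_unchosen_p_choice": take(p_hat, best_c),
        "worst_unchosen_p_choice": take(p_hat, worst_c),
        "chosen_outcome": take(outcomes, fc),
        "best_unchosen_outcome": take(outcomes, best_m),
        "worst_unchosen_outcome": take(outcomes, worst_m),
        "chosen_pe": take(outcomes, fc) - take(p_hat, fc),
        "cf_pe_best_unchosen": take(outcomes, best_m) - take(p_hat, best_m),
        "cf_pe_worst_unchosen": take(outcomes, worst_m) - take(p_hat, worst_m),
    })
    # second-decision perspective (conditions 2-3)
    sc = (np.asarray(session["second_choice"], dtype=float)
          if "second_choice" in session else np.full(n, np.nan))
    df["second_chosen_pe"] = take(outcomes, sc) - take(p_hat, sc)
    df["second_unchosen_outcome"] = take(outcomes, worst_c)
    df["second_unchosen_pe"] = take(outcomes, worst_c) - take(p_hat, worst_c)
    df["second_outcome"] = take(outcomes, sc)
    df["regret"] = [
        regret_signal(session.iloc[i], cond3_magnitude)
        if cond[i] != 1 else np.nan
        for i in range(n)]
    for col in ("t_dec1", "t_fb1", "t_foregone", "t_dec2", "t_fb2"):
        if col in session:
            df[col] = np.asarray(session[col], dtype=float)
    return df


def prediction_errors(session, estimates, cond3_magnitude: int = 50
                      ) -> pd.DataFrame:
    """Prediction-error fields only (see :func:`build_regressor_set`)."""
    full = build_regressor_set(session, estimates, cond3_magnitude)
    return full[["trial", "condition", "chosen_pe", "cf_pe_best_unchosen",
                 "cf_pe_worst_unchosen", "second_chosen_pe",
                 "second_unchosen_pe"]]


def regret_signal(trial_row, cond3_magnitude: int = 50) -> float:
    """Delivered-magnitude difference, foregone minus chosen, at the
    second feedback phase.

    An unrewarded option delivers 0 regardless of its magnitude; the
    signal therefore tracks outcome sizes, not expectations.  Only
    conditions 2-3 have a phase at which both outcomes are revealed
    together with payable magnitudes.
    """
    cond = int(trial_row["condition"])
    if cond == 1:
        raise ValueError("condition 1 has no second feedback phase; "
                         "no regret signal is defined")
    fc = int(trial_row["first_choice"])
    sc = float(trial_row["second_choice"])
    if np.isnan(sc):
        raise ValueError("second choice missing")
    sc = int(sc)
    mags = [trial_row[f"mag_{s}"] for s in (1, 2, 3)]
    opts, omags = second_phase_options(cond, fc, mags, cond3_magnitude)
    unch = opts[0] if opts[1] == sc else opts[1]
    mag_of = dict(zip(opts, omags))
    delivered_ch = mag_of[sc] * float(trial_row[f"outcome_{sc}"])
    delivered_un = mag_of[unch] * float(trial_row[f"outcome_{unch}"])
    return float(delivered_un - delivered_ch)


def hrf_double_gamma(dt: float, duration: float = 32.0,
                     peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, peak 1."""
    t = np.arange(0, duration, dt)
    h = (_stats.gamma.pdf(t, peak_delay, scale=1.0)
         - ratio * _stats.gamma.pdf(t, undershoot_delay, scale=1.0))
    return h / h.max()


MOTION_COLUMNS = [f"motion_{i}" for i in range(1, 7)]


def convolve_events(onsets, tr: float, n_volumes: int,
                    modulator=None, oversample: int = 30,
                    mean_center: bool = True) -> np.ndarray:
    """Convolve stick events with the canonical HRF, sampled at the TR.

    ``modulator`` (optional) scales each event after mean-centering
    within the event set; without it every event has unit amplitude.
    """
    onsets = np.asarray(onsets, dtype=float)
    keep = ~np.isnan(onsets)
    onsets = onsets[keep]
    if modulator is None:
        amp = np.ones(len(onsets))
    else:
        amp = np.asarray(modulator, dtype=float)[keep]
        if len(amp) != len(onsets):
            raise ValueError("modulator/onset length mismatch")
        if mean_center and len(amp):
            amp = amp - amp.mean()
    dt = tr / oversample
    n_fine = n_volumes * oversample
    if len(onsets) and onsets.max() >= n_volumes * tr:
        raise ValueError(f"events extend to {onsets.max():.1f}s, beyond "
                         f"the scan of {n_volumes} volumes x TR {tr}s")
    fine = np.zeros(n_fine)
    np.add.at(fine, np.round(onsets / dt).astype(int), amp)
    conv = np.convolve(fine, hrf_double_gamma(dt))[:n_fine]
    return conv[np.arange(n_volumes) * oversample]


@dataclass
class DesignMatrix:
    """Time-resolved design matrix (volumes x regressors) after HRF
    convolution; motion columns are zero placeholders."""

    frame: pd.DataFrame
    tr: float
    placeholder_columns: list[str] = field(default_factory=lambda: list(MOTION_COLUMNS))

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def task_columns(self) -> list[str]:
        return [c for c in self.frame.columns
                if c not in self.placeholder_columns]

    def task_rank(self) -> int:
        return int(np.linalg.matrix_rank(self.frame[self.task_columns]))


def build_design_matrix(session, regressors: pd.DataFrame, tr: float = 3.0,
                        n_volumes: int | None = None, oversample: int = 30,
                        ) -> DesignMatrix:
    """Assemble the 24-column convolved design matrix for one session.

    Columns: five phase main effects (first decision, first feedback,
    foregone-outcome phase, second decision, second feedback);
    probability modulators on the first decision and feedback phases —
    chosen probability on all trials, best/worst unchosen probability
    split into model-ranked (conditions 1-2) and participant-choice
    ranked (condition 3) columns; outcome modulators at each of the
    three feedback events; six zero motion placeholders.
    """
    cond = np.asarray(session["condition"], dtype=int)
    t_dec1 = np.asarray(session["t_dec1"], dtype=float)
    t_fb1 = np.asarray(session["t_fb1"], dtype=float)
    t_fore = np.asarray(session["t_foregone"], dtype=float)
    t_dec2 = np.asarray(session["t_dec2"], dtype=float)
    t_fb2 = np.asarray(session["t_fb2"], dtype=float)

    c1 = cond == 1
    c12 = (cond == 1) | (cond == 2)
    c23 = ~c1
    c3 = cond == 3

    r = regressors
    fore_outcome = 0.5 * (r["best_unchosen_outcome"]
                          + r["worst_unchosen_outcome"]).to_numpy()

    events: dict[str, tuple[np.ndarray, np.ndarray | None]] = {
        "dec1": (t_dec1, None),
        "fb1": (t_fb1, None),
        "foregone": (t_fore[c1], None),
        "dec2": (t_dec2[c23], None),
        "fb2": (t_fb2[c23], None),
        "chosen_p_x_dec1": (t_dec1, r["chosen_p"].to_numpy()),
        "chosen_p_x_fb1": (t_fb1, r["chosen_p"].to_numpy()),
        "best_unchosen_p_model_x_dec1":
            (t_dec1[c12], r["best_unchosen_p_model"].to_numpy()[c12]),
        "best_unchosen_p_choice_x_dec1":
            (t_dec1[c3], r["best_unchosen_p_choice"].to_numpy()[c3]),
        "best_unchosen_p_model_x_fb1":
            (t_fb1[c12], r["best_unchosen_p_model"].to_numpy()[c12]),
        "best_unchosen_p_choice_x_fb1":
            (t_fb1[c3], r["best_unchosen_p_choice"].to_numpy()[c3]),
        "worst_unchosen_p_model_x_dec1":
            (t_dec1[c12], r["worst_unchosen_p_model"].to_numpy()[c12]),
        "worst_unchosen_p_choice_x_dec1":
            (t_dec1[c3], r["worst_unchosen_p_choice"].to_numpy()[c3]),
        "worst_unchosen_p_model_x_fb1":
            (t_fb1[c12], r["worst_unchosen_p_model"].to_numpy()[c12]),
        "worst_unchosen_p_choice_x_fb1":
            (t_fb1[c3], r["worst_unchosen_p_choice"].to_numpy()[c3]),
        "outcome_x_fb1": (t_fb1, r["chosen_outcome"].to_numpy()),
        "outcome_x_foregone": (t_fore[c1], fore_outcome[c1]),
        "outcome_x_fb2": (t_fb2[c23], r["second_outcome"].to_numpy()[c23]),
    }

    t_max = max(np.nanmax(v[0]) for v in events.values() if len(v[0]))
    if n_volumes is None:
        n_volumes = int(np.ceil((t_max + 20.0) / tr)) + 1
    elif t_max >= n_volumes * tr:
        raise ValueError(
            f"events extend to {t_max:.1f}s, beyond the scan of "
            f"{n_volumes} volumes x TR {tr}s")

    cols = {}
    for name, (onsets, modulator) in events.items():
        cols[name] = convolve_events(onsets, tr, n_volumes,
                                     modulator=modulator,
                                     oversample=oversample)
    for name in MOTION_COLUMNS:
        cols[name] = np.zeros(n_volumes)
    return DesignMatrix(frame=pd.DataFrame(cols), tr=tr)


def synthetic_bold_recovery(design: DesignMatrix, true_betas, noise_sd: float,
                            seed: int = 0):
    """Simulate BOLD from the design and re-estimate the betas by OLS.

    ``true_betas`` is an array over the non-placeholder columns.  Returns
    (estimated betas as a Series, max absolute recovery error).  Raises
    on a rank-deficient task design, naming the collinear columns.
    """
    X = design.frame[design.task_columns].to_numpy()
    names = design.task_columns
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(X)[1]))
        bad = [names[i] for i in np.where(rdiag < 1e-8 * rdiag.max())[0]]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    beta = np.asarray(true_betas, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"expected {X.shape[1]} betas, got {beta.shape}")
    rng = np.random.default_rng(seed)
    y = X @ beta + rng.normal(0.0, noise_sd, size=X.shape[0])
    est, *_ = np.linalg.lstsq(X, y, rcond=None)
    err = float(np.max(np.abs(est - beta)))
    return pd.Series(est, index=names), err


def write_events_tsv(session, regressors: pd.DataFrame, path) -> None:
    """BIDS-style long events table (onset, duration, trial_type + modulators)."""
    rows = []
    r = regressors
    for i in range(len(session)):
        cond = int(session["condition"].iloc[i])
        rows.append({"onset": session["t_dec1"].iloc[i], "duration": 0.0,
                     "trial_type": "decision1",
                     "chosen_p": r["chosen_p"].iloc[i],
                     "best_unchosen_p": (r["best_unchosen_p_choice"].iloc[i]
                                         if cond == 3 else
                                         r["best_unchosen_p_model"].iloc[i])})
        rows.append({"onset": session["t_fb1"].iloc[i], "duration": 0.0,
                     "trial_type": "feedback1",
                     "chosen_pe": r["chosen_pe"].iloc[i]})
        if cond == 1:
            rows.append({"onset": session["t_foregone"].iloc[i],
                         "duration": 0.0, "trial_type": "foregone_outcome",
                         "cf_pe_best": r["cf_pe_best_unchosen"].iloc[i],
                         "cf_pe_worst": r["cf_pe_worst_unchosen"].iloc[i]})
        else:
            rows.append({"onset": session["t_dec2"].iloc[i], "duration": 0.0,
                         "trial_type": "decision2"})
            rows.append({"onset": session["t_fb2"].iloc[i], "duration": 0.0,
                         "trial_type": "feedback2",
                         "second_chosen_pe": r["second_chosen_pe"].iloc[i],
                         "second_unchosen_pe": r["second_unchosen_pe"].iloc[i],
                         "regret": r["regret"].iloc[i]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="")
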