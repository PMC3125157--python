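"""Volatile three-armed bandit task: schedules, sessions, simulated agents.

The task presents three options whose true reward probabilities drift
independently from trial to trial (a beta random walk at fixed
volatility) while displayed reward magnitudes are redrawn uniformly from
1..100 on every trial.  Each of 180 trials belongs to one of three
interleaved conditions (60 each):

* condition 1 — one decision among all three options; the outcomes of
  the two foregone options are then shown (no points for them);
* condition 2 — after first feedback, a second decision between the two
  previously unchosen options at their original magnitudes;
* condition 3 — as condition 2 but both second-phase magnitudes are
  reset to 50, so only reward probability should guide the choice.

Every option's outcome is revealed on every trial, which is what makes
counterfactual learning measurable.  Sessions are tidy pandas frames,
one row per trial; :func:`simulate_agent` fills in choices and outcomes
for a softmax agent running any of the supported learning rules.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
import yaml

from . import choice as _choice
from . import learner as _learner
from .choice import ChoiceParams, choice_probabilities, subjective_values
from .learner import GridSpec, init_belief, run_learner

__all__ = [
    "Schedule",
    "SessionConfig",
    "generate_true_probability_walk",
    "select_decorrelated_schedule",
    "generate_session",
    "simulate_agent",
    "simulate_cohort",
    "write_session_tsv",
    "read_session_tsv",
]

logger = logging.getLogger(__name__)

AGENT_VARIANTS = ("optimal", "experiential", "rescorla_wagner", "dual_rate")

#: default beta step variance of the true-probability walk; gives a
#: per-trial step s.d. of ~0.03 so probabilities sweep much of (0,1)
#: over a 180-trial session while remaining trackable
DEFAULT_VOLATILITY = 1e-3

#: first-trial probabilities are drawn uniformly from this interval
INITIAL_PROB_RANGE = (0.2, 0.8)


@dataclass(frozen=True)
class Schedule:
    """True reward probabilities, one row per trial and column per option."""

    true_prob: np.ndarray
    volatility: float
    seed: int

    @property
    def n_trials(self) -> int:
        return self.true_prob.shape[0]

    @property
    def n_options(self) -> int:
        return self.true_prob.shape[1]


@dataclass(frozen=True)
class SessionConfig:
    n_trials_per_condition: int = 60
    n_options: int = 3
    magnitude_range: tuple[int, int] = (1, 100)
    condition3_magnitude: int = 50
    jitter_interval_s: tuple[float, float] = (2.5, 5.5)
    tr_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.magnitude_range
        if not (0 < lo < hi):
            raise ValueError("magnitude_range must be positive with low < high")
        jlo, jhi = self.jitter_interval_s
        if not jlo < jhi:
            raise ValueError("jitter interval must have low < high")

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_condition * 3

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("magnitude_range", "jitter_interval_s"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def generate_true_probability_walk(n_trials: int, volatility: float = DEFAULT_VOLATILITY,
                                   n_options: int = 3, seed: int = 0,
                                   initial_range: tuple[float, float] = INITIAL_PROB_RANGE,
                                   ) -> Schedule:
    """Beta random walk of each option's true reward probability.

    Row 1 is uniform on ``initial_range``; row ``i+1`` column ``s`` is a
    beta draw with mean equal to row ``i`` column ``s`` and variance
    ``volatility`` (clipped to 90% of the feasible maximum near the
    boundaries, with a log message when that happens).  Options use
    independent random streams.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if volatility < 0:
        raise ValueError("volatility must be >= 0")
    streams = np.random.SeedSequence(seed).spawn(n_options)
    cols = []
    clipped = 0
    for s in range(n_options):
        rng = np.random.default_rng(streams[s])
        p = np.empty(n_trials)
        lo, hi = initial_range
        p[0] = rng.uniform(lo, hi)
        for i in range(1, n_trials):
            mean = p[i - 1]
            cap = mean * (1.0 - mean)
            var = volatility
            if var >= cap:
                var = 0.9 * cap
                clipped += 1
            if var == 0.0:
                p[i] = mean
                continue
            nu = cap / var - 1.0
            p[i] = rng.beta(mean * nu, (1.0 - mean) * nu)
        cols.append(p)
    if clipped:
        logger.info("clipped beta step variance on %d transitions", clipped)
    prob = np.column_stack(cols)
    # beta draws can underflow to exactly 0/1 in extreme tails; keep the
    # open-interval invariant
    np.clip(prob, 1e-12, 1 - 1e-12, out=prob)
    return Schedule(true_prob=prob, volatility=volatility, seed=seed)


def select_decorrelated_schedule(n_candidates: int, learner_config: GridSpec | None = None,
                                 threshold: float = 0.5, seed: int = 0,
                                 n_trials: int = 180,
                                 volatility: float = DEFAULT_VOLATILITY) -> Schedule:
    """Pick the candidate walk whose learner-estimated option probabilities
    are most mutually decorrelated.

    For each candidate schedule, outcomes for all options are drawn from
    the true probabilities and filtered by the optimal Bayesian learner;
    the candidate minimising the maximum absolute pairwise Pearson
    correlation between the three estimate series is returned.  Raises if
    even the best candidate exceeds ``threshold``.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    grid = learner_config or GridSpec()
    seeds = np.random.SeedSequence(seed).generate_state(n_candidates) % (2**31)
    best = None
    best_r = np.inf
    for cand_seed in seeds:
        sched = generate_true_probability_walk(n_trials, volatility,
                                               seed=int(cand_seed))
        rng = np.random.default_rng(int(cand_seed) + 1)
        outcomes = (rng.random(sched.true_prob.shape)
                    < sched.true_prob).astype(int)
        pseudo = pd.DataFrame({
            "condition": np.ones(n_trials, dtype=int),
            "first_choice": np.ones(n_trials, dtype=int),
            "outcome_1": outcomes[:, 0],
            "outcome_2": outcomes[:, 1],
            "outcome_3": outcomes[:, 2],
        })
        est = run_learner(pseudo, variant="optimal", grid=grid)
        corr = np.corrcoef(est.p_hat.T)
        max_r = float(np.max(np.abs(corr[np.triu_indices(3, k=1)])))
        if max_r < best_r:
            best_r, best = max_r, sched
    if best_r > threshold:
        raise RuntimeError(
            f"no candidate schedule below threshold {threshold}; best "
            f"max |r| achieved was {best_r:.3f}")
    logger.info("selected schedule with max |r| = %.3f", best_r)
    return best


def generate_session(schedule: Schedule, config: SessionConfig | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Session skeleton: conditions, magnitudes and event onsets (no choices).

    Conditions are a balanced, seeded shuffle (exactly
    ``n_trials_per_condition`` of each); magnitudes are i.i.d. uniform
    integers on ``magnitude_range``; event onsets accumulate with one
    uniform jitter draw per event.  Second-phase event times exist only
    in conditions 2-3, the foregone-outcome phase only in condition 1.
    """
    config = config or SessionConfig()
    if schedule.n_trials != config.n_trials:
        raise ValueError(
            f"schedule has {schedule.n_trials} trials but config requires "
            f"{config.n_trials}")
    rng = np.random.default_rng(seed)
    conditions = np.repeat([1, 2, 3], config.n_trials_per_condition)
    rng.shuffle(conditions)
    lo, hi = config.magnitude_range
    mags = rng.integers(lo, hi + 1, size=(config.n_trials, 3))

    jlo, jhi = config.jitter_interval_s
    t = 0.0
    onsets = {k: np.full(config.n_trials, np.nan)
              for k in ("t_dec1", "t_fb1", "t_foregone", "t_dec2", "t_fb2")}
    for i, cond in enumerate(conditions):
        events = (("t_dec1", "t_fb1", "t_foregone") if cond == 1
                  else ("t_dec1", "t_fb1", "t_dec2", "t_fb2"))
        for ev in events:
            onsets[ev][i] = t
            t += rng.uniform(jlo, jhi)

    df = pd.DataFrame({
        "trial": np.arange(1, config.n_trials + 1),
        "condition": conditions,
        "mag_1": mags[:, 0],
        "mag_2": mags[:, 1],
        "mag_3": mags[:, 2],
        **onsets,
    })
    df.attrs["condition3_magnitude"] = config.condition3_magnitude
    return df


def simulate_agent(session: pd.DataFrame, schedule: Schedule,
                   params: ChoiceParams, learner_variant: str = "optimal",
                   seed: int = 0, grid: GridSpec | None = None,
                   alpha_chosen: float = 0.3, alpha_unchosen: float = 0.3,
                   cond3_magnitude: int = 50) -> pd.DataFrame:
    """Complete a session skeleton with a simulated softmax agent.

    The agent forms reward-probability estimates with the requested
    learning rule (``optimal`` / ``experiential`` Bayesian filters, or
    ``rescorla_wagner`` / ``dual_rate`` delta rules with the given
    learning rates), converts them to subjective values, samples its
    first choice from a softmax over three options and its second choice
    (conditions 2-3) over the two remaining options, and observes
    outcomes drawn Bernoulli from the schedule's true probabilities.
    Beliefs are updated after each trial's feedback exactly as the
    corresponding learner variant prescribes.
    """
    if learner_variant not in AGENT_VARIANTS:
        raise ValueError(f"unknown learner variant {learner_variant!r}")
    n = len(session)
    if schedule.n_trials != n:
        raise ValueError("schedule and session lengths differ")
    rng = np.random.default_rng(seed)
    bayes = learner_variant in ("optimal", "experiential")
    if bayes:
        grid = grid or GridSpec()
        kern = _learner._kernels(grid)
        density = init_belief(grid).density
        r_grid = grid.r_grid
    else:
        est = np.full(3, 0.5)
        a_ch, a_un = ((alpha_chosen, alpha_chosen)
                      if learner_variant == "rescorla_wagner"
                      else (alpha_chosen, alpha_unchosen))

    conditions = np.asarray(session["condition"], dtype=int)
    mags = np.column_stack([session[f"mag_{s}"] for s in (1, 2, 3)]).astype(float)
    true_prob = schedule.true_prob

    first_choice = np.empty(n, dtype=int)
    second_choice = np.full(n, np.nan)
    outcomes = np.empty((n, 3), dtype=int)

    for i in range(n):
        p_hat = (np.einsum("orvk,r->o", density, r_grid) if bayes
                 else est.copy())
        p_hat = np.clip(p_hat, 1e-9, 1 - 1e-9)
        v1 = subjective_values(p_hat, mags[i], params)
        fc = int(rng.choice(3, p=choice_probabilities(v1))) + 1
        first_choice[i] = fc
        outcomes[i] = (rng.random(3) < true_prob[i]).astype(int)

        chosen_mask = np.zeros(3, dtype=bool)
        chosen_mask[fc - 1] = True
        if conditions[i] in (2, 3):
            opts, omags = _choice.second_phase_options(
                conditions[i], fc, mags[i], cond3_magnitude)
            v2 = subjective_values(p_hat[np.array(opts) - 1],
                                   np.asarray(omags, dtype=float), params)
            sc = opts[int(rng.choice(2, p=choice_probabilities(v2)))]
            second_choice[i] = sc
            chosen_mask[sc - 1] = True

        if bayes:
            observed = (np.ones(3, dtype=bool) if learner_variant == "optimal"
                        else chosen_mask)
            density = _learner._step_all(density, kern, outcomes[i], observed)
        else:
            alphas = np.where(chosen_mask, a_ch, a_un)
            est = est + alphas * (outcomes[i] - est)

    out = session.copy()
    out["first_choice"] = first_choice
    out["outcome_1"] = outcomes[:, 0]
    out["outcome_2"] = outcomes[:, 1]
    out["outcome_3"] = outcomes[:, 2]
    out["second_choice"] = second_choice
    return out


def simulate_cohort(n_agents: int, params: ChoiceParams,
                    learner_variant: str = "optimal", seed: int = 0,
                    config: SessionConfig | None = None,
                    volatility: float = DEFAULT_VOLATILITY,
                    grid: GridSpec | None = None,
                    decorrelate: bool = False, n_candidates: int = 12,
                    alpha_chosen: float = 0.3,
                    alpha_unchosen: float = 0.3) -> list[pd.DataFrame]:
    """Simulate a cohort of agents facing a shared schedule.

    All agents in a cohort see the same true-probability schedule (as in
    a study where one schedule is preselected) but make independent
    choices and observe independent outcome draws.
    """
    config = config or SessionConfig()
    ss = np.random.SeedSequence(seed)
    sched_seed, sess_seed, *agent_seeds = [
        int(s) for s in ss.generate_state(2 + n_agents) % (2**31)]
    if decorrelate:
        schedule = select_decorrelated_schedule(
            n_candidates, learner_config=grid, seed=sched_seed,
            n_trials=config.n_trials, volatility=volatility)
    else:
        schedule = generate_true_probability_walk(
            config.n_trials, volatility, seed=sched_seed)
    sessions = []
    for j in range(n_agents):
        skeleton = generate_session(schedule, config, seed=sess_seed + j)
        sessions.append(simulate_agent(
            skeleton, schedule, params, learner_variant,
            seed=agent_seeds[j], grid=grid, alpha_chosen=alpha_chosen,
            alpha_unchosen=alpha_unchosen,
            cond3_magnitude=config.condition3_magnitude))
    return sessions


_SESSION_COLUMNS = ["trial", "condition", "mag_1", "mag_2", "mag_3",
                    "t_dec1", "t_fb1", "t_foregone", "t_dec2", "t_fb2",
                    "first_choice", "outcome_1", "outcome_2", "outcome_3",
                    "second_choice"]


def write_session_tsv(session: pd.DataFrame, path) -> None:
    """Write a session as tidy TSV; absent fields become empty strings."""
    cols = [c for c in _SESSION_COLUMNS if c in session.columns]
    session[cols].to_csv(path, sep="\t", index=False, na_rep="")


def read_session_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("trial", "condition", "mag_1", "mag_2", "mag_3"):
        if col in df:
            df[col] = df[col].astype(int)
    return df
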