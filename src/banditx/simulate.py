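"""Simulate choice data from parameterized agents and build synthetic cohorts.

``simulate_session`` plays one subject through one task's fixed reward set:
the agent's belief is updated trial by trial and each free choice is sampled
from the model's choice probabilities. ``generate_synthetic_cohort`` builds a
two-session, three-task cohort whose subject-level true parameters are drawn
from a two-factor latent structure (value-guided, directed) with a
configurable cross-session correlation — the synthetic stand-in for a real
test–retest study, with ground truth retained for recovery and reliability
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from banditx.agents import (
    HorizonParams,
    KalmanBelief,
    LearnerConfig,
    RestlessParams,
    TwoArmedParams,
    diffusion_prior_step,
    horizon_features,
    kalman_update,
    logistic_choice_prob,
    restless_learner_config,
    twoarmed_learner_config,
    twoarmed_predictors,
    ucb_choice_probs,
)
from banditx.task_env import (
    HORIZON_FORCED_TRIALS,
    TASK_HORIZON,
    TASK_RESTLESS,
    TASK_TWOARMED,
    RewardSet,
    rewardset_for_task,
)

SESSION_COLUMNS = ["round", "trial", "condition", "forced", "choice", "reward"]


@dataclass
class SessionData:
    """Ordered trial records for one subject x session x task.

    ``trials`` columns: round and trial are 1-based; ``forced`` is 0/1;
    ``choice`` is the 1-based chosen arm; ``condition`` is the round's label
    (e.g. "long|13" for the Horizon task).
    """

    subject: int
    session: int
    task: str
    trials: pd.DataFrame

    def validate(self) -> None:
        missing = [c for c in SESSION_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"session trials missing columns: {missing}")
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")
        if self.task == TASK_HORIZON:
            for _, grp in self.trials.groupby("round"):
                f = grp.sort_values("trial")["forced"].to_numpy()
                if f.sum() != HORIZON_FORCED_TRIALS or np.any(np.diff(f) > 0):
                    raise ValueError("forced trials must precede free trials in a round")

    def free_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["forced"] == 0]


def _simulate_restless(
    rewardset: RewardSet, params: RestlessParams, cfg: LearnerConfig, rng, n_trials=None
) -> pd.DataFrame:
    n_t = rewardset.n_trials if n_trials is None else min(n_trials, rewardset.n_trials)
    belief = KalmanBelief.prior(rewardset.n_arms, cfg)
    rows = np.empty((n_t, 2))
    for t in range(n_t):
        probs = ucb_choice_probs(belief, params, cfg)
        choice = rng.choice(rewardset.n_arms, p=probs)
        reward = rewardset.rewards[0, t, choice]
        rows[t] = (choice, reward)
        belief = kalman_update(belief, choice, reward, cfg)
        belief = diffusion_prior_step(belief, cfg)
    return pd.DataFrame(
        {
            "round": 1,
            "trial": np.arange(1, n_t + 1),
            "condition": "restless",
            "forced": 0,
            "choice": rows[:, 0].astype(int) + 1,
            "reward": rows[:, 1],
        }
    )


def _simulate_twoarmed(
    rewardset: RewardSet, params: TwoArmedParams, cfg: LearnerConfig, rng, n_trials=None
) -> pd.DataFrame:
    variant = params.variant
    n_t = rewardset.n_trials if n_trials is None else min(n_trials, rewardset.n_trials)
    recs = []
    for r in range(rewardset.n_rounds):
        belief = KalmanBelief.prior(2, cfg)
        cond = rewardset.condition_label(r)
        for t in range(n_t):
            x = twoarmed_predictors(belief, variant)
            p1 = logistic_choice_prob(x, params)
            choice = 0 if rng.random() < p1 else 1
            reward = rewardset.rewards[r, t, choice]
            recs.append((r + 1, t + 1, cond, 0, choice + 1, reward))
            belief = kalman_update(belief, choice, reward, cfg)
    return pd.DataFrame(recs, columns=SESSION_COLUMNS)


def _simulate_horizon(rewardset: RewardSet, params: HorizonParams, rng) -> pd.DataFrame:
    recs = []
    for r in range(rewardset.n_rounds):
        cond_row = rewardset.conditions.iloc[r]
        cond = rewardset.condition_label(r)
        horizon = cond_row["horizon"]
        n_free = int(cond_row["n_free"])
        forced = rewardset.forced_arms[r]
        forced_rewards = [
            rewardset.rewards[r, t, forced[t]] for t in range(HORIZON_FORCED_TRIALS)
        ]
        for t in range(HORIZON_FORCED_TRIALS):
            recs.append((r + 1, t + 1, cond, 1, int(forced[t]) + 1, forced_rewards[t]))
        feats = horizon_features(np.asarray(forced) + 1, forced_rewards, horizon)
        b0, wv, wi = params.weights(horizon)
        p1 = logistic_choice_prob(feats.predictors(), (b0, wv, wi))
        # features stay at their t=5 values for all free choices of the round
        for t in range(HORIZON_FORCED_TRIALS, HORIZON_FORCED_TRIALS + n_free):
            choice = 0 if rng.random() < p1 else 1
            recs.append((r + 1, t + 1, cond, 0, choice + 1, rewardset.rewards[r, t, choice]))
    return pd.DataFrame(recs, columns=SESSION_COLUMNS)


def simulate_session(
    rewardset: RewardSet,
    params,
    learner_cfg: LearnerConfig | None = None,
    seed: int | np.random.Generator = 0,
    subject: int = 1,
    session: int = 1,
    n_trials: int | None = None,
) -> SessionData:
    """Simulate one subject's session on a fixed reward set.

    ``params`` must match the task (RestlessParams, TwoArmedParams or
    HorizonParams). ``n_trials`` optionally truncates each round (used by the
    optimality analysis, e.g. 50 choices in the Restless bandit).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    task = rewardset.task
    if task == TASK_RESTLESS:
        if not isinstance(params, RestlessParams):
            raise TypeError("Restless bandit requires RestlessParams")
        cfg = learner_cfg or restless_learner_config()
        trials = _simulate_restless(rewardset, params, cfg, rng, n_trials)
    elif task == TASK_TWOARMED:
        if not isinstance(params, TwoArmedParams):
            raise TypeError("Two-armed bandit requires TwoArmedParams")
        cfg = learner_cfg or twoarmed_learner_config()
        trials = _simulate_twoarmed(rewardset, params, cfg, rng, n_trials)
    elif task == TASK_HORIZON:
        if not isinstance(params, HorizonParams):
            raise TypeError("Horizon task requires HorizonParams")
        trials = _simulate_horizon(rewardset, params, rng)
    else:
        raise ValueError(f"unknown task id: {task!r}")
    return SessionData(subject=subject, session=session, task=task, trials=trials)


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

#: Improved-variant group scales: (task, parameter) -> (mean, sd, factor).
#: Means sit at the scale of group-level effects reported for these tasks;
#: sds default to half the group mean's magnitude.
DEFAULT_PARAMETER_SCALES: dict[tuple[str, str], tuple[float, float, str | None]] = {
    (TASK_HORIZON, "beta0_long"): (0.0, 0.3, None),
    (TASK_HORIZON, "w_value_long"): (3.62, 1.81, "value"),
    (TASK_HORIZON, "w_info_long"): (0.32, 0.16, "directed"),
    (TASK_TWOARMED, "beta0"): (0.0, 0.3, None),
    (TASK_TWOARMED, "w_value"): (0.13, 0.065, "value"),
    (TASK_TWOARMED, "w_directed"): (0.15, 0.075, "directed"),
    (TASK_RESTLESS, "tau"): (0.15, 0.075, "value"),
    (TASK_RESTLESS, "beta"): (-0.41, 0.205, "directed"),
}

TASKS = (TASK_HORIZON, TASK_TWOARMED, TASK_RESTLESS)


@dataclass
class CohortSpec:
    """Specification of the synthetic two-session cohort.

    True subject parameters follow a two-factor model: for a parameter with
    loading ``l`` on its factor, the standardized score is
    ``l * factor + sqrt(1 - l^2) * unique``, scaled by the group sd and
    shifted by the group mean. Session-2 standardized scores correlate
    ``rho`` with session 1. The default loading sqrt(0.7) leaves 30% of each
    parameter's group variance as unique noise.
    """

    n_subjects: int = 100
    parameter_scales: dict = field(
        default_factory=lambda: dict(DEFAULT_PARAMETER_SCALES)
    )
    factor_corr: float = 0.64
    loading: float = float(np.sqrt(0.7))
    rho: float = 0.7
    seed: int = 0
    tasks: tuple = TASKS

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [-1, 1]")
        if not (-1.0 <= self.factor_corr <= 1.0):
            raise ValueError("factor_corr must be in [-1, 1]")
        if not (0.0 <= self.loading <= 1.0):
            raise ValueError("loading must be in [0, 1]")


@dataclass
class CohortData:
    """Synthetic cohort with ground truth retained.

    ``true_params``: subject, session, task, parameter, value (long format).
    ``factor_scores``: subject, value_factor, directed_factor.
    ``sessions``: list of SessionData (all subjects x sessions x tasks).
    ``rewardsets``: (task, session) -> RewardSet (shared across subjects).
    """

    spec: CohortSpec
    true_params: pd.DataFrame
    factor_scores: pd.DataFrame
    sessions: list[SessionData]
    rewardsets: dict[tuple[str, int], RewardSet]

    def params_for(self, subject: int, session: int, task: str):
        sub = self.true_params
        sel = sub[
            (sub["subject"] == subject)
            & (sub["session"] == session)
            & (sub["task"] == task)
        ]
        d = dict(zip(sel["parameter"], sel["value"]))
        return build_params(task, d)


def build_params(task: str, values: dict):
    """Assemble a task's improved-variant params object from a name->value map."""
    if task == TASK_RESTLESS:
        return RestlessParams(tau=values["tau"], beta=values["beta"])
    if task == TASK_TWOARMED:
        return TwoArmedParams(
            beta0=values["beta0"],
            w_value=values["w_value"],
            w_directed=values["w_directed"],
        )
    if task == TASK_HORIZON:
        return HorizonParams(
            beta0_long=values["beta0_long"],
            w_value_long=values["w_value_long"],
            w_info_long=values["w_info_long"],
        )
    raise ValueError(f"unknown task id: {task!r}")


_PARAM_BOUNDS = {"tau": (0.0, 5.0)}  # inverse temperature must stay non-negative


def _draw_true_parameters(spec: CohortSpec, rng: np.random.Generator):
    n = spec.n_subjects
    r = spec.factor_corr
    cov = np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(cov)
    factors = rng.standard_normal((n, 2)) @ chol.T  # columns: value, directed
    factor_idx = {"value": 0, "directed": 1}

    rows = []
    for (task, name), (mean, sd, factor) in spec.parameter_scales.items():
        if task not in spec.tasks:
            continue
        unique1 = rng.standard_normal(n)
        fresh2 = rng.standard_normal(n)
        if factor is None:
            z1 = unique1
        else:
            lam = spec.loading
            z1 = lam * factors[:, factor_idx[factor]] + np.sqrt(1 - lam**2) * unique1
        z2 = spec.rho * z1 + np.sqrt(1 - spec.rho**2) * fresh2
        for session, z in ((1, z1), (2, z2)):
            vals = mean + sd * z
            if name in _PARAM_BOUNDS:
                lo, hi = _PARAM_BOUNDS[name]
                vals = np.clip(vals, lo + 1e-3, hi)
            for s in range(n):
                rows.append((s + 1, session, task, name, vals[s]))
    true_params = pd.DataFrame(
        rows, columns=["subject", "session", "task", "parameter", "value"]
    )
    factor_scores = pd.DataFrame(
        {
            "subject": np.arange(1, n + 1),
            "value_factor": factors[:, 0],
            "directed_factor": factors[:, 1],
        }
    )
    return true_params, factor_scores


def generate_synthetic_cohort(
    spec: CohortSpec, simulate: bool = True
) -> CohortData:
    """Generate the synthetic two-session cohort.

    One shared RewardSet per (task, session) for all subjects; session 1 and
    session 2 use different reward sets. With ``simulate=False`` only the
    ground-truth parameter draws are produced (used by analyses that operate
    on true parameters).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    true_params, factor_scores = _draw_true_parameters(spec, rng)

    rewardsets: dict[tuple[str, int], RewardSet] = {}
    for session in (1, 2):
        for task in spec.tasks:
            rewardsets[(task, session)] = rewardset_for_task(
                task, seed=int(rng.integers(2**31))
            )

    sessions: list[SessionData] = []
    cohort = CohortData(spec, true_params, factor_scores, sessions, rewardsets)
    if not simulate:
        return cohort

    learner_cfgs = {
        TASK_RESTLESS: restless_learner_config(),
        TASK_TWOARMED: twoarmed_learner_config(),
        TASK_HORIZON: None,
    }
    for subject in range(1, spec.n_subjects + 1):
        for session in (1, 2):
            for task in spec.tasks:
                params = cohort.params_for(subject, session, task)
                sessions.append(
                    simulate_session(
                        rewardsets[(task, session)],
                        params,
                        learner_cfgs[task],
                        seed=rng,
                        subject=subject,
                        session=session,
                    )
                )
    return cohort


def sessions_to_frame(sessions: list[SessionData]) -> pd.DataFrame:
    """Stack SessionData records into the long CSV schema."""
    frames = []
    for s in sessions:
        df = s.trials.copy()
        df.insert(0, "subject", s.subject)
        df.insert(1, "session", s.session)
        df.insert(2, "task", s.task)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
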