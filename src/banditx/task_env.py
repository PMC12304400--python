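"""Reward-structure construction for the three bandit tasks.

All three reward sets are pre-sampled once per (config, seed) pair and are
intended to be shared across simulated participants, mirroring a fixed
stimulus set. The three generators are:

* Restless bandit — four arms whose latent means follow a mean-reverting
  AR(1) random walk, ``mu[t+1] = lam * mu[t] + (1 - lam) * theta + eps``,
  with ``eps ~ N(0, innovation_sd**2)``; one round of 200 choices.
* Horizon task — two stable arms per round; 4 forced choices realizing an
  unequal [1,3] or equal [2,2] information condition, followed by 1 (short)
  or 6 (long) free choices; mean gaps drawn from a fixed multiset and fully
  counterbalanced across the horizon-by-information cells.
* Two-armed bandit — 30 rounds of 10 free choices; each arm independently
  stable or drifting (fully crossed), with the generating gap biased toward
  8 points and the per-round average gap capped at 15.

Presented rewards default to integers clipped to [1, 99] (slot-machine point
displays); latent means are kept at full precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TASK_RESTLESS = "restless"
TASK_HORIZON = "horizon"
TASK_TWOARMED = "twoarmed"

HORIZON_FORCED_TRIALS = 4
HORIZON_GAPS = (30.0, 20.0, 12.0, 8.0, 4.0)


@dataclass(frozen=True)
class RewardWalkConfig:
    """Mean-reverting random-walk configuration for the Restless bandit.

    ``decay_rate`` (lam) and ``decay_center`` (theta) parameterize the
    AR(1) pull toward the long-run center; ``innovation_sd`` is the
    per-trial diffusion noise of the latent means and ``reward_noise_sd``
    the observation noise added when a reward is presented.
    """

    decay_rate: float = 0.9836
    decay_center: float = 50.0
    innovation_sd: float = 2.8
    reward_noise_sd: float = 4.0
    n_arms: int = 4
    n_trials: int = 200
    initial_means: Sequence[float] | None = None
    min_best_arm_changes: int = 5
    max_best_run: int = 80
    round_rewards: bool = True

    def validate(self) -> None:
        if not (0.0 < self.decay_rate <= 1.0):
            raise ValueError(f"decay_rate must be in (0, 1], got {self.decay_rate}")
        if self.innovation_sd < 0 or self.reward_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.initial_means is not None and len(self.initial_means) != self.n_arms:
            raise ValueError("initial_means length must equal n_arms")


@dataclass(frozen=True)
class HorizonDesign:
    """Design of the Horizon task's fixed reward set.

    80 rounds fully cross horizon length (1 vs 6 free choices) and available
    information ([1,3] vs [2,2] forced allocation); each of the four cells
    uses the same multiset of absolute mean gaps so the cells are equally
    difficult, and the better side is counterbalanced so both arms are
    equally rewarding on grand average.
    """

    n_rounds: int = 80
    short_free: int = 1
    long_free: int = 6
    mean_differences: Sequence[float] = HORIZON_GAPS
    reward_noise_sd: float = 4.0
    center: float = 50.0
    round_rewards: bool = True

    def validate(self) -> None:
        if len(self.mean_differences) == 0:
            raise ValueError("mean_differences must not be empty")
        n_cell = self.n_rounds // 4
        if self.n_rounds % 4 != 0 or n_cell % len(self.mean_differences) != 0:
            raise ValueError(
                "n_rounds must split into 4 equal cells with each gap "
                f"appearing equally often; got n_rounds={self.n_rounds}"
            )
        if self.reward_noise_sd < 0:
            raise ValueError("reward_noise_sd must be >= 0")


@dataclass(frozen=True)
class TwoArmedDesign:
    """Design of the Two-armed bandit's fixed reward set."""

    n_rounds: int = 30
    trials_per_round: int = 10
    max_mean_diff: float = 15.0
    target_mean_diff: float = 8.0
    gap_sd: float = 2.0
    drift_sd: float = 2.0
    center: float = 50.0
    center_sd: float = 3.0
    reward_noise_sd: float = 4.0
    round_rewards: bool = True

    def validate(self) -> None:
        if self.max_mean_diff < 0:
            raise ValueError("max_mean_diff must be >= 0 (constraints infeasible)")
        if self.n_rounds < 4:
            raise ValueError("n_rounds must be >= 4 so all drift conditions occur")
        if self.trials_per_round < 1:
            raise ValueError("trials_per_round must be >= 1")
        if self.target_mean_diff > self.max_mean_diff:
            raise ValueError("target_mean_diff must not exceed max_mean_diff")


@dataclass
class RewardSet:
    """Pre-sampled latent means and realized rewards for one task.

    ``latent_means`` and ``rewards`` have shape (n_rounds, n_trials, n_arms).
    ``conditions`` has one row per round; its columns depend on the task
    (horizon/info/gap and the forced-arm schedule for the Horizon task,
    drift condition for the Two-armed bandit).
    """

    task: str
    latent_means: np.ndarray
    rewards: np.ndarray
    conditions: pd.DataFrame
    forced_arms: np.ndarray | None = None  # (n_rounds, 4), 0-based; Horizon only

    @property
    def n_rounds(self) -> int:
        return self.latent_means.shape[0]

    @property
    def n_trials(self) -> int:
        return self.latent_means.shape[1]

    @property
    def n_arms(self) -> int:
        return self.latent_means.shape[2]

    def validate(self) -> None:
        if self.latent_means.shape != self.rewards.shape:
            raise ValueError("latent_means and rewards shapes differ")
        if not np.all(np.isfinite(self.rewards)):
            raise ValueError("realized rewards must be finite")
        if len(self.conditions) != self.n_rounds:
            raise ValueError("conditions must have one row per round")

    def condition_label(self, round_index: int) -> str:
        row = self.conditions.iloc[round_index]
        if self.task == TASK_HORIZON:
            return f"{row['horizon']}|{row['info']}"
        if self.task == TASK_TWOARMED:
            return str(row["drift_condition"])
        return "restless"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (round, trial, arm)."""
        n_r, n_t, n_a = self.latent_means.shape
        rounds, trials, arms = np.meshgrid(
            np.arange(1, n_r + 1), np.arange(1, n_t + 1), np.arange(1, n_a + 1),
            indexing="ij",
        )
        conds = [self.condition_label(i) for i in range(n_r)]
        return pd.DataFrame(
            {
                "task": self.task,
                "round": rounds.ravel(),
                "trial": trials.ravel(),
                "arm": arms.ravel(),
                "latent_mean": self.latent_means.ravel(),
                "reward": self.rewards.ravel(),
                "condition": np.repeat(conds, n_t * n_a),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _present(rewards: np.ndarray, round_rewards: bool) -> np.ndarray:
    """Presented-reward transform: integer points clipped to [1, 99]."""
    if not round_rewards:
        return rewards
    return np.clip(np.rint(rewards), 1.0, 99.0)


def _best_arm_turnover_ok(means: np.ndarray, min_changes: int, max_run: int) -> bool:
    best = np.argmax(means, axis=1)
    changes = int(np.sum(best[1:] != best[:-1]))
    if changes < min_changes:
        return False
    # longest run of a single best arm
    run, longest = 1, 1
    for t in range(1, len(best)):
        run = run + 1 if best[t] == best[t - 1] else 1
        longest = max(longest, run)
    return longest <= max_run


def generate_restless_rewardset(
    cfg: RewardWalkConfig = RewardWalkConfig(), seed: int = 0, max_resamples: int = 1000
) -> RewardSet:
    """Sample the Restless bandit reward set (one 200-trial round, 4 arms).

    Re-samples the walk until the identity of the best arm changes at least
    ``cfg.min_best_arm_changes`` times and no arm stays best for more than
    ``cfg.max_best_run`` consecutive trials, so that exploration stays
    worthwhile throughout the round.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    lam, theta = cfg.decay_rate, cfg.decay_center
    stat_sd = (
        cfg.innovation_sd / np.sqrt(1.0 - lam**2) if lam < 1.0 else cfg.innovation_sd
    )
    for _ in range(max_resamples):
        if cfg.initial_means is not None:
            mu0 = np.asarray(cfg.initial_means, dtype=float)
        else:
            mu0 = theta + stat_sd * rng.standard_normal(cfg.n_arms)
        means = np.empty((cfg.n_trials, cfg.n_arms))
        means[0] = mu0
        innov = cfg.innovation_sd * rng.standard_normal((cfg.n_trials - 1, cfg.n_arms))
        for t in range(1, cfg.n_trials):
            means[t] = lam * means[t - 1] + (1.0 - lam) * theta + innov[t - 1]
        if cfg.innovation_sd == 0.0 or _best_arm_turnover_ok(
            means, cfg.min_best_arm_changes, cfg.max_best_run
        ):
            break
    else:
        raise RuntimeError("could not satisfy the best-arm turnover filter")
    noise = cfg.reward_noise_sd * rng.standard_normal(means.shape)
    rewards = _present(means + noise, cfg.round_rewards)
    rs = RewardSet(
        task=TASK_RESTLESS,
        latent_means=means[None, :, :],
        rewards=rewards[None, :, :],
        conditions=pd.DataFrame({"round": [1]}),
    )
    rs.validate()
    return rs


def generate_horizon_rewardset(
    design: HorizonDesign = HorizonDesign(), seed: int = 0
) -> RewardSet:
    """Construct the Horizon task reward set.

    Per horizon-by-information cell, each absolute mean gap appears equally
    often, with the side of the better arm and (in the unequal condition)
    the identity of the less-explored arm counterbalanced. Latent means are
    stable within a round, so both arms have exactly equal grand-mean latent
    reward across the full set.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    gaps = list(design.mean_differences)
    per_cell = design.n_rounds // 4
    reps = per_cell // len(gaps)

    rows = []
    for horizon in ("short", "long"):
        for info in ("13", "22"):
            k = 0
            for gap in gaps:
                for _ in range(reps):
                    better_side = k % 2  # counterbalance better arm's side
                    # unequal information: counterbalance which arm is rare
                    rare_arm = (k // 2) % 2
                    rows.append((horizon, info, gap, better_side, rare_arm))
                    k += 1
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    n_trials = HORIZON_FORCED_TRIALS + design.long_free
    n_r = design.n_rounds
    means = np.empty((n_r, n_trials, 2))
    forced = np.empty((n_r, HORIZON_FORCED_TRIALS), dtype=int)
    cond_rows = []
    for i, (horizon, info, gap, better_side, rare_arm) in enumerate(rows):
        mu = np.array([design.center + gap / 2.0, design.center - gap / 2.0])
        if better_side == 1:
            mu = mu[::-1]
        means[i] = mu[None, :]
        if info == "22":
            sched = np.array([0, 0, 1, 1])
        else:
            common = 1 - rare_arm
            sched = np.array([rare_arm] + [common] * 3)
        forced[i] = rng.permutation(sched)
        cond_rows.append(
            {
                "round": i + 1,
                "horizon": horizon,
                "info": info,
                "gap": gap,
                "better_arm": better_side + 1,
                "n_free": design.short_free if horizon == "short" else design.long_free,
            }
        )
    noise = design.reward_noise_sd * rng.standard_normal(means.shape)
    rewards = _present(means + noise, design.round_rewards)
    rs = RewardSet(
        task=TASK_HORIZON,
        latent_means=means,
        rewards=rewards,
        conditions=pd.DataFrame(cond_rows),
        forced_arms=forced,
    )
    rs.validate()
    return rs


_DRIFT_CONDITIONS = ("stable/stable", "stable/drift", "drift/stable", "drift/drift")


def generate_twoarmed_rewardset(
    design: TwoArmedDesign = TwoArmedDesign(), seed: int = 0, max_resamples: int = 1000
) -> RewardSet:
    """Construct the Two-armed bandit reward set.

    The four drift conditions (each arm stable or drifting, fully crossed)
    are allocated as evenly as the round count allows and shuffled. Each
    round's generating means are biased toward a ``target_mean_diff``-point
    gap; rounds are rejection-resampled until the average absolute latent
    gap over the round does not exceed ``max_mean_diff``.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    n_r, n_t = design.n_rounds, design.trials_per_round
    counts = [n_r // 4 + (1 if i < n_r % 4 else 0) for i in range(4)]
    conditions = [c for c, k in zip(_DRIFT_CONDITIONS, counts) for _ in range(k)]
    conditions = [conditions[i] for i in rng.permutation(n_r)]

    means = np.empty((n_r, n_t, 2))
    for i, cond in enumerate(conditions):
        drifting = [part == "drift" for part in cond.split("/")]
        for _ in range(max_resamples):
            center = design.center + design.center_sd * rng.standard_normal()
            gap = abs(design.target_mean_diff + design.gap_sd * rng.standard_normal())
            sign = rng.choice([-1.0, 1.0])
            mu0 = np.array([center + sign * gap / 2.0, center - sign * gap / 2.0])
            m = np.empty((n_t, 2))
            m[0] = mu0
            for t in range(1, n_t):
                step = np.where(
                    drifting, design.drift_sd * rng.standard_normal(2), 0.0
                )
                m[t] = m[t - 1] + step
            if np.mean(np.abs(m[:, 0] - m[:, 1])) <= design.max_mean_diff:
                means[i] = m
                break
        else:
            raise RuntimeError("could not satisfy the average mean-gap constraint")
    noise = design.reward_noise_sd * rng.standard_normal(means.shape)
    rewards = _present(means + noise, design.round_rewards)
    rs = RewardSet(
        task=TASK_TWOARMED,
        latent_means=means,
        rewards=rewards,
        conditions=pd.DataFrame(
            {"round": np.arange(1, n_r + 1), "drift_condition": conditions}
        ),
    )
    rs.validate()
    return rs


def rewardset_for_task(task: str, seed: int, **overrides) -> RewardSet:
    """Convenience dispatcher used by the cohort generator and the CLI."""
    if task == TASK_RESTLESS:
        return generate_restless_rewardset(
            dataclasses.replace(RewardWalkConfig(), **overrides), seed
        )
    if task == TASK_HORIZON:
        return generate_horizon_rewardset(
            dataclasses.replace(HorizonDesign(), **overrides), seed
        )
    if task == TASK_TWOARMED:
        return generate_twoarmed_rewardset(
            dataclasses.replace(TwoArmedDesign(), **overrides), seed
        )
    raise ValueError(f"unknown task id: {task!r}")
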