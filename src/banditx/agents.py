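"""Learning rules and choice models for the three bandit tasks.

Learning: a per-arm Kalman filter tracks the posterior mean ``E_j`` and
variance ``V_j`` of each arm's latent mean reward. On a trial where arm c is
chosen and reward r observed,

    K = (V_c + s_innov2) / (V_c + s_innov2 + s_noise2)          (Kalman gain)
    E_c <- E_c + K * (r - E_c)
    V_c <- (1 - K) * (V_c + s_innov2)

while unchosen arms keep their mean and diffuse, ``V_j <- V_j + s_innov2``.
For the Restless bandit only, the means additionally decay toward the
walk's center before the next decision, ``E_j <- lam * E_j + (1-lam) * C``.
The generative constants (innovation and noise variances, decay, priors)
are fixed to the task's generating values and are never fitted.

Choice: the Restless bandit uses a softmax over upper-confidence utilities
``tau * E_j + beta * sqrt(V_j + s_innov2)`` (tau = value-guided weight,
beta = directed-exploration bonus). The Horizon task and the Two-armed
bandit use a logistic regression on arm-difference predictors; the Horizon
task learns by plain averaging of the four forced-choice rewards rather
than by Kalman filtering.

Model variants: the "original" Two-armed model carries a third,
random-exploration (Thompson) predictor ``(E1-E2)/sqrt(V1+V2)``; the
"improved" variant drops it. The original Horizon model fits separate
weights in the short and the long horizon and scores exploration as the
long-minus-short difference; the improved variant keeps only the
long-horizon weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

Variant = Literal["original", "improved"]

VARIANTS = ("original", "improved")


@dataclass(frozen=True)
class LearnerConfig:
    """Fixed generative parameters of the Kalman learner (never fitted)."""

    innov_var: float
    noise_var: float
    decay_rate: float = 1.0
    decay_center: float = 50.0
    prior_mean: float = 50.0
    prior_var: float = 100.0
    apply_diffusion_to_means: bool = False

    def validate(self) -> None:
        if self.innov_var < 0 or self.noise_var < 0 or self.prior_var < 0:
            raise ValueError("variances must be >= 0")
        if not (0.0 < self.decay_rate <= 1.0):
            raise ValueError("decay_rate must be in (0, 1]")


def restless_learner_config(
    innov_var: float = 7.84,
    noise_var: float = 16.0,
    decay_rate: float = 0.9836,
    decay_center: float = 50.0,
) -> LearnerConfig:
    """Restless-bandit learner at the generating values.

    The prior mean equals the walk's decay center and the prior variance the
    walk's stationary variance ``v_innov / (1 - lam^2)``.
    """
    prior_var = innov_var / (1.0 - decay_rate**2) if decay_rate < 1.0 else innov_var
    return LearnerConfig(
        innov_var=innov_var,
        noise_var=noise_var,
        decay_rate=decay_rate,
        decay_center=decay_center,
        prior_mean=decay_center,
        prior_var=prior_var,
        apply_diffusion_to_means=True,
    )


def twoarmed_learner_config(
    innov_var: float = 4.0,
    noise_var: float = 16.0,
    trials_per_round: int = 10,
) -> LearnerConfig:
    """Two-armed-bandit learner at the generating values.

    No mean decay; the prior variance is the generating drift variance
    accumulated over one round.
    """
    return LearnerConfig(
        innov_var=innov_var,
        noise_var=noise_var,
        decay_rate=1.0,
        prior_mean=50.0,
        prior_var=innov_var * trials_per_round,
        apply_diffusion_to_means=False,
    )


@dataclass
class KalmanBelief:
    """Posterior mean and variance per arm."""

    means: np.ndarray
    variances: np.ndarray

    @classmethod
    def prior(cls, n_arms: int, cfg: LearnerConfig) -> "KalmanBelief":
        return cls(
            means=np.full(n_arms, cfg.prior_mean, dtype=float),
            variances=np.full(n_arms, cfg.prior_var, dtype=float),
        )

    @property
    def n_arms(self) -> int:
        return len(self.means)

    def copy(self) -> "KalmanBelief":
        return KalmanBelief(self.means.copy(), self.variances.copy())


def kalman_update(
    belief: KalmanBelief, chosen_arm: int, reward: float, cfg: LearnerConfig
) -> KalmanBelief:
    """One Kalman-filter step after observing ``reward`` on ``chosen_arm``.

    Unchosen arms keep their mean and have their variance inflated by the
    innovation variance (their latent mean keeps drifting unobserved).
    """
    cfg.validate()
    if not (0 <= chosen_arm < belief.n_arms):
        raise IndexError(f"chosen_arm {chosen_arm} out of range")
    means = belief.means.copy()
    variances = belief.variances + cfg.innov_var
    prior_var = variances[chosen_arm]
    gain = prior_var / (prior_var + cfg.noise_var) if prior_var > 0 or cfg.noise_var > 0 else 1.0
    means[chosen_arm] += gain * (reward - means[chosen_arm])
    variances = variances.copy()
    variances[chosen_arm] = (1.0 - gain) * prior_var
    return KalmanBelief(means, variances)


def diffusion_prior_step(belief: KalmanBelief, cfg: LearnerConfig) -> KalmanBelief:
    """Propagate the priors through the walk's diffusion (Restless only).

    Means decay toward the walk center, ``E <- lam * E + (1-lam) * C``, and
    variances decay as ``V <- lam^2 * V``. Together with the ``+ s_innov2``
    inflation inside the Kalman update this is exactly the one-step prior
    propagation of the Kalman filter for the mean-reverting AR(1) walk
    (prior variance ``lam^2 * P + s_innov2``); without the decay the
    posterior variance of never-chosen arms would grow without bound
    instead of converging to the walk's stationary variance.
    """
    if not cfg.apply_diffusion_to_means:
        raise ValueError("diffusion step requested for a task without mean decay")
    means = cfg.decay_rate * belief.means + (1.0 - cfg.decay_rate) * cfg.decay_center
    return KalmanBelief(means, cfg.decay_rate**2 * belief.variances)


#: Root-mean-square latent mean gap of the default Horizon design
#: (gaps 30, 20, 12, 8, 4, balanced in sign). The choice model's value
#: predictor is value_diff / HORIZON_VALUE_SCALE, putting the value weight
#: on a dimensionless scale comparable across conditions and tasks — the
#: same motivation as dividing the information predictor by 4.
HORIZON_VALUE_SCALE = float(np.sqrt(np.mean(np.square([30.0, 20.0, 12.0, 8.0, 4.0]))))


@dataclass(frozen=True)
class HorizonFeatures:
    """First-free-choice predictors in the Horizon task."""

    value_diff: float  # E1(t=5) - E2(t=5), reward units
    info_diff: float  # (I1 - I2) / 4, in {-0.5, 0, +0.5}
    horizon: str = "long"

    def predictors(self, value_scale: float = HORIZON_VALUE_SCALE) -> tuple[float, float]:
        """(standardized value difference, information difference)."""
        return (self.value_diff / value_scale, self.info_diff)


def horizon_features(forced_arms, forced_rewards, horizon: str = "long") -> HorizonFeatures:
    """Features of the first free choice from the four forced trials.

    ``forced_arms`` uses 1-based arm indices. Each arm must have been forced
    at least once; the per-arm expected value is the plain average of its
    observed rewards and the information difference is (count1 - count2)/4.
    """
    arms = np.asarray(forced_arms, dtype=int)
    rewards = np.asarray(forced_rewards, dtype=float)
    if arms.shape != (4,) or rewards.shape != (4,):
        raise ValueError("exactly 4 forced trials are required")
    counts = np.array([np.sum(arms == 1), np.sum(arms == 2)])
    if np.any(counts == 0):
        raise ValueError("each arm must be sampled at least once in the forced trials")
    e1 = rewards[arms == 1].mean()
    e2 = rewards[arms == 2].mean()
    return HorizonFeatures(
        value_diff=float(e1 - e2),
        info_diff=float(counts[0] - counts[1]) / 4.0,
        horizon=horizon,
    )


@dataclass(frozen=True)
class RestlessParams:
    """Free parameters of the Restless-bandit choice model."""

    tau: float  # value-guided: inverse temperature on posterior means
    beta: float  # directed: weight on posterior uncertainty (may be negative)

    def to_vector(self) -> np.ndarray:
        return np.array([self.tau, self.beta])

    @classmethod
    def names(cls) -> list[str]:
        return ["tau", "beta"]


@dataclass(frozen=True)
class TwoArmedParams:
    """Free parameters of the Two-armed-bandit logistic choice model.

    ``w_random`` is present only in the original three-predictor variant;
    the improved variant sets it to None.
    """

    beta0: float
    w_value: float
    w_directed: float
    w_random: float | None = None

    @property
    def variant(self) -> Variant:
        return "original" if self.w_random is not None else "improved"

    def to_vector(self) -> np.ndarray:
        v = [self.beta0, self.w_value, self.w_directed]
        if self.w_random is not None:
            v.append(self.w_random)
        return np.array(v)

    @classmethod
    def names(cls, variant: Variant = "improved") -> list[str]:
        base = ["beta0", "w_value", "w_directed"]
        return base + ["w_random"] if variant == "original" else base


@dataclass(frozen=True)
class HorizonParams:
    """Free parameters of the Horizon-task logistic choice model.

    The improved variant carries long-horizon weights only. The original
    variant additionally fits short-horizon weights; its strategy scores are
    the long-minus-short weight differences.
    """

    beta0_long: float
    w_value_long: float
    w_info_long: float
    beta0_short: float | None = None
    w_value_short: float | None = None
    w_info_short: float | None = None

    @property
    def variant(self) -> Variant:
        return "improved" if self.beta0_short is None else "original"

    @property
    def delta_w_value(self) -> float:
        if self.variant != "original":
            raise ValueError("difference scores exist only for the original variant")
        return self.w_value_long - self.w_value_short

    @property
    def delta_w_info(self) -> float:
        if self.variant != "original":
            raise ValueError("difference scores exist only for the original variant")
        return self.w_info_long - self.w_info_short

    def weights(self, horizon: str) -> tuple[float, float, float]:
        if horizon == "long" or self.variant == "improved":
            return (self.beta0_long, self.w_value_long, self.w_info_long)
        return (self.beta0_short, self.w_value_short, self.w_info_short)

    @classmethod
    def names(cls, variant: Variant = "improved") -> list[str]:
        long = ["beta0_long", "w_value_long", "w_info_long"]
        if variant == "improved":
            return long
        return long + ["beta0_short", "w_value_short", "w_info_short"]


def ucb_utilities(belief: KalmanBelief, cfg: LearnerConfig) -> np.ndarray:
    """Per-arm (mean, uncertainty-bonus) feature pairs, shape (n_arms, 2)."""
    bonus = np.sqrt(belief.variances + cfg.innov_var)
    return np.column_stack([belief.means, bonus])


def softmax(utilities: np.ndarray) -> np.ndarray:
    u = utilities - np.max(utilities)
    e = np.exp(u)
    return e / e.sum()


def ucb_choice_probs(
    belief: KalmanBelief, params: RestlessParams, cfg: LearnerConfig
) -> np.ndarray:
    """Softmax over ``tau * E_j + beta * sqrt(V_j + s_innov2)``.

    Max-subtraction makes the result invariant to adding a constant to all
    utilities and guards against overflow.
    """
    feats = ucb_utilities(belief, cfg)
    return softmax(params.tau * feats[:, 0] + params.beta * feats[:, 1])


def twoarmed_predictors(belief: KalmanBelief, variant: Variant = "improved") -> tuple:
    """Arm-difference predictors of the Two-armed logistic model.

    Returns (value_diff, directed) for the improved variant and
    (value_diff, directed, random) for the original one, where
    random = (E1 - E2) / sqrt(V1 + V2) is the Thompson-sampling predictor.
    """
    if belief.n_arms != 2:
        raise ValueError("two-armed predictors require exactly 2 arms")
    e1, e2 = belief.means
    v1, v2 = belief.variances
    value_diff = e1 - e2
    directed = np.sqrt(v1) - np.sqrt(v2)
    if variant == "improved":
        return (value_diff, directed)
    total = v1 + v2
    if total <= 0.0:
        raise ZeroDivisionError(
            "random-exploration predictor undefined: zero total variance"
        )
    return (value_diff, directed, value_diff / np.sqrt(total))


def logistic_choice_prob(predictors, params) -> float:
    """P(choose arm 1) = logistic(beta0 + beta . x).

    ``params`` is a TwoArmedParams, a HorizonParams (long-horizon weights),
    or a plain (beta0, *weights) sequence matching the predictor count.
    """
    x = np.asarray(predictors, dtype=float)
    if isinstance(params, TwoArmedParams):
        vec = params.to_vector()
    elif isinstance(params, HorizonParams):
        vec = np.array(params.weights("long"))
    else:
        vec = np.asarray(params, dtype=float)
    if len(vec) != len(x) + 1:
        raise ValueError(
            f"parameter count {len(vec)} does not match predictor count {len(x)} + intercept"
        )
    eta = vec[0] + float(vec[1:] @ x)
    # numerically stable logistic
    if eta >= 0:
        return 1.0 / (1.0 + np.exp(-eta))
    z = np.exp(eta)
    return z / (1.0 + z)
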