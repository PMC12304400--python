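"""Per-subject maximum-likelihood and hierarchical estimation.

Because the learner constants (innovation/noise variances, decay, priors)
are fixed to the generating values and never fitted, replaying a session's
observed choices and rewards through the Kalman filter yields a belief
trajectory that does not depend on the free choice parameters. Every
model's likelihood therefore reduces to a generalized linear form —
logistic regression for the Horizon and Two-armed tasks, a softmax with
utilities linear in (tau, beta) for the Restless bandit — which is convex
and cheap to optimize. ``fit_mle`` still uses bounded multi-start
optimization as a safeguard.

``fit_hierarchical`` implements partial pooling by parametric empirical
Bayes: independent Normal group distributions per parameter, subject-level
MAP estimates under the current group prior (Laplace posterior variances),
and EM updates of the group mean and sd. This realizes the hierarchical
contract — shrinkage of extreme subjects toward the group mean and a 95%
interval for the group-level mean — with a deterministic optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from banditx.agents import (
    HorizonParams,
    KalmanBelief,
    LearnerConfig,
    RestlessParams,
    TwoArmedParams,
    horizon_features,
    kalman_update,
    diffusion_prior_step,
    restless_learner_config,
    twoarmed_learner_config,
)
from banditx.simulate import SessionData
from banditx.task_env import (
    HORIZON_FORCED_TRIALS,
    TASK_HORIZON,
    TASK_RESTLESS,
    TASK_TWOARMED,
)

WEIGHT_BOUND = 50.0
TAU_BOUNDS = (0.0, 5.0)
BETA_BOUNDS = (-20.0, 20.0)


@dataclass
class FitResult:
    """Point estimates for one subject/session/task."""

    params: dict
    loglik: float
    converged: bool
    n_observations: int
    variant: str
    task: str
    se: dict | None = None
    n_floored: int = 0  # choice probabilities floored during optimization

    def wald_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        if self.se is None or name not in self.se:
            raise ValueError(f"no standard error available for {name!r}")
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return (self.params[name] - z * self.se[name], self.params[name] + z * self.se[name])


# ---------------------------------------------------------------------------
# Design construction: replay sessions into GLM design matrices
# ---------------------------------------------------------------------------


def _replay_restless(session: SessionData, cfg: LearnerConfig):
    """Belief-feature trajectory (means, uncertainty bonuses) and choices."""
    trials = session.trials.sort_values("trial")
    choices = trials["choice"].to_numpy(dtype=int) - 1
    rewards = trials["reward"].to_numpy(dtype=float)
    n = len(trials)
    n_arms = int(choices.max()) + 1 if n else 0
    n_arms = max(n_arms, 4) if session.task == TASK_RESTLESS else n_arms
    belief = KalmanBelief.prior(n_arms, cfg)
    E = np.empty((n, n_arms))
    B = np.empty((n, n_arms))
    for t in range(n):
        E[t] = belief.means
        B[t] = np.sqrt(belief.variances + cfg.innov_var)
        belief = kalman_update(belief, choices[t], rewards[t], cfg)
        belief = diffusion_prior_step(belief, cfg)
    return E, B, choices


def _twoarmed_design(session: SessionData, cfg: LearnerConfig, variant: str):
    """Logistic design: intercept + (value, directed[, random]) predictors."""
    xs, ys = [], []
    for _, grp in session.trials.groupby("round", sort=True):
        grp = grp.sort_values("trial")
        belief = KalmanBelief.prior(2, cfg)
        for choice, reward in zip(grp["choice"], grp["reward"]):
            e1, e2 = belief.means
            v1, v2 = belief.variances
            value = e1 - e2
            directed = np.sqrt(v1) - np.sqrt(v2)
            if variant == "original":
                xs.append((value, directed, value / np.sqrt(v1 + v2)))
            else:
                xs.append((value, directed))
            ys.append(1.0 if choice == 1 else 0.0)
            belief = kalman_update(belief, int(choice) - 1, float(reward), cfg)
    X = np.column_stack([np.ones(len(ys)), np.asarray(xs)])
    return X, np.asarray(ys)


def _horizon_design(session: SessionData, variant: str):
    """First-free-choice logistic designs, keyed by horizon condition.

    The improved variant uses only the long-horizon rounds; the original
    variant fits short and long rounds with separate weights.
    """
    designs = {"short": ([], []), "long": ([], [])}
    for _, grp in session.trials.groupby("round", sort=True):
        grp = grp.sort_values("trial")
        forced = grp[grp["forced"] == 1]
        free = grp[grp["forced"] == 0]
        if len(forced) != HORIZON_FORCED_TRIALS or len(free) == 0:
            raise ValueError("horizon rounds need 4 forced trials and >= 1 free trial")
        horizon = str(grp["condition"].iloc[0]).split("|")[0]
        feats = horizon_features(
            forced["choice"].to_numpy(), forced["reward"].to_numpy(), horizon
        )
        first_free = free.sort_values("trial").iloc[0]
        designs[horizon][0].append(feats.predictors())
        designs[horizon][1].append(1.0 if first_free["choice"] == 1 else 0.0)
    out = {}
    for horizon, (xs, ys) in designs.items():
        if variant == "improved" and horizon == "short":
            continue
        if xs:
            X = np.column_stack([np.ones(len(ys)), np.asarray(xs)])
            out[horizon] = (X, np.asarray(ys))
    return out


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------


def _logistic_nll_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    eta = X @ theta
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    return nll, X.T @ (p - y)


def _restless_nll_grad(theta: np.ndarray, E: np.ndarray, B: np.ndarray, chosen: np.ndarray):
    tau, beta = theta
    U = tau * E + beta * B
    m = U.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(U - m).sum(axis=1))
    idx = np.arange(len(chosen))
    nll = float(np.sum(lse - U[idx, chosen]))
    P = np.exp(U - lse[:, None])
    g_tau = float(np.sum(P * E) - E[idx, chosen].sum())
    g_beta = float(np.sum(P * B) - B[idx, chosen].sum())
    return nll, np.array([g_tau, g_beta])


def negative_log_likelihood(
    session: SessionData,
    params,
    learner_cfg: LearnerConfig | None = None,
    variant: str | None = None,
) -> float:
    """Sum of -log choice probability over the variant's usable free choices.

    Forced trials contribute belief updates only. A non-finite likelihood
    (possible only under degenerate parameters) raises rather than being
    silently clipped.
    """
    task = session.task
    if task == TASK_RESTLESS:
        if not isinstance(params, RestlessParams):
            raise TypeError("Restless bandit requires RestlessParams")
        cfg = learner_cfg or restless_learner_config()
        E, B, chosen = _replay_restless(session, cfg)
        nll, _ = _restless_nll_grad(params.to_vector(), E, B, chosen)
    elif task == TASK_TWOARMED:
        if not isinstance(params, TwoArmedParams):
            raise TypeError("Two-armed bandit requires TwoArmedParams")
        cfg = learner_cfg or twoarmed_learner_config()
        X, y = _twoarmed_design(session, cfg, params.variant)
        nll, _ = _logistic_nll_grad(params.to_vector(), X, y)
    elif task == TASK_HORIZON:
        if not isinstance(params, HorizonParams):
            raise TypeError("Horizon task requires HorizonParams")
        v = variant or params.variant
        designs = _horizon_design(session, v)
        nll = 0.0
        for horizon, (X, y) in designs.items():
            theta = np.array(params.weights(horizon))
            part, _ = _logistic_nll_grad(theta, X, y)
            nll += part
    else:
        raise ValueError(f"unknown task id: {task!r}")
    if not np.isfinite(nll):
        raise FloatingPointError("likelihood is not finite (degenerate parameters)")
    return nll


# ---------------------------------------------------------------------------
# MLE
# ---------------------------------------------------------------------------


def _numeric_hessian(fun, theta: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Finite-difference Hessian from the analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps
        _, g_plus = fun(theta + step)
        _, g_minus = fun(theta - step)
        H[:, j] = (g_plus - g_minus) / (2 * eps)
    return (H + H.T) / 2.0


def _multistart_minimize(fun, bounds, n_starts: int, rng: np.random.Generator):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    any_converged = False
    starts = [np.zeros(len(bounds))]
    starts[0] = np.clip(starts[0], lo, hi)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(lo + (hi - lo) * rng.random(len(bounds)))
    for x0 in starts:
        res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    return best, any_converged


def _fit_glm(fun, bounds, names, rng, n_starts, compute_se):
    best, converged = _multistart_minimize(fun, bounds, n_starts, rng)
    params = dict(zip(names, best.x))
    se = None
    if compute_se:
        H = _numeric_hessian(fun, best.x)
        with np.errstate(all="ignore"):
            try:
                cov = np.linalg.inv(H)
                d = np.diag(cov)
                se = {
                    n: (float(np.sqrt(v)) if v > 0 else np.nan)
                    for n, v in zip(names, d)
                }
            except np.linalg.LinAlgError:
                se = {n: np.nan for n in names}
    return params, float(-best.fun), converged, se


def fit_mle(
    session: SessionData,
    variant: str = "improved",
    learner_cfg: LearnerConfig | None = None,
    n_starts: int = 5,
    seed: int = 0,
    compute_se: bool = True,
) -> FitResult:
    """Bounded multi-start maximum-likelihood fit of one session."""
    rng = np.random.default_rng(seed)
    task = session.task
    if task == TASK_RESTLESS:
        cfg = learner_cfg or restless_learner_config()
        E, B, chosen = _replay_restless(session, cfg)
        params, ll, conv, se = _fit_glm(
            lambda th: _restless_nll_grad(th, E, B, chosen),
            [TAU_BOUNDS, BETA_BOUNDS],
            RestlessParams.names(),
            rng,
            n_starts,
            compute_se,
        )
        n_obs = len(chosen)
    elif task == TASK_TWOARMED:
        cfg = learner_cfg or twoarmed_learner_config()
        X, y = _twoarmed_design(session, cfg, variant)
        names = TwoArmedParams.names(variant)
        bounds = [(-WEIGHT_BOUND, WEIGHT_BOUND)] * len(names)
        params, ll, conv, se = _fit_glm(
            lambda th: _logistic_nll_grad(th, X, y), bounds, names, rng, n_starts, compute_se
        )
        n_obs = len(y)
    elif task == TASK_HORIZON:
        designs = _horizon_design(session, variant)
        params, se, ll, n_obs, conv = {}, {}, 0.0, 0, True
        for horizon, (X, y) in sorted(designs.items()):
            names = [f"beta0_{horizon}", f"w_value_{horizon}", f"w_info_{horizon}"]
            bounds = [(-WEIGHT_BOUND, WEIGHT_BOUND)] * 3
            p, part_ll, part_conv, part_se = _fit_glm(
                lambda th: _logistic_nll_grad(th, X, y), bounds, names, rng, n_starts, compute_se
            )
            params.update(p)
            if part_se:
                se.update(part_se)
            ll += part_ll
            n_obs += len(y)
            conv = conv and part_conv
        se = se or None
        if variant == "original":
            params["delta_w_value"] = params["w_value_long"] - params["w_value_short"]
            params["delta_w_info"] = params["w_info_long"] - params["w_info_short"]
    else:
        raise ValueError(f"unknown task id: {task!r}")
    return FitResult(
        params=params,
        loglik=ll,
        converged=conv,
        n_observations=n_obs,
        variant=variant,
        task=task,
        se=se if compute_se else None,
    )


def fit_params_table(
    sessions: list[SessionData],
    variant: str = "improved",
    learner_cfg: LearnerConfig | None = None,
    seed: int = 0,
    n_starts: int = 5,
    method: str = "mle",
) -> pd.DataFrame:
    """Fit a collection of sessions into a long parameter table.

    ``method="mle"`` fits each session independently;
    ``method="hierarchical"`` partially pools subjects within each
    (task, session) group, which tames the boundary outliers that
    independent fits produce on nearly deterministic sessions.
    """
    rows = []
    if method == "hierarchical":
        groups: dict[tuple, list[SessionData]] = {}
        for s in sessions:
            groups.setdefault((s.task, s.session), []).append(s)
        for gi, ((task, session), group) in enumerate(sorted(groups.items())):
            hf = fit_hierarchical(group, variant, seed=seed + gi, learner_cfg=learner_cfg)
            for _, row in hf.subject_estimates.iterrows():
                rows.append(
                    (
                        int(row["subject"]), session, task, variant,
                        row["parameter"], row["value"], hf.converged,
                    )
                )
            if variant == "original" and task == TASK_HORIZON:
                wide = hf.subject_estimates.pivot(
                    index="subject", columns="parameter", values="value"
                )
                for score, a, b in (
                    ("delta_w_value", "w_value_long", "w_value_short"),
                    ("delta_w_info", "w_info_long", "w_info_short"),
                ):
                    for subject, value in (wide[a] - wide[b]).items():
                        rows.append(
                            (int(subject), session, task, variant, score, value, hf.converged)
                        )
    else:
        for i, s in enumerate(sessions):
            fr = fit_mle(
                s, variant, learner_cfg, n_starts=n_starts, seed=seed + i, compute_se=False
            )
            for name, value in fr.params.items():
                rows.append(
                    (s.subject, s.session, s.task, variant, name, value, fr.converged)
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "session", "task", "variant", "parameter", "value", "converged"],
    )


# ---------------------------------------------------------------------------
# Hierarchical (parametric empirical Bayes)
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalConfig:
    max_iter: int = 100
    tol: float = 1e-4
    min_group_sd: float = 1e-3
    init_group_sd: float | None = None


@dataclass
class HierarchicalFit:
    """Partial-pooling fit: group means with 95% intervals, shrunken subjects."""

    group_mean: dict
    group_sd: dict
    ci_low: dict
    ci_high: dict
    subject_estimates: pd.DataFrame  # subject, parameter, value
    converged: bool
    n_iter: int
    variant: str
    task: str


def _session_objective(session: SessionData, variant: str, learner_cfg):
    """Return (names, bounds, fun(theta)->(nll, grad)) for one session."""
    task = session.task
    if task == TASK_RESTLESS:
        cfg = learner_cfg or restless_learner_config()
        E, B, chosen = _replay_restless(session, cfg)
        return (
            RestlessParams.names(),
            [TAU_BOUNDS, BETA_BOUNDS],
            lambda th: _restless_nll_grad(th, E, B, chosen),
        )
    if task == TASK_TWOARMED:
        cfg = learner_cfg or twoarmed_learner_config()
        X, y = _twoarmed_design(session, cfg, variant)
        names = TwoArmedParams.names(variant)
        return (
            names,
            [(-WEIGHT_BOUND, WEIGHT_BOUND)] * len(names),
            lambda th: _logistic_nll_grad(th, X, y),
        )
    if task == TASK_HORIZON:
        designs = _horizon_design(session, variant)
        horizons = sorted(designs.keys())
        names, blocks = [], []
        for h in horizons:
            names += [f"beta0_{h}", f"w_value_{h}", f"w_info_{h}"]
            blocks.append(designs[h])

        def fun(th):
            nll, grads = 0.0, []
            for k, (X, y) in enumerate(blocks):
                part, g = _logistic_nll_grad(th[3 * k : 3 * k + 3], X, y)
                nll += part
                grads.append(g)
            return nll, np.concatenate(grads)

        return names, [(-WEIGHT_BOUND, WEIGHT_BOUND)] * len(names), fun
    raise ValueError(f"unknown task id: {task!r}")


def fit_hierarchical(
    sessions: list[SessionData],
    variant: str = "improved",
    prior_config: HierarchicalConfig | None = None,
    seed: int = 0,
    learner_cfg: LearnerConfig | None = None,
) -> HierarchicalFit:
    """Empirical-Bayes hierarchical fit with independent Normal group priors.

    Alternates subject-level MAP estimation under the current group prior
    with EM updates of the group mean and sd; the sd update includes each
    subject's Laplace posterior variance so the group sd does not collapse
    onto the spread of the point estimates. The reported 95% interval is for
    the group-level mean.
    """
    if len(sessions) < 2:
        raise ValueError("hierarchical fitting requires >= 2 subjects")
    cfg = prior_config or HierarchicalConfig()
    tasks = {s.task for s in sessions}
    if len(tasks) != 1:
        raise ValueError("all sessions must be from the same task")
    task = tasks.pop()

    objectives = [_session_objective(s, variant, learner_cfg) for s in sessions]
    names, bounds = objectives[0][0], objectives[0][1]
    k = len(names)
    n = len(sessions)

    # initialize from per-subject MLEs
    rng = np.random.default_rng(seed)
    theta = np.empty((n, k))
    curv = np.empty((n, k))  # diagonal NLL curvature at the current estimate
    for i, (_, bds, fun) in enumerate(objectives):
        best, _ = _multistart_minimize(fun, bds, 3, rng)
        theta[i] = best.x
        curv[i] = np.clip(np.diag(_numeric_hessian(fun, best.x)), 1e-8, None)

    mu = theta.mean(axis=0)
    if cfg.init_group_sd is not None:
        sd = np.full(k, cfg.init_group_sd)
    else:
        sd = np.clip(theta.std(axis=0, ddof=1), cfg.min_group_sd, None)

    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        prec = 1.0 / sd**2
        for i, (_, bds, fun) in enumerate(objectives):

            def pen_fun(th, fun=fun):
                nll, g = fun(th)
                resid = (th - mu) * prec
                return nll + 0.5 * float(((th - mu) ** 2 * prec).sum()), g + resid

            res = minimize(pen_fun, theta[i], jac=True, method="L-BFGS-B", bounds=bds)
            theta[i] = res.x
            curv[i] = np.clip(
                np.diag(_numeric_hessian(objectives[i][2], theta[i])), 1e-8, None
            )
        post_var = 1.0 / (curv + prec[None, :])
        new_mu = theta.mean(axis=0)
        new_sd = np.sqrt(
            np.clip(
                ((theta - new_mu) ** 2 + post_var).mean(axis=0),
                cfg.min_group_sd**2,
                None,
            )
        )
        if np.max(np.abs(new_mu - mu)) < cfg.tol and np.max(np.abs(new_sd - sd)) < cfg.tol:
            mu, sd = new_mu, new_sd
            converged = True
            break
        mu, sd = new_mu, new_sd
    if not converged:
        warnings.warn("hierarchical EM did not reach tolerance; results are approximate")

    half = 1.959963984540054 * sd / np.sqrt(n)
    est_rows = [
        (sessions[i].subject, names[j], theta[i, j]) for i in range(n) for j in range(k)
    ]
    return HierarchicalFit(
        group_mean=dict(zip(names, mu)),
        group_sd=dict(zip(names, sd)),
        ci_low=dict(zip(names, mu - half)),
        ci_high=dict(zip(names, mu + half)),
        subject_estimates=pd.DataFrame(est_rows, columns=["subject", "parameter", "value"]),
        converged=converged,
        n_iter=it,
        variant=variant,
        task=task,
    )
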