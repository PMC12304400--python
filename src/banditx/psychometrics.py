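"""Model-free task measures, inclusion checks, reliability, and validity.

Test–retest reliability uses the two-way mixed, single-measure intraclass
correlation in its consistency form, ICC3(C,1) = (MS_S - MS_E) /
(MS_S + (k-1) MS_E), and its absolute-agreement form ICC3(A,1), which
additionally penalizes mean differences between sessions through the
session mean square. Convergent validity is a matrix of pairwise-complete
Pearson correlations of the same construct's measures across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from banditx.simulate import SessionData
from banditx.task_env import RewardSet, TASK_HORIZON


@dataclass
class ICCEstimate:
    """Two-way mixed single-measure ICCs for an n-subject x k-session table."""

    icc_consistency: float  # ICC3(C,1)
    icc_agreement: float  # ICC3(A,1)
    n_subjects: int
    n_sessions: int
    degenerate: bool = False  # zero between-subject variance


def switch_probability(session: SessionData) -> float:
    """Proportion of eligible free-choice pairs where the chosen arm changed.

    Eligible pairs are consecutive free choices within the same round;
    cross-round pairs and forced trials are excluded.
    """
    switches = 0
    pairs = 0
    for _, grp in session.trials.groupby("round", sort=True):
        free = grp[grp["forced"] == 0].sort_values("trial")["choice"].to_numpy()
        if len(free) >= 2:
            switches += int(np.sum(free[1:] != free[:-1]))
            pairs += len(free) - 1
    if pairs == 0:
        raise ValueError("no eligible consecutive free-choice pairs")
    return switches / pairs


def p_optimal(session: SessionData, rewardset: RewardSet) -> float:
    """Proportion of free choices selecting an arm with the maximal latent
    mean on that trial; ties count as optimal."""
    free = session.free_trials()
    if len(free) == 0:
        raise ValueError("no free choices in session")
    hits = 0
    for _, row in free.iterrows():
        mu = rewardset.latent_means[int(row["round"]) - 1, int(row["trial"]) - 1]
        hits += int(mu[int(row["choice"]) - 1] >= mu.max() - 1e-12)
    return hits / len(free)


def chance_inclusion_threshold(
    n_trials: int, n_arms: int, percentile: float = 0.95
) -> int:
    """Smallest correct count k with Binomial(n, 1/n_arms) CDF >= percentile.

    Participants scoring at or below chance-level performance (below this
    threshold) are excluded from analysis.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must be in (0, 1)")
    return int(binom.ppf(percentile, n_trials, 1.0 / n_arms))


def icc(two_session_values, definition: str | None = None) -> ICCEstimate:
    """Two-way mixed single-measure ICCs from an (n_subjects, k) value table.

    Row/column/error mean squares come from the standard two-way ANOVA
    decomposition with one observation per cell. Zero between-subject
    variance makes the ratio undefined; the estimate is then flagged
    ``degenerate`` with NaN coefficients.
    """
    X = np.asarray(two_session_values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("expected an (n_subjects, k>=2) array of values")
    if np.isnan(X).any():
        keep = ~np.isnan(X).any(axis=1)
        X = X[keep]
    n, k = X.shape
    if n < 3:
        raise ValueError("ICC requires >= 3 complete subjects")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    denom_c = ms_rows + (k - 1) * ms_err
    if denom_c <= 0 or ss_rows <= 1e-300:
        return ICCEstimate(np.nan, np.nan, n, k, degenerate=True)
    icc_c = (ms_rows - ms_err) / denom_c
    denom_a = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    icc_a = (ms_rows - ms_err) / denom_a if denom_a > 0 else np.nan
    est = ICCEstimate(float(icc_c), float(icc_a), n, k)
    if definition == "C1":
        return est
    return est


def measure_table(
    sessions: list[SessionData],
    rewardsets: dict | None = None,
    params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format per subject x session x task measure table.

    Includes switch probability and, when reward sets are supplied,
    p(optimal); fitted-parameter rows are appended when ``params`` (the long
    table from ``fit_params_table``) is given.
    """
    rows = []
    for s in sessions:
        rows.append((s.subject, s.session, s.task, "p_switch", switch_probability(s)))
        if rewardsets is not None:
            rs = rewardsets[(s.task, s.session)]
            rows.append((s.subject, s.session, s.task, "p_optimal", p_optimal(s, rs)))
    out = pd.DataFrame(rows, columns=["subject", "session", "task", "measure", "value"])
    if params is not None:
        p = params.rename(columns={"parameter": "measure"})[
            ["subject", "session", "task", "measure", "value"]
        ]
        out = pd.concat([out, p], ignore_index=True)
    return out


def session_pair_table(measures: pd.DataFrame, task: str, measure: str) -> np.ndarray:
    """Pivot one measure into an (n_subjects, 2) session-pair array."""
    sel = measures[(measures["task"] == task) & (measures["measure"] == measure)]
    wide = sel.pivot_table(index="subject", columns="session", values="value")
    wide = wide.dropna()
    if wide.shape[1] != 2:
        raise ValueError(f"measure {measure!r} on task {task!r} lacks two sessions")
    return wide.to_numpy()


def convergent_matrix(
    measures: pd.DataFrame, measure_keys: list[tuple[str, str]], session: int = 1
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix across tasks.

    ``measure_keys`` is a list of (task, measure) pairs; the result is a
    symmetric matrix with unit diagonal indexed by "task:measure" labels.
    Constant columns yield NaN entries.
    """
    cols = {}
    sel = measures[measures["session"] == session]
    for task, measure in measure_keys:
        sub = sel[(sel["task"] == task) & (sel["measure"] == measure)]
        cols[f"{task}:{measure}"] = sub.set_index("subject")["value"]
    wide = pd.DataFrame(cols)
    if wide.dropna().shape[0] < 3:
        raise ValueError("need >= 3 complete subjects per measure pair")
    corr = wide.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr
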