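# Methods

`banditx` implements a complete measurement pipeline for individual
differences in exploration strategies on three few-armed bandit paradigms:
the Horizon task, a Two-armed bandit with stable/drifting arms, and a
four-armed Restless bandit. This note documents the models, the synthetic
cohort that stands in for a real test–retest study, the numerical choices,
and the known limitations.

## Task environments

All reward sets are pre-sampled once per seed and shared across simulated
participants, mimicking a fixed stimulus set.

**Restless bandit.** One round of 200 choices among 4 arms. Latent means
follow a mean-reverting AR(1) walk,

    mu[t+1] = lam * mu[t] + (1 - lam) * theta + eps,   eps ~ N(0, sigma_innov^2)

with lam = 0.9836, theta = 50, sigma_innov = 2.8; observed rewards add
N(0, 4) noise. Walks are rejection-sampled until the identity of the best
arm changes at least 5 times and no arm stays best for more than 80
consecutive trials, so exploration remains worthwhile. Initial means are
drawn from the walk's stationary distribution N(theta, sigma_innov^2 /
(1 - lam^2)); the walk is stationary thereafter.

**Horizon task.** 80 rounds with two stable arms. Four forced choices
realize an unequal ([1,3]) or equal ([2,2]) information condition, followed
by 1 (short) or 6 (long) free choices. Horizon length and information are
fully crossed (20 rounds per cell); each cell carries the same multiset of
absolute mean gaps {30, 20, 12, 8, 4} (each four times), with the better
arm's side and, in unequal rounds, the identity of the rarely-forced arm
counterbalanced — so both arms are exactly equally rewarding in latent
grand mean. Reward noise sd defaults to 4.

**Two-armed bandit.** 30 rounds of 10 free choices. Each arm is
independently stable or drifting (sd 2 per step), fully crossed and
allocated as evenly as 30 rounds allow. Generating means are biased toward
an 8-point gap (gap ~ |N(8, 2)|, random sign, round center ~ N(50, 3));
rounds are resampled until the average absolute latent gap stays ≤ 15.

Presented rewards are rounded to integers and clipped to [1, 99]
(slot-machine point displays); latent means keep full precision. Both
behaviors are configurable.

## Learning models

The Two-armed and Restless learners are per-arm Kalman filters with all
generative constants fixed (never fitted). On choosing arm c and observing
reward r:

    K   = (V_c + s_i) / (V_c + s_i + s_n)
    E_c <- E_c + K (r - E_c);   V_c <- (1 - K)(V_c + s_i)

with innovation variance s_i and noise variance s_n; unchosen arms diffuse,
V_j <- V_j + s_i. For the Restless bandit only, priors are propagated
through the walk before the next decision:

    E_j <- lam E_j + (1 - lam) C;   V_j <- lam^2 V_j

The variance decay together with the +s_i inflation inside the update is
exactly the Kalman prior propagation for the AR(1) walk (prior variance
lam^2 P + s_i): the posterior variance of a never-chosen arm converges to
the walk's stationary variance rather than growing without bound. Without
it, simulated agents with a negative uncertainty weight become almost
deterministic avoiders and the likelihood degenerates, which would make
parameter recovery impossible at realistic parameter scales.

Defaults: Restless s_i = 7.84, s_n = 16, E_0 = 50, V_0 = s_i/(1 - lam^2) ≈
241 (stationary); Two-armed s_i = 4 (the generating drift variance),
s_n = 16, E_0 = 50, V_0 = 40 (drift variance accumulated over one round),
no mean decay. All configurable.

The Horizon learner is deliberately simpler: each arm's expected value at
the first free choice is the plain average of its forced-choice rewards,
and I_j counts how often arm j was forced.

## Choice models

**Restless:** softmax over upper-confidence utilities,
P(c = j) ∝ exp(tau E_j + beta sqrt(V_j + s_i)), with tau the value-guided
weight (inverse temperature) and beta the directed-exploration bonus
(negative values = uncertainty avoidance). Max-subtraction makes the
softmax shift-invariant and overflow-safe.

**Two-armed:** logistic regression on arm differences,
eta = b0 + w_v (E_1 - E_2) + w_d (sqrt(V_1) - sqrt(V_2)) [+ w_r (E_1 -
E_2)/sqrt(V_1 + V_2)]. The third, random-exploration (Thompson) predictor
is present only in the *original* variant; the *improved* variant drops it
because it is nearly collinear with the value predictor and induces a
severe estimation trade-off (visible in the recovery cross-correlations).
b0 is a side bias.

**Horizon:** logistic regression on the first free choice,
eta = b0 + w_v (E_1 - E_2)/s_E + w_i (I_1 - I_2)/4. The information
predictor is scaled to levels {-0.5, 0, +0.5}; the value difference is
standardized by the design's root-mean-square latent gap s_E =
sqrt(mean(30², 20², 12², 8², 4²)) ≈ 17.46, which makes the value weight
dimensionless and comparable across tasks (group-scale value weights of
order 3–5 would imply impossible determinism on a raw reward-point
predictor). The *original* variant fits separate weights per horizon and
scores each strategy as the long-minus-short weight difference; the
*improved* variant keeps only the long-horizon weights.

Simulation convention: within a Horizon round, the features are frozen at
their first-free-choice values for all free choices; the fitted models use
only the first free choice, so this convention does not affect estimation.

## Fitting

Because the learner constants are fixed, replaying a session's observed
choices/rewards yields a belief trajectory independent of the free
parameters — every likelihood is a convex GLM (logistic, or softmax with
linear utilities). `fit_mle` uses bounded L-BFGS-B with analytic gradients
from 5 starts drawn uniformly in the bounds (|weights| ≤ 50, tau ∈ [0, 5],
beta ∈ [-20, 20]); standard errors come from a finite-difference Hessian.

`fit_hierarchical` is parametric empirical Bayes: independent Normal group
distributions per parameter, subject-level MAP estimates under the current
group prior, Laplace (curvature-based) posterior variances, and EM updates
of the group mean and sd (the sd update includes the posterior variances so
it does not collapse onto the spread of point estimates). The reported 95%
interval is for the group-level mean, mu ± 1.96 sd/sqrt(n). This realizes
the hierarchical contract — shrinkage of outlier subjects and calibrated
group intervals — with a deterministic optimizer. Sessions simulated from
strongly uncertainty-avoiding parameters are nearly deterministic and their
unpenalized MLEs diverge to the bounds; shrinkage is what makes recovery
correlations meaningful, the same motivation the hierarchical-modeling
literature gives for empirical choice data.

## Synthetic cohort

`generate_synthetic_cohort` emulates a two-session (different fixed reward
sets per session), three-task study. Subject-level true parameters follow a
two-factor structure (value-guided, directed): with loading l (default
sqrt(0.7), leaving 30% unique variance) the standardized score is
l·factor + sqrt(1-l²)·unique, scaled by the group sd and shifted by the
group mean. Factor scores correlate 0.64 by default. Session-2 standardized
scores correlate rho (default 0.7) with session 1; rho = 1 reproduces
session-1 parameters exactly. Group means sit at the scale of group-level
effects reported for these paradigms (Horizon value ≈ 3.62, info ≈ 0.32; Two-armed
value ≈ 0.13, directed ≈ 0.15; Restless tau ≈ 0.15, beta ≈ -0.41), with
sds at half the mean's magnitude and tau clipped positive.

What the generator does *not* emulate: practice effects, attention lapses,
strategy switches mid-session, heavy-tailed or skewed parameter
distributions, and any questionnaire or working-memory structure. Passing
tests therefore show that the pipeline measures what the models generate —
not that human data satisfy the models.

## Psychometrics

Test–retest reliability uses two-way mixed single-measure intraclass
correlations from the standard ANOVA decomposition: consistency
ICC3(C,1) = (MS_S - MS_E)/(MS_S + (k-1) MS_E), and absolute agreement
ICC3(A,1), which adds the session mean square ((k/n)(MS_K - MS_E)) to the
denominator and so also penalizes session mean shifts. Degenerate tables
(zero between-subject variance) are flagged, not silently returned.
Convergent validity is pairwise-complete Pearson correlation across tasks,
session 1 by default. Model-free measures: within-round switch probability
(free choices only) and p(optimal) (ties count as optimal). The inclusion
threshold is the smallest correct count whose Binomial(n, 1/arms) CDF
reaches the 95th percentile of chance.

## Recovery, optimality, information value

Parameter recovery simulates each subject on the fixed reward set from its
generative parameters, re-fits (MLE or hierarchical), and reports the full
generative-by-fitted cross-correlation matrix: the diagonal is recovery,
off-diagonal entries expose estimation trade-offs (the original Two-armed
model shows a large value↔random entry that the improved model removes).

The optimality grids simulate truncated sessions (10 choices per round in
Horizon/Two-armed, 50 in the Restless bandit; defaults configurable) per
(value weight, directed weight) cell on the fixed reward set, reusing the
same per-repetition seeds in every cell so cell contrasts are paired.
Because a single fixed Horizon set carries a small set-specific asymmetry,
the null check for the directed weight averages the paired contrast over
reward-set replicates and uses the across-set standard error.

The information-value analysis asks, for each unequal-information long
round, whether adding the forced fifth observation of the less-explored arm
flips the sample-mean best-arm estimate, and whether the flip improves
accuracy against the latent means. On the default (noise sd 4) reward sets
the flip fraction is typically zero; it rises with reward noise.

## Latent factor models

`fit_cfa` is a normal-theory maximum-likelihood CFA on the sample
covariance (ML, 1/n convention): Sigma = Lambda Phi Lambda' + Psi, factors
identified by unit variance, free factor correlations, and optional
residual covariances for same-task indicator pairs (absorbing
fitting-induced trade-offs). The discrepancy log|Sigma| + tr(S Sigma^-1) -
log|S| - p is minimized by L-BFGS from several jittered starts; chi-square
= n·F, CFI against the diagonal-covariance baseline, RMSEA from the
noncentrality estimate, BIC from the full normal log-likelihood. Negative
residual variances (Heywood cases) and |standardized loadings| > 1 are
flagged inadmissible and excluded from model comparison by default. Model
comparison uses the BIC approximation BF_AB = exp((BIC_B - BIC_A)/2).

Caveat: with free same-task residual covariances the factor correlation is
identified only through cross-task cross-factor covariances and is weakly
determined in small samples; on true-parameter cohorts (no trade-offs to
absorb) the factor correlation is read from the model without residual
pairs.

## Problem sizes and defaults used in the shipped analyses

Recovery runs use 200 subjects per task/variant; reliability cohorts 100
subjects; the latent comparison 175 subjects (a typical
final-sample size for test-retest studies of this kind); optimality grids default to 21×21 cells × 200 repetitions,
with coarser grids in the demo pipeline. The full pipeline
(`banditx run-all`) defaults to a 60-subject cohort with reduced recovery
and optimality settings so a complete run stays in the minutes range; its
fit and recovery stages use the hierarchical estimator by default
(configurable to MLE). At that sample size the two-factor CFA on fitted
parameters regularly produces an inadmissible (Heywood) solution — the
shrunken indicators are almost purely common variance — in which case the
Bayes-factor comparison is reported as unavailable rather than computed
from an inadmissible fit.

## Known limitations

- The hierarchical fitter is empirical Bayes with Laplace posteriors, not
  full MCMC; posterior skew (e.g. tau near its positivity bound) is
  approximated by a symmetric Gaussian.
- Horizon free choices after the first are simulated from frozen features;
  model-free Horizon measures (switch probability) should be interpreted
  under that convention.
- Recovery of the Restless value weight is capped near r ≈ 0.8 at the
  default generative scales: subjects in the strongly uncertainty-avoiding
  tail produce nearly deterministic sessions that carry little information
  about tau, and their estimates shrink to the group mean.
- The CFA assumes multivariate normal indicators and complete data; there
  is no FIML for missingness and no mean structure.
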