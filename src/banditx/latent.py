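"""Confirmatory factor models of latent exploration strategies.

Normal-theory maximum-likelihood CFA fitted directly on the sample
covariance matrix: the implied covariance is

    Sigma(theta) = Lambda Phi Lambda' + Psi

with free loadings Lambda (factors identified by unit variance, so Phi has
a unit diagonal and free factor correlations), diagonal residual variances,
and optional residual covariances for indicator pairs estimated from the
same task (absorbing fitting-induced parameter trade-offs). The ML
discrepancy F = log|Sigma| + tr(S Sigma^-1) - log|S| - p is minimized with
a quasi-Newton optimizer from several jittered starts; chi-square = n * F.
Fit indices follow the usual conventions: CFI against the independence
baseline, RMSEA from the noncentrality estimate, BIC from the full normal
log-likelihood. Inadmissible solutions (negative residual variances,
Heywood cases) are flagged, never silently accepted.

Model comparison uses the BIC approximation to the Bayes factor,
BF_AB = exp((BIC_B - BIC_A) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize


@dataclass
class CFAModelSpec:
    """Measurement-model specification.

    ``loadings`` maps each factor name to its indicator list; every
    indicator must load on at least one factor. ``residual_pairs`` lists
    indicator pairs whose residuals are allowed to covary (same-task
    parameter pairs).
    """

    loadings: dict[str, list[str]]
    residual_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def indicators(self) -> list[str]:
        seen: list[str] = []
        for items in self.loadings.values():
            for v in items:
                if v not in seen:
                    seen.append(v)
        return seen

    @property
    def factors(self) -> list[str]:
        return list(self.loadings.keys())

    def validate(self) -> None:
        if not self.loadings:
            raise ValueError("model needs at least one factor")
        for a, b in self.residual_pairs:
            if a == b:
                raise ValueError("residual pairs must reference distinct indicators")
            if a not in self.indicators or b not in self.indicators:
                raise ValueError(f"residual pair ({a}, {b}) references unknown indicator")

    def n_free(self) -> int:
        n_load = sum(len(v) for v in self.loadings.values())
        k = len(self.factors)
        return n_load + k * (k - 1) // 2 + len(self.indicators) + len(self.residual_pairs)


@dataclass
class CFAFit:
    """Fitted measurement model with standard fit indices."""

    spec: CFAModelSpec
    loadings: pd.DataFrame  # indicator x factor, unstandardized
    std_loadings: pd.DataFrame
    residual_variances: dict
    residual_covariances: dict
    factor_corr: pd.DataFrame
    loglik: float
    n: int
    df: int
    chi2: float
    cfi: float
    rmsea: float
    bic: float
    converged: bool
    heywood: bool
    implied_cov: pd.DataFrame

    @property
    def admissible(self) -> bool:
        return self.converged and not self.heywood


def _pack_sigma(theta, spec, idx):
    p = len(idx["indicators"])
    k = len(idx["factors"])
    Lam = np.zeros((p, k))
    for (i, j), pos in idx["load_pos"].items():
        Lam[i, j] = theta[pos]
    Phi = np.eye(k)
    for (a, b), pos in idx["phi_pos"].items():
        Phi[a, b] = Phi[b, a] = theta[pos]
    Psi = np.diag([theta[pos] for pos in idx["psi_pos"]])
    for (a, b), pos in idx["rescov_pos"].items():
        Psi[a, b] = Psi[b, a] = theta[pos]
    return Lam @ Phi @ Lam.T + Psi, Lam, Phi, Psi


def _index_spec(spec: CFAModelSpec):
    indicators = spec.indicators
    factors = spec.factors
    ind_pos = {v: i for i, v in enumerate(indicators)}
    pos = 0
    load_pos = {}
    for j, f in enumerate(factors):
        for v in spec.loadings[f]:
            load_pos[(ind_pos[v], j)] = pos
            pos += 1
    phi_pos = {}
    for a in range(len(factors)):
        for b in range(a + 1, len(factors)):
            phi_pos[(a, b)] = pos
            pos += 1
    psi_pos = list(range(pos, pos + len(indicators)))
    pos += len(indicators)
    rescov_pos = {}
    for a, b in spec.residual_pairs:
        rescov_pos[(ind_pos[a], ind_pos[b])] = pos
        pos += 1
    return {
        "indicators": indicators,
        "factors": factors,
        "load_pos": load_pos,
        "phi_pos": phi_pos,
        "psi_pos": psi_pos,
        "rescov_pos": rescov_pos,
        "n_free": pos,
    }


def _start_values(S, idx, rng):
    theta = np.zeros(idx["n_free"])
    sd = np.sqrt(np.diag(S))
    for (i, _), pos in idx["load_pos"].items():
        theta[pos] = 0.7 * sd[i] * (1 + 0.1 * rng.standard_normal())
    for pos in idx["phi_pos"].values():
        theta[pos] = 0.3 + 0.1 * rng.standard_normal()
    for i, pos in enumerate(idx["psi_pos"]):
        theta[pos] = 0.5 * S[i, i] * (1 + 0.1 * rng.standard_normal())
    return theta


def fit_cfa(
    data=None,
    spec: CFAModelSpec = None,
    cov: np.ndarray | pd.DataFrame = None,
    n: int | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> CFAFit:
    """Fit a CFA by normal-theory maximum likelihood.

    Provide either ``data`` (observations x indicators DataFrame) or a
    sample covariance ``cov`` with its sample size ``n``. The sample
    covariance uses the ML (1/n) convention throughout, so chi-square is
    ``n * F_ML``.
    """
    if spec is None:
        raise ValueError("a CFAModelSpec is required")
    spec.validate()
    indicators = spec.indicators
    if data is not None:
        data = pd.DataFrame(data)[indicators]
        n = len(data)
        X = data.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        S = (Xc.T @ Xc) / n
    else:
        if cov is None or n is None:
            raise ValueError("need either data or (cov, n)")
        if isinstance(cov, pd.DataFrame):
            cov = cov.loc[indicators, indicators].to_numpy()
        S = np.asarray(cov, dtype=float)
    p = len(indicators)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance must be positive definite")
    idx = _index_spec(spec)
    df = p * (p + 1) // 2 - idx["n_free"]
    if df < 0:
        raise ValueError("model has more free parameters than covariance moments")

    def discrepancy(theta):
        Sigma, *_ = _pack_sigma(theta, spec, idx)
        s, logdet = np.linalg.slogdet(Sigma)
        if s <= 0:
            return 1e10
        try:
            Sinv = np.linalg.solve(Sigma, S)
        except np.linalg.LinAlgError:
            return 1e10
        return logdet + np.trace(Sinv) - logdet_S - p

    rng = np.random.default_rng(seed)
    best, converged = None, False
    for _ in range(n_starts):
        theta0 = _start_values(S, idx, rng)
        res = minimize(discrepancy, theta0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    theta = best.x
    F = max(float(best.fun), 0.0)
    Sigma, Lam, Phi, Psi = _pack_sigma(theta, spec, idx)

    chi2 = n * F
    # independence baseline: diagonal covariance
    F_base = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_base = n * F_base
    df_base = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, num, np.finfo(float).tiny)
    cfi = 1.0 - num / den if df_base > 0 else 1.0
    rmsea = float(np.sqrt(num / (df * n))) if df > 0 else 0.0

    loglik = -0.5 * n * (p * np.log(2 * np.pi) + float(np.linalg.slogdet(Sigma)[1])
                         + float(np.trace(np.linalg.solve(Sigma, S))))
    bic = -2.0 * loglik + idx["n_free"] * np.log(n)

    with np.errstate(invalid="ignore"):
        sd_sigma = np.sqrt(np.diag(Sigma))
        fac_sd = np.sqrt(np.diag(Phi))
        std_lam = Lam * fac_sd[None, :] / sd_sigma[:, None]
    heywood = bool(np.any(np.diag(Psi) < 0) or np.any(np.abs(std_lam) > 1.0 + 1e-6))

    factors = spec.factors
    return CFAFit(
        spec=spec,
        loadings=pd.DataFrame(Lam, index=indicators, columns=factors),
        std_loadings=pd.DataFrame(std_lam, index=indicators, columns=factors),
        residual_variances={v: float(Psi[i, i]) for i, v in enumerate(indicators)},
        residual_covariances={
            (a, b): float(theta[pos]) for (a, b), pos in zip(spec.residual_pairs, idx["rescov_pos"].values())
        },
        factor_corr=pd.DataFrame(Phi, index=factors, columns=factors),
        loglik=float(loglik),
        n=int(n),
        df=int(df),
        chi2=float(chi2),
        cfi=float(cfi),
        rmsea=float(rmsea),
        bic=float(bic),
        converged=converged,
        heywood=heywood,
        implied_cov=pd.DataFrame(Sigma, index=indicators, columns=indicators),
    )


def compare_models_bf(fit_a: CFAFit, fit_b: CFAFit) -> float:
    """BIC-approximate Bayes factor for model A over model B.

    BF_AB = exp((BIC_B - BIC_A) / 2); values > 1 favor A. Both fits must be
    on the same data (equal sample sizes are enforced).
    """
    if fit_a.n != fit_b.n:
        raise ValueError("models were fitted to different sample sizes")
    return float(np.exp(np.clip((fit_b.bic - fit_a.bic) / 2.0, -700, 700)))


def exploration_measurement_specs(residual_pairs=True) -> dict[str, CFAModelSpec]:
    """Canonical model specs for the six exploration indicators.

    Indicators are named "task:parameter" with the improved-variant
    parameters; the two-factor model maps value-guided and directed
    indicators to separate correlated factors, the one-factor model loads
    all six on a single factor. Residual correlations connect the two
    parameters estimated from the same task.
    """
    value = ["horizon:w_value_long", "twoarmed:w_value", "restless:tau"]
    directed = ["horizon:w_info_long", "twoarmed:w_directed", "restless:beta"]
    pairs = (
        [(v, d) for v, d in zip(value, directed)] if residual_pairs else []
    )
    return {
        "two_factor": CFAModelSpec(
            loadings={"value": value, "directed": directed}, residual_pairs=pairs
        ),
        "one_factor": CFAModelSpec(
            loadings={"exploration": value + directed}, residual_pairs=pairs
        ),
    }
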