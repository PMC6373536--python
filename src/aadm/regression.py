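"""Accuracy and reaction-time regression models.

Accuracy is modelled at trial level as Bernoulli correctness with a
logit link, fitted by generalised estimating equations (GEE) with an
exchangeable working correlation over participants and robust (sandwich)
standard errors; predictors are sum-coded so main effects and
interactions read like ANOVA terms.

RT moderation by questionnaire traits uses an ex-Gaussian response
distribution (Gaussian convolved with exponential; parameters mu, sigma,
tau). The Gaussian mean mu is a linear function of treatment-coded
expression x response x participant-gender x covariate terms plus fixed
per-participant intercept offsets, with sigma and tau shared; fitting is
maximum likelihood with fully analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "sum_code",
    "sum_design",
    "GEEFit",
    "fit_gee_binomial",
    "exgauss_logpdf",
    "exgauss_density",
    "ExGaussianFit",
    "fit_exgauss_ml",
    "scale_2sd",
    "fit_exgauss_regression",
]

ACCURACY_FACTORS = (
    "expression",
    "required_response",
    "face_gender",
    "participant_gender",
)


def sum_code(values) -> np.ndarray:
    """Map a 2-level factor to +1/-1 (first level alphabetically is +1)."""
    values = np.asarray(values)
    levels = sorted(pd.unique(values))
    if len(levels) != 2:
        raise ValueError(f"sum coding requires exactly 2 levels, got {levels}")
    return np.where(values == levels[0], 1.0, -1.0)


def sum_design(
    table: pd.DataFrame, factors: tuple[str, ...] = ACCURACY_FACTORS
) -> pd.DataFrame:
    """Sum-coded design columns for all main effects and interactions.

    Interaction columns are elementwise products of the main-effect
    columns, so on a balanced factorial design all columns are mutually
    orthogonal.
    """
    mains = {f: sum_code(table[f]) for f in factors}
    cols: dict[str, np.ndarray] = {}
    for r in range(1, len(factors) + 1):
        for term in combinations(factors, r):
            cols[" x ".join(term)] = np.prod([mains[f] for f in term], axis=0)
    return pd.DataFrame(cols, index=table.index)


@dataclass
class GEEFit:
    """Binomial GEE result with robust covariance for Wald contrasts."""

    coefficients: pd.DataFrame  # name, estimate, robust_se, z, p
    alpha: float  # exchangeable working correlation
    n_clusters: int
    converged: bool
    params: np.ndarray = field(repr=False)
    robust_cov: np.ndarray = field(repr=False)

    def wald_contrast(self, weights: dict[str, float]) -> tuple[float, float, float]:
        """z-test of a linear combination of coefficients.

        Returns (estimate, z, p). Names not in ``weights`` get weight 0.
        """
        names = list(self.coefficients["name"])
        w = np.array([weights.get(n, 0.0) for n in names])
        unknown = set(weights) - set(names)
        if unknown:
            raise KeyError(f"unknown coefficients: {sorted(unknown)}")
        est = float(w @ self.params)
        se = float(np.sqrt(w @ self.robust_cov @ w))
        z = est / se
        return est, z, float(2.0 * stats.norm.sf(abs(z)))


def fit_gee_binomial(
    trials: pd.DataFrame,
    factors: tuple[str, ...] = ACCURACY_FACTORS,
    cluster: str = "participant_id",
) -> GEEFit:
    """Trial-level logistic GEE for correctness, exchangeable clusters.

    All sum-coded main effects and interactions of ``factors`` enter one
    model (the ANOVA-like specification); standard errors are sandwich
    estimates robust to the working-correlation choice.
    """
    import statsmodels.api as sm

    if trials[cluster].nunique() < 2:
        raise ValueError("need at least 2 clusters")
    y = trials["correct"].astype(float).to_numpy()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    X = sum_design(trials, factors)
    X.insert(0, "intercept", 1.0)
    model = sm.GEE(
        y,
        X.to_numpy(),
        groups=trials[cluster].to_numpy(),
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    res = model.fit(maxiter=100, ctol=1e-8)
    se = np.sqrt(np.diag(res.cov_params()))
    zvals = res.params / se
    table = pd.DataFrame(
        {
            "name": list(X.columns),
            "estimate": res.params,
            "robust_se": se,
            "z": zvals,
            "p": 2.0 * stats.norm.sf(np.abs(zvals)),
        }
    )
    return GEEFit(
        coefficients=table,
        alpha=float(np.atleast_1d(model.cov_struct.dep_params)[0]),
        n_clusters=int(trials[cluster].nunique()),
        converged=bool(res.converged),
        params=np.asarray(res.params),
        robust_cov=np.asarray(res.cov_params()),
    )


def exgauss_logpdf(t, mu, sigma, tau) -> np.ndarray:
    """Log density of the ex-Gaussian distribution, stable in log space.

    ``log f(t) = -log tau + (mu - t)/tau + sigma^2/(2 tau^2)
    + log Phi((t - mu)/sigma - sigma/tau)``.
    """
    if np.any(np.asarray(sigma) <= 0) or np.any(np.asarray(tau) <= 0):
        raise ValueError("sigma and tau must be positive")
    t = np.asarray(t, dtype=float)
    z = (t - mu) / sigma - sigma / tau
    return (
        -np.log(tau)
        + (mu - t) / tau
        + sigma * sigma / (2.0 * tau * tau)
        + special.log_ndtr(z)
    )


def exgauss_density(t, mu, sigma, tau) -> np.ndarray:
    """Ex-Gaussian density (Gaussian-exponential convolution)."""
    return np.exp(exgauss_logpdf(t, mu, sigma, tau))


@dataclass
class ExGaussianFit:
    """Maximum-likelihood ex-Gaussian fit, optionally with a mu regression."""

    mu: float
    sigma: float
    tau: float
    loglik: float
    converged: bool
    coefficients: pd.DataFrame | None = None


def _moment_start(x: np.ndarray) -> tuple[float, float, float]:
    m, v = x.mean(), x.var(ddof=1)
    skew = stats.skew(x, bias=False)
    tau = max((max(skew, 0.05) * v**1.5 / 2.0) ** (1.0 / 3.0), 1e-3)
    sigma = np.sqrt(max(v - tau * tau, 0.05 * v))
    return m - tau, sigma, tau


def _mu_gradients(t, mu, sigma, tau):
    """Per-observation d(logf)/d(mu, sigma, tau)."""
    z = (t - mu) / sigma - sigma / tau
    ratio = np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))
    dmu = 1.0 / tau - ratio / sigma
    dsigma = sigma / tau**2 + ratio * (-(t - mu) / sigma**2 - 1.0 / tau)
    dtau = (
        -1.0 / tau
        - (mu - t) / tau**2
        - sigma**2 / tau**3
        + ratio * sigma / tau**2
    )
    return dmu, dsigma, dtau


def _fit_exgauss_design(
    t: np.ndarray, X: np.ndarray, beta0: np.ndarray, sigma0: float, tau0: float
):
    """Maximise the ex-Gaussian likelihood with mu = X beta, shared sigma/tau."""

    def unpack(theta):
        return theta[:-2], np.exp(theta[-2]), np.exp(theta[-1])

    def negloglik_grad(theta):
        beta, sigma, tau = unpack(theta)
        mu = X @ beta
        ll = exgauss_logpdf(t, mu, sigma, tau)
        dmu, dsigma, dtau = _mu_gradients(t, mu, sigma, tau)
        grad = np.concatenate(
            [X.T @ dmu, [sigma * dsigma.sum(), tau * dtau.sum()]]
        )
        return -ll.sum(), -grad

    theta0 = np.concatenate([beta0, [np.log(sigma0), np.log(tau0)]])
    res = optimize.minimize(
        negloglik_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta, sigma, tau = unpack(res.x)
    return beta, sigma, tau, -res.fun, bool(res.success), res.x, negloglik_grad


def fit_exgauss_ml(rts_s) -> ExGaussianFit:
    """Maximum-likelihood (mu, sigma, tau) for a sample of RTs in seconds."""
    x = np.asarray(rts_s, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if x.var(ddof=1) <= 0:
        raise ValueError("degenerate (zero-variance) sample")
    mu0, sigma0, tau0 = _moment_start(x)
    X = np.ones((x.size, 1))
    beta, sigma, tau, ll, ok, _, _ = _fit_exgauss_design(
        x, X, np.array([mu0]), sigma0, tau0
    )
    return ExGaussianFit(
        mu=float(beta[0]), sigma=float(sigma), tau=float(tau), loglik=float(ll),
        converged=ok,
    )


def scale_2sd(x) -> np.ndarray:
    """Mean-centre and divide by twice the SD (result has SD 0.5)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-SD covariate cannot be scaled")
    return (x - x.mean()) / (2.0 * sd)


def _treatment_design(
    trials: pd.DataFrame, covariate_z: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded 4-way factorial with the scaled covariate.

    Reference levels: angry, push, male; the covariate enters as its
    2-SD-scaled value. Interaction columns are products. Terms constant
    within a participant (female, cov, female x cov) are absorbed by the
    per-participant intercept offsets and therefore excluded.
    """
    base = {
        "happy": (trials["expression"] == "happy").to_numpy(float),
        "pull": (trials["required_response"] == "pull").to_numpy(float),
        "female": (trials["participant_gender"] == "female").to_numpy(float),
        "cov": covariate_z,
    }
    between = {"female", "cov"}
    names, cols = ["intercept"], [np.ones(len(trials))]
    keys = list(base)
    for r in range(1, 5):
        for term in combinations(keys, r):
            if set(term) <= between:
                continue
            names.append(" x ".join(term))
            cols.append(np.prod([base[k] for k in term], axis=0))
    return np.column_stack(cols), names


def fit_exgauss_regression(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    covariate: str = "bis",
) -> ExGaussianFit:
    """Ex-Gaussian mu regression of correct RTs on design x trait terms.

    The covariate (a BIS/BAS total from ``participants``) is mean-centred
    and scaled to 2 SD across participants; mu is modelled by the
    treatment-coded expression x response x participant-gender x covariate
    factorial plus fixed per-participant intercept offsets; sigma and tau
    are shared. Returns the fit with a Wald coefficient table for the
    factorial terms.
    """
    if participants["participant_id"].nunique() != len(participants):
        raise ValueError("duplicate participants")
    cov_map = dict(
        zip(
            participants["participant_id"],
            scale_2sd(participants[covariate].to_numpy()),
        )
    )
    data = trials[trials["correct"]].copy()
    data = data[data["participant_id"].isin(cov_map)]
    per_gender = data.groupby("participant_gender")["participant_id"].nunique()
    if len(per_gender) < 2 or per_gender.min() < 2:
        raise ValueError("need at least 2 participants per gender")
    t = data["rt_ms"].to_numpy(dtype=float) / 1000.0
    cov_z = data["participant_id"].map(cov_map).to_numpy(dtype=float)
    X, names = _treatment_design(data, cov_z)

    pids = sorted(data["participant_id"].unique())
    dummies = pd.get_dummies(data["participant_id"])[pids].to_numpy(float)[:, 1:]
    names = names + [f"participant[{p}]" for p in pids[1:]]
    X = np.column_stack([X, dummies])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design matrix")

    mu0, sigma0, tau0 = _moment_start(t)
    beta0 = np.zeros(X.shape[1])
    beta0[0] = mu0
    beta, sigma, tau, ll, ok, theta, nll_grad = _fit_exgauss_design(
        t, X, beta0, sigma0, tau0
    )

    # observed information by finite differences of the analytic gradient
    eps = 1e-5
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps
        H[:, j] = (nll_grad(theta + step)[1] - nll_grad(theta - step)[1]) / (2 * eps)
    H = (H + H.T) / 2.0
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov)[: len(names)], 0.0, None))
    zvals = beta / np.where(se > 0, se, np.nan)
    table = pd.DataFrame(
        {
            "name": names,
            "estimate": beta,
            "se": se,
            "z": zvals,
            "p": 2.0 * stats.norm.sf(np.abs(zvals)),
        }
    )
    return ExGaussianFit(
        mu=float(beta[0]), sigma=float(sigma), tau=float(tau), loglik=float(ll),
        converged=ok, coefficients=table,
    )
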