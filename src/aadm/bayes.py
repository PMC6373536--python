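"""Bayes-factor inference for per-participant cell statistics.

Two BF engines are used, mirroring the split between omnibus and follow-up
inference in repeated-measures designs:

* ANOVA-style model terms are scored by the BIC approximation
  ``BF10 = exp((BIC_null - BIC_term)/2)``, where both models are linear
  mixed models (participant random intercept) fitted by maximum
  likelihood and the term adds its sum-coded contrast column.
* Follow-up one-sample tests use the exact JZS Bayes factor (Cauchy prior
  on the standardised effect, numerical integration over the mixing
  variance), together with a standardised paired effect size dz and its
  95% highest-density interval from the analytic posterior of mu/sigma
  under the Jeffreys prior.

Evidence strength is labelled with Jeffreys-style bands: anecdotal
(1, 3.2], moderate (3.2, 10], strong (10, 100], decisive (> 100); Bayes
factors at or below 1 favour the null and are labelled by the band of the
reciprocal.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .types import BayesFactorResult, EffectSizeResult

__all__ = [
    "classify_bf",
    "jzs_ttest_bf",
    "effect_size_hdi",
    "run_bayes_anova",
    "simple_interaction_followup",
    "compare_group_means",
]

DEFAULT_RSCALE = np.sqrt(2.0) / 2.0
WITHIN_FACTORS = ("expression", "required_response", "face_gender")


def _band(bf: float) -> str:
    if bf <= 3.2:
        return "anecdotal"
    if bf <= 10.0:
        return "moderate"
    if bf <= 100.0:
        return "strong"
    return "decisive"


def classify_bf(bf10: float) -> str:
    """Jeffreys evidence label for a Bayes factor (boundaries go to the
    lower band)."""
    if not np.isfinite(bf10) or bf10 <= 0:
        raise ValueError(f"bf10 must be a positive finite number, got {bf10}")
    if bf10 <= 1.0:
        return f"favours null ({_band(1.0 / bf10)})"
    return _band(bf10)


def jzs_ttest_bf(differences, rscale: float = DEFAULT_RSCALE) -> float:
    """One-sample JZS Bayes factor (alternative vs point null at 0).

    The Cauchy(0, rscale) prior on the standardised effect is expressed as
    a normal scale mixture, delta | g ~ N(0, g * rscale^2) with
    g ~ InverseGamma(1/2, 1/2), and the marginal-likelihood ratio is
    integrated over g by adaptive quadrature.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input: t statistic undefined")
    t = d.mean() / (sd / np.sqrt(n))
    nu = n - 1
    r2 = rscale * rscale

    log_null = -0.5 * (nu + 1) * np.log1p(t * t / nu)

    def integrand(g: float) -> float:
        c = 1.0 + n * g * r2
        log_alt = -0.5 * np.log(c) - 0.5 * (nu + 1) * np.log1p(t * t / (c * nu))
        log_prior = -1.5 * np.log(g) - 0.5 / g - 0.5 * np.log(2.0 * np.pi)
        # for overwhelming evidence the ratio overflows to inf, which is the
        # honest float answer for the Bayes factor itself
        with np.errstate(over="ignore"):
            return np.exp(log_alt - log_null + log_prior)

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-10, epsrel=1e-8,
                            limit=200)
    return float(val)


def _hdi(draws: np.ndarray, cred: float) -> tuple[float, float]:
    """Narrowest interval containing ``cred`` mass, by sorted-window scan."""
    x = np.sort(draws)
    k = int(np.ceil(cred * x.size))
    widths = x[k - 1:] - x[: x.size - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def effect_size_hdi(
    differences,
    cred: float = 0.95,
    draws: int = 100_000,
    seed: int | np.random.Generator = 0,
    contrast: str = "",
) -> EffectSizeResult:
    """dz = mean/SD of paired differences, with a posterior HDI.

    Under a normal likelihood with the Jeffreys prior on (mu, sigma^2) the
    posterior is sampled exactly: sigma^2 ~ (n-1) s^2 / chi^2_{n-1},
    mu | sigma ~ N(xbar, sigma^2 / n); the HDI is the narrowest interval
    holding ``cred`` of the mu/sigma draws.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input: dz undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = (n - 1) * sd * sd / rng.chisquare(n - 1, size=draws)
    mu = rng.normal(d.mean(), np.sqrt(sigma2 / n))
    lo, hi = _hdi(mu / np.sqrt(sigma2), cred)
    return EffectSizeResult(
        contrast=contrast,
        dz=float(d.mean() / sd),
        hdi_low=lo,
        hdi_high=hi,
        bf10=jzs_ttest_bf(d),
        cred=cred,
    )


def _sum_coded_columns(table: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """+1/-1 main-effect columns (first level alphabetically is +1)."""
    cols = {}
    for f in factors:
        levels = sorted(table[f].unique())
        if len(levels) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, got {levels}")
        cols[f] = np.where(table[f] == levels[0], 1.0, -1.0)
    return pd.DataFrame(cols, index=table.index)


def _check_balance(table: pd.DataFrame, factors: list[str]) -> None:
    counts = table.groupby(["participant_id", *factors]).size()
    bad = counts[counts != 1]
    if len(bad):
        raise ValueError(f"unbalanced cells (expect one value each): {bad.to_dict()}")
    per_p = table.groupby("participant_id").size()
    if per_p.nunique() != 1:
        raise ValueError(f"participants have unequal cell counts: {per_p.to_dict()}")


def _bic_mixed(dv: np.ndarray, X: np.ndarray, groups: np.ndarray) -> float:
    """BIC of a random-intercept linear mixed model fitted by ML."""
    import warnings

    from statsmodels.regression.mixed_linear_model import MixedLM
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        fit = MixedLM(dv, X, groups=groups).fit(reml=False, disp=False)
    k = X.shape[1] + 2  # fixed effects + intercept variance + residual variance
    return float(-2.0 * fit.llf + k * np.log(dv.size))


def run_bayes_anova(
    stat_table: pd.DataFrame,
    dv: str,
    between: str | None = "participant_gender",
    within: tuple[str, ...] = WITHIN_FACTORS,
    terms: list[tuple[str, ...]] | None = None,
) -> list[BayesFactorResult]:
    """BIC-approximation Bayes factors for ANOVA-style model terms.

    Each candidate term (main effect or interaction over the 2-level
    factors) is compared against the null model containing only the
    participant random intercept; the term enters as a single sum-coded
    product column. Results are sorted by decreasing BF10.
    """
    factors = list(within) + ([between] if between else [])
    table = stat_table.dropna(subset=[dv])
    _check_balance(table, list(within))
    coded = _sum_coded_columns(table, factors)
    if terms is None:
        terms = [
            c for r in range(1, len(factors) + 1) for c in combinations(factors, r)
        ]
    y = table[dv].to_numpy(dtype=float)
    # standardise for optimiser conditioning; BIC differences are invariant
    # to affine transformations of the dv
    y = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    groups = table["participant_id"].to_numpy()
    intercept = np.ones((len(table), 1))
    bic_null = _bic_mixed(y, intercept, groups)
    results = []
    for term in terms:
        col = np.prod([coded[f].to_numpy() for f in term], axis=0)
        bic_term = _bic_mixed(y, np.column_stack([intercept, col]), groups)
        bf10 = float(np.exp((bic_null - bic_term) / 2.0))
        results.append(
            BayesFactorResult(
                dv=dv,
                term=" x ".join(term),
                bf10=bf10,
                method="bic-approx",
                label=classify_bf(bf10),
            )
        )
    return sorted(results, key=lambda r: r.bf10, reverse=True)


def simple_interaction_followup(
    stat_table: pd.DataFrame,
    dv: str,
    group: str,
    within: tuple[str, str] = ("expression", "required_response"),
    seed: int = 0,
) -> tuple[BayesFactorResult, list[EffectSizeResult]]:
    """2x2 simple interaction within one participant-gender group.

    Restricts the table to the group, averages the dv over any remaining
    design factors, scores the interaction term by the BIC-approximation
    BF, and returns paired follow-up contrasts (difference between the
    levels of ``within[1]`` at each level of ``within[0]``) with dz, HDI
    and JZS BF. Degenerate (zero-variance) contrasts are reported as NaN
    effect sizes rather than raised.
    """
    sub = stat_table[stat_table["participant_gender"] == group]
    if sub.empty:
        raise ValueError(f"no participants with gender {group!r}")
    cell = (
        sub.dropna(subset=[dv])
        .groupby(["participant_id", *within], as_index=False)[dv]
        .mean()
    )
    cell["participant_gender"] = group
    [interaction] = run_bayes_anova(
        cell, dv, between=None, within=within, terms=[tuple(within)]
    )
    interaction = BayesFactorResult(
        dv=dv,
        term=f"{interaction.term} | {group}",
        bf10=interaction.bf10,
        method=interaction.method,
        label=interaction.label,
    )

    fac_a, fac_b = within
    b_levels = sorted(cell[fac_b].unique())
    contrasts = []
    rng = np.random.default_rng(seed)
    wide = cell.pivot_table(index=["participant_id", fac_a], columns=fac_b, values=dv)
    for level in sorted(cell[fac_a].unique()):
        diffs = (
            wide.xs(level, level=fac_a)[b_levels[0]]
            - wide.xs(level, level=fac_a)[b_levels[1]]
        ).dropna().to_numpy()
        name = f"{level}: {b_levels[0]} - {b_levels[1]} | {group}"
        try:
            contrasts.append(
                effect_size_hdi(diffs, seed=rng, contrast=name)
            )
        except ValueError:
            contrasts.append(
                EffectSizeResult(
                    contrast=name, dz=np.nan, hdi_low=np.nan, hdi_high=np.nan,
                    bf10=np.nan,
                )
            )
    return interaction, contrasts


def compare_group_means(values, groups) -> tuple[float, float, float]:
    """One-way ANOVA: F statistic, partial eta squared, p value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least two observations")
    grand = values.mean()
    ss_effect = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_error = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1 = levels.size - 1
    df2 = values.size - levels.size
    if ss_error == 0:
        return np.inf if ss_effect > 0 else 0.0, 1.0 if ss_effect > 0 else 0.0, 0.0
    F = (ss_effect / df1) / (ss_error / df2)
    eta_p2 = ss_effect / (ss_effect + ss_error)
    return float(F), float(eta_p2), float(stats.f.sf(F, df1, df2))
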