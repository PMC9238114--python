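"""Closed-form predictions and the exact enumeration oracle.

Under the logit participation model, the post-selection association between
an autosomal variant and sex has a closed form in the rare-participation
limit: the log-odds of male among participants is linear in dosage with slope
exactly b_male - b_female, the between-sex difference of the variant's
participation effects. At any participation rate the association can be
computed without sampling error by enumerating the six (genotype x sex)
cells with weights HWE(g) * P(s) * P(participate | g, s) and fitting a
weighted logistic regression to the exact cell masses. The oracle therefore
validates the Monte-Carlo engine at finite rates and the rare-limit formula
as pi -> 0.

An optional per-sex Gaussian "background" standard deviation integrates the
participation probability over the linear-predictor contribution of all
other variants (and traits), so the oracle also predicts marginal per-variant
associations inside polygenic simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "OracleResult",
    "SlopeFit",
    "rare_limit_sex_effect",
    "exact_sex_effect_oracle",
    "oracle_intercept_for_rate",
    "oracle_at_rate",
    "predicted_vs_estimated_slope",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def rare_limit_sex_effect(b_female, b_male):
    """Predicted sex-GWAS log-odds effect in the pi -> 0 limit:
    b_male - b_female. Depends only on the between-sex difference."""
    return np.asarray(b_male, dtype=float) - np.asarray(b_female, dtype=float)


def _participation_prob(alpha: float, eta: np.ndarray, sd: float) -> np.ndarray:
    """E_z[expit(alpha + eta + sd*z)], z standard normal (Gauss-Hermite)."""
    if np.isposinf(alpha):
        return np.ones_like(eta, dtype=float)
    if sd == 0.0:
        return expit(alpha + eta)
    z = np.sqrt(2.0) * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    return expit(alpha + eta[..., None] + sd * z) @ w


def _hwe(maf: float) -> np.ndarray:
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


@dataclass(frozen=True)
class OracleResult:
    """Exact post-selection sex-genotype association for one variant."""

    maf: float
    log_odds_male: np.ndarray  # log-odds of male among participants at g=0,1,2
    slope: float               # weighted-logistic slope (the sex-GWAS estimand)
    intercept: float
    ncp_per_participant: float # Wald chi2 non-centrality per participant
    participation_rate: float
    rate_female: float
    rate_male: float
    cell_weights: np.ndarray   # 2x3 joint masses P(s, g, participate)

    def expected_mean_chi2(self, n_participants: float) -> float:
        """Predicted mean Wald chi-squared for a sex GWAS with this many
        participants: 1 + N * ncp per participant."""
        return 1.0 + n_participants * self.ncp_per_participant


def _weighted_logistic_slope(
    weights: np.ndarray, g: np.ndarray
) -> tuple[float, float, float]:
    """Exact 2-parameter logistic MLE of sex on dosage under cell masses.

    weights[s, k] are joint masses over sex s in {0,1} and genotype cells k.
    Returns (intercept, slope, var_slope_per_participant).
    """
    wn = weights / weights.sum()
    tot = wn.sum(axis=0)           # mass of each genotype cell
    ybar = wn[1].sum()
    theta = np.array([logit(min(max(ybar, 1e-12), 1 - 1e-12)), 0.0])
    X = np.column_stack([np.ones_like(g, dtype=float), g.astype(float)])
    for _ in range(100):
        mu = expit(X @ theta)
        w = tot * mu * (1.0 - mu)
        score = X.T @ (wn[1] - tot * mu)
        info = (X * w[:, None]).T @ X
        step = np.linalg.solve(info, score)
        theta = theta + step
        if np.max(np.abs(step)) < 1e-13:
            break
    mu = expit(X @ theta)
    info = (X * (tot * mu * (1 - mu))[:, None]).T @ X
    var_slope = np.linalg.inv(info)[1, 1]
    return float(theta[0]), float(theta[1]), float(var_slope)


def exact_sex_effect_oracle(
    maf: float,
    b_female: float,
    b_male: float,
    alpha_female: float,
    alpha_male: float,
    male_fraction: float = 0.5,
    background_sd: tuple[float, float] = (0.0, 0.0),
) -> OracleResult:
    """Enumerate the 6 (genotype, sex) cells exactly.

    Cell mass = HWE(g) * P(s) * P(participate | g, s) with the logit model on
    centered dosage; returns the exact log-odds of male at each genotype, the
    weighted-logistic slope (what a sex GWAS estimates as n -> inf), and the
    per-participant Wald non-centrality.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if not 0.0 < male_fraction < 1.0:
        raise ValueError("male_fraction must lie in (0, 1)")
    g = np.array([0.0, 1.0, 2.0])
    gc = g - 2.0 * maf
    p_part = np.vstack(
        [
            _participation_prob(alpha_female, b_female * gc, background_sd[0]),
            _participation_prob(alpha_male, b_male * gc, background_sd[1]),
        ]
    )
    p_sex = np.array([1.0 - male_fraction, male_fraction])
    weights = _hwe(maf) * p_sex[:, None] * p_part
    log_odds = np.log(weights[1]) - np.log(weights[0])
    intercept, slope, var_slope = _weighted_logistic_slope(weights, g)
    ncp = slope**2 / var_slope if var_slope > 0 else np.nan
    hwe = _hwe(maf)
    return OracleResult(
        maf=maf,
        log_odds_male=log_odds,
        slope=slope,
        intercept=intercept,
        ncp_per_participant=float(ncp),
        participation_rate=float(weights.sum()),
        rate_female=float((hwe * p_part[0]).sum()),
        rate_male=float((hwe * p_part[1]).sum()),
        cell_weights=weights,
    )


def oracle_intercept_for_rate(
    maf: float,
    b: float,
    pi: float,
    background_sd: float = 0.0,
) -> float:
    """Intercept alpha such that the HWE-averaged participation probability
    equals pi exactly (the population analogue of intercept calibration)."""
    if not 0.0 < pi <= 1.0:
        raise ValueError("participation rate must lie in (0, 1]")
    if pi == 1.0:
        return np.inf
    g = np.array([0.0, 1.0, 2.0])
    gc = g - 2.0 * maf
    hwe = _hwe(maf)

    def gap(a: float) -> float:
        return float(hwe @ _participation_prob(a, b * gc, background_sd)) - pi

    width = 40.0 + abs(b) * 2.0 + 6.0 * background_sd
    return float(brentq(gap, -width, width, xtol=1e-13))


def oracle_at_rate(
    maf: float,
    b_female: float,
    b_male: float,
    pi_female: float,
    pi_male: float,
    male_fraction: float = 0.5,
    background_sd: tuple[float, float] = (0.0, 0.0),
) -> OracleResult:
    """Calibrate per-sex intercepts to target rates, then run the oracle."""
    a_f = oracle_intercept_for_rate(maf, b_female, pi_female, background_sd[0])
    a_m = oracle_intercept_for_rate(maf, b_male, pi_male, background_sd[1])
    return exact_sex_effect_oracle(
        maf, b_female, b_male, a_f, a_m, male_fraction, background_sd
    )


@dataclass(frozen=True)
class SlopeFit:
    """OLS of estimated sex-GWAS effects on between-sex participation-effect
    differences (the proportionality readout)."""

    slope: float
    intercept: float
    slope_se: float
    ci_low: float
    ci_high: float
    r_squared: float
    n: int


def predicted_vs_estimated_slope(
    estimated_effects: np.ndarray,
    effect_differences: np.ndarray,
    min_points: int = 10,
) -> SlopeFit:
    """Regress estimated per-variant sex-GWAS effects on the per-variant
    between-sex participation-effect differences; slope ~ 1 on the log-odds
    scale in the rare-participation limit."""
    y = np.asarray(estimated_effects, dtype=float)
    x = np.asarray(effect_differences, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} variants with valid estimates")
    if np.var(x) <= 1e-16:
        raise ValueError("predictor (effect differences) has no variance")
    X = np.column_stack([np.ones_like(x), x])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = x.size - 2
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    tcrit = float(norm.ppf(0.975)) if dof > 30 else 2.0
    ss_tot = np.sum((y - y.mean()) ** 2)
    return SlopeFit(
        slope=float(coef[1]),
        intercept=float(coef[0]),
        slope_se=se,
        ci_low=float(coef[1] - tcrit * se),
        ci_high=float(coef[1] + tcrit * se),
        r_squared=float(1.0 - resid @ resid / ss_tot) if ss_tot > 0 else np.nan,
        n=int(x.size),
    )
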