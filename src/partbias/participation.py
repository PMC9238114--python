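"""The logit study-participation model.

Individual i of sex s participates with probability

    P(participate | g, x, s) = expit(alpha_s + eta_{s,i}),
    eta_{s,i} = sum_j b_{s,j} (g_ij - 2 maf_j) + sum_t gamma_{s,t} x_it,

i.e. a liability-threshold model with standard-logistic noise (variance
pi^2/3). Per-sex intercepts alpha_s are calibrated by root-finding so the
realized participation rate hits its target pi_s; per-variant effects are
scaled so the liability-scale heritability of participation

    h2_s = Var(eta_s) / (Var(eta_s) + pi^2 / 3)

holds analytically. "Sex-independent" forces identical effect vectors in
both sexes; "sex-differential" allows any between-sex effect correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .popsim import Cohort, scale_effects_to_variance

__all__ = [
    "LOGISTIC_VARIANCE",
    "ParticipationModel",
    "ParticipationSummary",
    "draw_participation_effects",
    "calibrate_intercepts",
    "calibrate_model",
    "simulate_participation",
    "genetic_variance_target",
]

#: variance of the standard logistic distribution
LOGISTIC_VARIANCE = np.pi**2 / 3.0

SCENARIOS = ("sex_independent", "sex_differential")


def genetic_variance_target(h2: float) -> float:
    """Linear-predictor variance implied by a logistic-liability h2:
    Var(eta) = h2 / (1 - h2) * pi^2/3."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError("liability-scale heritability must lie in [0, 1)")
    return h2 / (1.0 - h2) * LOGISTIC_VARIANCE


@dataclass
class ParticipationModel:
    """Per-sex logit participation model (intercepts, variant and trait effects).

    ``b_female``/``b_male`` are per-variant log-odds effects on centered
    dosages; ``gamma_female``/``gamma_male`` map trait names to log-odds
    effects. Intercepts are ``None`` until calibrated against a cohort.
    """

    pi_female: float
    pi_male: float
    b_female: np.ndarray
    b_male: np.ndarray
    gamma_female: dict[str, float] = field(default_factory=dict)
    gamma_male: dict[str, float] = field(default_factory=dict)
    h2_female: float = 0.0
    h2_male: float = 0.0
    scenario: str = "sex_differential"
    alpha_female: float | None = None
    alpha_male: float | None = None

    def __post_init__(self) -> None:
        for pi in (self.pi_female, self.pi_male):
            if not 0.0 < pi <= 1.0:
                raise ValueError("participation rates must lie in (0, 1]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        self.b_female = np.asarray(self.b_female, dtype=float)
        self.b_male = np.asarray(self.b_male, dtype=float)
        if self.scenario == "sex_independent":
            if not np.array_equal(self.b_female, self.b_male) or (
                self.gamma_female != self.gamma_male
            ):
                raise ValueError(
                    "sex_independent requires identical effects in both sexes"
                )

    @property
    def calibrated(self) -> bool:
        return self.alpha_female is not None and self.alpha_male is not None

    @property
    def symmetric(self) -> bool:
        """True when the model is exactly sex-symmetric (shared intercept is
        then calibrated on the pooled sample, preserving the exact null)."""
        return (
            self.scenario == "sex_independent"
            and self.pi_female == self.pi_male
            and self.gamma_female == self.gamma_male
        )

    def linear_predictor(self, cohort: Cohort) -> np.ndarray:
        """eta_i (without intercept) for every individual, using each
        individual's own sex."""
        gc = cohort.centered_genotypes()
        eta_f = gc @ self.b_female
        eta_m = gc @ self.b_male
        for name, g in self.gamma_female.items():
            eta_f += g * cohort.traits[name]
        for name, g in self.gamma_male.items():
            eta_m += g * cohort.traits[name]
        return np.where(cohort.sex == 1, eta_m, eta_f)


@dataclass(frozen=True)
class ParticipationSummary:
    """Realized participation rates and marginal per-variant effects."""

    realized_rate_female: float
    realized_rate_male: float
    marginal_effects_female: np.ndarray
    marginal_effects_male: np.ndarray

    @property
    def rate_difference(self) -> float:
        return self.realized_rate_male - self.realized_rate_female


def draw_participation_effects(
    mafs: np.ndarray,
    h2_female: float,
    h2_male: float,
    scenario: str = "sex_differential",
    correlation: float = 0.0,
    causal_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-sex per-variant participation effects.

    Effects are normal per standardized genotype on the causal set, with the
    requested between-sex correlation, then rescaled exactly so
    Var(eta_s) = h2_s/(1-h2_s) * pi^2/3. Under ``sex_independent`` the two
    vectors are the same draw (correlation is forced to 1).
    """
    mafs = np.asarray(mafs, dtype=float)
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    targets = (genetic_variance_target(h2_female), genetic_variance_target(h2_male))
    if causal_mask is None:
        causal_mask = np.ones(mafs.size, dtype=bool)
    causal_mask = np.asarray(causal_mask, dtype=bool)
    if max(targets) > 0 and not causal_mask.any():
        raise ValueError("nonzero participation h2 requires a causal set")
    if rng is None:
        rng = np.random.default_rng(seed)

    k = int(causal_mask.sum())
    sd = np.sqrt(2.0 * mafs[causal_mask] * (1.0 - mafs[causal_mask]))
    z_f = rng.standard_normal(k)
    if scenario == "sex_independent":
        z_m = z_f
    else:
        rho = correlation
        z_m = rho * z_f + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(k)
    out = []
    for z, target in ((z_f, targets[0]), (z_m, targets[1])):
        b = np.zeros(mafs.size)
        b[causal_mask] = z / sd
        out.append(scale_effects_to_variance(b, mafs, target))
    return out[0], out[1]


def _solve_intercept(eta: np.ndarray, pi: float, tolerance: float) -> float:
    if pi == 1.0:
        return np.inf

    def gap(a: float) -> float:
        return float(np.mean(expit(a + eta))) - pi

    lo, hi = -40.0, 40.0
    width = float(np.max(np.abs(eta), initial=0.0))
    lo -= width
    hi += width
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"failed to bracket the intercept for pi={pi}: "
            f"gap({lo})={gap(lo):.3g}, gap({hi})={gap(hi):.3g}"
        )
    alpha = brentq(gap, lo, hi, xtol=1e-12)
    if abs(gap(alpha)) > tolerance:
        raise RuntimeError("intercept calibration missed the target rate")
    return float(alpha)


def calibrate_intercepts(
    eta_female: np.ndarray,
    eta_male: np.ndarray,
    pi_female: float,
    pi_male: float,
    tolerance: float = 1e-4,
) -> tuple[float, float]:
    """Solve per-sex intercepts so the mean of expit(alpha_s + eta_s) over the
    supplied linear-predictor samples equals pi_s within tolerance.

    Monotone bracketing root-finding (Brent); deterministic given inputs.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    for pi in (pi_female, pi_male):
        if not 0.0 < pi <= 1.0:
            raise ValueError("participation rates must lie in (0, 1]")
    eta_female = np.asarray(eta_female, dtype=float)
    eta_male = np.asarray(eta_male, dtype=float)
    if not (np.isfinite(eta_female).all() and np.isfinite(eta_male).all()):
        raise ValueError("linear predictors must be finite")
    return (
        _solve_intercept(eta_female, pi_female, tolerance),
        _solve_intercept(eta_male, pi_male, tolerance),
    )


def calibrate_model(
    cohort: Cohort, model: ParticipationModel, tolerance: float = 1e-4
) -> ParticipationModel:
    """Return a copy of ``model`` with intercepts calibrated on ``cohort``.

    For an exactly sex-symmetric model a single intercept is solved on the
    pooled sample and shared, which preserves the exact null
    P(male | participate, g) = male fraction at every participation rate.
    """
    eta = model.linear_predictor(cohort)
    if model.symmetric:
        alpha = _solve_intercept(eta, model.pi_female, tolerance)
        return replace(model, alpha_female=alpha, alpha_male=alpha)
    a_f, a_m = calibrate_intercepts(
        eta[cohort.sex == 0], eta[cohort.sex == 1],
        model.pi_female, model.pi_male, tolerance,
    )
    return replace(model, alpha_female=a_f, alpha_male=a_m)


def _marginal_effects(
    participation: np.ndarray, cohort: Cohort, sex_value: int
) -> np.ndarray:
    """Per-variant slope of participation on dosage within one sex
    (linear-probability scale): Cov(part, g | s) / Var(g | s)."""
    mask = cohort.sex == sex_value
    g = cohort.genotypes[mask]
    y = participation[mask].astype(float)
    n = y.size
    gbar = g.mean(axis=0)
    cov = (y @ g) / n - y.mean() * gbar
    var = (g * g).mean(axis=0) - gbar**2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(var > 0, cov / var, np.nan)


def simulate_participation(
    cohort: Cohort,
    model: ParticipationModel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, ParticipationSummary]:
    """Draw the participation indicator and attach it to the cohort.

    Equivalent liability formulation: participate iff
    alpha_s + eta_s + eps > 0 with eps standard logistic.
    """
    if not model.calibrated:
        raise RuntimeError("model must be calibrated before simulation")
    if rng is None:
        rng = np.random.default_rng(seed)
    eta = model.linear_predictor(cohort)
    alpha = np.where(cohort.sex == 1, model.alpha_male, model.alpha_female)
    prob = expit(alpha + eta)
    part = (rng.random(cohort.n_individuals) < prob).astype(np.int8)
    cohort.participation = part
    summary = ParticipationSummary(
        realized_rate_female=float(part[cohort.sex == 0].mean()),
        realized_rate_male=float(part[cohort.sex == 1].mean()),
        marginal_effects_female=_marginal_effects(part, cohort, 0),
        marginal_effects_male=_marginal_effects(part, cohort, 1),
    )
    return part, summary


def intercept_for_rate(pi: float) -> float:
    """Closed-form intercept when the linear predictor is identically zero."""
    if not 0.0 < pi <= 1.0:
        raise ValueError("participation rate must lie in (0, 1]")
    return np.inf if pi == 1.0 else float(logit(pi))
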