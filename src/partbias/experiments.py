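"""Figure-style scenario sweeps: participation-rate grid, stratification
correction, MR robustness, power equivalence, and the effect-difference
slope experiment.

Every experiment returns a tidy long-format table (one metric value per row)
carrying the derived seed that reproduces it; reruns with the same config and
master seed are bit-identical. Per-cell RNGs are split from the master seed
with ``numpy.random.SeedSequence(master_seed, spawn_key=cell_key)``.

The default configurations are the package's canonical study conditions;
problem sizes are sized for single-workstation runs (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import assoc, combine, participation, popsim, theory

__all__ = [
    "TABLE_COLUMNS",
    "PiGridConfig",
    "CorrectionConfig",
    "MrConfig",
    "PowerConfig",
    "SlopeConfig",
    "run_pi_grid",
    "run_correction_experiment",
    "run_mr_experiment",
    "run_power_experiment",
    "run_slope_experiment",
    "load_config",
]

TABLE_COLUMNS = [
    "scenario", "pi_female", "pi_male", "h2_female", "h2_male",
    "estimator", "replicate", "seed", "metric", "value",
]


def cell_seed_sequence(master_seed: int, *key: int) -> np.random.SeedSequence:
    """Documented seed-splitting rule: spawn_key = the cell index tuple."""
    return np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in key))


def cell_rng(master_seed: int, *key: int) -> tuple[np.random.Generator, int]:
    ss = cell_seed_sequence(master_seed, *key)
    record = int(ss.generate_state(1)[0] % 2**31)
    return np.random.default_rng(ss), record


class _YamlConfig:
    @classmethod
    def from_dict(cls, d: dict):
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------- pi grid

@dataclass(frozen=True)
class PiGridConfig(_YamlConfig):
    """Sex-GWAS inflation versus participation rate (Fig-1a-style sweep)."""

    n_individuals: int = 50_000
    n_variants: int = 400
    maf: tuple = (0.15, 0.5)
    male_fraction: float = 0.5
    pi_grid: tuple = (0.01, 0.05, 0.2, 1.0)
    h2_pairs: tuple = ((0.2, 0.2),)
    scenarios: tuple = ("sex_independent", "sex_differential")
    correlation: float = 0.0
    replicates: int = 5
    master_seed: int = 0
    emit_oracle: bool = True


def _sex_gwas_cell(
    cfg: PiGridConfig,
    scenario: str,
    h2_pair: tuple[float, float],
    pi: float,
    rng: np.random.Generator,
) -> tuple[float, float, int]:
    """One replicate: returns (ratio, oracle-predicted ratio, n participants)."""
    pop = popsim.PopulationConfig(
        cfg.n_individuals, cfg.n_variants, maf=cfg.maf,
        male_fraction=cfg.male_fraction,
    )
    cohort = popsim.simulate_cohort(pop, rng)
    if scenario == "sex_independent":
        # identical effects in both sexes imply a single participation h2
        h2_pair = (h2_pair[0], h2_pair[0])
    b_f, b_m = participation.draw_participation_effects(
        cohort.mafs, h2_pair[0], h2_pair[1], scenario=scenario,
        correlation=cfg.correlation, rng=rng,
    )
    model = participation.ParticipationModel(
        pi_female=pi, pi_male=pi, b_female=b_f, b_male=b_m,
        h2_female=h2_pair[0], h2_male=h2_pair[1], scenario=scenario,
    )
    model = participation.calibrate_model(cohort, model)
    participation.simulate_participation(cohort, model, rng=rng)
    results, infl = assoc.run_sex_gwas(cohort)
    n_part = int(cohort.participation.sum())
    oracle_ratio = np.nan
    if cfg.emit_oracle:
        pq2 = 2.0 * cohort.mafs * (1.0 - cohort.mafs)
        var_f = float(np.sum(pq2 * b_f**2))
        var_m = float(np.sum(pq2 * b_m**2))
        ncp = 0.0
        for j in range(cohort.n_variants):
            sd_f = np.sqrt(max(var_f - pq2[j] * b_f[j] ** 2, 0.0))
            sd_m = np.sqrt(max(var_m - pq2[j] * b_m[j] ** 2, 0.0))
            orc = theory.oracle_at_rate(
                cohort.mafs[j], b_f[j], b_m[j], pi, pi,
                cfg.male_fraction, background_sd=(sd_f, sd_m),
            )
            ncp += orc.ncp_per_participant
        oracle_ratio = 1.0 + n_part * ncp / cohort.n_variants
    return infl.ratio, oracle_ratio, n_part


def run_pi_grid(config: PiGridConfig | None = None, **overrides) -> pd.DataFrame:
    cfg = replace(config or PiGridConfig(), **overrides)
    if len(cfg.pi_grid) == 0:
        raise ValueError("pi_grid must be nonempty")
    if any(not 0 < pi <= 1 for pi in cfg.pi_grid):
        raise ValueError("pi grid values must lie in (0, 1]")
    rows = []
    for i_s, scenario in enumerate(cfg.scenarios):
        for i_h, h2_pair in enumerate(cfg.h2_pairs):
            for i_p, pi in enumerate(cfg.pi_grid):
                for rep in range(cfg.replicates):
                    rng, seed = cell_rng(cfg.master_seed, i_s, i_h, i_p, rep)
                    ratio, oracle_ratio, _ = _sex_gwas_cell(
                        cfg, scenario, h2_pair, pi, rng
                    )
                    base = dict(
                        scenario=scenario, pi_female=pi, pi_male=pi,
                        h2_female=h2_pair[0], h2_male=h2_pair[1],
                        estimator="sex_gwas", replicate=rep, seed=seed,
                    )
                    rows.append({**base, "metric": "mean_chi2_ratio", "value": ratio})
                    if cfg.emit_oracle:
                        rows.append(
                            {**base, "metric": "oracle_mean_chi2_ratio",
                             "value": oracle_ratio}
                        )
                        rows.append(
                            {**base, "metric": "oracle_discrepancy",
                             "value": ratio - oracle_ratio}
                        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# ----------------------------------------------------- correction (Fig 1b)

@dataclass(frozen=True)
class CorrectionConfig(_YamlConfig):
    """Combined vs stratified vs meta-analyzed trait GWAS at trait-null,
    participation-associated variants under sex-differential participation.

    The trait is heritability-free (its variants are all null) but drives
    participation with mirrored per-sex log-odds gamma; variant effects on
    participation are fully sex-differential (between-sex correlation -1).
    The combined arm is the unadjusted pooled GWAS (see docs/methods.md).
    """

    n_individuals: int = 200_000
    n_variants: int = 50
    maf: tuple = (0.2, 0.5)
    male_fraction: float = 0.5
    pi: float = 0.01
    h2_female: float = 0.2
    h2_male: float = 0.2
    correlation: float = -1.0
    trait_prevalence: float = 0.3
    gamma_male: float = 0.7
    gamma_female: float = -0.7
    replicates: int = 50
    master_seed: int = 0
    adjust_sex_combined: bool = False


ESTIMATOR_LABELS = ("combined", "stratified_f", "stratified_m", "meta")


def _correction_replicate(cfg: CorrectionConfig, rng: np.random.Generator):
    pop = popsim.PopulationConfig(
        cfg.n_individuals, cfg.n_variants, maf=cfg.maf,
        male_fraction=cfg.male_fraction,
    )
    cohort = popsim.simulate_cohort(pop, rng)
    arch = popsim.draw_trait_effects(
        cohort.mafs, 0.0, cfg.trait_prevalence, rng=rng
    )
    popsim.simulate_binary_trait(cohort, arch, rng=rng, name="trait")
    b_f, b_m = participation.draw_participation_effects(
        cohort.mafs, cfg.h2_female, cfg.h2_male,
        scenario="sex_differential", correlation=cfg.correlation, rng=rng,
    )
    model = participation.ParticipationModel(
        pi_female=cfg.pi, pi_male=cfg.pi, b_female=b_f, b_male=b_m,
        gamma_female={"trait": cfg.gamma_female},
        gamma_male={"trait": cfg.gamma_male},
        h2_female=cfg.h2_female, h2_male=cfg.h2_male,
        scenario="sex_differential",
    )
    model = participation.calibrate_model(cohort, model)
    participation.simulate_participation(cohort, model, rng=rng)
    comb = assoc.run_trait_gwas(
        cohort, "trait", mode="combined", adjust_sex=cfg.adjust_sex_combined
    )
    strat = assoc.run_trait_gwas(cohort, "trait", mode="stratified")
    meta = combine.meta_analyze(strat)
    out = {
        "combined": assoc.inflation_summary(comb).mean_chi2,
        "stratified_f": assoc.inflation_summary(
            strat[strat["stratum"] == "female"]
        ).mean_chi2,
        "stratified_m": assoc.inflation_summary(
            strat[strat["stratum"] == "male"]
        ).mean_chi2,
        "meta": assoc.inflation_summary(meta).mean_chi2,
    }
    return out


def run_correction_experiment(
    config: CorrectionConfig | None = None, **overrides
) -> pd.DataFrame:
    cfg = replace(config or CorrectionConfig(), **overrides)
    rows = []
    for rep in range(cfg.replicates):
        rng, seed = cell_rng(cfg.master_seed, rep)
        means = _correction_replicate(cfg, rng)
        for est, value in means.items():
            rows.append(
                dict(
                    scenario="sex_differential", pi_female=cfg.pi,
                    pi_male=cfg.pi, h2_female=cfg.h2_female,
                    h2_male=cfg.h2_male, estimator=est, replicate=rep,
                    seed=seed, metric="mean_chi2_ratio", value=value,
                )
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# ------------------------------------------------------------ MR (Fig 1c)

@dataclass(frozen=True)
class MrConfig(_YamlConfig):
    """MR-IVW between two causally independent binary traits that both drive
    participation sex-differentially (mirrored, opposite-sign gammas)."""

    n_individuals: int = 100_000
    n_causal_per_trait: int = 30
    maf: tuple = (0.2, 0.5)
    male_fraction: float = 0.5
    pi: float = 0.01
    trait_h2: float = 0.3
    trait_prevalence: float = 0.3
    gamma_exposure: tuple = (0.7, -0.7)   # (male, female)
    gamma_outcome: tuple = (-0.7, 0.7)
    replicates: int = 40
    master_seed: int = 0
    adjust_sex_combined: bool = False


def _mr_replicate(cfg: MrConfig, rng: np.random.Generator):
    m = 2 * cfg.n_causal_per_trait
    pop = popsim.PopulationConfig(
        cfg.n_individuals, m, maf=cfg.maf, male_fraction=cfg.male_fraction
    )
    cohort = popsim.simulate_cohort(pop, rng)
    mask_x = np.zeros(m, dtype=bool)
    mask_x[: cfg.n_causal_per_trait] = True
    mask_y = ~mask_x
    arch_x = popsim.draw_trait_effects(
        cohort.mafs, cfg.trait_h2, cfg.trait_prevalence, causal_mask=mask_x, rng=rng
    )
    arch_y = popsim.draw_trait_effects(
        cohort.mafs, cfg.trait_h2, cfg.trait_prevalence, causal_mask=mask_y, rng=rng
    )
    popsim.simulate_binary_trait(cohort, arch_x, rng=rng, name="exposure")
    popsim.simulate_binary_trait(cohort, arch_y, rng=rng, name="outcome")
    model = participation.ParticipationModel(
        pi_female=cfg.pi, pi_male=cfg.pi,
        b_female=np.zeros(m), b_male=np.zeros(m),
        gamma_female={"exposure": cfg.gamma_exposure[1],
                      "outcome": cfg.gamma_outcome[1]},
        gamma_male={"exposure": cfg.gamma_exposure[0],
                    "outcome": cfg.gamma_outcome[0]},
        scenario="sex_differential",
    )
    model = participation.calibrate_model(cohort, model)
    participation.simulate_participation(cohort, model, rng=rng)
    instruments = [f"v{j}" for j in np.flatnonzero(mask_x)]
    out = {}
    # combined (unadjusted pooled) summary statistics
    ex_c = assoc.run_trait_gwas(
        cohort, "exposure", mode="combined", adjust_sex=cfg.adjust_sex_combined
    )
    out_c = assoc.run_trait_gwas(
        cohort, "outcome", mode="combined", adjust_sex=cfg.adjust_sex_combined
    )
    out["mr_combined"] = combine.mr_from_sumstats(
        ex_c, out_c, instruments, source="combined"
    )
    # stratified + fixed-effects meta summary statistics
    ex_m = combine.meta_analyze(
        assoc.run_trait_gwas(cohort, "exposure", mode="stratified")
    )
    out_m = combine.meta_analyze(
        assoc.run_trait_gwas(cohort, "outcome", mode="stratified")
    )
    out["mr_meta"] = combine.mr_from_sumstats(
        ex_m, out_m, instruments, source="stratified_meta"
    )
    return out


def run_mr_experiment(config: MrConfig | None = None, **overrides) -> pd.DataFrame:
    cfg = replace(config or MrConfig(), **overrides)
    rows = []
    for rep in range(cfg.replicates):
        rng, seed = cell_rng(cfg.master_seed, rep)
        results = _mr_replicate(cfg, rng)
        for est, mr in results.items():
            base = dict(
                scenario="sex_differential", pi_female=cfg.pi, pi_male=cfg.pi,
                h2_female=np.nan, h2_male=np.nan, estimator=est,
                replicate=rep, seed=seed,
            )
            rows.append({**base, "metric": "estimate", "value": mr.estimate})
            rows.append({**base, "metric": "se", "value": mr.se})
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# --------------------------------------------------------- power (Fig S7)

@dataclass(frozen=True)
class PowerConfig(_YamlConfig):
    """Power of combined vs stratified+meta GWAS in a representative sample
    (pi = 1, no participation bias), at a workstation-scale alpha."""

    n_individuals: int = 6_000
    n_variants: int = 50
    maf: tuple = (0.2, 0.5)
    male_fraction: float = 0.5
    pi: float = 1.0
    trait_h2: float = 0.2
    trait_prevalence: float = 0.5
    alpha: float = 5e-4
    replicates: int = 500
    master_seed: int = 0


def _power_replicate(cfg: PowerConfig, rng: np.random.Generator):
    pop = popsim.PopulationConfig(
        cfg.n_individuals, cfg.n_variants, maf=cfg.maf,
        male_fraction=cfg.male_fraction,
    )
    cohort = popsim.simulate_cohort(pop, rng)
    arch = popsim.draw_trait_effects(
        cohort.mafs, cfg.trait_h2, cfg.trait_prevalence, rng=rng
    )
    popsim.simulate_binary_trait(cohort, arch, rng=rng, name="trait")
    model = participation.ParticipationModel(
        pi_female=cfg.pi, pi_male=cfg.pi,
        b_female=np.zeros(cfg.n_variants), b_male=np.zeros(cfg.n_variants),
        scenario="sex_independent",
    )
    model = participation.calibrate_model(cohort, model)
    participation.simulate_participation(cohort, model, rng=rng)
    comb = assoc.run_trait_gwas(cohort, "trait", mode="combined", adjust_sex=True)
    strat = assoc.run_trait_gwas(cohort, "trait", mode="stratified")
    meta = combine.meta_analyze(strat)
    powers = {}
    for label, df in (("combined", comb), ("meta", meta)):
        ok = df[df["status"] == assoc.STATUS_OK]
        powers[label] = float((ok["p"] < cfg.alpha).mean()) if len(ok) else np.nan
    return powers


def run_power_experiment(config: PowerConfig | None = None, **overrides) -> pd.DataFrame:
    cfg = replace(config or PowerConfig(), **overrides)
    rows = []
    for rep in range(cfg.replicates):
        rng, seed = cell_rng(cfg.master_seed, rep)
        powers = _power_replicate(cfg, rng)
        base = dict(
            scenario="representative", pi_female=cfg.pi, pi_male=cfg.pi,
            h2_female=np.nan, h2_male=np.nan, replicate=rep, seed=seed,
            metric="power",
        )
        for est, value in powers.items():
            rows.append({**base, "estimator": est, "value": value})
        rows.append(
            {**base, "estimator": "difference",
             "value": powers["combined"] - powers["meta"]}
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def simulate_single_variant_sex_beta(
    maf: float,
    b_female: float,
    b_male: float,
    pi: float,
    n: int,
    rng: np.random.Generator,
    male_fraction: float = 0.5,
):
    """Simulate one unlinked variant's population and return the sex-GWAS
    logistic fit among participants as a one-row result frame plus the
    participation indicator context (g, sex, part).

    Intercepts are calibrated analytically (population HWE expectation), so
    the simulation matches the enumeration oracle's conditions exactly.
    """
    g = rng.binomial(2, maf, n).astype(np.int8)
    sex = (rng.random(n) < male_fraction).astype(np.int8)
    gc = g.astype(float) - 2.0 * maf
    a_f = theory.oracle_intercept_for_rate(maf, b_female, pi)
    a_m = theory.oracle_intercept_for_rate(maf, b_male, pi)
    prob = expit(np.where(sex == 1, a_m + b_male * gc, a_f + b_female * gc))
    part = rng.random(n) < prob
    res = assoc.logistic_gwas(sex[part], g[part][:, None], outcome_name="sex")
    return res, g, sex, part


def power_difference_ci(table: pd.DataFrame, n_variants: int):
    """Binomial (two-proportion Wald) 95% CI on the power difference.

    Treats every replicate x variant decision as one Bernoulli trial per
    estimator; conservative relative to the paired comparison.
    """
    p_c = table[table["estimator"] == "combined"]["value"].to_numpy()
    p_m = table[table["estimator"] == "meta"]["value"].to_numpy()
    n_dec = p_c.size * n_variants
    pc, pm = float(np.nanmean(p_c)), float(np.nanmean(p_m))
    diff = pc - pm
    half = 1.96 * np.sqrt(
        pc * (1 - pc) / n_dec + pm * (1 - pm) / n_dec
    )
    return diff, diff - half, diff + half


# ------------------------------------------------------------ slope (Fig 1d)

@dataclass(frozen=True)
class SlopeConfig(_YamlConfig):
    """Regression of estimated sex-GWAS effects on between-sex
    participation-effect differences at a low participation rate.

    Each variant is simulated independently (variants are unlinked) with its
    own population of ``n_per_variant`` individuals, so very low rates remain
    affordable. Effects are drawn uniformly within ``effect_range`` per sex.
    """

    n_per_variant: int = 2_000_000
    n_variants: int = 100
    maf: float = 0.3
    male_fraction: float = 0.5
    pi: float = 0.001
    effect_range: tuple = (-0.3, 0.3)
    master_seed: int = 0


def run_slope_experiment(config: SlopeConfig | None = None, **overrides):
    """Returns (table, logit-scale SlopeFit, marginal-scale SlopeFit)."""
    cfg = replace(config or SlopeConfig(), **overrides)
    rng, seed = cell_rng(cfg.master_seed, 0)
    b_f = rng.uniform(*cfg.effect_range, cfg.n_variants)
    b_m = rng.uniform(*cfg.effect_range, cfg.n_variants)
    beta_logit = np.full(cfg.n_variants, np.nan)
    beta_linear = np.full(cfg.n_variants, np.nan)
    marg_diff = np.full(cfg.n_variants, np.nan)
    rate_diff = np.full(cfg.n_variants, np.nan)
    n = cfg.n_per_variant
    for j in range(cfg.n_variants):
        vrng, _ = cell_rng(cfg.master_seed, 1, j)
        res, g, sex, part = simulate_single_variant_sex_beta(
            cfg.maf, b_f[j], b_m[j], cfg.pi, n, vrng, cfg.male_fraction
        )
        gp, sp = g[part], sex[part]
        if res.loc[0, "status"] == assoc.STATUS_OK:
            beta_logit[j] = res.loc[0, "beta"]
        lin = assoc.linear_gwas(sp, gp[:, None].astype(float), outcome_name="sex")
        if lin.loc[0, "status"] == assoc.STATUS_OK:
            beta_linear[j] = lin.loc[0, "beta"]
        # marginal (linear-probability) participation-effect difference
        pm = part[sex == 1]
        pf = part[sex == 0]
        gm = g[sex == 1]
        gf = g[sex == 0]
        slope_m = np.cov(pm, gm)[0, 1] / np.var(gm)
        slope_f = np.cov(pf, gf)[0, 1] / np.var(gf)
        marg_diff[j] = slope_m - slope_f
        rate_diff[j] = pm.mean() - pf.mean()
    logit_fit = theory.predicted_vs_estimated_slope(beta_logit, b_m - b_f)
    marginal_fit = theory.predicted_vs_estimated_slope(beta_linear, marg_diff)
    rows = []
    base = dict(
        scenario="slope", pi_female=cfg.pi, pi_male=cfg.pi,
        h2_female=np.nan, h2_male=np.nan, estimator="sex_gwas",
        replicate=0, seed=seed,
    )
    rows.append({**base, "metric": "slope_logit_scale", "value": logit_fit.slope})
    rows.append({**base, "metric": "slope_logit_se", "value": logit_fit.slope_se})
    rows.append(
        {**base, "metric": "slope_marginal_scale", "value": marginal_fit.slope}
    )
    rows.append(
        {**base, "metric": "slope_marginal_se", "value": marginal_fit.slope_se}
    )
    rows.append(
        {**base, "metric": "mean_rate_difference", "value": float(np.nanmean(rate_diff))}
    )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS), logit_fit, marginal_fit


# ----------------------------------------------------------------- config IO

_CONFIG_KINDS = {
    "pi_grid": PiGridConfig,
    "correction": CorrectionConfig,
    "mr": MrConfig,
    "power": PowerConfig,
    "slope": SlopeConfig,
}


def load_config(path, kind: str):
    """Load a YAML scenario file.

    Accepts either a flat mapping of config fields or the nested
    population/participation/experiment block layout; blocks are merged flat.
    """
    if kind not in _CONFIG_KINDS:
        raise ValueError(f"unknown experiment kind {kind!r}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat: dict = {}
    for key, value in raw.items():
        if key in ("population", "participation", "experiment") and isinstance(
            value, dict
        ):
            flat.update(value)
        else:
            flat[key] = value
    for key, value in list(flat.items()):
        if isinstance(value, list):
            flat[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
    return _CONFIG_KINDS[kind].from_dict(flat)
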