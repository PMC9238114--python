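"""Per-variant association engine on the participant subsample.

Each variant is tested marginally: logistic (maximum-likelihood, IRLS) or
ordinary-least-squares regression of an outcome on allele dosage plus shared
covariates, with Wald statistics. Fits are vectorized across variants in
blocks, which is why the Newton solver lives here rather than behind a
generic GLM library; per-variant agreement with a reference GLM fit is pinned
in the test suite.

Results are tidy pandas DataFrames with one row per (variant, stratum) and
columns ``variant_id beta se chi2 p n stratum outcome status``. Variants that
cannot be estimated (monomorphic, sparse genotype-by-outcome margins,
separation, non-convergence) are flagged via ``status``, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2 as chi2_dist

from .popsim import Cohort

__all__ = [
    "GWAS_COLUMNS",
    "InflationSummary",
    "logistic_gwas",
    "linear_gwas",
    "run_sex_gwas",
    "run_trait_gwas",
    "inflation_summary",
    "write_sumstats",
    "read_sumstats",
]

GWAS_COLUMNS = ["variant_id", "beta", "se", "chi2", "p", "n", "stratum", "outcome", "status"]

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_LOW_COUNT = "low_count"
STATUS_SEPARATION = "separation"
STATUS_NOT_CONVERGED = "not_converged"
STATUS_ZERO_RESIDUAL = "zero_residual"
STATUS_SMALL_STRATUM = "small_stratum"

# IRLS settings: deterministic, auditable failures
_IRLS_TOL = 1e-8
_IRLS_MAX_ITER = 50
_SEPARATION_BETA = 30.0


@dataclass(frozen=True)
class InflationSummary:
    """Mean chi-squared over validly estimated variants, against the null
    expectation of 1 (the Fig-1a style inflation statistic)."""

    mean_chi2: float
    n_variants: int
    expected_chi2: float = 1.0

    @property
    def ratio(self) -> float:
        return self.mean_chi2 / self.expected_chi2


def inflation_summary(results: pd.DataFrame) -> InflationSummary:
    ok = results[results["status"] == STATUS_OK]
    return InflationSummary(
        mean_chi2=float(ok["chi2"].mean()) if len(ok) else np.nan,
        n_variants=int(len(ok)),
    )


def _is_dosage_coded(G: np.ndarray) -> bool:
    return (
        np.issubdtype(G.dtype, np.integer)
        and int(G.min(initial=0)) >= 0
        and int(G.max(initial=0)) <= 2
    )


def _level_counts(G: np.ndarray) -> np.ndarray:
    """(m, 3) counts of dosage levels 0/1/2 per variant."""
    return np.stack([(G == lev).sum(axis=0) for lev in range(3)], axis=1)


def _precheck(
    y: np.ndarray | None, G: np.ndarray, min_count: int | None
) -> np.ndarray:
    """Per-variant status before fitting; outcome=None skips margin checks.

    The margin rule inspects the observed genotype-class totals and the
    outcome totals of the genotype-by-outcome table.
    """
    n, m = G.shape
    status = np.full(m, STATUS_OK, dtype=object)
    if _is_dosage_coded(G):
        counts = _level_counts(G)
        status[(counts > 0).sum(axis=1) < 2] = STATUS_MONOMORPHIC
        if min_count is not None and y is not None:
            observed_min = np.where(counts > 0, counts, np.iinfo(np.int64).max).min(axis=1)
            n1 = int(y.sum())
            low = (observed_min < min_count) | (min(n1, n - n1) < min_count)
            status[(status == STATUS_OK) & low] = STATUS_LOW_COUNT
        return status
    status[G.min(axis=0) == G.max(axis=0)] = STATUS_MONOMORPHIC
    if min_count is not None and y is not None:
        n1 = int(y.sum())
        for j in np.flatnonzero(status == STATUS_OK):
            _, counts = np.unique(G[:, j], return_counts=True)
            if counts.min() < min_count or min(n1, n - n1) < min_count:
                status[j] = STATUS_LOW_COUNT
    return status


def _logistic_fit_block(
    y: np.ndarray, G: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint IRLS over a block of variants.

    Model per variant j: logit P(y=1) = C @ theta_j + g_j * beta_j.
    Returns (beta, se, status_flags) for the dosage coefficient.
    """
    n, m = G.shape
    c = C.shape[1]
    p = c + 1
    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    coef = np.zeros((m, p))
    coef[:, 0] = logit(ybar)  # first covariate column is the intercept
    status = np.full(m, STATUS_NOT_CONVERGED, dtype=object)
    active = np.ones(m, dtype=bool)
    yf = y.astype(float)

    for _ in range(_IRLS_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ga = G[:, idx]
        eta = C @ coef[idx, :c].T + Ga * coef[idx, c]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = yf[:, None] - mu
        score = np.empty((idx.size, p))
        score[:, :c] = r.T @ C
        score[:, c] = np.einsum("nk,nk->k", Ga, r)
        info = np.empty((idx.size, p, p))
        info[:, :c, :c] = np.einsum("np,nk,nq->kpq", C, w, C)
        cross = np.einsum("np,nk,nk->kp", C, w, Ga)
        info[:, :c, c] = cross
        info[:, c, :c] = cross
        info[:, c, c] = np.einsum("nk,nk->k", w, Ga * Ga)
        try:
            step = np.linalg.solve(info, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # singular information for some variant: pseudo-inverse keeps the
            # batch going; the affected variant ends as separation/nonconverged
            step = (np.linalg.pinv(info) @ score[..., None])[..., 0]
        coef[idx] += step
        done = np.max(np.abs(step), axis=1) < _IRLS_TOL
        sep = np.abs(coef[idx, c]) > _SEPARATION_BETA
        status[idx[done & ~sep]] = STATUS_OK
        status[idx[sep]] = STATUS_SEPARATION
        active[idx[done | sep]] = False

    beta = coef[:, c].copy()
    se = np.full(m, np.nan)
    ok = status == STATUS_OK
    if ok.any():
        idx = np.flatnonzero(ok)
        Ga = G[:, idx]
        eta = C @ coef[idx, :c].T + Ga * coef[idx, c]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = np.empty((idx.size, p, p))
        info[:, :c, :c] = np.einsum("np,nk,nq->kpq", C, w, C)
        cross = np.einsum("np,nk,nk->kp", C, w, Ga)
        info[:, :c, c] = cross
        info[:, c, :c] = cross
        info[:, c, c] = np.einsum("nk,nk->k", w, Ga * Ga)
        cov = np.linalg.inv(info)
        var = cov[:, c, c]
        bad = ~np.isfinite(var) | (var <= 0)
        status[idx[bad]] = STATUS_SEPARATION
        se[idx[~bad]] = np.sqrt(var[~bad])
    beta[status != STATUS_OK] = np.nan
    return beta, se, status


def _is_binary(x: np.ndarray) -> bool:
    return np.isin(x, (0, 1)).all()


def _group_counts(
    y: np.ndarray, G: np.ndarray, cov: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse individual-level data onto the (genotype x covariate) design
    cells: returns (totals, successes, design) with design rows
    [1, g] or [1, g, cov] over the 3 (or 6) support points.

    Dosage is in {0,1,2} and the covariate binary, so these cell counts are
    sufficient statistics: the grouped MLE equals the individual-level MLE.
    """
    m = G.shape[1]
    levels = 3 if cov is None else 6
    totals = np.zeros((m, levels), dtype=np.int64)
    successes = np.zeros((m, levels), dtype=np.int64)
    case = y.astype(bool)
    cov_masks = [None] if cov is None else [cov == 0, cov == 1]
    for ci, cmask in enumerate(cov_masks):
        for is_case, ymask in ((0, ~case), (1, case)):
            rmask = ymask if cmask is None else (ymask & cmask)
            counts = _level_counts(G[rmask])
            cols = slice(3 * ci, 3 * ci + 3)
            totals[:, cols] += counts
            if is_case:
                successes[:, cols] = counts
    g_lev = np.tile(np.arange(3.0), levels // 3)
    cols = [np.ones(levels), g_lev]
    if cov is not None:
        cols.append(np.repeat([0.0, 1.0], 3))
    X = np.column_stack(cols)
    return totals, successes, X


def _logistic_fit_grouped(
    totals: np.ndarray, successes: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized binomial IRLS on the shared grouped design.

    totals/successes are (m, cells); X is the common (cells, p) design with
    the dosage column last but one convention kept: column 1 is dosage.
    Returns (beta, se, status) for the dosage coefficient.
    """
    m, cells = totals.shape
    p = X.shape[1]
    nt = totals.astype(float)
    kt = successes.astype(float)
    ybar = np.clip(kt.sum(axis=1) / nt.sum(axis=1), 1e-12, 1 - 1e-12)
    theta = np.zeros((m, p))
    theta[:, 0] = logit(ybar)
    status = np.full(m, STATUS_NOT_CONVERGED, dtype=object)
    active = np.ones(m, dtype=bool)
    for _ in range(_IRLS_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = theta[idx] @ X.T
        mu = expit(eta)
        w = nt[idx] * mu * (1.0 - mu)
        score = (kt[idx] - nt[idx] * mu) @ X
        info = np.einsum("mc,cp,cq->mpq", w, X, X)
        try:
            step = np.linalg.solve(info, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = (np.linalg.pinv(info) @ score[..., None])[..., 0]
        theta[idx] += step
        done = np.max(np.abs(step), axis=1) < _IRLS_TOL
        sep = np.abs(theta[idx, 1]) > _SEPARATION_BETA
        status[idx[done & ~sep]] = STATUS_OK
        status[idx[sep]] = STATUS_SEPARATION
        active[idx[done | sep]] = False
    beta = theta[:, 1].copy()
    se = np.full(m, np.nan)
    ok = status == STATUS_OK
    if ok.any():
        idx = np.flatnonzero(ok)
        mu = expit(theta[idx] @ X.T)
        w = nt[idx] * mu * (1.0 - mu)
        info = np.einsum("mc,cp,cq->mpq", w, X, X)
        cov = np.linalg.inv(info)
        var = cov[:, 1, 1]
        bad = ~np.isfinite(var) | (var <= 0)
        status[idx[bad]] = STATUS_SEPARATION
        se[idx[~bad]] = np.sqrt(var[~bad])
    beta[status != STATUS_OK] = np.nan
    return beta, se, status


def _as_result_frame(
    variant_ids, beta, se, n, stratum, outcome, status
) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (beta / se) ** 2
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p": chi2_dist.sf(chi2, df=1),
            "n": n,
            "stratum": stratum,
            "outcome": outcome,
            "status": status,
        }
    )


def logistic_gwas(
    outcome: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray | None = None,
    min_count: int = 5,
    variant_ids=None,
    stratum: str = "combined",
    outcome_name: str = "outcome",
    block_size: int = 128,
) -> pd.DataFrame:
    """Per-variant ML logistic regression of a binary outcome on dosage.

    ``covariates`` (if given) are shared columns added to every fit; an
    intercept is always included. Variants failing the ``min_count`` margin
    rule, monomorphic variants, separations and non-convergences are flagged.
    """
    outcome = np.asarray(outcome)
    if not np.isin(outcome, (0, 1)).all():
        raise ValueError("logistic outcome must be binary 0/1")
    G = np.asarray(genotypes)
    n, m = G.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        C = np.hstack([C, cov])
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("covariates are rank deficient")
    status = _precheck(outcome, G, min_count)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    fit_idx = np.flatnonzero(status == STATUS_OK)
    cov1 = None
    groupable = covariates is None
    if not groupable and C.shape[1] == 2 and _is_binary(C[:, 1]):
        cov1 = C[:, 1].astype(np.int8)
        groupable = True
    if groupable and _is_dosage_coded(G):
        # dosage and any binary covariate take at most 6 joint levels, whose
        # counts are sufficient: grouped IRLS gives the identical MLE, fast
        totals, successes, X = _group_counts(outcome, G[:, fit_idx], cov1)
        b, s, st = _logistic_fit_grouped(totals, successes, X)
        beta[fit_idx] = b
        se[fit_idx] = s
        status[fit_idx] = st
    else:
        Gf = G.astype(float)
        for start in range(0, fit_idx.size, block_size):
            idx = fit_idx[start : start + block_size]
            b, s, st = _logistic_fit_block(outcome, Gf[:, idx], C)
            beta[idx] = b
            se[idx] = s
            status[idx] = st
    return _as_result_frame(variant_ids, beta, se, n, stratum, outcome_name, status)


def linear_gwas(
    outcome: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_ids=None,
    stratum: str = "combined",
    outcome_name: str = "outcome",
) -> pd.DataFrame:
    """Per-variant OLS of a numeric outcome on dosage (+ shared covariates),
    via residualization on the covariates (Frisch-Waugh)."""
    y = np.asarray(outcome, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("outcome must be finite")
    if np.var(y) == 0.0:
        raise ValueError("outcome has zero variance")
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        C = np.hstack([C, cov])
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)
    gss = np.einsum("nm,nm->m", G_res, G_res)
    status = np.full(m, STATUS_OK, dtype=object)
    status[gss <= 1e-12] = STATUS_MONOMORPHIC
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (G_res.T @ y_res) / gss
    dof = n - C.shape[1] - 1
    tss = float(y_res @ y_res)
    rss = np.maximum(tss - beta**2 * gss, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rss / dof / gss)
    # numerically perfect fit: Wald se degenerates to the 0 limit
    exact = (status == STATUS_OK) & (rss <= 1e-12 * max(tss, 1e-300))
    status[exact] = STATUS_ZERO_RESIDUAL
    bad = status != STATUS_OK
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    return _as_result_frame(variant_ids, beta, se, n, stratum, outcome_name, status)


def run_sex_gwas(
    cohort: Cohort, min_count: int = 5
) -> tuple[pd.DataFrame, InflationSummary]:
    """Sex GWAS among participants: logistic regression of sex on each
    variant, no covariates. Autosomal signal here is the participation-bias
    readout."""
    part = cohort.participants() if cohort.participation is not None else None
    if part is None:
        raise ValueError("cohort has no participation indicator")
    if part.sex.min() == part.sex.max():
        raise ValueError("sex GWAS requires both sexes among participants")
    res = logistic_gwas(
        part.sex, part.genotypes, min_count=min_count, outcome_name="sex"
    )
    return res, inflation_summary(res)


def run_trait_gwas(
    cohort: Cohort,
    trait: str,
    mode: str = "combined",
    adjust_sex: bool = True,
    min_count: int = 5,
    min_stratum: int = 50,
) -> pd.DataFrame:
    """Trait GWAS among participants.

    mode='combined': one logistic fit per variant on all participants (sex as
    covariate when ``adjust_sex``). mode='stratified': separate fits within
    females and males; strata below ``min_stratum`` are flagged wholesale.
    """
    part = cohort.participants()
    y = part.traits[trait]
    if mode == "combined":
        cov = part.sex if adjust_sex else None
        return logistic_gwas(
            y, part.genotypes, covariates=cov, min_count=min_count,
            outcome_name=trait,
        )
    if mode != "stratified":
        raise ValueError("mode must be 'combined' or 'stratified'")
    frames = []
    for value, label in ((0, "female"), (1, "male")):
        mask = part.sex == value
        if int(mask.sum()) < min_stratum:
            frames.append(
                _as_result_frame(
                    [f"v{j}" for j in range(part.n_variants)],
                    np.full(part.n_variants, np.nan),
                    np.full(part.n_variants, np.nan),
                    int(mask.sum()), label, trait,
                    np.full(part.n_variants, STATUS_SMALL_STRATUM, dtype=object),
                )
            )
            continue
        frames.append(
            logistic_gwas(
                y[mask], part.genotypes[mask], min_count=min_count,
                stratum=label, outcome_name=trait,
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------- I/O

def write_sumstats(results: pd.DataFrame, path) -> None:
    """Tab-separated summary statistics (12 significant digits, NA for
    missing) — the interchange format for the combine stage."""
    df = results[GWAS_COLUMNS].copy()
    with open(path, "w") as fh:
        fh.write("\t".join(GWAS_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            out = []
            for col, val in zip(GWAS_COLUMNS, row):
                if col in ("beta", "se", "chi2", "p"):
                    out.append("NA" if not np.isfinite(val) else format(val, ".12g"))
                else:
                    out.append(str(val))
            fh.write("\t".join(out) + "\n")


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"variant_id": str})
    missing = set(GWAS_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics file lacks columns: {sorted(missing)}")
    if "status" not in df.columns:
        df["status"] = STATUS_OK
    return df
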