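"""Evidence combination on summary statistics.

Fixed-effects inverse-variance meta-analysis of sex-stratified GWAS — the
practical correction for sex-differential participation bias — and the
inverse-variance-weighted (IVW) Mendelian-randomization estimator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .assoc import GWAS_COLUMNS, STATUS_OK

__all__ = [
    "MrResult",
    "fixed_effects_meta",
    "meta_analyze",
    "mr_ivw",
    "mr_from_sumstats",
]


def fixed_effects_meta(
    betas: np.ndarray, ses: np.ndarray
) -> tuple[float, float]:
    """Inverse-variance fixed-effects pooling of any number of strata.

    w_s = 1/se_s^2; beta = sum(w b)/sum(w); se = sum(w)^(-1/2). NaN entries
    (flagged-missing strata) are ignored; with every stratum missing the
    result is (nan, nan).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    keep = np.isfinite(betas) & np.isfinite(ses)
    if np.any(ses[keep] <= 0):
        raise ValueError("standard errors must be positive")
    if not keep.any():
        return np.nan, np.nan
    w = 1.0 / ses[keep] ** 2
    return float(np.sum(w * betas[keep]) / np.sum(w)), float(np.sum(w) ** -0.5)


def meta_analyze(stratified: pd.DataFrame) -> pd.DataFrame:
    """Meta-analyze a stratified GWAS result table variant by variant.

    Input rows must carry stratum labels (e.g. female/male); output has
    stratum='meta'. Flagged strata are treated as missing; a variant with a
    single valid stratum reproduces that stratum's estimate exactly. Cochran's
    Q over contributing strata is emitted as column ``q``.
    """
    rows = []
    for (vid, outcome), grp in stratified.groupby(
        ["variant_id", "outcome"], sort=False
    ):
        ok = grp[grp["status"] == STATUS_OK]
        beta, se = fixed_effects_meta(ok["beta"].to_numpy(), ok["se"].to_numpy())
        k = len(ok)
        if k and np.isfinite(beta):
            w = 1.0 / ok["se"].to_numpy() ** 2
            q = float(np.sum(w * (ok["beta"].to_numpy() - beta) ** 2))
            chi2 = (beta / se) ** 2
            p = float(chi2_dist.sf(chi2, df=1))
            status = STATUS_OK
        else:
            q = np.nan
            chi2 = np.nan
            p = np.nan
            status = "no_valid_stratum"
        rows.append(
            {
                "variant_id": vid,
                "beta": beta,
                "se": se,
                "chi2": chi2,
                "p": p,
                "n": int(grp["n"].sum()),
                "stratum": "meta",
                "outcome": outcome,
                "status": status,
                "n_strata": k,
                "q": q,
            }
        )
    return pd.DataFrame(rows, columns=GWAS_COLUMNS + ["n_strata", "q"])


@dataclass(frozen=True)
class MrResult:
    """MR-IVW causal-effect estimate from per-instrument summary statistics."""

    estimate: float
    se: float
    p: float
    n_instruments: int
    source: str = "combined"

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def mr_ivw(
    beta_exposure: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    source: str = "combined",
) -> MrResult:
    """Inverse-variance-weighted MR: the zero-intercept regression of outcome
    effects on exposure effects with weights 1/se_outcome^2.

    estimate = sum(bx by / se^2) / sum(bx^2 / se^2); se = sum(bx^2/se^2)^(-1/2).
    Exposure-side uncertainty is ignored (first-order IVW). With one
    instrument this is the Wald ratio by/bx.
    """
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    keep = np.isfinite(bx) & np.isfinite(by) & np.isfinite(sy) & (sy > 0)
    bx, by, sy = bx[keep], by[keep], sy[keep]
    if bx.size == 0 or np.all(bx == 0.0):
        raise ValueError("MR-IVW needs at least one instrument with a nonzero exposure effect")
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    estimate = float(np.sum(w * bx * by) / denom)
    se = float(denom**-0.5)
    chi2 = (estimate / se) ** 2
    return MrResult(
        estimate=estimate,
        se=se,
        p=float(chi2_dist.sf(chi2, df=1)),
        n_instruments=int(bx.size),
        source=source,
    )


def mr_from_sumstats(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    instruments: list[str] | None = None,
    source: str = "combined",
) -> MrResult:
    """Run MR-IVW from two GWAS result tables joined on variant_id.

    ``instruments`` restricts to the given variant ids (oracle instruments in
    the simulation experiments); otherwise every jointly valid variant is
    used.
    """
    ex = exposure[exposure["status"] == STATUS_OK][["variant_id", "beta"]]
    out = outcome[outcome["status"] == STATUS_OK][["variant_id", "beta", "se"]]
    merged = ex.merge(out, on="variant_id", suffixes=("_x", "_y"))
    if instruments is not None:
        merged = merged[merged["variant_id"].isin(instruments)]
    return mr_ivw(
        merged["beta_x"].to_numpy(),
        merged["beta_y"].to_numpy(),
        merged["se"].to_numpy(),
        source=source,
    )
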