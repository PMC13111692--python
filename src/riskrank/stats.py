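"""Statistical battery: paired contrasts and mixed models with Elo terms.

The central model is a linear mixed model per PT parameter on the per-chunk
analysis table,

    response ~ age_category + sex + elo_z + elo_z**2 + experience_z
               + (1 | individual)

fitted by REML with a random intercept per individual and no random slopes
(each animal only ever occupies a narrow band of ranks, so a common slope
across the full predictor range is not estimable subject-by-subject).
Reference levels are adult (age) and male (sex); continuous covariates are
z-scored; responses for lam and the two alphas are natural-log transformed
upstream.  Significance is declared at the conservative P < 0.01.

A variant replaces the quadratic Elo term with conflict outcome
predictability (COP), which carries the same U-shape information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "LMMResult",
    "wilcoxon_paired",
    "variability_contrast",
    "fit_lmm",
    "fit_lmm_cop",
    "model_diagnostics",
    "RESPONSES",
]

#: admissible LMM responses on the assembled table
RESPONSES = ("rho_plus", "rho_minus", "log_alpha_plus", "log_alpha_minus", "log_lam")

P_THRESHOLD = 0.01


def wilcoxon_paired(x, y) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Uses the exact null distribution for n <= 25 pairs (without ties in the
    absolute differences) and the normal approximation above.  All-zero
    differences carry no signal and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    nz = d[d != 0]
    if len(nz) == 0:
        # identical vectors carry no signal at all; flag it rather than fail
        warnings.warn("all paired differences are zero; no signal", RuntimeWarning)
        return 0.0, 1.0
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ties) else "approx"
    res = scipy.stats.wilcoxon(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def variability_contrast(
    table: pd.DataFrame,
    gain_col: str = "rho_plus",
    loss_col: str = "rho_minus",
) -> Tuple[pd.DataFrame, float, float]:
    """Within-individual variance of the gain vs loss risk parameter.

    Computes each individual's sample variance of the two columns across its
    chunks (individuals with < 2 chunks are skipped) and compares the paired
    variances with the signed-rank test.  Returns (per-individual table,
    statistic, p).
    """
    rows = []
    for ind, sub in table.groupby("individual_id"):
        if len(sub) < 2:
            continue
        rows.append(
            {
                "individual_id": ind,
                "var_gain": float(sub[gain_col].var(ddof=1)),
                "var_loss": float(sub[loss_col].var(ddof=1)),
                "n_chunks": len(sub),
            }
        )
    if len(rows) < 2:
        raise ValueError("need >= 2 individuals with >= 2 chunks each")
    per_ind = pd.DataFrame(rows)
    stat, p = wilcoxon_paired(per_ind["var_gain"], per_ind["var_loss"])
    return per_ind, stat, p


@dataclass
class LMMResult:
    response: str
    formula: str
    fixed: pd.DataFrame  # index: term; columns: estimate, ci_low, ci_high, p
    sigma2: float  # residual variance
    tau00: float  # random-intercept variance
    icc: float  # tau00 / (tau00 + sigma2)
    r2_marginal: float
    r2_conditional: float
    n_individuals: int
    n_obs: int
    aic: float
    converged: bool
    warnings: Tuple[str, ...] = ()

    def significant(self, term: str, threshold: float = P_THRESHOLD) -> bool:
        return bool(self.fixed.loc[term, "p"] < threshold)


_FIXED_TERMS = (
    "C(age_category, Treatment('adult'))"
    " + C(sex, Treatment('male')) + elo_z + {quad} + experience_z"
)


def _fit_mixed(
    table: pd.DataFrame, response: str, quad_term: str, reml: bool
) -> LMMResult:
    df = table.copy()
    df["elo_z2"] = df["elo_z"] ** 2

    flags: List[str] = []
    dropped_quad = False
    if df[quad_term].nunique() <= 1:
        # a constant quadratic/COP column is collinear with the intercept:
        # its coefficient is undefined, so fit without it and report NaN
        warnings.warn(
            f"rank-deficient fixed-effect design for {response}: "
            f"{quad_term} is constant, its coefficient is not identified",
            RuntimeWarning,
        )
        flags.append("rank_deficient")
        dropped_quad = True

    quad_in_formula = "1" if dropped_quad else quad_term
    formula = f"{response} ~ " + _FIXED_TERMS.format(quad=quad_in_formula)
    model = smf.mixedlm(formula, df, groups=df["individual_id"])
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        warnings.warn(
            f"rank-deficient fixed-effect design for {response}; "
            "some coefficients are not identified",
            RuntimeWarning,
        )
        flags.append("rank_deficient")
    # near-singular random-effect variances can break gradient-based
    # optimizers; fall back to derivative-free methods before giving up
    result = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for method in (["lbfgs", "bfgs"], ["powell"], ["nm"]):
            try:
                result = model.fit(reml=reml, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                flags.append(f"optimizer_failed_{method[0]}")
        if result is None:
            raise RuntimeError(f"mixed model for {response} failed to fit")
        for w in caught:
            flags.append(type(w.message).__name__)

    tau00 = float(result.cov_re.iloc[0, 0])
    sigma2 = float(result.scale)
    if tau00 < 1e-10:
        flags.append("singular_random_effect")
    icc = tau00 / (tau00 + sigma2)

    fe_names = model.exog_names
    params = result.params[: len(fe_names)]
    ci = result.conf_int().iloc[: len(fe_names)]
    pvals = result.pvalues[: len(fe_names)]
    fixed = pd.DataFrame(
        {
            "estimate": params.to_numpy(dtype=float),
            "ci_low": ci.iloc[:, 0].to_numpy(dtype=float),
            "ci_high": ci.iloc[:, 1].to_numpy(dtype=float),
            "p": pvals.to_numpy(dtype=float),
        },
        index=fe_names,
    )
    if dropped_quad:
        fixed.loc[quad_term] = [np.nan, np.nan, np.nan, np.nan]

    # Nakagawa-style R2: fixed-effect variance over total variance
    var_f = float(np.var(model.exog @ params.to_numpy(dtype=float)))
    denom = var_f + tau00 + sigma2
    r2m = var_f / denom
    r2c = (var_f + tau00) / denom

    return LMMResult(
        response=response,
        formula=formula,
        fixed=fixed,
        sigma2=sigma2,
        tau00=tau00,
        icc=icc,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_individuals=int(df["individual_id"].nunique()),
        n_obs=int(len(df)),
        aic=float(result.aic),
        converged=bool(result.converged),
        warnings=tuple(dict.fromkeys(flags)),
    )


def fit_lmm(table: pd.DataFrame, response: str, reml: bool = True) -> LMMResult:
    """Mixed model with linear + quadratic z-scored Elo terms.

    The quadratic term ``elo_z2`` (square of the z-scored Elo) is the
    U-shape test: a positive significant coefficient means animals at both
    hierarchy extremes have higher response values than mid-ranking ones.
    """
    if response not in table.columns:
        raise ValueError(f"response {response!r} not in table")
    if table["individual_id"].nunique() < 2:
        raise ValueError("mixed model needs >= 2 individuals")
    return _fit_mixed(table, response, "elo_z2", reml)


def fit_lmm_cop(table: pd.DataFrame, response: str, reml: bool = True) -> LMMResult:
    """Variant replacing the quadratic Elo term with COP."""
    if "cop" not in table.columns:
        raise ValueError("table has no 'cop' column")
    if table["individual_id"].nunique() < 2:
        raise ValueError("mixed model needs >= 2 individuals")
    return _fit_mixed(table, response, "cop", reml)


def model_diagnostics(table: pd.DataFrame, result: LMMResult) -> dict:
    """Residual-based model checks (reported, never gating the fit).

    Returns Shapiro-Wilk normality of residuals and a Breusch-Pagan-style
    heteroscedasticity screen (correlation of |residual| with the fitted
    values).
    """
    df = table.copy()
    df["elo_z2"] = df["elo_z"] ** 2
    import statsmodels.formula.api as smf_

    model = smf_.mixedlm(result.formula, df, groups=df["individual_id"])
    fe = result.fixed["estimate"].to_numpy()
    fitted = model.exog @ fe
    resid = df[result.response].to_numpy(dtype=float) - fitted
    sub = resid if len(resid) <= 5000 else resid[:: max(1, len(resid) // 5000)]
    sh_stat, sh_p = scipy.stats.shapiro(sub)
    het_r, het_p = scipy.stats.pearsonr(np.abs(resid), fitted)
    return {
        "shapiro_stat": float(sh_stat),
        "shapiro_p": float(sh_p),
        "abs_resid_fitted_corr": float(het_r),
        "abs_resid_fitted_p": float(het_p),
    }
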