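"""eQTL regression models: conventional, purity-interaction, and effect tests.

Two linear models are fit per SNP-gene pair.  The conventional model regresses
bulk expression on genotype dosage plus covariates,

    y = b0 + b1*x + covariates + e,

and attributes the eQTL to the tumor as a whole.  The interaction model adds
the tumor-associated normal-cell fraction p (= 1 - purity, so that p = 0 means
100% cancer cells) and its product with genotype,

    y = b0 + b1*x + covariates + b4*p + b5*(p*x) + e.

Because p is an actual bounded cell-fraction estimate, the genotype main
effect b1 is the eQTL effect extrapolated to a pure cancer-cell sample; the
interaction coefficient b5 measures how the effect differs between the two
cell types.  Significance of an eQTL is a two-sided t test on b1 with
residual degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EqtlFit",
    "fit_conventional",
    "fit_interaction",
    "run_scan",
    "bh_fdr",
    "zdiff_test",
    "binned_effects",
]

logger = logging.getLogger(__name__)

#: stable column order of scan result tables
RESULT_COLUMNS = [
    "variant_id",
    "gene_id",
    "model",
    "beta1",
    "se1",
    "t",
    "p",
    "q",
    "beta4",
    "beta5",
    "n",
]


@dataclass
class EqtlFit:
    """One SNP-gene regression fit.

    ``beta1`` is the genotype effect (for the interaction model: extrapolated
    to 100% cancer cells), ``beta4`` the normal-fraction main effect and
    ``beta5`` the genotype x normal-fraction interaction (both NaN for the
    conventional model).  ``reason`` is non-empty when the design was
    degenerate and the statistics are NaN.
    """

    model: str
    beta1: float
    se1: float
    t: float
    p: float
    n: int
    df_resid: int
    beta0: float = np.nan
    beta4: float = np.nan
    beta5: float = np.nan
    reason: str = ""

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval for beta1."""
        half = stats.t.ppf(0.5 + level / 2.0, self.df_resid) * self.se1
        return self.beta1 - half, self.beta1 + half


def _as_covar_array(covars, n: int) -> tuple[np.ndarray, list[str]]:
    if covars is None:
        return np.empty((n, 0)), []
    if isinstance(covars, pd.DataFrame):
        return covars.to_numpy(dtype=float), [str(c) for c in covars.columns]
    arr = np.atleast_2d(np.asarray(covars, dtype=float))
    if arr.shape[0] != n:
        arr = arr.T
    return arr, [f"covar_{i}" for i in range(arr.shape[1])]


def _check_nonconstant(vec: np.ndarray, name: str) -> None:
    if np.ptp(vec) == 0:
        raise ValueError(f"design term '{name}' is constant; cannot fit")


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """Least squares via Cholesky on the normal equations.

    Returns (beta, se, df_resid); raises np.linalg.LinAlgError on a
    rank-deficient design.
    """
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than parameters ({k})")
    xtx = X.T @ X
    try:
        chol = linalg.cho_factor(xtx)
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "rank-deficient design (collinear terms among: " + ", ".join(names) + ")"
        )
    beta = linalg.cho_solve(chol, X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = linalg.cho_solve(chol, np.eye(k))
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    return beta, se, df


def _fit(y, X, names, model, genotype_idx, extra_idx=None) -> EqtlFit:
    beta, se, df = _ols(y, X, names)
    i = genotype_idx
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = beta[i] / se[i]
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    fit = EqtlFit(
        model=model,
        beta1=float(beta[i]),
        se1=float(se[i]),
        t=float(t_stat),
        p=float(p),
        n=X.shape[0],
        df_resid=df,
        beta0=float(beta[0]),
    )
    if extra_idx is not None:
        fit.beta4 = float(beta[extra_idx[0]])
        fit.beta5 = float(beta[extra_idx[1]])
    return fit


def fit_conventional(y, x, covars=None) -> EqtlFit:
    """Fit the conventional eQTL model y ~ genotype + covariates (OLS).

    The eQTL statistics (beta1, se1, t, p) come from the genotype term with
    n - k residual degrees of freedom.  Raises ValueError on a constant
    genotype vector and LinAlgError on a collinear design.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    _check_nonconstant(x, "genotype")
    covar_arr, covar_names = _as_covar_array(covars, len(y))
    X = np.column_stack([np.ones(len(y)), x, covar_arr])
    names = ["intercept", "genotype", *covar_names]
    return _fit(y, X, names, "conventional", genotype_idx=1)


def fit_interaction(y, x, purity=None, normal_fraction=None, covars=None) -> EqtlFit:
    """Fit the purity-interaction model y ~ x + covars + p + p:x (OLS).

    Exactly one of ``purity`` (cancer-cell fraction) or ``normal_fraction``
    must be given; a cancer-cell fraction is converted internally to
    p = 1 - purity so that beta1 extrapolates the eQTL effect to 100% cancer
    cells.  beta4 is the normal-fraction main effect, beta5 the cell-type
    difference (interaction) effect.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if (purity is None) == (normal_fraction is None):
        raise ValueError("pass exactly one of purity or normal_fraction")
    if purity is not None:
        logger.debug("converting cancer purity to normal fraction (p = 1 - purity)")
        p = 1.0 - np.asarray(purity, dtype=float)
    else:
        p = np.asarray(normal_fraction, dtype=float)
    _check_nonconstant(x, "genotype")
    _check_nonconstant(p, "normal_fraction (purity)")
    covar_arr, covar_names = _as_covar_array(covars, len(y))
    X = np.column_stack([np.ones(len(y)), x, covar_arr, p, p * x])
    names = ["intercept", "genotype", *covar_names, "normal_fraction", "genotype:normal_fraction"]
    return _fit(y, X, names, "interaction", genotype_idx=1, extra_idx=(X.shape[1] - 2, X.shape[1] - 1))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are excluded from the adjustment and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def run_scan(
    expr: pd.DataFrame,
    geno: pd.DataFrame,
    pairs: pd.DataFrame,
    purity: pd.Series | None = None,
    covars: pd.DataFrame | None = None,
    model: str = "conventional",
    purity_as_covariate: bool = False,
) -> pd.DataFrame:
    """Fit one model per cis pair and BH-adjust over all tested pairs.

    ``expr`` and ``geno`` are samples x features frames sharing a sample
    index; ``pairs`` has variant_id/gene_id columns.  ``purity`` is the
    cancer-cell fraction; required for the interaction model, and optionally
    added as a plain additive covariate to the conventional model
    (``purity_as_covariate=True``) -- the control showing that purity cannot
    simply be "adjusted for".  Missing values are handled per pair by
    complete-case analysis.  Degenerate designs yield NaN statistics with a
    reason code rather than being dropped.
    """
    if model not in ("conventional", "interaction"):
        raise ValueError(f"unknown model '{model}'")
    if not expr.index.equals(geno.index):
        both = expr.index.intersection(geno.index)
        missing = expr.index.symmetric_difference(geno.index)
        if len(both) == 0 or len(missing):
            raise ValueError(
                f"sample IDs misaligned between expression and genotypes: {list(missing[:5])}"
            )
    if model == "interaction" or purity_as_covariate:
        if purity is None:
            raise ValueError(f"model '{model}' requires a purity vector")
        if not expr.index.equals(purity.index):
            raise ValueError("sample IDs misaligned between expression and purity")
        p_norm = 1.0 - purity.to_numpy(dtype=float)
    covar_df = covars
    if covars is not None and not expr.index.equals(covars.index):
        raise ValueError("sample IDs misaligned between expression and covariates")

    records = []
    for variant_id, gene_id in pairs[["variant_id", "gene_id"]].itertuples(index=False):
        y = expr[gene_id].to_numpy(dtype=float)
        x = geno[variant_id].to_numpy(dtype=float)
        keep = ~(np.isnan(y) | np.isnan(x))
        cov = covar_df.loc[expr.index[keep]] if covar_df is not None else None
        try:
            if model == "interaction":
                fit = fit_interaction(
                    y[keep], x[keep], normal_fraction=p_norm[keep], covars=cov
                )
            elif purity_as_covariate:
                cov_arr, _ = _as_covar_array(cov, int(keep.sum()))
                cov_full = np.column_stack([cov_arr, p_norm[keep]])
                fit = fit_conventional(y[keep], x[keep], covars=cov_full)
            else:
                fit = fit_conventional(y[keep], x[keep], covars=cov)
        except (ValueError, np.linalg.LinAlgError) as err:
            fit = EqtlFit(
                model=model, beta1=np.nan, se1=np.nan, t=np.nan, p=np.nan,
                n=int(keep.sum()), df_resid=0, reason=str(err),
            )
        records.append(
            (variant_id, gene_id, model, fit.beta1, fit.se1, fit.t, fit.p,
             np.nan, fit.beta4, fit.beta5, fit.n)
        )
    out = pd.DataFrame(records, columns=RESULT_COLUMNS)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def zdiff_test(beta_a, se_a, beta_b, se_b) -> pd.DataFrame:
    """Z test for a difference between two effect estimates.

    ``z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2)`` with a two-sided p-value
    from the standard normal; used to compare the same SNP-gene effect across
    two cohorts/tissues.  Accepts scalars or aligned vectors.
    """
    beta_a, se_a, beta_b, se_b = (np.atleast_1d(np.asarray(v, dtype=float))
                                  for v in (beta_a, se_a, beta_b, se_b))
    if (se_a <= 0).any() or (se_b <= 0).any():
        raise ValueError("standard errors must be positive")
    z = (beta_a - beta_b) / np.sqrt(se_a**2 + se_b**2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"beta_a": beta_a, "se_a": se_a, "beta_b": beta_b, "se_b": se_b, "z": z, "p": p}
    )


def binned_effects(
    y,
    x,
    purity: pd.Series | np.ndarray,
    n_bins: int = 5,
    covars=None,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, EqtlFit, EqtlFit]:
    """Deconstruct an eQTL effect across equal-sized purity bins.

    Samples are split into ``n_bins`` equal-sized groups by purity rank; the
    conventional model is refit within each bin.  Returns the per-bin effect
    table (with t-based CIs) together with the whole-cohort conventional and
    interaction fits, for plotting effect-vs-purity deconstructions.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    pvec = np.asarray(purity, dtype=float)
    n_params = 2 + (_as_covar_array(covars, len(y))[0].shape[1])
    if len(y) < n_bins * (n_params + 2):
        raise ValueError(
            f"too few samples ({len(y)}) for {n_bins} bins of >= {n_params + 2}"
        )
    order = np.argsort(pvec, kind="stable")
    rows = []
    for b, idx in enumerate(np.array_split(order, n_bins)):
        cov_b = covars.iloc[idx] if isinstance(covars, pd.DataFrame) else (
            None if covars is None else np.asarray(covars)[idx]
        )
        fit = fit_conventional(y[idx], x[idx], covars=cov_b)
        lo, hi = fit.ci(ci_level)
        rows.append(
            {
                "bin_index": b,
                "purity_low": float(pvec[idx].min()),
                "purity_high": float(pvec[idx].max()),
                "beta": fit.beta1,
                "ci_low": lo,
                "ci_high": hi,
                "n_in_bin": len(idx),
            }
        )
    whole_conv = fit_conventional(y, x, covars=covars)
    whole_int = fit_interaction(y, x, purity=pvec, covars=covars)
    return pd.DataFrame(rows), whole_conv, whole_int
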