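"""Covariate-adjusted Spearman association scans, cytokine group
comparisons, and cross-cohort heterogeneity (Cochran's Q).

"Adjusted Spearman" is the residualised partial Spearman correlation:
both variables are inverse-rank transformed, each is residualised on the
covariates by least squares, and the Spearman correlation of the
residuals is tested with a t approximation on ``n - 2 - k`` degrees of
freedom.  Missing phenotype values are handled pairwise per association,
never listwise across a scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr, design_matrix
from .transforms import inverse_rank_transform

__all__ = [
    "HeterogeneityResult",
    "adjusted_spearman",
    "association_scan",
    "cytokine_group_comparison",
    "cochran_q",
    "fisher_z",
]


@dataclass
class HeterogeneityResult:
    """Cochran's Q homogeneity test across per-cohort effect estimates."""

    q_statistic: float
    df: int
    p: float
    betas: np.ndarray
    ses: np.ndarray


def _residualize(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def adjusted_spearman(
    x, y, covariates: pd.DataFrame | None = None
) -> tuple[float, float, int]:
    """Covariate-adjusted Spearman correlation.

    Returns ``(rho, p, n_used)`` after pairwise-complete deletion over
    x, y and the covariates.  With no covariates this equals the plain
    Spearman correlation (residualising on the intercept preserves
    ranks).
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n_cov = 0
    if covariates is not None and covariates.shape[1] > 0:
        if len(covariates) != len(x):
            raise ValueError("covariates must align with x and y")
        design = design_matrix(covariates.reset_index(drop=True),
                               list(covariates.columns))
        n_cov = design.shape[1] - 1
        complete = (~x.isna()) & (~y.isna()) & (~design.isna().any(axis=1))
        xmat = design.loc[complete].to_numpy(dtype=float)
    else:
        complete = (~x.isna()) & (~y.isna())
        xmat = np.ones((int(complete.sum()), 1))
    n_used = int(complete.sum())
    if n_used < max(10, n_cov + 3):
        raise ValueError(
            f"only {n_used} complete cases; need at least {max(10, n_cov + 3)}"
        )
    xv = inverse_rank_transform(x[complete].to_numpy())
    yv = inverse_rank_transform(y[complete].to_numpy())
    rx = _residualize(xv, xmat)
    ry = _residualize(yv, xmat)
    rho = float(stats.spearmanr(rx, ry).statistic)
    df = n_used - 2 - n_cov
    if df <= 0:
        raise ValueError("not enough degrees of freedom after adjustment")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p, n_used


def association_scan(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates=(),
    fdr_threshold: float = 0.1,
    extra_covariates=None,
) -> pd.DataFrame:
    """Adjusted-Spearman scan of every (feature, phenotype) pair.

    BH correction is applied across the block; when ``extra_covariates``
    is given (e.g. sexual-behaviour variables) a second pass with the
    extended covariate set is run and both passes are reported, tagged by
    their ``covariate_set``.  Phenotypes that are entirely missing are
    skipped with a warning.
    """
    common = features.index.intersection(phenotypes.index).intersection(metadata.index)
    if len(common) == 0:
        raise ValueError("no shared sample ids between features and phenotypes")
    features = features.loc[common]
    phenotypes = phenotypes.loc[common]
    metadata = metadata.loc[common]

    passes = [tuple(covariates)]
    if extra_covariates:
        passes.append(tuple(covariates) + tuple(extra_covariates))

    records = []
    for cov_set in passes:
        cov_df = metadata[list(cov_set)] if cov_set else None
        tag = "+".join(cov_set) if cov_set else "none"
        block = []
        for pheno in phenotypes.columns:
            y = phenotypes[pheno]
            if y.isna().all():
                warnings.warn(
                    f"phenotype {pheno!r} entirely missing; skipped",
                    UserWarning, stacklevel=2,
                )
                continue
            for feat in features.columns:
                try:
                    rho, p, n_used = adjusted_spearman(
                        features[feat].to_numpy(), y.to_numpy(), cov_df
                    )
                except ValueError:
                    continue
                block.append(
                    dict(feature_id=feat, phenotype_id=pheno, rho=rho, p=p,
                         n_used=n_used, covariate_set=tag)
                )
        if block:
            df = pd.DataFrame.from_records(block)
            df["q"] = bh_fdr(df["p"].to_numpy())
            df["significant"] = df["q"] < fdr_threshold
            records.append(df)
    if not records:
        return pd.DataFrame(
            columns=["feature_id", "phenotype_id", "rho", "p", "n_used",
                     "covariate_set", "q", "significant"]
        )
    return pd.concat(records, ignore_index=True)


def cytokine_group_comparison(
    cytokines: pd.DataFrame,
    group,
    metadata: pd.DataFrame,
    covariates=("age", "sex"),
    fdr_threshold: float = 0.05,
    case_level=None,
) -> pd.DataFrame:
    """Per cytokine-stimulus pair, OLS of INT(cytokine) on group plus
    covariates (default age and sex), BH-corrected across the pairs.
    Constant cytokines are flagged rather than tested."""
    group = pd.Series(group)
    if group.index.equals(pd.RangeIndex(len(group))):
        group.index = cytokines.index
    common = cytokines.index.intersection(metadata.index)
    cytokines, metadata, group = (
        cytokines.loc[common], metadata.loc[common], group.reindex(common)
    )
    levels = sorted(group.dropna().astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"cytokine comparison requires 2 groups, got {levels}")
    if case_level is None:
        case_level = "case" if "case" in levels else levels[0]

    records = []
    for name in cytokines.columns:
        y = cytokines[name]
        frame = pd.concat([y.rename("_y"), metadata[list(covariates)],
                           group.rename("_group")], axis=1).dropna()
        if frame.empty or frame["_y"].nunique() <= 1:
            records.append(dict(cytokine=name, beta=np.nan, se=np.nan, p=1.0,
                                n_used=len(frame), constant=True))
            continue
        x = design_matrix(frame, list(covariates))
        x["group"] = (frame["_group"].astype(str) == str(case_level)).astype(float)
        yv = inverse_rank_transform(frame["_y"].to_numpy())
        xm = x.to_numpy(dtype=float)
        beta_all, *_ = np.linalg.lstsq(xm, yv, rcond=None)
        resid = yv - xm @ beta_all
        dof = len(yv) - xm.shape[1]
        sigma2 = float((resid**2).sum() / dof)
        xtx_inv = np.linalg.inv(xm.T @ xm)
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        t = beta_all[-1] / se if se > 0 else 0.0
        p = float(2.0 * stats.t.sf(abs(t), dof))
        records.append(dict(cytokine=name, beta=float(beta_all[-1]), se=se, p=p,
                            n_used=len(frame), constant=False))
    out = pd.DataFrame.from_records(records)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_threshold
    return out


def fisher_z(rho: float, n: int) -> tuple[float, float]:
    """Fisher z-transform of a correlation with its standard error
    ``1/sqrt(n - 3)``, for feeding correlations into :func:`cochran_q`."""
    if not -1 < rho < 1:
        raise ValueError("rho must lie strictly within (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3 for a Fisher-z standard error")
    return float(np.arctanh(rho)), float(1.0 / np.sqrt(n - 3))


def cochran_q(betas, ses) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test over per-cohort effect estimates.

    ``Q = sum w_i (beta_i - beta_w)^2`` with inverse-variance weights
    ``w_i = 1/se_i^2`` and weighted mean ``beta_w``; p from the
    chi-square upper tail on k-1 degrees of freedom.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and ses must be 1-D vectors of equal length")
    if len(betas) < 2:
        raise ValueError("need at least 2 estimates")
    if (ses <= 0).any():
        raise ValueError("standard errors must be strictly positive")
    w = 1.0 / ses**2
    beta_w = float((w * betas).sum() / w.sum())
    q = float((w * (betas - beta_w) ** 2).sum())
    df = len(betas) - 1
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q_statistic=q, df=df, p=p, betas=betas, ses=ses)
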