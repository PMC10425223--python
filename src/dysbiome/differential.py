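"""Covariate-adjusted differential abundance, BH-FDR, fold changes, and
enriched/depleted feature-set definition."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transforms import AbundanceTable, TransformedTable, table_pseudocount

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "bh_fdr",
    "design_matrix",
    "differential_abundance",
    "fold_change",
    "define_feature_sets",
    "replication_check",
]


@dataclass(frozen=True)
class FeatureSet:
    """A named set of features with a common direction of change."""

    name: str
    feature_ids: tuple
    direction: str  # 'enriched' | 'depleted'

    def __len__(self) -> int:
        return len(self.feature_ids)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_i = min_{j >= i} p_(j) * m / j`` mapped back to the input order;
    satisfies ``p <= q <= 1`` and is monotone in ``p``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def design_matrix(
    metadata: pd.DataFrame, columns, add_intercept: bool = True
) -> pd.DataFrame:
    """Build a numeric design matrix from metadata columns.

    Numeric columns pass through; object/categorical columns are dummy
    coded dropping the first level.  Collinear designs are rejected with
    the offending columns named.
    """
    parts = []
    for name in columns:
        if name not in metadata.columns:
            raise ValueError(f"metadata column {name!r} not found")
        col = metadata[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            parts.append(col.astype(float).to_frame(name))
    if parts:
        x = pd.concat(parts, axis=1)
    else:
        x = pd.DataFrame(index=metadata.index)
    if add_intercept:
        x.insert(0, "intercept", 1.0)
    values = x.to_numpy(dtype=float)
    if values.size and np.linalg.matrix_rank(values) < values.shape[1]:
        bad = []
        for j, cname in enumerate(x.columns):
            reduced = np.delete(values, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(values):
                bad.append(str(cname))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return x


def _ols_scan(
    y: np.ndarray, x: np.ndarray, coef_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-column OLS of y (n x m) on x (n x p); returns
    (beta, se, p) for the coefficient at ``coef_index``."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    betas = xtx_inv @ x.T @ y  # p x m
    resid = y - x @ betas
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    var = sigma2 * xtx_inv[coef_index, coef_index]
    beta = betas[coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var)
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, pvals


def differential_abundance(
    transformed: TransformedTable,
    metadata: pd.DataFrame,
    group_var: str,
    covariates=(),
    case_level=None,
    abundance: AbundanceTable | None = None,
) -> pd.DataFrame:
    """Per-feature OLS of transformed abundance on group + covariates.

    The group coefficient is coded so that ``beta > 0`` means higher in
    the case (``case_level``) group.  Samples with missing covariates or
    group labels are dropped and logged.  Constant features receive
    ``p = 1`` and a ``constant`` flag.  BH q-values are computed across
    the features of this call (correct species and pathways separately
    by calling once per family).  If ``abundance`` (the raw relative
    table) is given, per-feature fold changes are attached.
    """
    needed = [group_var, *covariates]
    meta = metadata.loc[metadata.index.intersection(transformed.data.index), needed]
    complete = meta.dropna()
    dropped = sorted(set(meta.index) - set(complete.index))
    if dropped:
        logger.info("dropping %d samples with missing covariates: %s",
                    len(dropped), dropped[:10])
    data = transformed.data.loc[complete.index]

    group = complete[group_var]
    levels = sorted(group.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"group variable {group_var!r} must have 2 levels, got {levels}")
    if case_level is None:
        case_level = "case" if "case" in levels else levels[0]
    case = (group.astype(str) == str(case_level)).astype(float)

    x_cov = design_matrix(complete, covariates, add_intercept=True)
    x = pd.concat([x_cov, case.rename("group")], axis=1)
    # validate full design (naming collinear columns)
    design_matrix(pd.concat([complete[list(covariates)], case.rename("group")], axis=1),
                  [*covariates, "group"])
    y = data.to_numpy(dtype=float)
    beta, se, p = _ols_scan(y, x.to_numpy(dtype=float), coef_index=x.shape[1] - 1)

    constant = data.nunique(axis=0).to_numpy() <= 1
    p = np.where(constant, 1.0, p)
    beta = np.where(constant, 0.0, beta)

    out = pd.DataFrame(
        {
            "feature_id": transformed.feature_ids,
            "beta": beta,
            "se": se,
            "p": p,
            "q": bh_fdr(p),
            "direction": np.where(beta > 0, "enriched", "depleted"),
            "constant": constant,
            "n_used": len(complete),
        }
    )
    if abundance is not None:
        fc = fold_change(abundance, metadata[group_var], case_level=case_level)
        out["fold_change"] = fc.reindex(out["feature_id"]).to_numpy()
        out["log2_fold_change"] = np.log2(out["fold_change"])
    return out


def fold_change(
    table: AbundanceTable, group_labels, case_level=None
) -> pd.Series:
    """Per-feature case/control ratio of arithmetic group means of
    relative abundance, pseudocounted with the table pseudocount."""
    labels = pd.Series(group_labels)
    if labels.index.equals(pd.RangeIndex(len(labels))):
        labels.index = table.data.index
    labels = labels.reindex(table.data.index).astype(str)
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"fold change requires 2 groups, got {levels}")
    if case_level is None:
        case_level = "case" if "case" in levels else levels[0]
    case_level = str(case_level)
    control_level = [lv for lv in levels if lv != case_level][0]
    pc = table_pseudocount(table.data)
    mean_case = table.data.loc[labels == case_level].mean(axis=0)
    mean_control = table.data.loc[labels == control_level].mean(axis=0)
    return ((mean_case + pc) / (mean_control + pc)).rename("fold_change")


def define_feature_sets(
    da: pd.DataFrame, fdr_threshold: float = 0.05, name: str = "features"
) -> tuple[FeatureSet, FeatureSet]:
    """Partition q < threshold features by the sign of beta into
    (enriched, depleted) sets.  Empty sides emit a warning; downstream
    scoring refuses empty sets."""
    hits = da[da["q"] < fdr_threshold]
    enriched = tuple(hits.loc[hits["beta"] > 0, "feature_id"])
    depleted = tuple(hits.loc[hits["beta"] < 0, "feature_id"])
    if not enriched or not depleted:
        warnings.warn(
            f"feature-set definition for {name!r} produced an empty side "
            f"(enriched={len(enriched)}, depleted={len(depleted)})",
            UserWarning,
            stacklevel=2,
        )
    return (
        FeatureSet(f"{name}_enriched", enriched, "enriched"),
        FeatureSet(f"{name}_depleted", depleted, "depleted"),
    )


def replication_check(
    primary: pd.DataFrame, secondary: pd.DataFrame, fdr_threshold: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Check which primary hits replicate in a secondary comparison.

    A primary hit (q < threshold) replicates iff the secondary q is below
    the threshold *and* the beta signs agree.  Returns per-feature flags
    and summary counts/fractions.
    """
    merged = primary.merge(
        secondary, on="feature_id", suffixes=("_primary", "_secondary")
    )
    if merged.empty:
        raise ValueError("primary and secondary results share no features")
    merged["primary_hit"] = merged["q_primary"] < fdr_threshold
    merged["replicated"] = (
        merged["primary_hit"]
        & (merged["q_secondary"] < fdr_threshold)
        & (np.sign(merged["beta_primary"]) == np.sign(merged["beta_secondary"]))
    )
    n_hits = int(merged["primary_hit"].sum())
    n_rep = int(merged["replicated"].sum())
    summary = {
        "n_overlap": len(merged),
        "n_primary_hits": n_hits,
        "n_replicated": n_rep,
        "fraction_replicated": (n_rep / n_hits) if n_hits else float("nan"),
    }
    cols = ["feature_id", "beta_primary", "q_primary", "beta_secondary",
            "q_secondary", "primary_hit", "replicated"]
    return merged[cols], summary
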