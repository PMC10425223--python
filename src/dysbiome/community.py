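"""Alpha/beta diversity, ordination, permutational ANOVA, and rank-based
group tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .transforms import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "PCoAResult",
    "shannon_index",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
    "wilcoxon_rank_sum",
    "dunn_test",
    "rank_group_tests",
]


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids.

    Supported metrics (``bray_curtis``, ``jaccard``) are bounded in
    [0, 1]; symmetry and a zero diagonal are enforced on construction.
    """

    ids: list
    values: np.ndarray
    metric_tag: str = "bray_curtis"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if self.metric_tag in ("bray_curtis", "jaccard"):
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValueError(
                    f"{self.metric_tag} distances must lie in [0, 1]"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def filter(self, ids) -> "DistanceMatrix":
        ids = list(ids)
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids, self.values[np.ix_(pos, pos)], self.metric_tag)


@dataclass
class PermanovaResult:
    """Sequential (Type-I) partition of a distance matrix, group term
    last, with a permutation p-value for the group term."""

    terms: pd.DataFrame  # index: term names + 'residual'; cols df, ss, r_squared, pseudo_F, p
    n_permutations: int
    seed: int | None

    @property
    def group_p(self) -> float:
        return float(self.terms["p"].dropna().iloc[-1])

    @property
    def group_r_squared(self) -> float:
        name = self.terms["p"].dropna().index[-1]
        return float(self.terms.loc[name, "r_squared"])


@dataclass
class PCoAResult:
    """Classical scaling of a dissimilarity matrix.  Negative
    eigenvalues are retained and flagged, never silently dropped."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    has_negative_eigenvalues: bool


def shannon_index(table: AbundanceTable) -> pd.Series:
    """Shannon diversity H = -sum p_i ln p_i per sample (natural log,
    computed over non-zero entries after row closure)."""
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    if (sums == 0).any():
        sample = table.data.index[int(np.argmax(sums == 0))]
        raise ValueError(f"sample {sample!r} has all-zero abundances")
    p = values / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-plogp.sum(axis=1), index=table.data.index, name="shannon")


def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    condensed = pdist(table.data.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(
        list(table.data.index), squareform(condensed), metric_tag="bray_curtis"
    )


def _gower_matrix(d: np.ndarray) -> np.ndarray:
    """Double-centred -D^2/2 (Gower) matrix."""
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Principal coordinates analysis (classical scaling).

    Axes are ordered by decreasing eigenvalue; coordinates are returned
    for the first ``k`` positive axes, and explained-variance fractions
    are computed over the positive eigenvalues.
    """
    n = d.n
    if k >= n:
        raise ValueError(f"k must be < number of samples ({n}), got {k}")
    g = _gower_matrix(d.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    pos = np.clip(eigvals, 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(pos[:k])
    total_pos = pos.sum()
    explained = (pos[:k] / total_pos) if total_pos > 0 else np.zeros(k)
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=d.ids, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        proportion_explained=explained,
        has_negative_eigenvalues=bool(eigvals.min() < -1e-8 * max(1.0, abs(eigvals).max())),
    )


def _hat_trace(x: np.ndarray, g: np.ndarray) -> float:
    """tr(H G) for the hat matrix H of design x, via thin QR."""
    q, _ = np.linalg.qr(x)
    return float(np.einsum("ij,ij->", q, g @ q))


def _group_design(groups: pd.Series) -> np.ndarray:
    dummies = pd.get_dummies(groups, drop_first=True)
    return dummies.to_numpy(dtype=float)


def permanova(
    d: DistanceMatrix,
    groups,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> PermanovaResult:
    """PERMANOVA with sequential sums of squares, covariates first.

    Covariate terms are entered one at a time in the given column order,
    the grouping factor last; the p-value for the group term comes from
    permuting the group labels while holding covariates fixed.
    Deterministic given ``seed``.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    groups = pd.Series(groups)
    if groups.index.equals(pd.RangeIndex(len(groups))):
        groups.index = pd.Index(d.ids)
    groups = groups.reindex(d.ids)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("grouping must have at least 2 levels")
    if (counts < 2).any():
        small = counts.index[counts < 2][0]
        raise ValueError(f"group level {small!r} has fewer than 2 samples")

    n = d.n
    g = _gower_matrix(d.values)
    ss_total = float(np.trace(g))
    intercept = np.ones((n, 1))

    cov_names: list[str] = []
    cov_blocks: list[np.ndarray] = []
    if covariates is not None and covariates.shape[1] > 0:
        covariates = covariates.reindex(d.ids)
        if covariates.isna().any().any():
            raise ValueError("covariates contain missing values")
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                block = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            else:
                block = col.to_numpy(dtype=float)[:, None]
            cov_names.append(str(name))
            cov_blocks.append(block)

    group_block = _group_design(groups)
    df_group = group_block.shape[1]

    rows = []
    x = intercept
    tr_prev = _hat_trace(x, g)
    for name, block in zip(cov_names, cov_blocks):
        x = np.hstack([x, block])
        tr_here = _hat_trace(x, g)
        rows.append((name, block.shape[1], tr_here - tr_prev))
        tr_prev = tr_here
    x_reduced = x
    x_full = np.hstack([x_reduced, group_block])
    tr_full = _hat_trace(x_full, g)
    ss_group = tr_full - tr_prev
    ss_resid = ss_total - tr_full
    df_resid = n - x_full.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    f_obs = (ss_group / df_group) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        x_perm = np.hstack([x_reduced, group_block[perm]])
        tr_perm = _hat_trace(x_perm, g)
        ss_g = tr_perm - tr_prev
        ss_r = ss_total - tr_perm
        f_perm = (ss_g / df_group) / (ss_r / df_resid)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p_group = (count + 1) / (n_perm + 1)

    records = []
    for name, df_term, ss in rows:
        records.append(
            dict(term=name, df=df_term, ss=ss, r_squared=ss / ss_total,
                 pseudo_F=(ss / df_term) / (ss_resid / df_resid), p=np.nan)
        )
    records.append(
        dict(term="group", df=df_group, ss=ss_group,
             r_squared=ss_group / ss_total, pseudo_F=f_obs, p=p_group)
    )
    records.append(
        dict(term="residual", df=df_resid, ss=ss_resid,
             r_squared=ss_resid / ss_total, pseudo_F=np.nan, p=np.nan)
    )
    terms = pd.DataFrame.from_records(records).set_index("term")
    return PermanovaResult(terms=terms, n_permutations=n_perm, seed=seed)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test with average-rank
    ties and tie-corrected variance; exact null for small tie-free
    samples.  Returns (U statistic of the first sample, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and max(len(x), len(y)) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def dunn_test(values, groups) -> pd.DataFrame:
    """Dunn's post-hoc test: pairwise z statistics on shared (pooled)
    average ranks with tie correction, BH-adjusted two-sided p-values.

    Returns a DataFrame with one row per group pair.
    """
    from .differential import bh_fdr

    values = np.asarray(values, dtype=float)
    groups = pd.Series(groups).reset_index(drop=True)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok].reset_index(drop=True)
    levels = list(pd.unique(groups))
    if len(levels) < 3:
        raise ValueError("dunn test requires at least 3 groups")
    counts = groups.value_counts()
    if (counts == 0).any() or len(values) == 0:
        raise ValueError("every group must be non-empty")
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    mean_rank = {lv: ranks[groups == lv].mean() for lv in levels}
    sizes = {lv: int((groups == lv).sum()) for lv in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    base_var = n * (n + 1) / 12.0 - tie_term
    records = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            records.append(dict(group_a=a, group_b=b, z=z, p=min(p, 1.0)))
    out = pd.DataFrame.from_records(records)
    out["p_adjusted"] = bh_fdr(out["p"].to_numpy())
    return out


def rank_group_tests(values, groups, method: str) -> pd.DataFrame:
    """Dispatch for rank-based group comparisons.

    ``method='wilcoxon_two_sample'`` requires exactly two groups;
    ``method='dunn'`` requires three or more and BH-adjusts the pairwise
    p-values.
    """
    groups = pd.Series(groups).reset_index(drop=True)
    levels = list(pd.unique(groups.dropna()))
    if method == "wilcoxon_two_sample":
        if len(levels) != 2:
            raise ValueError(
                f"wilcoxon_two_sample requires exactly 2 groups, got {len(levels)}"
            )
        values = np.asarray(values, dtype=float)
        stat, p = wilcoxon_rank_sum(
            values[(groups == levels[0]).to_numpy()],
            values[(groups == levels[1]).to_numpy()],
        )
        return pd.DataFrame(
            [dict(group_a=levels[0], group_b=levels[1], statistic=stat, p=p)]
        )
    if method == "dunn":
        return dunn_test(values, groups)
    raise ValueError(f"unknown method {method!r}")
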