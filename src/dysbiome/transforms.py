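"""Compositional normalisation, prevalence filtering, CLR, and rank-based
inverse-normal transforms.

All tables are handled samples-in-rows internally.  The canonical
pre-analysis pipeline is::

    closure -> CLR -> prevalence filter -> per-feature INT

Note the filter is applied *after* the CLR, so the geometric mean in the
CLR is taken over all features; the prevalence mask itself is computed
from the raw (zero-containing) table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTable",
    "TransformedTable",
    "table_pseudocount",
    "prevalence_mask",
    "prevalence_filter",
    "clr_transform",
    "inverse_rank_transform",
    "int_transform_table",
]


@dataclass
class AbundanceTable:
    """Sample-by-feature table of non-negative (relative) abundances.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and feature labels
        (taxonomic lineage strings or pathway ids) as columns.
    relative:
        If True, every row is required to sum to 1 within ``1e-6``.
    """

    data: pd.DataFrame
    relative: bool = True

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance table contains non-finite values")
        if (values < 0).any():
            raise ValueError("abundance table contains negative values")
        if self.relative and len(self.data):
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-6
            if bad.any():
                sample = self.data.index[int(np.argmax(bad))]
                raise ValueError(
                    f"table flagged relative but row {sample!r} sums to "
                    f"{sums[np.argmax(bad)]:.6g}, not 1"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    def closure(self) -> "AbundanceTable":
        """Return a copy with every row rescaled to sum to one."""
        sums = self.data.sum(axis=1)
        if (sums == 0).any():
            sample = self.data.index[int(np.argmax(sums.to_numpy() == 0))]
            raise ValueError(f"sample {sample!r} has all-zero abundances")
        return AbundanceTable(self.data.div(sums, axis=0), relative=True)

    def subset_features(self, features) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[:, list(features)], relative=False)


@dataclass
class TransformedTable:
    """A transformed abundance table; ``transform_tag`` records the chain
    applied (``CLR``, ``INT``, or ``CLR+INT``)."""

    data: pd.DataFrame
    transform_tag: str = "CLR"

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    def subset_features(self, features) -> "TransformedTable":
        return TransformedTable(self.data.loc[:, list(features)], self.transform_tag)


def table_pseudocount(data) -> float:
    """Half the smallest non-zero value of the table (multiplicative
    replacement pseudocount used for zeros throughout)."""
    values = np.asarray(data if not isinstance(data, AbundanceTable) else data.data)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("table has no non-zero entries")
    return 0.5 * float(nonzero.min())


def prevalence_mask(
    table: AbundanceTable,
    cohort_labels,
    threshold: float = 0.2,
    mode: str = "any",
) -> pd.Series:
    """Boolean keep-mask per feature from per-cohort prevalence.

    ``mode='any'`` keeps a feature if its prevalence (fraction of samples
    with non-zero abundance) reaches ``threshold`` in at least one cohort;
    ``mode='all'`` requires the threshold in every cohort.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    labels = pd.Series(cohort_labels)
    if labels.index.equals(pd.RangeIndex(len(labels))):
        labels.index = table.data.index
    labels = labels.reindex(table.data.index)
    if labels.isna().any():
        missing = labels.index[labels.isna()][0]
        raise ValueError(f"cohort label missing for sample {missing!r}")
    present = table.data > 0
    per_cohort = present.groupby(labels, observed=True).mean()
    keep = (per_cohort >= threshold).any(axis=0) if mode == "any" else (
        per_cohort >= threshold
    ).all(axis=0)
    return keep


def prevalence_filter(
    table: AbundanceTable,
    cohort_labels,
    threshold: float = 0.2,
    mode: str = "any",
) -> AbundanceTable:
    """Drop features below the per-cohort prevalence threshold.

    Feature order is preserved.  An empty result is returned with a
    warning rather than raised.
    """
    keep = prevalence_mask(table, cohort_labels, threshold, mode)
    kept = table.data.loc[:, keep[keep].index]
    if kept.shape[1] == 0:
        warnings.warn(
            "prevalence filter removed every feature", UserWarning, stacklevel=2
        )
    return AbundanceTable(kept, relative=False)


def clr_transform(
    table: AbundanceTable, pseudocount: float | None = None
) -> TransformedTable:
    """Centred log-ratio transform with multiplicative zero replacement.

    Zeros are replaced by ``pseudocount`` (default: half the smallest
    non-zero value of the table), rows are re-closed, and each entry
    becomes ``log(x_i / geometric_mean(x))``.  Every output row sums to
    zero.
    """
    values = table.data.to_numpy(dtype=float)
    row_sums = values.sum(axis=1)
    if (row_sums == 0).any():
        sample = table.data.index[int(np.argmax(row_sums == 0))]
        raise ValueError(f"sample {sample!r} has all-zero abundances")
    pc = table_pseudocount(values) if pseudocount is None else float(pseudocount)
    filled = np.where(values > 0, values, pc)
    filled /= filled.sum(axis=1, keepdims=True)
    logged = np.log(filled)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return TransformedTable(
        pd.DataFrame(clr, index=table.data.index, columns=table.data.columns),
        transform_tag="CLR",
    )


def inverse_rank_transform(values) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    Maps values to normal quantiles ``Phi^-1((r - 3/8) / (n + 1/4))``
    using average ranks for ties.  Missing entries are passed through as
    NaN; an all-constant vector maps to zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n == 0:
        return out
    if n < 2:
        raise ValueError("inverse_rank_transform needs at least 2 observations")
    obs = x[mask]
    if np.all(obs == obs[0]):
        warnings.warn(
            "all values identical; inverse-rank transform returns zeros",
            UserWarning,
            stacklevel=2,
        )
        out[mask] = 0.0
        return out
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


def int_transform_table(table: TransformedTable | pd.DataFrame) -> TransformedTable:
    """Apply the inverse-rank transform feature-by-feature."""
    if isinstance(table, TransformedTable):
        df, tag = table.data, table.transform_tag + "+INT"
    else:
        df, tag = table, "INT"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        transformed = df.apply(lambda col: inverse_rank_transform(col.to_numpy()))
    transformed.index = df.index
    return TransformedTable(transformed, transform_tag=tag)
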