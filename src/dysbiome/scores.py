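"""Per-sample summary scores: Prevotella/Bacteroides ratio and the
log2-geometric-mean dysbiosis / function-imbalance scores.

The dysbiosis score of a sample is

    log2( geomean(abundance + pc | enriched set)
          / geomean(abundance + pc | depleted set) )

computed from case-derived enriched/depleted feature sets.  Applied to a
species table it is the dysbiosis index (DI); applied to a pathway table
with pathway-derived sets it is the function-imbalance (FI) score.
Because the sets travel as plain feature-id lists, scoring an external
cohort's table with case-derived sets is a file-level operation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import FeatureSet
from .transforms import AbundanceTable, table_pseudocount

logger = logging.getLogger(__name__)

__all__ = ["genus_totals", "pb_ratio", "dysbiosis_score", "score_panel"]


def _genus_of(feature_id: str) -> str | None:
    for part in str(feature_id).split("|"):
        if part.startswith("g__"):
            return part[3:]
    return None


def genus_totals(table: AbundanceTable, genus: str) -> pd.Series:
    """Sum abundances of all features whose lineage carries ``g__<genus>``."""
    cols = [f for f in table.feature_ids if _genus_of(f) == genus]
    if not cols:
        return pd.Series(0.0, index=table.data.index)
    return table.data[cols].sum(axis=1)


def pb_ratio(
    table: AbundanceTable,
    numerator_genus: str = "Prevotella",
    denominator_genus: str = "Bacteroides",
) -> pd.Series:
    """Per-sample genus-ratio (total Prevotella + pc) / (total
    Bacteroides + pc).  Rejected if neither genus occurs in the table;
    zero denominators are kept finite by the pseudocount and flagged in
    the log."""
    num_cols = [f for f in table.feature_ids if _genus_of(f) == numerator_genus]
    den_cols = [f for f in table.feature_ids if _genus_of(f) == denominator_genus]
    if not num_cols and not den_cols:
        raise ValueError(
            f"neither genus {numerator_genus!r} nor {denominator_genus!r} "
            "present in the table"
        )
    pc = table_pseudocount(table.data)
    num = (table.data[num_cols].sum(axis=1) if num_cols else 0.0) + pc
    den = (table.data[den_cols].sum(axis=1) if den_cols else 0.0) + pc
    if isinstance(den, pd.Series) and (den <= pc).any():
        n_zero = int((den <= pc).sum())
        logger.warning(
            "%d samples have zero %s abundance; ratio kept finite by pseudocount",
            n_zero, denominator_genus,
        )
    ratio = num / den
    return pd.Series(np.asarray(ratio, dtype=float), index=table.data.index,
                     name="pb_ratio")


def dysbiosis_score(
    table: AbundanceTable,
    enriched: FeatureSet,
    depleted: FeatureSet,
    pseudocount: float | None = None,
) -> pd.Series:
    """Per-sample log2 ratio of geometric means over the enriched versus
    depleted feature sets (pseudocounted).  Features missing from the
    table are skipped with a log message; a set that is empty (before or
    after intersection) is rejected."""
    if len(enriched) == 0 or len(depleted) == 0:
        raise ValueError("dysbiosis score requires non-empty enriched and depleted sets")
    pc = table_pseudocount(table.data) if pseudocount is None else float(pseudocount)

    def _geomean_log2(feature_set: FeatureSet) -> np.ndarray:
        present = [f for f in feature_set.feature_ids if f in table.data.columns]
        missing = len(feature_set) - len(present)
        if missing:
            logger.info("%d features of set %r missing from table; skipped",
                        missing, feature_set.name)
        if not present:
            raise ValueError(f"no features of set {feature_set.name!r} in table")
        values = table.data[present].to_numpy(dtype=float) + pc
        return np.log2(values).mean(axis=1)

    score = _geomean_log2(enriched) - _geomean_log2(depleted)
    return pd.Series(score, index=table.data.index, name="dysbiosis_score")


def score_panel(
    species: AbundanceTable,
    pathways: AbundanceTable | None,
    species_enriched: FeatureSet,
    species_depleted: FeatureSet,
    pathway_enriched: FeatureSet | None = None,
    pathway_depleted: FeatureSet | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample score panel: Shannon index, P/B ratio, DI
    score and (when pathway inputs are given) FI score."""
    from .community import shannon_index

    panel = pd.DataFrame(index=species.data.index)
    panel["shannon"] = shannon_index(species)
    panel["pb_ratio"] = pb_ratio(species)
    panel["di_score"] = dysbiosis_score(species, species_enriched, species_depleted)
    if pathways is not None and pathway_enriched is not None and pathway_depleted is not None:
        panel["fi_score"] = dysbiosis_score(pathways, pathway_enriched, pathway_depleted)
    if not np.isfinite(panel.to_numpy(dtype=float)).all():
        raise ValueError("score panel contains non-finite values")
    return panel
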