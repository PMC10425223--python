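"""Strain typing from gene-family presence/absence profiles.

Samples are clustered by complete-linkage agglomeration on binary
Jaccard distances and the tree is cut at a fixed height (default 0.3);
small clusters are excluded from downstream contrasts.  Cluster-versus-
cohort enrichment uses Fisher's exact test; per-gene differential
carriage uses logistic regression with an exact-test fallback under
perfect separation; annotation enrichment uses one-sided hypergeometric
over-representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .community import DistanceMatrix
from .differential import bh_fdr, design_matrix
from .transforms import inverse_rank_transform

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFamilyMatrix",
    "StrainClustering",
    "jaccard_distance_matrix",
    "cluster_and_cut",
    "cluster_cohort_enrichment",
    "differential_gene_families",
    "pfam_enrichment",
    "strain_phenotype_association",
]


@dataclass
class GeneFamilyMatrix:
    """Binary gene-family presence/absence profiles for one species.

    ``data`` is samples-in-rows (transposed from the genes-in-rows file
    layout); ``pfam_map`` optionally maps gene-family ids to sets of
    Pfam labels.  Samples with no present gene family are dropped with a
    warning.
    """

    data: pd.DataFrame
    pfam_map: dict | None = None

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("gene-family matrix must be binary (0/1)")
        self.data = self.data.astype(np.int8)
        empty = self.data.sum(axis=1) == 0
        if empty.any():
            dropped = list(self.data.index[empty])
            warnings.warn(
                f"dropping {len(dropped)} samples with no present gene "
                f"family: {dropped[:5]}",
                UserWarning,
                stacklevel=2,
            )
            self.data = self.data.loc[~empty]

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_family_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class StrainClustering:
    """Complete-linkage tree over Jaccard distances with a fixed-height
    cut, small-cluster exclusion, and the cluster-by-cohort table."""

    linkage_matrix: np.ndarray
    cut_height: float
    cluster_labels: pd.Series  # retained samples only
    excluded_samples: list
    cohort_contingency: pd.DataFrame | None = None

    @property
    def cluster_ids(self) -> list:
        return sorted(self.cluster_labels.unique())

    def samples_in(self, cluster_id) -> list:
        return list(self.cluster_labels.index[self.cluster_labels == cluster_id])


def jaccard_distance_matrix(m: GeneFamilyMatrix) -> DistanceMatrix:
    """Binary Jaccard distance 1 - |intersection|/|union| between the
    presence sets of each sample pair; joint absences are ignored."""
    if len(m.data) < 2:
        raise ValueError("need at least 2 samples")
    condensed = pdist(m.data.to_numpy(dtype=bool), metric="jaccard")
    return DistanceMatrix(m.sample_ids, squareform(condensed), metric_tag="jaccard")


def cluster_and_cut(
    d: DistanceMatrix,
    cut_height: float = 0.3,
    min_cluster_size: int = 20,
) -> StrainClustering:
    """Complete-linkage clustering cut at ``cut_height``; clusters smaller
    than ``min_cluster_size`` are moved to ``excluded_samples``.

    Cluster ids are renumbered 1..k by decreasing size among retained
    clusters.
    """
    z = linkage(d.condensed(), method="complete")
    max_height = float(z[:, 2].max()) if len(z) else 0.0
    if not 0 < cut_height:
        raise ValueError(f"cut_height must be positive, got {cut_height}")
    if len(z) and cut_height > max_height:
        logger.info("cut height %.3g above the root (%.3g); one cluster",
                    cut_height, max_height)
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=d.ids, name="cluster")
    sizes = labels.value_counts()
    kept_ids = sizes.index[sizes >= min_cluster_size]
    excluded = sorted(labels.index[~labels.isin(kept_ids)])
    retained = labels[labels.isin(kept_ids)]
    if retained.empty:
        raise ValueError(
            f"all samples excluded: largest cluster has {int(sizes.max())} "
            f"samples but min_cluster_size={min_cluster_size}"
        )
    # stable renumbering by decreasing size (ties by original id)
    order = sorted(kept_ids, key=lambda c: (-int(sizes[c]), c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    retained = retained.map(remap).rename("cluster")
    return StrainClustering(
        linkage_matrix=z,
        cut_height=cut_height,
        cluster_labels=retained,
        excluded_samples=excluded,
    )


def cluster_cohort_enrichment(
    clustering: StrainClustering, cohort_labels
) -> pd.DataFrame:
    """Fisher-exact enrichment of each retained cluster in the cohorts.

    With exactly two retained clusters and two cohorts a single 2x2 test
    is performed; with more clusters, each cluster is tested against the
    rest and the p-values are BH-adjusted across clusters.  A zero
    margin yields p = 1 with a flag.
    """
    labels = pd.Series(cohort_labels)
    if labels.index.equals(pd.RangeIndex(len(labels))):
        raise ValueError("cohort_labels must be indexed by sample id")
    cohorts = labels.reindex(clustering.cluster_labels.index)
    if cohorts.isna().any():
        missing = cohorts.index[cohorts.isna()][0]
        raise ValueError(f"cohort label missing for sample {missing!r}")
    contingency = pd.crosstab(clustering.cluster_labels, cohorts)
    clustering.cohort_contingency = contingency
    cohort_levels = list(contingency.columns)
    if len(cohort_levels) < 2:
        raise ValueError("need at least 2 cohorts")
    clusters = clustering.cluster_ids
    if len(clusters) < 2:
        raise ValueError("need at least 2 retained clusters")

    records = []
    for c in clusters:
        in_c = contingency.loc[c]
        rest = contingency.drop(index=c).sum(axis=0)
        if len(cohort_levels) == 2:
            table = np.array([[in_c.iloc[0], in_c.iloc[1]],
                              [rest.iloc[0], rest.iloc[1]]], dtype=int)
        else:
            # first cohort vs all others
            table = np.array(
                [[in_c.iloc[0], in_c.iloc[1:].sum()],
                 [rest.iloc[0], rest.iloc[1:].sum()]], dtype=int
            )
        zero_margin = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if zero_margin:
            p, odds, flag = 1.0, np.nan, True
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            flag = False
        records.append(dict(cluster=c, n=int(in_c.sum()), odds_ratio=odds,
                            p=float(p), zero_margin=flag))
    out = pd.DataFrame.from_records(records)
    if len(clusters) == 2:
        # one 2x2 comparison; both rows describe the same test
        out["q"] = out["p"]
    else:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def _fisher_fallback(presence: np.ndarray, exposure: np.ndarray) -> float:
    table = np.array(
        [
            [int(((presence == 1) & (exposure == 1)).sum()),
             int(((presence == 1) & (exposure == 0)).sum())],
            [int(((presence == 0) & (exposure == 1)).sum()),
             int(((presence == 0) & (exposure == 0)).sum())],
        ]
    )
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def differential_gene_families(
    m: GeneFamilyMatrix,
    clustering: StrainClustering,
    metadata: pd.DataFrame,
    covariates=("age", "sex", "read_count"),
    clusters: tuple = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene-family logistic regression of presence on cluster
    membership plus covariates (Wald p, BH across gene families).

    ``clusters`` selects the two retained clusters to contrast (default:
    the two largest).  Gene families constant across the contrasted
    samples are excluded and listed with a flag.  Perfect separation is
    detected and assigned a two-sided Fisher-exact fallback p with a
    ``separation`` flag, so p-value semantics stay uniform.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if clusters is None:
        clusters = tuple(clustering.cluster_ids[:2])
    if len(clusters) != 2:
        raise ValueError("exactly two clusters must be contrasted")
    keep = clustering.cluster_labels[clustering.cluster_labels.isin(clusters)]
    samples = keep.index.intersection(m.data.index).intersection(metadata.index)
    meta = metadata.loc[samples, list(covariates)].dropna()
    samples = meta.index
    if len(samples) < len(covariates) + 4:
        raise ValueError("too few samples with complete covariates")
    exposure = (keep.reindex(samples) == clusters[1]).astype(float)
    x = design_matrix(meta, list(covariates))
    x["cluster"] = exposure
    xm = x.to_numpy(dtype=float)
    data = m.data.loc[samples]

    records = []
    for gene in data.columns:
        y = data[gene].to_numpy(dtype=float)
        if y.min() == y.max():
            records.append(dict(gene_family_id=gene, beta=np.nan, p=np.nan,
                                constant=True, separation=False))
            continue
        beta = p = np.nan
        separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, xm).fit(disp=0, maxiter=100)
            beta = float(fit.params[-1])
            p = float(fit.pvalues[-1])
            se = float(fit.bse[-1])
            if not np.isfinite(p) or not fit.mle_retvals.get("converged", True) \
               or abs(beta) > 15 or se > 100:
                separated = True
        except (PerfectSeparationError, np.linalg.LinAlgError, Exception):
            separated = True
        if separated:
            p = _fisher_fallback(data[gene].to_numpy(), exposure.to_numpy())
            direction = data[gene][exposure == 1].mean() - data[gene][exposure == 0].mean()
            beta = float(np.sign(direction) * np.inf) if direction != 0 else 0.0
        records.append(dict(gene_family_id=gene, beta=beta, p=p,
                            constant=False, separation=separated))
    out = pd.DataFrame.from_records(records)
    tested = ~out["constant"]
    q = np.full(len(out), np.nan)
    q[tested.to_numpy()] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["significant"] = out["q"] < fdr_threshold
    return out


def pfam_enrichment(
    hits,
    m: GeneFamilyMatrix,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of Pfam categories in
    a hit set of gene families.

    The universe is the set of gene families present in the matrix that
    carry at least one Pfam annotation; ``p = P(X >= k_hits)`` under
    hypergeometric(universe, category, draw), BH-adjusted across Pfams.
    """
    if m.pfam_map is None:
        raise ValueError("gene-family matrix has no pfam_map")
    hits = set(hits)
    universe = [g for g in m.gene_family_ids if m.pfam_map.get(g)]
    universe_set = set(universe)
    unknown = hits - set(m.gene_family_ids)
    if unknown:
        raise ValueError(f"hit gene families not in the matrix: {sorted(unknown)[:5]}")
    draw = hits & universe_set
    if not hits:
        warnings.warn("empty hit set; no enrichment computed", UserWarning,
                      stacklevel=2)
        return pd.DataFrame(
            columns=["pfam_label", "k_hits", "category_size", "draw_size",
                     "universe_size", "p", "q"]
        )
    categories: dict[str, set] = {}
    for gene in universe:
        for pfam in m.pfam_map[gene]:
            categories.setdefault(pfam, set()).add(gene)
    big_m, big_n = len(universe_set), len(draw)
    records = []
    for pfam in sorted(categories):
        cat = categories[pfam]
        k = len(cat & draw)
        p = float(stats.hypergeom.sf(k - 1, big_m, len(cat), big_n))
        records.append(dict(pfam_label=pfam, k_hits=k, category_size=len(cat),
                            draw_size=big_n, universe_size=big_m, p=p))
    out = pd.DataFrame.from_records(records)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_threshold
    return out


def strain_phenotype_association(
    clustering: StrainClustering,
    phenotypes: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates=("age", "sex", "read_count"),
    species_abundance: pd.Series | None = None,
    encoding: str = "indicator",
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Linear association of phenotypes with strain carriage.

    Exposure encoding per strain cluster: ``indicator`` uses a carrier
    0/1 indicator over the retained samples; ``abundance`` uses the
    species relative abundance restricted to that strain's carriers
    (zero elsewhere), which requires ``species_abundance``.  Each model
    is OLS of INT(phenotype) on exposure + covariates, BH at
    ``fdr_threshold`` within the block.  Output betas and ses are
    suitable for a Cochran's Q contrast between strains.
    """
    if encoding not in ("indicator", "abundance"):
        raise ValueError(f"unknown encoding {encoding!r}")
    if encoding == "abundance" and species_abundance is None:
        raise ValueError("encoding='abundance' requires species_abundance")
    retained = clustering.cluster_labels
    records = []
    for cluster in clustering.cluster_ids:
        carrier = (retained == cluster).astype(float)
        if encoding == "indicator":
            exposure = carrier
        else:
            exposure = species_abundance.reindex(retained.index).fillna(0.0) * carrier
        for pheno in phenotypes.columns:
            frame = pd.concat(
                [phenotypes[pheno].rename("_y"), metadata[list(covariates)],
                 exposure.rename("_x")], axis=1, join="inner"
            ).dropna()
            n_cov = len(covariates)
            if len(frame) < n_cov + 3 or frame["_x"].nunique() <= 1:
                warnings.warn(
                    f"strain {cluster} / phenotype {pheno!r}: too few usable "
                    "samples; skipped", UserWarning, stacklevel=2,
                )
                continue
            x = design_matrix(frame, list(covariates))
            x["exposure"] = frame["_x"].to_numpy(dtype=float)
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
            records.append(dict(cluster=cluster, phenotype_id=pheno,
                                beta=float(beta_all[-1]), se=se, p=p,
                                n_used=len(frame), encoding=encoding))
    out = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["cluster", "phenotype_id", "beta", "se", "p", "n_used", "encoding"]
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr_threshold
    return out
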