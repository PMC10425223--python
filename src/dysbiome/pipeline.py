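"""End-to-end orchestration: simulate -> transform -> diversity -> DA ->
scores -> strain -> associations.

Stages communicate only through their declared TSV outputs inside the
run directory, so the pipeline is restartable from any stage.  Every
output carries a provenance header (config hash, seed, package version —
no timestamps, so reruns with the same config are byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .associations import association_scan, cytokine_group_comparison
from .community import (bray_curtis_matrix, pcoa, permanova, shannon_index,
                        wilcoxon_rank_sum)
from .differential import define_feature_sets, differential_abundance
from .scores import score_panel
from .simulate import SimulationConfig, simulate_all
from .strains import (cluster_and_cut, cluster_cohort_enrichment,
                      differential_gene_families, jaccard_distance_matrix,
                      pfam_enrichment)
from .transforms import clr_transform, int_transform_table, prevalence_mask

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "transform", "diversity", "da", "scores", "strain", "assoc")

_DEPENDENCIES = {
    "simulate": (),
    "transform": ("simulate",),
    "diversity": ("simulate",),
    "da": ("simulate", "transform"),
    "scores": ("simulate", "da"),
    "strain": ("simulate",),
    "assoc": ("simulate", "scores"),
}


class PipelineError(RuntimeError):
    """Raised when one or more stages fail."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (thresholds default to the
    analysis conventions: prevalence 0.2, DA FDR 0.05, association FDR
    0.1, tree cut 0.3)."""

    outdir: str = "results"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort_column: str = "cohort"
    case_level: str = "case"
    prevalence_threshold: float = 0.2
    prevalence_mode: str = "any"
    da_fdr: float = 0.05
    assoc_fdr: float = 0.1
    cytokine_fdr: float = 0.05
    cut_height: float = 0.3
    min_cluster_size: int = 20
    n_permutations: int = 999
    da_covariates: tuple = ("bmi", "smoking", "read_count")
    assoc_covariates: tuple = ("age", "sex", "read_count")
    sexual_behavior_covariates: tuple = ("msm", "num_partners")
    strain_covariates: tuple = ("age", "sex", "read_count")
    cytokine_covariates: tuple = ("age", "sex")

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        # one seed drives every stochastic stage
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        for name in ("prevalence_threshold", "da_fdr", "assoc_fdr",
                     "cytokine_fdr", "cut_height"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.prevalence_mode not in ("any", "all"):
            raise ValueError(f"unknown prevalence_mode {self.prevalence_mode!r}")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        for key in ("da_covariates", "assoc_covariates",
                    "sexual_behavior_covariates", "strain_covariates",
                    "cytokine_covariates"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        # outdir is a run location, not part of the analysis configuration
        payload = self.to_dict()
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def provenance(self, stage: str) -> dict:
        from . import __version__

        return {"stage": stage, "config_hash": self.config_hash(),
                "seed": self.seed, "dysbiome_version": __version__}

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig) -> None:
    bundle = simulate_all(cfg.simulation)
    h = cfg.provenance("simulate")
    dio.write_metadata(bundle["metadata"], cfg.path("metadata.tsv"), h)
    dio.write_abundance_table(bundle["species"], cfg.path("species.tsv"), h)
    dio.write_abundance_table(bundle["pathways"], cfg.path("pathways.tsv"), h)
    dio.write_gene_matrix(bundle["gene_matrix"], cfg.path("gene_families.tsv"), h)
    if bundle["gene_matrix"].pfam_map:
        dio.write_pfam_map(bundle["gene_matrix"].pfam_map, cfg.path("pfam_map.tsv"), h)
    truth = bundle["ground_truth"]
    rows = [{"feature_id": f, "role": "enriched"} for f in sorted(truth.enriched_features)]
    rows += [{"feature_id": f, "role": "depleted"} for f in sorted(truth.depleted_features)]
    pw = bundle["pathway_truth"]
    rows += [{"feature_id": f, "role": "enriched"} for f in sorted(pw.enriched_features)]
    rows += [{"feature_id": f, "role": "depleted"} for f in sorted(pw.depleted_features)]
    dio._write_table(pd.DataFrame(rows, columns=["feature_id", "role"]).set_index("feature_id"),
                     cfg.path("truth_features.tsv"), h, index_label="feature_id")
    dio._write_table(truth.true_strain_labels.to_frame(),
                     cfg.path("truth_strains.tsv"), h, index_label="sample_id")
    targets = pd.DataFrame(truth.cytokine_target_pairs,
                           columns=["feature_id", "phenotype_id", "sign"])
    dio._write_table(targets.set_index("feature_id") if len(targets) else
                     targets.set_index(pd.Index([], name="feature_id")),
                     cfg.path("truth_cytokine_targets.tsv"), h, index_label="feature_id")
    cfg.path("cytokine_names.txt").write_text("\n".join(bundle["cytokine_names"]) + "\n")
    cfg.path("effective_config.yaml").write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _load_inputs(cfg: PipelineConfig):
    metadata = dio.read_metadata(cfg.path("metadata.tsv"))
    species = dio.read_abundance_table(cfg.path("species.tsv"))
    pathways = dio.read_abundance_table(cfg.path("pathways.tsv"))
    return metadata, species, pathways


def stage_transform(cfg: PipelineConfig) -> None:
    metadata, species, pathways = _load_inputs(cfg)
    h = cfg.provenance("transform")
    for name, table in (("species", species), ("pathways", pathways)):
        keep = prevalence_mask(table, metadata[cfg.cohort_column],
                               cfg.prevalence_threshold, cfg.prevalence_mode)
        clr = clr_transform(table)
        filtered = clr.subset_features(keep[keep].index)
        transformed = int_transform_table(filtered)
        dio.write_transformed_table(
            transformed, cfg.path(f"{name}_clr_int.tsv"),
            {**h, "n_features_kept": int(keep.sum()),
             "n_features_total": len(keep)})


def stage_diversity(cfg: PipelineConfig) -> None:
    metadata, species, pathways = _load_inputs(cfg)
    h = cfg.provenance("diversity")
    group = metadata[cfg.cohort_column]

    alpha = pd.DataFrame({
        "shannon_species": shannon_index(species),
        "shannon_pathways": shannon_index(pathways),
    })
    dio._write_table(alpha, cfg.path("alpha_diversity.tsv"), h,
                     index_label="sample_id")

    lines = []
    for name, tab in (("species", species), ("pathways", pathways)):
        d = bray_curtis_matrix(tab)
        dio.write_distance_matrix(d, cfg.path(f"bray_curtis_{name}.tsv"), h)
        ord_result = pcoa(d, k=min(4, d.n - 1))
        coords = ord_result.coordinates.copy()
        dio._write_table(coords, cfg.path(f"pcoa_{name}.tsv"),
                         {**h, "proportion_explained": ",".join(
                             f"{v:.6g}" for v in ord_result.proportion_explained),
                          "negative_eigenvalues": ord_result.has_negative_eigenvalues},
                         index_label="sample_id")
        result = permanova(d, group, metadata[list(cfg.da_covariates)],
                           n_perm=cfg.n_permutations, seed=cfg.seed)
        lines.append(f"[{name}]")
        for term, row in result.terms.iterrows():
            lines.append(
                f"{term}\tdf={int(row['df'])}\tR2={row['r_squared']:.6g}"
                f"\tF={row['pseudo_F']:.6g}\tp={row['p']:.6g}")
        stat, p = wilcoxon_rank_sum(
            alpha.loc[group == cfg.case_level, f"shannon_{name}"],
            alpha.loc[group != cfg.case_level, f"shannon_{name}"])
        lines.append(f"shannon_wilcoxon\tU={stat:.6g}\tp={p:.6g}")
    cfg.path("permanova.txt").write_text("\n".join(lines) + "\n")


def stage_da(cfg: PipelineConfig) -> None:
    metadata, species, pathways = _load_inputs(cfg)
    h = cfg.provenance("da")
    for name, raw in (("species", species), ("pathways", pathways)):
        transformed = dio.read_transformed_table(cfg.path(f"{name}_clr_int.tsv"))
        da = differential_abundance(
            transformed, metadata, cfg.cohort_column,
            covariates=list(cfg.da_covariates), case_level=cfg.case_level,
            abundance=raw.subset_features(transformed.feature_ids))
        dio._write_table(da.set_index("feature_id"), cfg.path(f"da_{name}.tsv"),
                         h, index_label="feature_id")
        enriched, depleted = define_feature_sets(da, cfg.da_fdr, name=name)
        dio.write_feature_sets(enriched, depleted,
                               cfg.path(f"feature_sets_{name}.tsv"), h)


def stage_scores(cfg: PipelineConfig) -> None:
    metadata, species, pathways = _load_inputs(cfg)
    h = cfg.provenance("scores")
    sp_enr, sp_dep = dio.read_feature_sets(cfg.path("feature_sets_species.tsv"))
    pw_enr, pw_dep = dio.read_feature_sets(cfg.path("feature_sets_pathways.tsv"))
    panel = score_panel(species, pathways, sp_enr, sp_dep, pw_enr, pw_dep)
    dio._write_table(panel, cfg.path("scores.tsv"), h, index_label="sample_id")


def stage_strain(cfg: PipelineConfig) -> None:
    metadata = dio.read_metadata(cfg.path("metadata.tsv"))
    matrix = dio.read_gene_matrix(cfg.path("gene_families.tsv"),
                                  pfam_map_path=cfg.path("pfam_map.tsv"))
    h = cfg.provenance("strain")
    d = jaccard_distance_matrix(matrix)
    dio.write_distance_matrix(d, cfg.path("jaccard_gene_families.tsv"), h)
    clustering = cluster_and_cut(d, cfg.cut_height, cfg.min_cluster_size)
    labels = clustering.cluster_labels.to_frame()
    dio._write_table(labels, cfg.path("strain_clusters.tsv"),
                     {**h, "cut_height": cfg.cut_height,
                      "excluded_samples": ",".join(map(str, clustering.excluded_samples))},
                     index_label="sample_id")
    merges = pd.DataFrame(clustering.linkage_matrix,
                          columns=["left", "right", "height", "size"])
    dio._write_table(merges, cfg.path("strain_dendrogram_merges.tsv"), h,
                     index_label="merge")
    enrich = cluster_cohort_enrichment(clustering, metadata[cfg.cohort_column])
    dio._write_table(enrich.set_index("cluster"),
                     cfg.path("strain_cohort_enrichment.tsv"), h,
                     index_label="cluster")
    dio._write_table(clustering.cohort_contingency,
                     cfg.path("strain_cohort_contingency.tsv"), h,
                     index_label="cluster")
    if len(clustering.cluster_ids) >= 2:
        diff = differential_gene_families(
            matrix, clustering, metadata, covariates=list(cfg.strain_covariates))
        dio._write_table(diff.set_index("gene_family_id"),
                         cfg.path("diff_gene_families.tsv"), h,
                         index_label="gene_family_id")
        hits = diff.loc[diff["significant"].fillna(False), "gene_family_id"]
        enr = pfam_enrichment(hits, matrix)
        dio._write_table(enr.set_index("pfam_label") if len(enr) else enr,
                         cfg.path("pfam_enrichment.tsv"), h,
                         index_label="pfam_label")
        cyto_names = [c for c in _cytokine_columns(cfg, metadata)]
        if cyto_names:
            from .strains import strain_phenotype_association

            assoc = strain_phenotype_association(
                clustering, metadata[cyto_names], metadata,
                covariates=list(cfg.strain_covariates),
                fdr_threshold=cfg.assoc_fdr)
            dio._write_table(assoc.set_index("cluster") if len(assoc) else assoc,
                             cfg.path("strain_phenotype_assoc.tsv"), h,
                             index_label="cluster")


def _cytokine_columns(cfg: PipelineConfig, metadata: pd.DataFrame) -> list:
    names_path = cfg.path("cytokine_names.txt")
    if names_path.exists():
        names = [n for n in names_path.read_text().splitlines() if n]
        return [n for n in names if n in metadata.columns]
    return []


def stage_assoc(cfg: PipelineConfig) -> None:
    metadata = dio.read_metadata(cfg.path("metadata.tsv"))
    h = cfg.provenance("assoc")
    scores = pd.read_csv(cfg.path("scores.tsv"), sep="\t", comment="#", index_col=0)
    cyto_names = _cytokine_columns(cfg, metadata)
    clinical = [c for c in ("cd4_count", "cd4_nadir", "ca_hiv_dna", "ca_hiv_rna")
                if c in metadata.columns]
    phenos = metadata[cyto_names + clinical]
    scan = association_scan(
        scores, phenos, metadata, covariates=list(cfg.assoc_covariates),
        fdr_threshold=cfg.assoc_fdr,
        extra_covariates=list(cfg.sexual_behavior_covariates))
    dio._write_table(scan.set_index("feature_id") if len(scan) else scan,
                     cfg.path("association_scan.tsv"), h,
                     index_label="feature_id")
    if cyto_names:
        comp = cytokine_group_comparison(
            metadata[cyto_names], metadata[cfg.cohort_column], metadata,
            covariates=list(cfg.cytokine_covariates),
            fdr_threshold=cfg.cytokine_fdr, case_level=cfg.case_level)
        dio._write_table(comp.set_index("cytokine"),
                         cfg.path("cytokine_comparison.tsv"), h,
                         index_label="cytokine")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "transform": stage_transform,
    "diversity": stage_diversity,
    "da": stage_da,
    "scores": stage_scores,
    "strain": stage_strain,
    "assoc": stage_assoc,
}


def _write_summary(cfg: PipelineConfig, status: dict) -> None:
    lines = [f"config_hash: {cfg.config_hash()}", f"seed: {cfg.seed}", ""]
    for stage in STAGES:
        lines.append(f"stage {stage}: {status.get(stage, 'not run')}")
    lines.append("")
    for name, fname in (("da_species", "da_species.tsv"),
                        ("da_pathways", "da_pathways.tsv")):
        p = cfg.path(fname)
        if p.exists():
            da = pd.read_csv(p, sep="\t", comment="#")
            hits = da[da["q"] < cfg.da_fdr]
            lines.append(
                f"{name}: {len(da)} features tested, "
                f"{int((hits['beta'] > 0).sum())} enriched / "
                f"{int((hits['beta'] < 0).sum())} depleted at q<{cfg.da_fdr}")
    p = cfg.path("strain_clusters.tsv")
    if p.exists():
        clusters = pd.read_csv(p, sep="\t", comment="#", index_col=0)["cluster"]
        sizes = clusters.value_counts().sort_index()
        lines.append("strain clusters: " + ", ".join(
            f"{c}:{n}" for c, n in sizes.items()))
    p = cfg.path("association_scan.tsv")
    if p.exists():
        scan = pd.read_csv(p, sep="\t", comment="#")
        if len(scan):
            lines.append(
                f"association scan: {len(scan)} tests, "
                f"{int(scan['significant'].sum())} at q<{cfg.assoc_fdr}")
    cfg.path("summary.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order.

    A stage failure aborts its dependents but independent stages still
    run; a :class:`PipelineError` summarising failures is raised at the
    end.  Returns the per-stage status mapping.
    """
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    status: dict[str, str] = {}
    failures: dict[str, str] = {}
    for stage in requested:
        blocked = [dep for dep in _DEPENDENCIES[stage] if dep in failures]
        if blocked:
            status[stage] = f"skipped (failed dependency: {blocked[0]})"
            continue
        try:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](cfg)
            status[stage] = "ok"
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.exception("stage %s failed", stage)
            status[stage] = f"failed ({exc})"
            failures[stage] = str(exc)
    _write_summary(cfg, status)
    if failures:
        raise PipelineError(
            "; ".join(f"{k}: {v}" for k, v in failures.items()))
    return status
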