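"""Synthetic case/control microbiome cohorts with known ground truth.

Generates per-sample metadata, log-normal compositional abundance tables
with planted enriched/depleted features, two-archetype binary
gene-family matrices with cohort-biased strain membership, and cytokine
phenotypes with planted covariate-confounded taxon associations.  All
randomness flows from the single config seed through per-stage child
generators, so every generator can be re-run independently and
reproduces bit-identical output for a given seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .transforms import AbundanceTable, inverse_rank_transform
from .strains import GeneFamilyMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "stage_rng",
    "generate_metadata",
    "generate_abundance_tables",
    "generate_gene_family_matrix",
    "generate_cytokines",
    "simulate_all",
]

#: cytokine measurement names (stimulus_readout), mirroring an ex vivo
#: PBMC stimulation panel
CYTOKINE_NAMES = (
    "Pam3Cys_IL10", "Pam3Cys_IL6", "Pam3Cys_IL1b", "LPS_TNF",
    "LPS_IL10", "SAureus_IFNy", "Candida_IL17", "PolyIC_IL22",
    "RPMI_IL1Ra", "LPS_IL6", "Candida_IL1b", "SAureus_IL22",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child generator for a named stage of the simulation."""
    key = zlib.crc32(stage.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(key,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    Counts must be >= 1 except the planted-effect counts
    (``n_enriched``, ``n_depleted``, ``n_diff_gene_families``,
    ``n_cytokine_targets``), which may be 0 for null simulations.
    """

    n_cases: int = 150
    n_controls: int = 190
    n_features: int = 200
    n_enriched: int = 20
    n_depleted: int = 10
    effect_log2fc: float = 1.0
    base_logmean_sd: float = 1.5
    overdispersion_sd: float = 1.0
    sparsity: float = 0.10
    n_gene_families: int = 400
    n_diff_gene_families: int = 240
    gene_flip_rate: float = 0.02
    gene_base_presence: float = 0.6
    cluster_mixing: float = 0.15
    n_cytokines: int = 8
    n_cytokine_targets: int = 3
    cytokine_assoc_rho: float = 0.5
    confounder_strength: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_features", "n_gene_families",
                     "n_cytokines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_enriched", "n_depleted", "n_diff_gene_families",
                     "n_cytokine_targets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_enriched + self.n_depleted > self.n_features:
            raise ValueError(
                "n_enriched + n_depleted exceeds n_features "
                f"({self.n_enriched} + {self.n_depleted} > {self.n_features})"
            )
        if self.n_diff_gene_families > self.n_gene_families:
            raise ValueError("n_diff_gene_families exceeds n_gene_families")
        if not 0 <= self.cluster_mixing <= 1:
            raise ValueError(f"cluster_mixing must be in [0, 1], got {self.cluster_mixing}")
        if not -1 < self.cytokine_assoc_rho < 1:
            raise ValueError(
                f"cytokine_assoc_rho must be in (-1, 1), got {self.cytokine_assoc_rho}"
            )
        if not 0 <= self.gene_flip_rate < 0.5:
            raise ValueError(
                f"gene_flip_rate must be in [0, 0.5), got {self.gene_flip_rate}"
            )
        if not 0 <= self.sparsity < 1:
            raise ValueError(f"sparsity must be in [0, 1), got {self.sparsity}")
        if self.n_cytokines > len(CYTOKINE_NAMES):
            raise ValueError(
                f"n_cytokines must be <= {len(CYTOKINE_NAMES)}, got {self.n_cytokines}"
            )
        if self.n_cytokine_targets > min(self.n_cytokines, self.n_features):
            raise ValueError("n_cytokine_targets exceeds available cytokines/features")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted structure of a simulation run."""

    enriched_features: frozenset = frozenset()
    depleted_features: frozenset = frozenset()
    true_strain_labels: pd.Series | None = None
    diff_gene_families: frozenset = frozenset()
    cytokine_target_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.enriched_features & self.depleted_features:
            raise ValueError("enriched and depleted feature sets overlap")


def _species_names(n: int) -> list[str]:
    """Taxonomy-style lineage labels; the first few features sit in the
    Prevotella and Bacteroides genera so genus-level scores are exercised."""
    names = []
    for i in range(n):
        if i < 4:
            genus, sp = "Prevotella", f"Prevotella_sp_{i + 1}"
        elif i < 8:
            genus, sp = "Bacteroides", f"Bacteroides_sp_{i - 3}"
        else:
            genus, sp = f"Genus_{i:03d}", f"Species_{i:03d}"
        names.append(
            f"k__Bacteria|p__Phylum_{i % 7}|g__{genus}|s__{sp}"
        )
    return names


def _pathway_names(n: int) -> list[str]:
    return [f"PWY-{1000 + i}: synthetic pathway {i}" for i in range(n)]


def generate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample metadata table: cohort, demographics, behaviour,
    read counts, and case-only clinical variables.

    Deterministic given ``config.seed``; indexed by sample id.
    """
    config.validate()
    rng = stage_rng(config.seed, "metadata")
    n = config.n_cases + config.n_controls
    cohort = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    ids = [f"S{i + 1:04d}" for i in range(n)]

    age = rng.normal(51.0, 11.0, n).clip(18, 90)
    sex = np.where(rng.random(n) < 0.88, "male", "female")
    bmi = rng.normal(25.0, 3.3, n).clip(16, 45)
    smoking = (rng.random(n) < np.where(cohort == "case", 0.28, 0.10)).astype(int)
    msm = ((sex == "male")
           & (rng.random(n) < np.where(cohort == "case", 0.67, 0.01))).astype(int)
    num_partners = rng.poisson(np.where(msm == 1, 4.0, 1.0))
    rai = ((msm == 1) & (rng.random(n) < 0.4)).astype(int)
    read_count = np.exp(rng.normal(np.log(25e6), 0.25, n)).round()

    case = cohort == "case"
    cd4_count = np.where(case, np.exp(rng.normal(np.log(650), 0.35, n)), np.nan)
    cd4_nadir = np.where(case, np.exp(rng.normal(np.log(260), 0.5, n)), np.nan)
    ca_hiv_dna = np.where(case, np.exp(rng.normal(np.log(500), 0.8, n)), np.nan)
    ca_hiv_rna = np.where(case, np.exp(rng.normal(np.log(50), 0.9, n)), np.nan)
    hiv_duration = np.where(case, np.exp(rng.normal(np.log(8.0), 0.6, n)), np.nan)

    return pd.DataFrame(
        {
            "cohort": cohort,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "msm": msm,
            "num_partners": num_partners,
            "rai": rai,
            "read_count": read_count,
            "cd4_count": cd4_count,
            "cd4_nadir": cd4_nadir,
            "ca_hiv_dna": ca_hiv_dna,
            "ca_hiv_rna": ca_hiv_rna,
            "hiv_duration": hiv_duration,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def generate_abundance_tables(
    config: SimulationConfig,
    metadata: pd.DataFrame,
    kind: str = "species",
) -> tuple[AbundanceTable, GroundTruth]:
    """Log-normal compositional abundances with planted group shifts.

    Per-feature log means are drawn once; cases receive a
    ``effect_log2fc * ln 2`` shift, positive on the planted enriched
    features and negative on the planted depleted ones.  Entries below
    the table-wide ``sparsity`` quantile are zeroed, then rows are
    re-closed to sum to one.  The planted sets are the leading features
    (deterministic), so independently simulated cohorts share them.
    """
    config.validate()
    if kind not in ("species", "pathway"):
        raise ValueError(f"kind must be 'species' or 'pathway', got {kind}")
    if metadata.index.has_duplicates:
        raise ValueError("metadata sample ids are not unique")
    rng = stage_rng(config.seed, f"abundance:{kind}")
    n, m = len(metadata), config.n_features
    names = _species_names(m) if kind == "species" else _pathway_names(m)
    enriched = names[: config.n_enriched]
    depleted = names[config.n_enriched: config.n_enriched + config.n_depleted]

    base = rng.normal(0.0, config.base_logmean_sd, m)
    shift = np.zeros(m)
    shift[: config.n_enriched] = config.effect_log2fc * np.log(2.0)
    shift[config.n_enriched: config.n_enriched + config.n_depleted] = (
        -config.effect_log2fc * np.log(2.0)
    )
    case = (metadata["cohort"].to_numpy() == "case").astype(float)[:, None]
    log_x = base[None, :] + case * shift[None, :] + rng.normal(
        0.0, config.overdispersion_sd, (n, m)
    )
    values = np.exp(log_x)
    if config.sparsity > 0:
        threshold = np.quantile(values, config.sparsity)
        values = np.where(values >= threshold, values, 0.0)
    row_sums = values.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("sparsity zeroed an entire sample; lower sparsity")
    values /= row_sums[:, None]
    table = AbundanceTable(
        pd.DataFrame(values, index=metadata.index, columns=names), relative=True
    )
    truth = GroundTruth(
        enriched_features=frozenset(enriched), depleted_features=frozenset(depleted)
    )
    return table, truth


def generate_gene_family_matrix(
    config: SimulationConfig, metadata: pd.DataFrame
) -> tuple[GeneFamilyMatrix, GroundTruth]:
    """Two-archetype binary gene-repertoire profiles.

    Archetype A (control strain) has Bernoulli base presence; archetype
    B flips the planted differential positions.  Each sample carries its
    strain archetype perturbed by a per-gene flip rate; cases carry the
    control archetype with probability ``cluster_mixing``.  A Pfam map
    concentrates the differential genes in a small set of Pfams.
    """
    config.validate()
    rng = stage_rng(config.seed, "genes")
    n, g = len(metadata), config.n_gene_families
    genes = [f"UniRef90_G{i + 1:05d}" for i in range(g)]
    diff = genes[: config.n_diff_gene_families]

    arche_a = (rng.random(g) < config.gene_base_presence).astype(np.int8)
    arche_b = arche_a.copy()
    arche_b[: config.n_diff_gene_families] ^= 1

    case = metadata["cohort"].to_numpy() == "case"
    carries_control = np.where(case, rng.random(n) < config.cluster_mixing, True)
    strain = np.where(carries_control, "control_strain", "case_strain")

    profiles = np.where(carries_control[:, None], arche_a[None, :], arche_b[None, :])
    if config.gene_flip_rate > 0:
        flips = rng.random((n, g)) < config.gene_flip_rate
        profiles = profiles ^ flips.astype(np.int8)

    # Pfam map: most differential genes concentrated in 5 'hot' Pfams,
    # background genes spread over 20 others, ~10% unannotated
    pfam_map: dict[str, frozenset] = {}
    hot = [f"PF9{i:04d}" for i in range(5)]
    cold = [f"PF8{i:04d}" for i in range(20)]
    for i, gene in enumerate(genes):
        u = rng.random()
        if u < 0.10:
            continue
        if i < config.n_diff_gene_families and u < 0.70:
            pfam_map[gene] = frozenset({hot[i % len(hot)]})
        else:
            pfam_map[gene] = frozenset({cold[int(rng.integers(len(cold)))]})

    matrix = GeneFamilyMatrix(
        pd.DataFrame(profiles.astype(np.int8), index=metadata.index, columns=genes),
        pfam_map=pfam_map,
    )
    truth = GroundTruth(
        true_strain_labels=pd.Series(strain, index=metadata.index, name="strain"),
        diff_gene_families=frozenset(diff),
    )
    return matrix, truth


def generate_cytokines(
    config: SimulationConfig,
    metadata: pd.DataFrame,
    table: AbundanceTable,
) -> tuple[pd.DataFrame, list]:
    """Cytokine phenotypes with planted, confounded taxon associations.

    Each planted target is ``sign * (rho * INT(feature) +
    sqrt(1 - rho^2) * noise)`` plus an age/sex confounder term scaled by
    ``confounder_strength``, so the covariate-adjusted (partial) Spearman
    correlation is approximately ``cytokine_assoc_rho``.  Non-target
    cytokines are pure noise plus the same confounding.  Returns the
    metadata with cytokine columns appended and the planted
    (feature, phenotype, sign) triples.
    """
    config.validate()
    if not table.data.index.equals(metadata.index):
        raise ValueError("abundance table sample ids do not match metadata")
    rng = stage_rng(config.seed, "cytokines")
    n = len(metadata)
    names = list(CYTOKINE_NAMES[: config.n_cytokines])
    rho = config.cytokine_assoc_rho

    age_z = (metadata["age"] - metadata["age"].mean()) / metadata["age"].std()
    sex_z = (metadata["sex"] == "male").astype(float)
    sex_z = (sex_z - sex_z.mean()) / (sex_z.std() if sex_z.std() > 0 else 1.0)
    confound = config.confounder_strength * (0.5 * age_z + 0.5 * sex_z).to_numpy()

    features = list(table.data.columns)
    pairs = []
    out = {}
    for j, name in enumerate(names):
        eps = rng.normal(0.0, 1.0, n)
        if j < config.n_cytokine_targets and abs(rho) > 0:
            feature = features[j]
            sign = 1 if j % 2 == 0 else -1
            z = inverse_rank_transform(table.data[feature].to_numpy())
            y = sign * (rho * z + np.sqrt(1 - rho**2) * eps) + confound
            pairs.append((feature, name, sign))
        else:
            y = eps + confound
        # map to a positive concentration-like scale (monotone, rank-safe)
        out[name] = np.exp(y)
    cytos = pd.DataFrame(out, index=metadata.index)
    return pd.concat([metadata, cytos], axis=1), pairs


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator off one config; returns a bundle dict with
    metadata (incl. cytokines), species/pathway tables, gene matrix, and
    the combined ground truth."""
    config.validate()
    metadata = generate_metadata(config)
    species, truth_sp = generate_abundance_tables(config, metadata, kind="species")
    pathways, truth_pw = generate_abundance_tables(config, metadata, kind="pathway")
    genes, truth_gn = generate_gene_family_matrix(config, metadata)
    metadata, pairs = generate_cytokines(config, metadata, species)
    truth = GroundTruth(
        enriched_features=truth_sp.enriched_features,
        depleted_features=truth_sp.depleted_features,
        true_strain_labels=truth_gn.true_strain_labels,
        diff_gene_families=truth_gn.diff_gene_families,
        cytokine_target_pairs=pairs,
    )
    return {
        "config": config,
        "metadata": metadata,
        "species": species,
        "pathways": pathways,
        "pathway_truth": truth_pw,
        "gene_matrix": genes,
        "ground_truth": truth,
        "cytokine_names": list(CYTOKINE_NAMES[: config.n_cytokines]),
    }
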