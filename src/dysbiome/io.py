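"""TSV readers and writers for the standard table dialects.

Abundance tables are stored features-in-rows (merged MetaPhlAn-style:
first column holds the lineage/pathway label, header row holds sample
ids) and transposed to samples-in-rows on read.  Gene-family matrices
are stored genes-in-rows (PanPhlAn-style).  Lines starting with ``#``
are provenance/comment lines and are skipped on read; writers accept a
``header`` mapping written as ``# key: value`` lines (no timestamps, so
reruns are byte-identical).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .community import DistanceMatrix
from .strains import GeneFamilyMatrix
from .transforms import AbundanceTable, TransformedTable

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_transformed_table",
    "write_transformed_table",
    "read_gene_matrix",
    "write_gene_matrix",
    "read_metadata",
    "write_metadata",
    "read_pfam_map",
    "write_pfam_map",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_feature_sets",
    "write_feature_sets",
]

_FLOAT_FMT = "%.12g"


def _read_table(path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValueError(f"{path}: no header row found")
    seen = set()
    for col in header:  # pandas silently mangles duplicate columns
        if col in seen:
            raise ValueError(f"{path}: duplicated column id {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated {index_name} {dup!r}")
    return df


def _write_table(df: pd.DataFrame, path, header: dict | None = None,
                 index_label: str = "feature_id") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, value in (header or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)
    path.write_text(buf.getvalue())


def _require_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().sum() > df[col].isna().sum():
                bad = df.index[coerced.isna() & ~df[col].isna()][0]
                raise ValueError(
                    f"{path}: non-numeric cell at row {bad!r}, column {col!r}"
                ) from exc
        raise


def read_abundance_table(path, relative: bool = True) -> AbundanceTable:
    """Read a features-in-rows abundance TSV and transpose to
    samples-in-rows."""
    df = _read_table(path, "feature id")
    return AbundanceTable(_require_numeric(df, path).T, relative=relative)


def write_abundance_table(table: AbundanceTable, path, header: dict | None = None) -> None:
    _write_table(table.data.T, path, header, index_label="feature_id")


def read_transformed_table(path, transform_tag: str = "CLR+INT") -> TransformedTable:
    df = _read_table(path, "feature id")
    return TransformedTable(_require_numeric(df, path).T, transform_tag=transform_tag)


def write_transformed_table(table: TransformedTable, path,
                            header: dict | None = None) -> None:
    meta = {"transform": table.transform_tag}
    meta.update(header or {})
    _write_table(table.data.T, path, meta, index_label="feature_id")


def read_gene_matrix(path, pfam_map_path=None, binarize: bool = False) -> GeneFamilyMatrix:
    """Read a genes-in-rows presence/absence TSV.  With ``binarize=True``
    numeric matrices are thresholded at > 0; otherwise entries must
    already be 0/1."""
    df = _require_numeric(_read_table(path, "gene family id"), path)
    if binarize:
        df = (df > 0).astype(np.int8)
    pfam_map = read_pfam_map(pfam_map_path) if pfam_map_path else None
    return GeneFamilyMatrix(df.T, pfam_map=pfam_map)


def write_gene_matrix(matrix: GeneFamilyMatrix, path, header: dict | None = None) -> None:
    _write_table(matrix.data.T, path, header, index_label="gene_family_id")


def read_metadata(path) -> pd.DataFrame:
    """Read a per-sample metadata TSV (first column sample id)."""
    df = _read_table(path, "sample id")
    df.index.name = "sample_id"
    return df


def write_metadata(metadata: pd.DataFrame, path, header: dict | None = None) -> None:
    _write_table(metadata, path, header, index_label="sample_id")


def read_pfam_map(path) -> dict:
    """Two-column TSV (gene_family_id, pfam_label); multiple rows per
    gene accumulate into a label set."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: pfam map needs two columns")
    mapping: dict[str, frozenset] = {}
    acc: dict[str, set] = {}
    for gene, pfam in zip(df.iloc[:, 0], df.iloc[:, 1]):
        acc.setdefault(str(gene), set()).add(str(pfam))
    for gene, labels in acc.items():
        mapping[gene] = frozenset(labels)
    return mapping


def write_pfam_map(pfam_map: dict, path, header: dict | None = None) -> None:
    rows = [
        {"gene_family_id": gene, "pfam_label": pfam}
        for gene in sorted(pfam_map)
        for pfam in sorted(pfam_map[gene])
    ]
    _write_table(pd.DataFrame(rows).set_index("gene_family_id"), path, header,
                 index_label="gene_family_id")


def read_distance_matrix(path, metric_tag: str = "bray_curtis") -> DistanceMatrix:
    df = _require_numeric(_read_table(path, "sample id"), path)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column sample ids differ")
    return DistanceMatrix(list(df.index), df.to_numpy(), metric_tag=metric_tag)


def write_distance_matrix(d: DistanceMatrix, path, header: dict | None = None) -> None:
    meta = {"metric": d.metric_tag}
    meta.update(header or {})
    _write_table(d.to_dataframe(), path, meta, index_label="sample_id")


def read_feature_sets(path):
    """Two-column TSV (feature_id, direction) -> (enriched, depleted)."""
    from .differential import FeatureSet

    df = pd.read_csv(path, sep="\t", comment="#")
    enriched = tuple(df.loc[df["direction"] == "enriched", "feature_id"])
    depleted = tuple(df.loc[df["direction"] == "depleted", "feature_id"])
    name = Path(path).stem
    return (FeatureSet(f"{name}_enriched", enriched, "enriched"),
            FeatureSet(f"{name}_depleted", depleted, "depleted"))


def write_feature_sets(enriched, depleted, path, header: dict | None = None) -> None:
    rows = [{"feature_id": f, "direction": "enriched"} for f in enriched.feature_ids]
    rows += [{"feature_id": f, "direction": "depleted"} for f in depleted.feature_ids]
    df = pd.DataFrame(rows, columns=["feature_id", "direction"])
    _write_table(df.set_index("feature_id"), path, header, index_label="feature_id")
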