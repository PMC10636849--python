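"""TSV readers and writers for the pipeline's tabular interchange formats.

All stage inputs and outputs are plain tab-separated tables with a header
row, so every intermediate is inspectable and diffable. Readers validate
the declared column schema; writers emit columns in schema order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

# Column schemas for the interchange tables. Optional columns may be absent.
SCHEMAS: dict[str, dict[str, list[str]]] = {
    "genomes": {
        "required": [
            "genome_id",
            "sample_id",
            "kingdom",
            "completeness_primary",
            "contamination_primary",
        ],
        "optional": [
            "completeness_secondary",
            "contamination_secondary",
            "rrna_5s",
            "rrna_ssu",
            "rrna_lsu",
            "n_unique_trnas",
            "n_contigs",
            "n50",
            "mean_depth",
            "strain_heterogeneity",
            "gunc_contamination",
            "gunc_css",
            "gunc_rrs",
        ],
    },
    "ani": {
        "required": ["genome_a", "genome_b", "ani", "aligned_fraction"],
        "optional": [],
    },
    "abundance": {"required": [], "optional": []},  # species x samples matrix
    "samples": {
        "required": ["sample_id", "subject_id", "family_id", "role", "site", "age_group"],
        "optional": ["total_reads"],
    },
    "snv": {
        "required": ["species_id", "genome_id", "position", "ref", "alt"],
        "optional": [],
    },
    "st_profiles": {
        "required": ["individual_id", "family_id", "role", "isolate_id"],
        "optional": [],  # plus the seven scheme locus columns
    },
    "genes": {
        "required": ["species_id", "gene_cluster_id", "genome_id"],
        "optional": [],
    },
    "gene_meta": {
        "required": ["species_id", "gene_cluster_id", "category"],
        "optional": ["origin"],
    },
    "classified": {
        "required": ["sample_id", "fraction_reference", "fraction_custom"],
        "optional": [],
    },
    "clusters": {
        "required": [
            "genome_id",
            "nonredundant",
            "species_cluster_id",
            "is_representative",
        ],
        "optional": [],
    },
}

BOOL_COLUMNS = {"rrna_5s", "rrna_ssu", "rrna_lsu", "nonredundant", "is_representative"}


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV table, optionally validating against a named schema."""
    df = pd.read_csv(path, sep="\t")
    if schema is not None:
        spec = SCHEMAS[schema]
        missing = [c for c in spec["required"] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing} for schema '{schema}'")
    for col in df.columns:
        if col in BOOL_COLUMNS:
            df[col] = df[col].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as TSV with header, no index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a species-by-sample count matrix (first column = species id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    try:
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
    except Exception:  # pragma: no cover
        pass
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> Path:
    """Write (id, sequence) pairs as FASTA."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path
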