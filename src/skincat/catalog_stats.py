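"""Catalog-level summary statistics.

Rarefaction of species discovery as a function of the number of
nonredundant genomes, the per-sample read-classification improvement
statistic, and species prevalence summaries.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

SingletonMode = Literal["none", "by_genome", "by_sample"]


def rarefaction_curve(
    genome_species: pd.DataFrame,
    n_perm: int = 10,
    seed: int = 0,
    exclude_singletons: SingletonMode = "none",
    n_points: int = 20,
) -> pd.DataFrame:
    """Mean species count discovered in random genome subsets of growing size.

    ``genome_species`` maps each genome to its species cluster (columns
    ``genome_id, species_cluster_id`` and, for sample-based singleton
    exclusion, ``sample_id``). Singleton species — backed by only one genome
    (``by_genome``) or recovered from only one distinct sample
    (``by_sample``) — are dropped from the pool before subsampling, since
    they may be transient or individual-specific. The subsample grid is
    ``n_points`` evenly spaced sizes plus the endpoint.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = genome_species
    if df.empty:
        raise ValueError("empty genome-species map")
    if exclude_singletons == "by_genome":
        counts = df.groupby("species_cluster_id")["genome_id"].nunique()
        keep = counts[counts > 1].index
        df = df[df["species_cluster_id"].isin(keep)]
    elif exclude_singletons == "by_sample":
        counts = df.groupby("species_cluster_id")["sample_id"].nunique()
        keep = counts[counts > 1].index
        df = df[df["species_cluster_id"].isin(keep)]
    species = pd.factorize(df["species_cluster_id"])[0]
    n = len(species)
    if n == 0:
        raise ValueError("no genomes left after singleton exclusion")
    sizes = np.unique(np.linspace(1, n, min(n_points, n), dtype=int).tolist() + [n])
    rng = np.random.default_rng(seed)
    # one genome permutation per replicate; prefix counts make each
    # replicate's accumulation curve (and hence the mean) non-decreasing,
    # and a prefix of size m is a uniform subset without replacement
    curves = np.empty((n_perm, len(sizes)))
    for i in range(n_perm):
        perm = rng.permutation(species)
        _, first_idx = np.unique(perm, return_index=True)
        cumulative = np.cumsum(np.bincount(first_idx, minlength=n))
        curves[i] = cumulative[sizes - 1]
    rows = [
        {
            "n_genomes": int(m),
            "mean_species": float(curves[:, j].mean()),
            "sd_species": float(curves[:, j].std(ddof=1)) if n_perm > 1 else 0.0,
        }
        for j, m in enumerate(sizes)
    ]
    return pd.DataFrame(rows)


def classification_improvement(fractions: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-sample relative classification improvement of a custom database.

    improvement = (fraction_custom − fraction_reference) / fraction_reference × 100.
    Samples with a zero reference fraction are excluded with a warning.
    Returns the per-sample table and a summary with the median and quartiles.
    """
    df = fractions.copy()
    for col in ("fraction_reference", "fraction_custom"):
        bad = (df[col] < 0) | (df[col] > 1)
        if bad.any():
            raise ValueError(f"{col} outside [0, 1] for samples {df.loc[bad, 'sample_id'].tolist()}")
    zero = df["fraction_reference"] == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} sample(s) with zero reference fraction",
            stacklevel=2,
        )
        df = df[~zero]
    df = df.assign(
        improvement=(df["fraction_custom"] - df["fraction_reference"])
        / df["fraction_reference"]
        * 100.0
    )
    q1, med, q3 = np.percentile(df["improvement"], [25, 50, 75]) if len(df) else (np.nan,) * 3
    summary = {
        "n": int(len(df)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "median_fraction_custom": float(df["fraction_custom"].median()) if len(df) else float("nan"),
    }
    return df, summary


def prevalence_summary(
    genome_species: pd.DataFrame, abundance: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-species sample prevalence and genome counts.

    Returns a table (species, n_samples_detected, n_genomes) over the union
    of catalog species and abundance-table species, plus the Pearson
    correlation between log10 genome count and prevalence across species
    with at least one genome.
    """
    n_genomes = genome_species.groupby("species_cluster_id")["genome_id"].nunique()
    detected = (abundance > 0).sum(axis=1)
    species = sorted(set(n_genomes.index) | set(abundance.index))
    n_samples = abundance.shape[1]
    out = pd.DataFrame(
        {
            "species_cluster_id": species,
            "n_samples_detected": [int(detected.get(s, 0)) for s in species],
            "n_genomes": [int(n_genomes.get(s, 0)) for s in species],
        }
    )
    out["prevalence"] = out["n_samples_detected"] / n_samples if n_samples else np.nan
    with_genomes = out[out["n_genomes"] > 0]
    if len(with_genomes) >= 3 and with_genomes["prevalence"].nunique() > 1:
        r = stats.pearsonr(
            np.log10(with_genomes["n_genomes"]), with_genomes["prevalence"]
        ).statistic
    else:
        r = float("nan")
    return out, float(r)
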