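"""Pan-genome core/accessory partition and functional-category enrichment.

For each species with enough high-quality conspecific genomes, genes are
partitioned by their frequency among those genomes: genes shared by at
least 90% of conspecific genomes are *core*, the rest *accessory*. Per
species and functional category (COG letter), an odds ratio is computed
from the 2x2 table (core/accessory x this-category/other-categories);
across species, a two-tailed t-test on log odds ratios against zero with
Bonferroni correction over categories identifies consistently enriched
functions. The same machinery compares catalog-specific versus shared
gene sets between two genome collections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bonferroni

QUALIFYING_TIERS = ("high_quality", "near_complete")
CORE_THRESHOLD = 0.90
MIN_GENOMES = 10
MIN_GENOMES_PER_CATALOG = 5
UNANNOTATED = "S?"  # label treated as unannotated and excluded from category axes


def eligible_species(
    tiers: pd.DataFrame,
    clusters: pd.DataFrame,
    min_genomes: int = MIN_GENOMES,
    qualifying=QUALIFYING_TIERS,
) -> list[str]:
    """Species with at least ``min_genomes`` near-complete or high-quality
    nonredundant genomes."""
    merged = clusters.merge(tiers[["genome_id", "tier"]], on="genome_id")
    if "nonredundant" in merged.columns:
        merged = merged[merged["nonredundant"]]
    ok = merged[merged["tier"].isin(qualifying)]
    counts = ok.groupby("species_cluster_id")["genome_id"].nunique()
    return sorted(counts[counts >= min_genomes].index)


def gene_frequencies(genes: pd.DataFrame, genomes: list[str] | None = None) -> pd.Series:
    """Per-gene fraction of conspecific genomes carrying the gene.

    ``genes`` is long-format (gene_cluster_id, genome_id) for one species;
    ``genomes`` optionally fixes the denominator (e.g. the qualifying
    genome set), defaulting to the genomes observed in the table.
    """
    if genes.empty:
        raise ValueError("empty gene table")
    if genomes is None:
        genomes = genes["genome_id"].unique().tolist()
    n = len(genomes)
    sub = genes[genes["genome_id"].isin(genomes)]
    freq = sub.groupby("gene_cluster_id")["genome_id"].nunique() / n
    return freq


def partition_core_accessory(
    frequencies: pd.Series, core_threshold: float = CORE_THRESHOLD
) -> pd.Series:
    """Label each gene core (frequency >= threshold, i.e. 'at least 90%')
    or accessory."""
    if not (0 < core_threshold <= 1):
        raise ValueError("core_threshold must be in (0, 1]")
    return pd.Series(
        np.where(frequencies >= core_threshold, "core", "accessory"),
        index=frequencies.index,
        name="partition",
    )


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """OR of [[a, b], [c, d]] with Haldane-Anscombe 0.5 correction on zeros."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def category_odds_ratio(labels: pd.Series, categories: pd.Series, category: str) -> float:
    """OR of one category in core vs accessory genes of one species.

    2x2 table: rows core/accessory, columns this-category/other-categories.
    Unannotated genes are excluded from both axes.
    """
    annotated = categories[categories != UNANNOTATED]
    lab = labels.loc[annotated.index]
    in_cat = annotated == category
    a = int(((lab == "core") & in_cat).sum())
    b = int(((lab == "core") & ~in_cat).sum())
    c = int(((lab == "accessory") & in_cat).sum())
    d = int(((lab == "accessory") & ~in_cat).sum())
    return _odds_ratio(a, b, c, d)


def category_enrichment(
    per_species: dict[str, tuple[pd.Series, pd.Series]],
    test: str = "one_sample",
) -> pd.DataFrame:
    """Cross-species enrichment of functional categories in core vs accessory.

    ``per_species`` maps species -> (core/accessory labels, categories),
    both indexed by gene cluster. For every category present in >= 2
    species, log odds ratios are collected across species and tested
    against 0 with a two-tailed one-sample t-test (default) or a two-sample
    t-test of core vs accessory category indicator means
    (``test='two_sample'`` pools per-species core/accessory category
    fractions); p-values are Bonferroni-adjusted over categories.
    """
    records: dict[str, list] = {}
    frac_records: dict[str, list] = {}
    for sp, (labels, categories) in per_species.items():
        annotated = categories[categories != UNANNOTATED]
        lab = labels.loc[annotated.index]
        if lab.nunique() < 2:
            continue  # need both core and accessory genes
        for cat in annotated.unique():
            orr = category_odds_ratio(labels, categories, cat)
            records.setdefault(cat, []).append(np.log(orr))
            in_cat = annotated == cat
            core_frac = float(in_cat[lab == "core"].mean())
            acc_frac = float(in_cat[lab == "accessory"].mean())
            frac_records.setdefault(cat, []).append((core_frac, acc_frac))
    rows = []
    for cat, logors in sorted(records.items()):
        if len(logors) < 2:
            continue
        logors = np.asarray(logors)
        if test == "one_sample":
            res = stats.ttest_1samp(logors, 0.0)
        elif test == "two_sample":
            core = np.array([x[0] for x in frac_records[cat]])
            acc = np.array([x[1] for x in frac_records[cat]])
            res = stats.ttest_ind(core, acc)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "category": cat,
                "n_species": len(logors),
                "mean_log_or": float(logors.mean()),
                "mean_or": float(np.exp(logors.mean())),
                "p_value": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bonferroni(out["p_value"])
        out["direction"] = np.where(out["mean_log_or"] > 0, "core", "accessory")
    return out


def catalog_overlap(
    genes: pd.DataFrame,
    gene_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-species counts of shared vs catalog-specific gene clusters.

    ``gene_meta`` carries an ``origin`` flag per (species, gene cluster):
    'both', 'a_specific' or 'b_specific'. Returns counts per species.
    """
    if "origin" not in gene_meta.columns:
        raise ValueError("gene_meta must carry an 'origin' column")
    rows = []
    for sp, sub in gene_meta.groupby("species_id"):
        counts = sub["origin"].value_counts()
        rows.append(
            {
                "species_id": sp,
                "shared": int(counts.get("both", 0)),
                "a_specific": int(counts.get("a_specific", 0)),
                "b_specific": int(counts.get("b_specific", 0)),
            }
        )
    return pd.DataFrame(rows)


def specific_vs_shared_enrichment(
    gene_meta: pd.DataFrame, which: str = "a_specific", test: str = "one_sample"
) -> pd.DataFrame:
    """Category enrichment of catalog-specific genes relative to shared genes.

    Reuses the core/accessory machinery with specific-vs-shared as the
    first axis of the 2x2 table.
    """
    per_species = {}
    for sp, sub in gene_meta.groupby("species_id"):
        sel = sub[sub["origin"].isin([which, "both"])].set_index("gene_cluster_id")
        labels = pd.Series(
            np.where(sel["origin"] == which, "core", "accessory"), index=sel.index
        )
        per_species[sp] = (labels, sel["category"])
    out = category_enrichment(per_species, test=test)
    if len(out):
        out = out.rename(columns={"direction": "_dir"})
        out["direction"] = np.where(out["_dir"] == "core", which, "shared")
        out = out.drop(columns="_dir")
    return out
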