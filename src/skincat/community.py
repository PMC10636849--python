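"""Community-level analyses of species abundance tables.

Implements the abundance workflow used for skin metagenome profiles:
depth filtering and rarefying of read counts, alpha diversity (richness at
a minimum read count, Shannon index), prevalence-filtered log-transformed
Bray-Curtis dissimilarity with classical-scaling ordination (PCoA), the
related-versus-unrelated mother-infant dyad comparison, and kingdom
composition with optional genome-size normalization.

Samples are species-by-sample integer count matrices (rows = species);
sample metadata carries subject, family, role (infant/mother), body site
(cheek / antecubital fossa) and age group (2-3m / 12m / mother).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._stats import rank_sum_test, u_statistic

MIN_CLASSIFIED_READS = 800_000

# Significance gates of the external differential-abundance model fit;
# recorded here for downstream users (the fit itself is not part of this
# package): adjusted p < 0.01 and > 2-fold change on rarefied counts with
# taxa present in >= 10% of samples.
DIFFERENTIAL_ABUNDANCE_GATES = {"max_adjusted_p": 0.01, "min_fold_change": 2.0, "min_prevalence": 0.10}


def filter_low_depth_and_rarefy(
    table: pd.DataFrame,
    min_reads: int = MIN_CLASSIFIED_READS,
    depth: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Drop shallow samples and subsample the rest to a common depth.

    Samples with fewer than ``min_reads`` total classified reads are
    excluded. Each retained sample is then subsampled without replacement
    to exactly ``depth`` reads (default: the minimum retained sample
    total). Samples with fewer reads than an explicit depth are dropped
    with a warning.
    """
    totals = table.sum(axis=0)
    keep = totals[totals >= min_reads].index
    if len(keep) == 0:
        raise ValueError("no samples pass the depth filter")
    sub = table[keep]
    totals = totals[keep]
    if depth is None:
        depth = int(totals.min())
    shallow = totals[totals < depth].index
    if len(shallow):
        warnings.warn(f"dropping {len(shallow)} sample(s) shallower than depth {depth}", stacklevel=2)
        sub = sub.drop(columns=shallow)
    rng = np.random.default_rng(seed)
    out = {}
    for col in sub.columns:
        counts = sub[col].to_numpy(dtype=np.int64)
        out[col] = rng.multivariate_hypergeometric(counts, depth)
    return pd.DataFrame(out, index=sub.index)


def alpha_diversity(table: pd.DataFrame, min_species_reads: int = 5) -> pd.DataFrame:
    """Richness (species with >= ``min_species_reads`` reads) and Shannon index.

    Shannon H = −Σ p_i ln p_i over nonzero proportions of the (rarefied)
    counts. All-zero samples get richness 0 and Shannon 0.
    """
    rows = []
    for col in table.columns:
        counts = table[col].to_numpy(dtype=float)
        total = counts.sum()
        richness = int((counts >= min_species_reads).sum())
        if total > 0:
            p = counts[counts > 0] / total
            shannon = float(-(p * np.log(p)).sum())
        else:
            shannon = 0.0
        rows.append({"sample_id": col, "richness": richness, "shannon": shannon})
    return pd.DataFrame(rows)


def transform_and_distance(
    table: pd.DataFrame,
    prevalence_cut: float = 0.20,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Prevalence-filtered, log-transformed Bray-Curtis dissimilarity matrix.

    Species present (count > 0) in <= ``prevalence_cut`` of samples are
    removed; remaining counts are transformed x -> ln(x + pseudocount);
    Bray-Curtis d(u, v) = Σ|u_i − v_i| / Σ(u_i + v_i) on the transformed
    values.
    """
    presence = (table > 0).mean(axis=1)
    kept = table[presence > prevalence_cut]
    if kept.empty:
        raise ValueError("all species removed by the prevalence filter")
    logged = np.log(kept.to_numpy(dtype=float) + pseudocount)
    d = squareform(pdist(logged.T, metric="braycurtis"))
    return pd.DataFrame(d, index=kept.columns, columns=kept.columns)


def pcoa(dissimilarity: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinate analysis (classical metric scaling).

    Double-centers the squared dissimilarities and eigendecomposes the Gram
    matrix; coordinates are returned for the ``k`` largest non-negative
    eigenvalues. Explained proportions are eigenvalues over the sum of
    positive eigenvalues; negative eigenvalues (non-Euclidean input) are
    truncated and their total magnitude reported via the attrs dict.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12
    neg_magnitude = float(-eigval[eigval < 0].sum())
    k = min(k, int(pos.sum()))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    explained = eigval[:k] / eigval[pos].sum() if pos.any() else np.zeros(k)
    out = pd.DataFrame(
        coords, index=dissimilarity.index, columns=[f"PCo{i+1}" for i in range(k)]
    )
    out.attrs["negative_eigenvalue_magnitude"] = neg_magnitude
    return out, explained


def dyad_dissimilarity_test(
    dissimilarity: pd.DataFrame,
    meta: pd.DataFrame,
    site: str = "antecubital",
    infant_age: str = "12m",
    p_mode: str = "ranksum",
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Related vs unrelated mother-infant dyad dissimilarity comparison.

    For each infant (at ``infant_age``, body site ``site``): the related
    value is the dissimilarity to its own mother's sample; the unrelated
    value is the median dissimilarity to all other mothers. The two
    per-infant vectors are compared with a two-sided Wilcoxon rank-sum
    test. Infants without a mother sample are excluded.

    ``p_mode='ranksum'`` (default) uses the analytic rank-sum null; note
    that it is conservative here because dyad values sharing a sample are
    dependent and the per-infant median is less dispersed than a single
    dyad distance. ``p_mode='permutation'`` keeps the same statistic but
    draws its null from random reassignments of mothers to families,
    which respects that dependence and is calibrated by construction.
    """
    m = meta.set_index("sample_id")
    mothers = m[(m["role"] == "mother") & (m["site"] == site)]
    infants = m[(m["role"] == "infant") & (m["site"] == site) & (m["age_group"] == infant_age)]
    mothers = mothers[mothers.index.isin(dissimilarity.index)]
    infants = infants[infants.index.isin(dissimilarity.index)]
    if len(mothers) < 2:
        raise ValueError("need at least two mother samples")
    mother_by_family = {fam: sid for sid, fam in mothers["family_id"].items()}
    mother_families = sorted(mother_by_family)
    mother_ids = [mother_by_family[f] for f in mother_families]
    used = [
        (sid, fam) for sid, fam in infants["family_id"].items() if fam in mother_by_family
    ]
    if len(used) < 2:
        raise ValueError("fewer than two complete mother-infant dyads")
    sub = dissimilarity.loc[[sid for sid, _ in used], mother_ids].to_numpy()

    def vectors(assignment: dict[str, str]) -> tuple[list[float], list[float]]:
        rel, unrel = [], []
        col = {mid: j for j, mid in enumerate(mother_ids)}
        for i, (sid, fam) in enumerate(used):
            own_j = col[assignment[fam]]
            rel.append(float(sub[i, own_j]))
            rest = np.delete(sub[i], own_j)
            unrel.append(float(np.median(rest)))
        return rel, unrel

    related, unrelated = vectors(mother_by_family)
    stat, p = rank_sum_test(related, unrelated)
    if p_mode == "permutation":
        rng = np.random.default_rng(seed)
        n1 = len(related)
        center = n1 * n1 / 2.0  # MW U expectation for equal group sizes
        observed_dev = abs(stat - center)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(mother_families)
            assignment = dict(zip(mother_families, (mother_by_family[f] for f in perm)))
            r, u = vectors(assignment)
            s = u_statistic(r, u)
            hits += abs(s - center) >= observed_dev - 1e-12
        p = (1 + hits) / (1 + n_perm)
    elif p_mode != "ranksum":
        raise ValueError(f"unknown p_mode {p_mode!r}")
    return {
        "n_dyads": len(used),
        "median_related": float(np.median(related)),
        "median_unrelated": float(np.median(unrelated)),
        "statistic": stat,
        "p_value": p,
        "p_mode": p_mode,
        "related": related,
        "unrelated": unrelated,
    }


def within_vs_between_individual_test(
    dissimilarity: pd.DataFrame,
    meta: pd.DataFrame,
    site: str,
    ages: tuple[str, str] = ("2-3m", "12m"),
) -> dict:
    """Longitudinal contrast: same-individual dissimilarity across two ages
    versus dissimilarity between different individuals at those ages."""
    m = meta.set_index("sample_id")
    sel = m[(m["site"] == site) & (m["age_group"].isin(ages)) & (m["role"] == "infant")]
    sel = sel[sel.index.isin(dissimilarity.index)]
    first = sel[sel["age_group"] == ages[0]]
    second = sel[sel["age_group"] == ages[1]]
    second_by_subject = {subj: sid for sid, subj in second["subject_id"].items()}
    within, between = [], []
    for sid, subj in first["subject_id"].items():
        for other_subj, other_sid in second_by_subject.items():
            d = float(dissimilarity.loc[sid, other_sid])
            (within if other_subj == subj else between).append(d)
    if len(within) < 2 or len(between) < 2:
        raise ValueError("not enough longitudinal pairs")
    stat, p = rank_sum_test(within, between)
    return {
        "n_within": len(within),
        "n_between": len(between),
        "median_within": float(np.median(within)),
        "median_between": float(np.median(between)),
        "statistic": stat,
        "p_value": p,
    }


def kingdom_composition(
    table: pd.DataFrame,
    species_meta: pd.DataFrame,
    normalize: bool = False,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Proportion of reads per kingdom, optionally genome-size normalized.

    ``species_meta`` maps species to ``kingdom`` and ``genome_size``. With
    ``normalize=True`` read counts are divided by genome size (yielding
    cell-number-like weights) before computing proportions. ``groups``
    optionally maps sample ids to group labels; default is one overall
    group.
    """
    meta = species_meta.set_index("species_id")
    missing = [s for s in table.index if s not in meta.index]
    if missing:
        raise ValueError(f"species without metadata: {missing[:5]}")
    kingdom = meta.loc[table.index, "kingdom"]
    values = table.to_numpy(dtype=float)
    if normalize:
        sizes = meta.loc[table.index, "genome_size"].to_numpy(dtype=float)
        if np.any(~np.isfinite(sizes)) or np.any(sizes <= 0):
            raise ValueError("genome_size required (positive) for normalization")
        values = values / sizes[:, None]
    df = pd.DataFrame(values, index=table.index, columns=table.columns)
    if groups is None:
        groups = pd.Series("all", index=table.columns)
    rows = []
    for grp, cols in groups.groupby(groups).groups.items():
        sub = df[list(cols)]
        by_kingdom = sub.groupby(kingdom).sum().sum(axis=1)
        total = by_kingdom.sum()
        for kgd, v in by_kingdom.items():
            rows.append({"group": grp, "kingdom": kgd, "proportion": float(v / total) if total else 0.0})
    return pd.DataFrame(rows)
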