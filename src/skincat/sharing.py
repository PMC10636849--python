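"""Strain-level mother-infant sharing analyses.

Single-nucleotide variants (SNVs) are called against each species'
representative genome on a shared coordinate system. The module computes
species SNV densities (requiring each variant in at least two conspecific
genomes), compares pairwise SNV counts between related mother-infant
pairs and unrelated pairs, partitions SNVs by host role (infant-only /
mother-only / shared), and assesses multi-locus sequence type (MLST)
sharing between mothers and infants with a permutation test on the
mother-to-infant pairing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from ._stats import rank_sum_test, u_statistic

MIN_GENOMES_FOR_SNV = 10
MIN_SNV_OCCURRENCE = 2
MIN_RELATED_PAIRS = 4
N_MLST_LOCI = 7


# ---------------------------------------------------------------------------
# SNV calling and density


def call_snvs_aligned(seq_a: str, seq_b: str) -> list[tuple[int, str, str]]:
    """Call substitutions between two equal-length aligned sequences.

    Returns (1-based position, base_a, base_b) for every position where
    both bases are in ACGT and differ; positions with N are skipped.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    valid = np.isin(a, bases) & np.isin(b, bases)
    diff = np.nonzero(valid & (a != b))[0]
    return [(int(i) + 1, a[i].decode(), b[i].decode()) for i in diff]


def species_snv_density(
    snvs: pd.DataFrame,
    representative_length: dict[str, int],
    min_genomes: int = MIN_GENOMES_FOR_SNV,
    min_occurrence: int = MIN_SNV_OCCURRENCE,
) -> pd.DataFrame:
    """Per-species SNV density (substitutions per kb of the representative).

    An SNV — identified by (position, alt allele) against the species
    representative — counts for a genome only when the same SNV occurs in
    at least ``min_occurrence`` conspecific genomes. Per-genome density is
    the retained SNV count over the representative length; the species
    density is the mean over conspecific genomes. Species with fewer than
    ``min_genomes`` genomes are skipped.
    """
    rows = []
    for sp, sub in snvs.groupby("species_id"):
        genomes = sub["genome_id"].unique()
        if len(genomes) < min_genomes:
            continue
        L = representative_length[sp]
        occ = sub.groupby(["position", "alt"])["genome_id"].nunique()
        shared = set(occ[occ >= min_occurrence].index)
        keys = list(zip(sub["position"], sub["alt"]))
        retained = sub[[k in shared for k in keys]]
        per_genome = retained.groupby("genome_id").size().reindex(genomes, fill_value=0)
        density_per_kb = per_genome / (L / 1000.0)
        rows.append(
            {
                "species_id": sp,
                "n_genomes": len(genomes),
                "snv_density_per_kb": float(density_per_kb.mean()),
            }
        )
    return pd.DataFrame(rows, columns=["species_id", "n_genomes", "snv_density_per_kb"])


def pairwise_snv_counts(snvs: pd.DataFrame, genome_pairs: pd.DataFrame) -> pd.DataFrame:
    """Count SNV differences between genome pairs of the same species.

    Both genomes are called against the shared representative, so the
    pairwise difference is the symmetric difference of their
    (position, alt) sets. ``genome_pairs`` has columns genome_a, genome_b,
    species_id and relationship.
    """
    by_genome: dict[tuple[str, str], set] = {}
    for (sp, g), sub in snvs.groupby(["species_id", "genome_id"]):
        by_genome[(sp, g)] = set(zip(sub["position"], sub["alt"]))
    out = genome_pairs.copy()
    out["n_snvs"] = [
        len(
            by_genome.get((r.species_id, r.genome_a), set())
            ^ by_genome.get((r.species_id, r.genome_b), set())
        )
        for r in genome_pairs.itertuples(index=False)
    ]
    return out


def related_vs_unrelated_snv_test(
    pairs: pd.DataFrame,
    min_pairs: int = MIN_RELATED_PAIRS,
    p_mode: str = "ranksum",
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-species two-sided rank-sum test of related- vs unrelated-pair
    SNV counts; species need at least ``min_pairs`` related pairs.

    ``p_mode='ranksum'`` uses the analytic rank-sum null. Because pairs
    sharing a genome share that strain's lineage, pooled pair counts are
    dependent and the analytic p is conservative; ``p_mode='permutation'``
    keeps the same statistic but permutes the mother-to-family matching
    (requires ``family_a``/``family_b`` columns with one genome per family
    and side), giving a calibrated null.
    """
    rows = []
    for sp, sub in pairs.groupby("species_id"):
        related = sub.loc[sub["relationship"] == "related_pair", "n_snvs"]
        unrelated = sub.loc[sub["relationship"] == "unrelated_pair", "n_snvs"]
        if len(related) < min_pairs:
            continue
        if len(unrelated) == 0:
            raise ValueError(f"species {sp}: no unrelated pairs")
        stat, p = rank_sum_test(related, unrelated)
        if p_mode == "permutation":
            p = _pair_permutation_p(sub, stat, n_perm, seed)
        elif p_mode != "ranksum":
            raise ValueError(f"unknown p_mode {p_mode!r}")
        rows.append(
            {
                "species_id": sp,
                "n_related": int(len(related)),
                "n_unrelated": int(len(unrelated)),
                "median_related": float(related.median()),
                "median_unrelated": float(unrelated.median()),
                "p_value": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "n_related",
            "n_unrelated",
            "median_related",
            "median_unrelated",
            "p_value",
        ],
    )


def _pair_permutation_p(sub: pd.DataFrame, observed_stat: float, n_perm: int, seed: int) -> float:
    """Two-sided permutation p for the rank-sum statistic of one species,
    permuting which mother family is matched to each infant family."""
    if "family_a" not in sub.columns or "family_b" not in sub.columns:
        raise ValueError("permutation p_mode requires family_a/family_b columns")
    matrix = sub.pivot_table(
        index="family_a", columns="family_b", values="n_snvs", aggfunc="first"
    )
    counts = matrix.to_numpy(dtype=float)
    fams_a = list(matrix.index)
    fams_b = list(matrix.columns)
    if set(fams_a) != set(fams_b):
        raise ValueError("permutation p_mode needs the complete infant x mother pair grid")
    order = [fams_b.index(f) for f in fams_a]
    counts = counts[:, order]  # align columns so the diagonal is the true match
    if np.isnan(counts).any():
        raise ValueError("permutation p_mode needs the complete infant x mother pair grid")
    n = len(fams_a)
    center = n * (n * (n - 1)) / 2.0  # MW U expectation: n related vs n(n-1) unrelated
    observed_dev = abs(observed_stat - center)
    rng = substream(seed, "snv_pair_permutation")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rel = counts[np.arange(n), perm]
        mask = np.ones_like(counts, dtype=bool)
        mask[np.arange(n), perm] = False
        s = u_statistic(rel, counts[mask])
        hits += abs(s - center) >= observed_dev - 1e-12
    return (1 + hits) / (1 + n_perm)


def estimate_sharing_fraction(pairs: pd.DataFrame, percentile: float = 1.0) -> float:
    """Estimate the fraction of related pairs carrying the maternal strain.

    A related pair is called 'shared strain' when its SNV count falls below
    the given percentile (default 1st) of the unrelated-pair distribution,
    i.e. far inside the unrelated background's lower tail.
    """
    related = pairs.loc[pairs["relationship"] == "related_pair", "n_snvs"].to_numpy()
    unrelated = pairs.loc[pairs["relationship"] == "unrelated_pair", "n_snvs"].to_numpy()
    if len(related) == 0 or len(unrelated) == 0:
        raise ValueError("need both related and unrelated pairs")
    threshold = np.percentile(unrelated, percentile)
    return float((related < threshold).mean())


def snv_source_partition(snvs: pd.DataFrame, roles: dict[str, str]) -> pd.DataFrame:
    """Partition distinct SNVs of each species by the roles of their carriers.

    Each distinct SNV (position, alt) is classed infant_only, mother_only
    or shared according to whether the genomes carrying it come from
    infants, mothers, or both. Proportions per species sum to 1.
    """
    unlabeled = set(snvs["genome_id"]) - roles.keys()
    if unlabeled:
        raise ValueError(f"genomes without role labels: {sorted(unlabeled)[:5]}")
    rows = []
    for sp, sub in snvs.groupby("species_id"):
        carrier_roles = sub.assign(role=sub["genome_id"].map(roles)).groupby(
            ["position", "alt"]
        )["role"].agg(set)
        n = len(carrier_roles)
        classes = carrier_roles.map(
            lambda s: "shared" if len(s) > 1 else ("infant_only" if "infant" in s else "mother_only")
        )
        counts = classes.value_counts()
        for cls in ("infant_only", "mother_only", "shared"):
            rows.append(
                {
                    "species_id": sp,
                    "class": cls,
                    "proportion": float(counts.get(cls, 0)) / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MLST


@dataclass
class MLSTScheme:
    """Seven-locus typing scheme: allele profile -> sequence type id."""

    loci: tuple[str, ...]
    profiles: dict[tuple[int, ...], str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.loci) != N_MLST_LOCI:
            raise ValueError(f"scheme must have {N_MLST_LOCI} loci")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, st_column: str = "st") -> "MLSTScheme":
        loci = tuple(c for c in df.columns if c != st_column)
        scheme = cls(loci=loci)
        for r in df.itertuples(index=False):
            profile = tuple(int(getattr(r, l)) for l in loci)
            scheme.profiles[profile] = str(getattr(r, st_column))
        return scheme

    def to_frame(self, st_column: str = "st") -> pd.DataFrame:
        rows = [
            {st_column: st, **dict(zip(self.loci, prof))}
            for prof, st in sorted(self.profiles.items(), key=lambda kv: kv[1])
        ]
        return pd.DataFrame(rows)


def assign_sequence_type(
    allele_profile: tuple[int, ...] | list[int], scheme: MLSTScheme
) -> tuple[str, int]:
    """Look up an allele profile; unmatched profiles are 'novel'.

    Returns (ST id or 'novel', Hamming distance to the nearest known
    profile; 0 for exact matches).
    """
    profile = tuple(int(a) for a in allele_profile)
    if len(profile) != len(scheme.loci):
        raise ValueError(f"expected {len(scheme.loci)} alleles, got {len(profile)}")
    st = scheme.profiles.get(profile)
    if st is not None:
        return st, 0
    if not scheme.profiles:
        return "novel", len(profile)
    nearest = min(
        sum(a != b for a, b in zip(profile, known)) for known in scheme.profiles
    )
    return "novel", int(nearest)


@dataclass
class STProfile:
    """Sequence types observed among one individual's isolates."""

    individual_id: str
    family_id: str
    role: str  # infant | mother
    st_set: frozenset[str]


def profiles_from_frame(df: pd.DataFrame, scheme: MLSTScheme) -> list[STProfile]:
    """Type each isolate of a per-isolate allele table and collect the ST
    set per individual. Novel profiles are labelled by their alleles so
    that identical novel profiles still match across individuals."""
    out = []
    for (ind, fam, role), sub in df.groupby(["individual_id", "family_id", "role"]):
        sts = set()
        for r in sub.itertuples(index=False):
            profile = tuple(int(getattr(r, l)) for l in scheme.loci)
            st, _ = assign_sequence_type(profile, scheme)
            sts.add(st if st != "novel" else "novel_" + "-".join(map(str, profile)))
        out.append(STProfile(str(ind), str(fam), str(role), frozenset(sts)))
    return out


def _family_sets(profiles: list[STProfile]) -> tuple[list[frozenset], list[frozenset]]:
    by_family: dict[str, dict[str, frozenset]] = {}
    for p in profiles:
        by_family.setdefault(p.family_id, {})[p.role] = p.st_set
    infants, mothers = [], []
    for fam in sorted(by_family):
        d = by_family[fam]
        if "infant" in d and "mother" in d:
            infants.append(d["infant"])
            mothers.append(d["mother"])
    return infants, mothers


def st_sharing_stat(profiles: list[STProfile]) -> int:
    """Number of families whose infant and mother share at least one ST.

    Families without both members typed are excluded.
    """
    infants, mothers = _family_sets(profiles)
    return sum(1 for i, m in zip(infants, mothers) if i & m)


def st_permutation_test(
    profiles: list[STProfile],
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "monte_carlo",
) -> dict:
    """Permutation test of mother-infant sequence-type sharing.

    The observed statistic is the number of families sharing at least one
    ST; the null permutes the mother-to-infant pairing. Monte-Carlo p uses
    the add-one correction (1 + #{null >= observed}) / (1 + n_perm); exact
    mode enumerates all pairings (families <= 8) and returns the exact
    tail probability #{null >= observed} / n!.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    infants, mothers = _family_sets(profiles)
    n = len(infants)
    if n < 2:
        raise ValueError("need at least two complete families")

    def stat(order) -> int:
        return sum(1 for i, j in enumerate(order) if infants[i] & mothers[j])

    observed = stat(range(n))
    if mode == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to <= 8 families")
        tail = sum(1 for perm in itertools.permutations(range(n)) if stat(perm) >= observed)
        total = math.factorial(n)
        null = None
        p = tail / total
    elif mode == "monte_carlo":
        rng = substream(seed, "st_permutation")
        null = [stat(rng.permutation(n)) for _ in range(n_perm)]
        p = (1 + sum(v >= observed for v in null)) / (1 + n_perm)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "observed": observed,
        "n_families": n,
        "p_value": float(p),
        "mode": mode,
        "null": null,
    }
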