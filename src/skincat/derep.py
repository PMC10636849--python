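"""ANI-based dereplication and species-level clustering.

Genomes are clustered by single linkage on an average-nucleotide-identity
(ANI) edge list: two genomes join when ANI ≥ threshold and the aligned
fraction (relative to the larger genome) ≥ a coverage gate. The catalog is
built in two stages: redundancy removal at 99.9% ANI (collapsing repeat
recoveries of the same strain, no coverage gate) followed by species
clustering of the survivors at 95% ANI with a 0.30 coverage gate. Each
cluster is represented by its best-scoring member, with a dRep-style
additive score over completeness, contamination, strain heterogeneity and
contig N50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

SPECIES_ANI = 95.0
REDUNDANCY_ANI = 99.9
SPECIES_MIN_COV = 0.30


@dataclass
class SpeciesCluster:
    cluster_id: str
    member_ids: set[str]
    representative_id: str | None = None

    def __post_init__(self):
        if self.representative_id is not None and self.representative_id not in self.member_ids:
            raise ValueError("representative must be a cluster member")


@dataclass
class ScoreWeights:
    """Weights of the additive representative score (config-exposed)."""

    completeness: float = 1.0
    contamination: float = -5.0
    strain_heterogeneity: float = 1.0  # applied as contamination * (het / 100)
    log_n50: float = 0.5


def build_ani_graph(
    edges: pd.DataFrame,
    genomes: list[str] | None = None,
    ani_threshold: float = SPECIES_ANI,
    min_cov: float = 0.0,
) -> nx.Graph:
    """Build the undirected genome graph from an ANI edge list.

    Edges qualify when ani >= ani_threshold and aligned_fraction >= min_cov.
    Asymmetric or duplicate reports of the same pair are resolved by keeping
    the maximum-ANI record. Self-edges are rejected.
    """
    g = nx.Graph()
    if genomes is not None:
        g.add_nodes_from(genomes)
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b, ani, cov in zip(
        edges["genome_a"], edges["genome_b"], edges["ani"], edges["aligned_fraction"]
    ):
        if a == b:
            raise ValueError(f"self-edge for genome {a!r}")
        key = (a, b) if a < b else (b, a)
        rec = (float(ani), float(cov))
        if key not in best or rec[0] > best[key][0]:
            best[key] = rec
    for (a, b), (ani, cov) in best.items():
        if genomes is not None and (a not in g or b not in g):
            unknown = [x for x in (a, b) if x not in g]
            raise ValueError(f"edge references unknown genome(s): {unknown}")
        if ani >= ani_threshold and cov >= min_cov:
            g.add_edge(a, b, ani=ani, aligned_fraction=cov)
        else:
            g.add_node(a)
            g.add_node(b)
    return g


def cluster_genomes(graph: nx.Graph) -> list[SpeciesCluster]:
    """Single-linkage clusters = connected components; ids ordered by the
    lexicographically smallest member."""
    comps = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    return [
        SpeciesCluster(cluster_id=f"c{i:05d}", member_ids=set(members))
        for i, members in enumerate(comps, start=1)
    ]


def score_genome(
    completeness: float,
    contamination: float,
    strain_heterogeneity: float = 0.0,
    n50: float = 1.0,
    weights: ScoreWeights = ScoreWeights(),
) -> float:
    """dRep-style representative score.

    score = completeness − 5·contamination
            + contamination·(strain_heterogeneity/100) + 0.5·log10(N50)
    """
    if n50 <= 0:
        raise ValueError(f"n50 must be positive, got {n50}")
    return (
        weights.completeness * completeness
        + weights.contamination * contamination
        + weights.strain_heterogeneity * contamination * (strain_heterogeneity / 100.0)
        + weights.log_n50 * math.log10(n50)
    )


def score_table(genomes: pd.DataFrame, weights: ScoreWeights = ScoreWeights()) -> dict[str, float]:
    """Score every genome of a quality table; returns genome_id -> score."""
    scores = {}
    for _, r in genomes.iterrows():
        scores[str(r["genome_id"])] = score_genome(
            float(r["completeness_primary"]),
            float(r["contamination_primary"]),
            float(r.get("strain_heterogeneity", 0.0) or 0.0),
            float(r.get("n50", 1.0) or 1.0),
            weights,
        )
    return scores


def select_representative(cluster: SpeciesCluster, scores: dict[str, float]) -> str:
    """Argmax score within the cluster; ties broken by smaller genome_id."""
    if not cluster.member_ids:
        raise ValueError("empty cluster")
    missing = cluster.member_ids - scores.keys()
    if missing:
        raise ValueError(f"unscored members: {sorted(missing)}")
    return min(cluster.member_ids, key=lambda m: (-scores[m], m))


@dataclass
class DereplicationResult:
    """Two-stage partition of a genome set."""

    redundancy_clusters: list[SpeciesCluster]
    species_clusters: list[SpeciesCluster]
    nonredundant: set[str] = field(default_factory=set)

    @property
    def species_representatives(self) -> dict[str, str]:
        return {c.cluster_id: c.representative_id for c in self.species_clusters}

    def membership(self) -> dict[str, str]:
        """genome -> species cluster id (nonredundant genomes only)."""
        out = {}
        for c in self.species_clusters:
            for m in c.member_ids:
                out[m] = c.cluster_id
        return out

    def to_frame(self) -> pd.DataFrame:
        red_rep = {}
        for c in self.redundancy_clusters:
            for m in c.member_ids:
                red_rep[m] = c.representative_id
        # species id of a redundant genome = that of its stage-1 representative
        sp = self.membership()
        rows = []
        for m in sorted(red_rep):
            rep = red_rep[m]
            rows.append(
                {
                    "genome_id": m,
                    "nonredundant": m in self.nonredundant,
                    "species_cluster_id": sp.get(m, sp.get(rep)),
                    "is_representative": any(
                        c.representative_id == m for c in self.species_clusters
                    ),
                }
            )
        return pd.DataFrame(rows)


def dereplicate_catalog(
    genomes: pd.DataFrame,
    edges: pd.DataFrame,
    redundancy_ani: float = REDUNDANCY_ANI,
    species_ani: float = SPECIES_ANI,
    redundancy_min_cov: float = 0.0,
    species_min_cov: float = SPECIES_MIN_COV,
    weights: ScoreWeights = ScoreWeights(),
) -> DereplicationResult:
    """Two-stage dereplication: collapse near-duplicates at 99.9% ANI, then
    cluster the nonredundant survivors into species at 95% ANI / 0.30 coverage.
    """
    ids = [str(g) for g in genomes["genome_id"]]
    scores = score_table(genomes, weights)

    g1 = build_ani_graph(edges, genomes=ids, ani_threshold=redundancy_ani, min_cov=redundancy_min_cov)
    stage1 = cluster_genomes(g1)
    for c in stage1:
        c.representative_id = select_representative(c, scores)
    survivors = {c.representative_id for c in stage1}

    surv_edges = edges[
        edges["genome_a"].isin(survivors) & edges["genome_b"].isin(survivors)
    ]
    g2 = build_ani_graph(
        surv_edges, genomes=sorted(survivors), ani_threshold=species_ani, min_cov=species_min_cov
    )
    stage2 = cluster_genomes(g2)
    for c in stage2:
        c.representative_id = select_representative(c, scores)
    return DereplicationResult(
        redundancy_clusters=stage1, species_clusters=stage2, nonredundant=survivors
    )


def assess_novelty(
    query_reps: list[str],
    reference_reps: list[str],
    edges: pd.DataFrame,
    ani_threshold: float = SPECIES_ANI,
    min_cov: float = SPECIES_MIN_COV,
) -> pd.DataFrame:
    """Label each query representative novel/known against reference catalogs.

    A query is *known* when single-linkage clustering of queries and
    references together at the species threshold places it in a component
    containing at least one reference genome.
    """
    refs = set(reference_reps)
    nodes = sorted(set(query_reps) | refs)
    g = build_ani_graph(edges, genomes=nodes, ani_threshold=ani_threshold, min_cov=min_cov)
    labels = {}
    for comp in nx.connected_components(g):
        known = bool(comp & refs)
        for n in comp:
            labels[n] = "known" if known else "novel"
    return pd.DataFrame(
        {"genome_id": list(query_reps), "novelty": [labels[q] for q in query_reps]}
    )
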