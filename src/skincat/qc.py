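"""Genome quality scoring, MIMAG-style tier assignment, and exclusion filters.

Draft genomes recovered from metagenomes (MAGs) are graded on completeness,
contamination, and the presence of ribosomal and transfer RNA genes:

* ``high_quality``  — completeness > 90, contamination < 5, all three rRNAs
  (5S plus the kingdom's SSU and LSU), and at least 18 of the 20 standard
  tRNAs;
* ``near_complete`` — completeness > 90 and contamination < 5 but the
  rRNA/tRNA requirement unmet;
* ``medium_quality`` — completeness > 50, contamination < 10 and quality
  score (completeness − 5 × contamination) > 50, accepted if satisfied under
  *either* the primary or the secondary completeness/contamination estimate
  (two estimators are routinely run and an inclusive rule is applied);
* ``fail`` otherwise.

All comparisons are strict, so boundary values fall to the lower tier.
Eukaryotic genomes use the same thresholds except that the medium tier has
no quality-score clause. Viral sequences are binned by completeness alone.

Two exclusion filters run before tiering in the full pipeline: a chimerism
filter on GUNC-style metrics and a removal of contigs whose best database
hit is a eukaryotic viral genome (host-virus carryover rather than a MAG
component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

Tier = Literal["high_quality", "near_complete", "medium_quality", "fail"]
ViralTier = Literal["complete", "high_quality", "medium_quality", "low_quality"]

#: Number of standard tRNA isotypes required for the high-quality tier.
MIN_TRNAS = 18


@dataclass
class GenomeQuality:
    """Quality and assembly metrics for one genome (estimates consumed as input)."""

    genome_id: str
    kingdom: str = "prokaryote"  # prokaryote | eukaryote
    completeness_primary: float = 0.0
    contamination_primary: float = 0.0
    completeness_secondary: float | None = None
    contamination_secondary: float | None = None
    rrna_5s: bool = False
    rrna_ssu: bool = False  # 16S (prokaryote) / 18S (eukaryote)
    rrna_lsu: bool = False  # 23S (prokaryote) / 26S (eukaryote)
    n_unique_trnas: int = 0
    n_contigs: int = 1
    n50: float = 0.0
    mean_depth: float = 0.0
    strain_heterogeneity: float = 0.0
    sample_id: str = ""
    gunc_contamination: float | None = None
    gunc_css: float | None = None
    gunc_rrs: float | None = None

    def __post_init__(self):
        for name in ("completeness_primary", "contamination_primary"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} out of [0, 100] for {self.genome_id}")
        if not (0 <= self.n_unique_trnas <= 20):
            raise ValueError(f"n_unique_trnas={self.n_unique_trnas} out of [0, 20]")


def compute_quality_score(completeness: float, contamination: float) -> float:
    """Quality score = completeness − 5 × contamination (may be negative)."""
    if not (0.0 <= completeness <= 100.0) or not (0.0 <= contamination <= 100.0):
        raise ValueError(
            f"completeness/contamination out of [0, 100]: ({completeness}, {contamination})"
        )
    return completeness - 5.0 * contamination

def _passes_medium(completeness: float | None, contamination: float | None, with_score: bool) -> bool:
    if completeness is None or contamination is None:
        return False
    if math.isnan(completeness) or math.isnan(contamination):
        return False
    ok = completeness > 50.0 and contamination < 10.0
    if ok and with_score:
        ok = compute_quality_score(completeness, contamination) > 50.0
    return ok


def _assign_tier(g: GenomeQuality, medium_uses_score: bool) -> Tier:
    comp, cont = g.completeness_primary, g.contamination_primary
    if comp > 90.0 and cont < 5.0:
        has_rnas = g.rrna_5s and g.rrna_ssu and g.rrna_lsu and g.n_unique_trnas >= MIN_TRNAS
        return "high_quality" if has_rnas else "near_complete"
    # Inclusive medium rule: either estimator may satisfy the criteria.
    if _passes_medium(comp, cont, medium_uses_score) or _passes_medium(
        g.completeness_secondary, g.contamination_secondary, medium_uses_score
    ):
        return "medium_quality"
    return "fail"


def assign_prokaryotic_tier(g: GenomeQuality) -> Tier:
    """Tier a prokaryotic genome; high/near-complete judged on the primary
    estimate only, the medium tier on either estimate (inclusive rule)."""
    return _assign_tier(g, medium_uses_score=True)


def assign_eukaryotic_tier(g: GenomeQuality) -> Tier:
    """Tier a eukaryotic genome; the medium tier omits the quality-score clause."""
    if g.kingdom != "eukaryote":
        raise TypeError(f"assign_eukaryotic_tier requires kingdom='eukaryote', got {g.kingdom!r}")
    return _assign_tier(g, medium_uses_score=False)


def assign_tier(g: GenomeQuality) -> Tier:
    """Dispatch on kingdom."""
    if g.kingdom == "eukaryote":
        return assign_eukaryotic_tier(g)
    return assign_prokaryotic_tier(g)


def assign_viral_tier(completeness: float) -> ViralTier:
    """Bin a viral sequence by completeness.

    complete at exactly 100; high_quality > 90; medium_quality > 50;
    otherwise low_quality (a sequence at exactly 50 falls to low_quality).
    """
    if not (0.0 <= completeness <= 100.0):
        raise ValueError(f"completeness={completeness} out of [0, 100]")
    if completeness == 100.0:
        return "complete"
    if completeness > 90.0:
        return "high_quality"
    if completeness > 50.0:
        return "medium_quality"
    return "low_quality"


def apply_chimera_filter(
    g: GenomeQuality, rule: Literal["all", "any"] = "all"
) -> bool:
    """Return True to keep the genome, False to discard it as chimeric.

    A genome is discarded when its GUNC-style portion of contaminated
    positions exceeds 0.05, clade separation score exceeds 0.45 and
    reference representation score exceeds 0.5. ``rule='all'`` requires all
    three criteria (default); ``rule='any'`` discards when any one trips.
    Missing metrics keep the genome.
    """
    metrics = (g.gunc_contamination, g.gunc_css, g.gunc_rrs)
    if any(m is None or (isinstance(m, float) and math.isnan(m)) for m in metrics):
        return True
    flags = (metrics[0] > 0.05, metrics[1] > 0.45, metrics[2] > 0.5)
    tripped = all(flags) if rule == "all" else any(flags)
    return not tripped


@dataclass
class ContigHit:
    """Best database hit for one contig of a MAG."""

    contig_id: str
    length: int
    top_hit_is_eukaryotic_viral: bool
    percent_identity: float
    aligned_length: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"contig {self.contig_id} has non-positive length")
        if self.aligned_length > self.length:
            raise ValueError(f"contig {self.contig_id}: aligned_length > length")


def filter_viral_contigs(hits: Iterable[ContigHit]) -> list[str]:
    """Return ids of contigs retained after removing eukaryotic-viral carryover.

    A contig is removed when its top hit is a eukaryotic viral genome with
    > 95% nucleotide identity, > 1000 bp aligned and > 70% of the contig
    aligned.
    """
    kept = []
    for h in hits:
        remove = (
            h.top_hit_is_eukaryotic_viral
            and h.percent_identity > 95.0
            and h.aligned_length > 1000
            and h.aligned_length / h.length > 0.70
        )
        if not remove:
            kept.append(h.contig_id)
    return kept


# ---------------------------------------------------------------------------
# table-level wrappers


def _row_to_genome(row: pd.Series) -> GenomeQuality:
    def opt(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    return GenomeQuality(
        genome_id=str(row["genome_id"]),
        sample_id=str(row.get("sample_id", "")),
        kingdom=str(row.get("kingdom", "prokaryote")),
        completeness_primary=float(row["completeness_primary"]),
        contamination_primary=float(row["contamination_primary"]),
        completeness_secondary=opt("completeness_secondary"),
        contamination_secondary=opt("contamination_secondary"),
        rrna_5s=bool(row.get("rrna_5s", False)),
        rrna_ssu=bool(row.get("rrna_ssu", False)),
        rrna_lsu=bool(row.get("rrna_lsu", False)),
        n_unique_trnas=int(row.get("n_unique_trnas", 0)),
        n_contigs=int(row.get("n_contigs", 1)),
        n50=float(row.get("n50", 0.0)),
        mean_depth=float(row.get("mean_depth", 0.0)),
        strain_heterogeneity=float(row.get("strain_heterogeneity", 0.0)),
        gunc_contamination=opt("gunc_contamination"),
        gunc_css=opt("gunc_css"),
        gunc_rrs=opt("gunc_rrs"),
    )


def assign_tiers(genomes: pd.DataFrame, gunc_rule: Literal["all", "any"] = "all") -> pd.DataFrame:
    """Tier every genome in a quality table.

    Returns a table with ``genome_id, kingdom, tier, quality_score,
    passed_chimera_filter``; genomes failing the chimera filter keep their
    tier but are flagged for exclusion by downstream stages.
    """
    rows = []
    for _, r in genomes.iterrows():
        g = _row_to_genome(r)
        rows.append(
            {
                "genome_id": g.genome_id,
                "sample_id": g.sample_id,
                "kingdom": g.kingdom,
                "tier": assign_tier(g),
                "quality_score": compute_quality_score(
                    g.completeness_primary, g.contamination_primary
                ),
                "passed_chimera_filter": apply_chimera_filter(g, rule=gunc_rule),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "sample_id",
            "kingdom",
            "tier",
            "quality_score",
            "passed_chimera_filter",
        ],
    )


def tier_summary(tiers: pd.DataFrame) -> pd.DataFrame:
    """Count genomes per (kingdom, tier); zero-filled over all tier labels."""
    all_tiers = ["high_quality", "near_complete", "medium_quality", "fail"]
    if tiers.empty:
        return pd.DataFrame(columns=["kingdom", "tier", "n"])
    out = (
        tiers.groupby(["kingdom", "tier"], sort=True)
        .size()
        .reset_index(name="n")
    )
    full = []
    for kingdom in sorted(tiers["kingdom"].unique()):
        for t in all_tiers:
            sel = out[(out["kingdom"] == kingdom) & (out["tier"] == t)]
            full.append(
                {"kingdom": kingdom, "tier": t, "n": int(sel["n"].iloc[0]) if len(sel) else 0}
            )
    return pd.DataFrame(full)
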