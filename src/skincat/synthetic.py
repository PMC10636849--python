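"""Ground-truth-labeled synthetic datasets for the catalog pipeline.

The generator emulates a longitudinal mother-infant skin-microbiome study:
families contribute an infant sampled at two body sites (cheek,
antecubital fossa) and two ages (2-3 months, 12 months) plus one maternal
antecubital sample. Species abundances follow a log-normal community
model with site/age effects and a tunable mother-infant correlation.
Genome recoveries from samples carry quality metrics drawn from
distributions that populate every tier boundary, and an ANI edge list
with within-species, between-species and duplicate-recovery structure.
Strain transmission is explicit: for each family and species the infant
carries the maternal strain lineage with probability ``sharing_prob``,
and strains accumulate substitutions under an infinite-sites model on a
fixed coordinate system (Poisson(mu * t * L) uniformly placed sites), so
downstream SNV calling is exact column comparison. Gene content has a
core mode at frequency 1 and a U-shaped accessory frequency spectrum,
thinned by each genome's completeness. Every table round-trips through
the package's TSV writers.

All draws come from named substreams of a single seed, so adding a stage
never perturbs the others, and identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._rng import substream

KINGDOMS = ("bacteria", "fungi", "virus")
COG_CATEGORIES = ("C", "E", "F", "G", "H", "I", "J", "K", "L", "M", "N", "O", "P", "Q", "T", "U", "V")
UNANNOTATED = "S?"


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Community-scale defaults mirror the emulated study design (67 families
    with maternal samples, two sites, two infant ages); distributional
    defaults are module decisions chosen to span the decision boundaries
    of the downstream stages, since no real-data fits back them.
    """

    n_families: int = 67
    n_species: int = 30
    sites: tuple[str, ...] = ("cheek", "antecubital")
    ages: tuple[str, ...] = ("2-3m", "12m")
    seed: int = 0

    # strain transmission
    sharing_prob: float = 0.5  # q: infant carries the maternal strain
    mutation_rate: float = 1e-6  # mu, substitutions / site / time unit
    divergence_time_related: float = 200.0
    divergence_time_unrelated: float = 12500.0
    genome_length: int = 100_000  # L, shared SNV coordinate system
    n_transmission_species: int = 6  # species tracked at strain level
    secondary_lineage_prob: float = 0.3  # chance an individual carries a 2nd strain
    n_isolates_range: tuple[int, int] = (4, 12)  # cultured isolates per individual
    mlst_allele_range: int = 50

    # community model
    kingdom_props: tuple[float, float, float] = (0.953, 0.012, 0.035)
    kingdom_abundance_weights: tuple[float, float, float] = (0.973, 0.024, 0.003)
    site_effect: float = 1.0  # sd of per-species site log-fold shifts
    age_effect: float = 1.0  # sd of per-species age log-fold shifts
    relatedness_correlation: float = 0.5  # mother-infant community correlation
    abundance_sigma: float = 1.0  # subject-level log-abundance noise
    sample_noise: float = 0.3
    reads_log10_mean: float = 6.3  # median ~2M classified reads per sample
    reads_log10_sd: float = 0.15

    # genome recoveries
    recovery_scale: float = 5e4  # reads at which recovery becomes likely
    duplicate_recovery_prob: float = 0.15  # second (pooled-assembly) recovery
    completeness_high_weight: float = 0.75  # weight of the high mode
    contamination_mean: float = 2.0  # exponential, truncated at 15
    chimera_rate: float = 0.02
    ani_within_range: tuple[float, float] = (95.2, 99.5)
    ani_between_range: tuple[float, float] = (80.0, 92.0)
    ani_duplicate_range: tuple[float, float] = (99.92, 100.0)
    aligned_fraction_range: tuple[float, float] = (0.40, 0.95)
    between_edge_prob: float = 0.1  # fraction of sub-threshold edges reported

    # gene content
    core_fraction: float = 0.5
    n_genes: int = 1000
    core_category_effects: dict = field(
        default_factory=lambda: {"J": 2.0, "E": 1.5, "G": 1.5}
    )
    accessory_category_effects: dict = field(
        default_factory=lambda: {"L": 2.0, "V": 2.0, "K": 1.5}
    )
    unannotated_fraction: float = 0.25
    a_specific_fraction: float = 0.15
    b_specific_fraction: float = 0.15

    # read classification
    reference_fraction_mean: float = 0.636
    reference_fraction_sd: float = 0.08
    improvement_median_pct: float = 21.0
    improvement_sd_pct: float = 8.0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("sharing_prob", "core_fraction", "relatedness_correlation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.divergence_time_related > self.divergence_time_unrelated:
            raise ValueError("divergence_time_related must be <= divergence_time_unrelated")
        if abs(sum(self.kingdom_props) - 1) > 1e-9:
            raise ValueError("kingdom_props must sum to 1")


# ---------------------------------------------------------------------------
# species pool


def generate_species_pool(config: ScenarioConfig) -> pd.DataFrame:
    """Species table: id, kingdom, prevalence, mean relative abundance,
    genome size. Kingdom abundance weights are split among the kingdom's
    species so the expected community composition matches the configured
    proportions."""
    rng = substream(config.seed, "species_pool")
    n = config.n_species
    kingdoms = rng.choice(KINGDOMS, size=n, p=config.kingdom_props)
    prevalence = np.clip(rng.beta(1.2, 1.5, size=n), 0.05, 1.0)
    raw = rng.lognormal(0.0, 1.0, size=n)
    weights = dict(zip(KINGDOMS, config.kingdom_abundance_weights))
    present_total = sum(w for k, w in weights.items() if (kingdoms == k).any())
    mean_abundance = np.zeros(n)
    for k in KINGDOMS:
        mask = kingdoms == k
        if mask.any():
            mean_abundance[mask] = raw[mask] / raw[mask].sum() * weights[k] / present_total
    size_params = {"bacteria": (2.5e6, 5e5, 5e5), "fungi": (1.2e7, 2e6, 2e6), "virus": (4e4, 1e4, 5e3)}
    genome_size = np.array(
        [max(rng.normal(*size_params[k][:2]), size_params[k][2]) for k in kingdoms]
    )
    return pd.DataFrame(
        {
            "species_id": [f"s{i:04d}" for i in range(1, n + 1)],
            "kingdom": kingdoms,
            "prevalence": prevalence,
            "mean_abundance": mean_abundance,
            "genome_size": genome_size.round().astype(np.int64),
        }
    )


# ---------------------------------------------------------------------------
# samples and abundances


def generate_samples_and_abundances(
    config: ScenarioConfig, pool: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species-by-sample count matrix plus sample metadata.

    Each family contributes up to 2 sites x 2 ages infant samples and one
    maternal antecubital sample. Presence and log-abundance deviations of
    mother and infant share a family component with weight
    sqrt(relatedness_correlation), so the mother-infant correlation equals
    ``relatedness_correlation``. Within each sample the kingdom-level
    intensity shares are pinned to ``kingdom_abundance_weights`` (species
    variation plays out within kingdoms), so the aggregate community
    composition matches the configured proportions.
    """
    if pool.empty:
        raise ValueError("species pool is empty")
    rng = substream(config.seed, "samples")
    n_sp = len(pool)
    prev = pool["prevalence"].to_numpy()
    log_mean = np.log(np.maximum(pool["mean_abundance"].to_numpy(), 1e-12))
    site_coef = rng.normal(0.0, config.site_effect, size=n_sp)
    age_coef = rng.normal(0.0, config.age_effect, size=n_sp)
    mother_coef = rng.normal(0.0, config.age_effect, size=n_sp)
    rho = config.relatedness_correlation
    w_fam, w_own = np.sqrt(rho), np.sqrt(1.0 - rho)
    from scipy.stats import norm

    thresh = norm.ppf(prev)
    meta_rows, columns = [], {}
    for f in range(1, config.n_families + 1):
        fam = f"F{f:03d}"
        u_fam = rng.normal(size=n_sp)
        v_fam = rng.normal(size=n_sp)
        subjects = [(f"{fam}_I", "infant"), (f"{fam}_M", "mother")]
        latents = {}
        for subj, _ in subjects:
            u = w_fam * u_fam + w_own * rng.normal(size=n_sp)
            v = w_fam * v_fam + w_own * rng.normal(size=n_sp)
            latents[subj] = (u < thresh, v)
        for subj, role in subjects:
            present, v = latents[subj]
            if role == "mother":
                site_age = [("antecubital", "mother")]
            else:
                site_age = [(s, a) for s in config.sites for a in config.ages]
            for site, age in site_age:
                sid = f"{subj}_{site}_{age}" if role == "infant" else f"{subj}_antecubital"
                log_int = (
                    log_mean
                    + site_coef * (site == "antecubital")
                    + age_coef * (age in ("12m", "mother"))
                    + mother_coef * (age == "mother")
                    + config.abundance_sigma * v
                    + rng.normal(0.0, config.sample_noise, size=n_sp)
                )
                intensity = np.where(present, np.exp(log_int), 0.0)
                for k, weight in zip(KINGDOMS, config.kingdom_abundance_weights):
                    mask = pool["kingdom"].to_numpy() == k
                    s = intensity[mask].sum()
                    if s > 0:
                        intensity[mask] *= weight / s
                if intensity.sum() == 0:
                    intensity[int(np.argmax(prev))] = 1.0
                total = int(round(10 ** rng.normal(config.reads_log10_mean, config.reads_log10_sd)))
                counts = rng.multinomial(total, intensity / intensity.sum())
                columns[sid] = counts
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": subj,
                        "family_id": fam,
                        "role": role,
                        "site": site,
                        "age_group": age,
                        "total_reads": total,
                    }
                )
    abundance = pd.DataFrame(columns, index=pool["species_id"])
    abundance.index.name = "species_id"
    return abundance, pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# genome recoveries


def generate_genome_recoveries(
    config: ScenarioConfig,
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    pool: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Genome quality table, ANI edge list and ground-truth labels.

    Recovery probability grows with a species' read count in the sample
    (1 − exp(−reads / recovery_scale)). With probability
    ``duplicate_recovery_prob`` the same strain is recovered a second time
    (emulating single- plus pooled-sample assembly), giving near-identical
    (>= 99.9% ANI) duplicates. Within-species ANI between different
    subjects' strains and between-species ANI are drawn from disjoint
    configured ranges on either side of the 95% species boundary.
    """
    rng = substream(config.seed, "recoveries")
    pool_idx = pool.set_index("species_id")
    subject_of = meta.set_index("sample_id")["subject_id"]
    genomes, truth_species, truth_lineage = [], {}, {}
    counter = 0
    for sid in abundance.columns:
        for sp in abundance.index:
            reads = int(abundance.loc[sp, sid])
            kingdom = pool_idx.loc[sp, "kingdom"]
            if kingdom == "virus":
                continue  # viral sequences are handled by the viral-tier path
            p_rec = 1.0 - np.exp(-reads / config.recovery_scale)
            if rng.random() >= p_rec:
                continue
            n_copies = 2 if rng.random() < config.duplicate_recovery_prob else 1
            lineage = f"{sp}|{subject_of[sid]}"
            for _ in range(n_copies):
                counter += 1
                gid = f"g{counter:05d}"
                genomes.append(_draw_quality_row(rng, config, gid, sid, kingdom, reads, pool_idx.loc[sp, "genome_size"]))
                truth_species[gid] = sp
                truth_lineage[gid] = lineage
    genome_df = pd.DataFrame(genomes)
    edges = _draw_ani_edges(rng, config, genome_df, truth_species, truth_lineage)
    truth = {"genome_species": truth_species, "genome_lineage": truth_lineage}
    return genome_df, edges, truth


def _draw_quality_row(rng, config, gid, sid, kingdom, reads, genome_size):
    if rng.random() < config.completeness_high_weight:
        completeness = 70.0 + 30.0 * rng.beta(5.0, 1.5)
    else:
        completeness = rng.uniform(40.0, 70.0)
    contamination = min(rng.exponential(config.contamination_mean), 15.0)
    comp2 = float(np.clip(completeness + rng.normal(0, 2.0), 0, 100))
    cont2 = float(np.clip(contamination + rng.normal(0, 1.0), 0, 100))
    p_rna = min(1.0, completeness / 100.0) * 0.85
    chimeric = rng.random() < config.chimera_rate
    if chimeric:
        gunc = (rng.uniform(0.06, 0.30), rng.uniform(0.50, 0.90), rng.uniform(0.55, 0.95))
    else:
        gunc = (rng.uniform(0.0, 0.04), rng.uniform(0.0, 0.40), rng.uniform(0.0, 0.45))
    return {
        "genome_id": gid,
        "sample_id": sid,
        "kingdom": "eukaryote" if kingdom == "fungi" else "prokaryote",
        "completeness_primary": round(completeness, 2),
        "contamination_primary": round(contamination, 2),
        "completeness_secondary": round(comp2, 2),
        "contamination_secondary": round(cont2, 2),
        "rrna_5s": bool(rng.random() < p_rna),
        "rrna_ssu": bool(rng.random() < p_rna),
        "rrna_lsu": bool(rng.random() < p_rna),
        "n_unique_trnas": int(rng.binomial(20, min(1.0, completeness / 100.0) * 0.95)),
        "n_contigs": int(1 + rng.poisson(2.0 * (100.0 - completeness))),
        "n50": int(rng.lognormal(10.5, 0.8)),
        "mean_depth": round(reads * 150.0 / genome_size, 2),
        "strain_heterogeneity": round(min(rng.exponential(0.5), 100.0), 3),
        "gunc_contamination": round(gunc[0], 4),
        "gunc_css": round(gunc[1], 4),
        "gunc_rrs": round(gunc[2], 4),
    }


def _draw_ani_edges(rng, config, genome_df, truth_species, truth_lineage):
    rows = []
    if genome_df.empty:
        return pd.DataFrame(columns=["genome_a", "genome_b", "ani", "aligned_fraction"])
    ids = genome_df["genome_id"].tolist()
    by_species: dict[str, list[str]] = {}
    for g in ids:
        by_species.setdefault(truth_species[g], []).append(g)
    lo_f, hi_f = config.aligned_fraction_range
    for members in by_species.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if truth_lineage[a] == truth_lineage[b]:
                    ani = rng.uniform(*config.ani_duplicate_range)
                else:
                    ani = rng.uniform(*config.ani_within_range)
                rows.append((a, b, round(ani, 3), round(rng.uniform(lo_f, hi_f), 3)))
    species_list = sorted(by_species)
    for i in range(len(species_list)):
        for j in range(i + 1, len(species_list)):
            for a in by_species[species_list[i]]:
                for b in by_species[species_list[j]]:
                    if rng.random() < config.between_edge_prob:
                        ani = rng.uniform(*config.ani_between_range)
                        rows.append((a, b, round(ani, 3), round(rng.uniform(lo_f, hi_f), 3)))
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "ani", "aligned_fraction"])


# ---------------------------------------------------------------------------
# strain transmission, SNVs, MLST


def _draw_snv_positions(rng, L: int, expected: float, taken: set[int] | None = None) -> np.ndarray:
    n = rng.poisson(expected)
    if expected > L or n > L:
        warnings.warn(
            f"expected mutations ({expected:.0f}) approach genome length {L}; saturating",
            stacklevel=3,
        )
        n = min(n, L)
    pos = set()
    forbidden = taken or set()
    while len(pos) < n:
        draw = rng.integers(1, L + 1, size=n - len(pos))
        pos.update(int(p) for p in draw if p not in forbidden and p not in pos)
        if len(forbidden) + n >= L:  # saturation guard: no free sites left
            break
    return np.array(sorted(pos), dtype=np.int64)


def _mutate(rng, ref_base: str) -> str:
    others = [b for b in "ACGT" if b != ref_base]
    return others[rng.integers(0, 3)]


def generate_strain_transmission(
    config: ScenarioConfig, pool: pd.DataFrame
) -> dict:
    """Strain-level ground truth: SNV tables, pairwise comparisons, MLST.

    For each of the ``n_transmission_species`` most prevalent bacterial
    species and each family carrying it, the infant's strain is the
    maternal lineage with probability ``sharing_prob`` (then both mother
    and infant accumulate private substitutions over
    ``divergence_time_related``) and an independent lineage otherwise.
    Lineages diverge from the species representative by
    Poisson(mu * divergence_time_unrelated * L) substitutions at uniform
    distinct sites (infinite-sites). Sequence types derive from each
    lineage's 7-locus allele profile, so ST sharing mirrors strain
    transmission. Returns a dict with snvs, pairs, roles, references,
    st_profiles, scheme and truth.
    """
    from .sharing import MLSTScheme

    rng = substream(config.seed, "transmission")
    bacteria = pool[pool["kingdom"] == "bacteria"].sort_values(
        "prevalence", ascending=False
    )
    focal = bacteria.head(config.n_transmission_species)
    L = config.genome_length
    mu = config.mutation_rate
    snv_rows, pair_rows, roles = [], [], {}
    truth = {"transmitted": {}, "lineage_of": {}}
    references: dict[str, str] = {}
    lineage_profiles: dict[str, tuple[int, ...]] = {}

    def lineage_snvs(ref: np.ndarray, taken=None) -> dict[int, str]:
        pos = _draw_snv_positions(rng, L, mu * config.divergence_time_unrelated * L, taken)
        return {int(p): _mutate(rng, ref[p - 1]) for p in pos}

    def private_snvs(ref: np.ndarray, base: dict[int, str]) -> dict[int, str]:
        pos = _draw_snv_positions(
            rng, L, mu * config.divergence_time_related * L, set(base)
        )
        out = dict(base)
        out.update({int(p): _mutate(rng, ref[p - 1]) for p in pos})
        return out

    def new_profile() -> tuple[int, ...]:
        while True:
            prof = tuple(int(a) for a in rng.integers(1, config.mlst_allele_range + 1, size=7))
            if prof not in lineage_profiles.values():
                return prof

    for sp in focal["species_id"]:
        prev = float(pool.set_index("species_id").loc[sp, "prevalence"])
        ref = np.array(list("ACGT"))[rng.integers(0, 4, size=L)]
        references[sp] = "".join(ref)
        for f in range(1, config.n_families + 1):
            fam = f"F{f:03d}"
            if rng.random() >= prev:
                continue  # dyad does not carry this species
            maternal_lineage = f"{sp}|{fam}_M"
            lineage_profiles[maternal_lineage] = new_profile()
            base = lineage_snvs(ref)
            transmitted = rng.random() < config.sharing_prob
            truth["transmitted"][f"{sp}|{fam}"] = bool(transmitted)
            mother_snvs = private_snvs(ref, base)
            if transmitted:
                infant_lineage = maternal_lineage
                infant_snvs = private_snvs(ref, base)
            else:
                infant_lineage = f"{sp}|{fam}_I"
                lineage_profiles[infant_lineage] = new_profile()
                infant_snvs = private_snvs(ref, lineage_snvs(ref))
            for role, gid, snvs, lineage in (
                ("mother", f"{sp}|{fam}_M", mother_snvs, maternal_lineage),
                ("infant", f"{sp}|{fam}_I", infant_snvs, infant_lineage),
            ):
                roles[gid] = role
                truth["lineage_of"][gid] = lineage
                for p, alt in sorted(snvs.items()):
                    snv_rows.append((sp, gid, p, ref[p - 1], alt))
        # pairwise comparisons: each infant vs own mother (related) and all
        # other mothers of the species (unrelated)
        sp_genomes = [g for g in roles if g.startswith(f"{sp}|")]
        mothers = [g for g in sp_genomes if roles[g] == "mother"]
        infants = [g for g in sp_genomes if roles[g] == "infant"]
        for ig in infants:
            fam = ig.split("|")[1].rsplit("_", 1)[0]
            for mg in mothers:
                fam_b = mg.split("|")[1].rsplit("_", 1)[0]
                rel = "related_pair" if fam_b == fam else "unrelated_pair"
                pair_rows.append((sp, ig, mg, rel, fam, fam_b))

    snvs = pd.DataFrame(snv_rows, columns=["species_id", "genome_id", "position", "ref", "alt"])
    pairs = pd.DataFrame(
        pair_rows,
        columns=["species_id", "genome_a", "genome_b", "relationship", "family_a", "family_b"],
    )
    st_profiles, scheme = _generate_st_profiles(config, rng, focal, lineage_profiles, truth)
    return {
        "snvs": snvs,
        "pairs": pairs,
        "roles": roles,
        "references": references,
        "st_profiles": st_profiles,
        "scheme": scheme,
        "truth": truth,
    }


def _generate_st_profiles(config, rng, focal, lineage_profiles, truth):
    """Per-isolate MLST table for the most prevalent focal species."""
    from .sharing import MLSTScheme

    loci = tuple(f"locus{i}" for i in range(1, 8))
    scheme = MLSTScheme(loci=loci)
    for i, prof in enumerate(sorted(set(lineage_profiles.values())), start=1):
        scheme.profiles[prof] = f"ST{i}"
    if focal.empty:
        return (
            pd.DataFrame(
                columns=["species_id", "individual_id", "family_id", "role", "isolate_id", *loci]
            ),
            scheme,
        )
    sp = focal["species_id"].iloc[0]
    rows = []
    lo, hi = config.n_isolates_range
    for gid, lineage in truth["lineage_of"].items():
        if not gid.startswith(f"{sp}|"):
            continue
        ind = gid.split("|")[1]
        fam = ind.rsplit("_", 1)[0]
        role = "mother" if ind.endswith("_M") else "infant"
        carried = [lineage_profiles[lineage]]
        if rng.random() < config.secondary_lineage_prob:
            extra = f"{sp}|{ind}_extra"
            if extra not in lineage_profiles:
                prof = tuple(int(a) for a in rng.integers(1, config.mlst_allele_range + 1, size=7))
                lineage_profiles[extra] = prof
                if prof not in scheme.profiles:
                    scheme.profiles[prof] = f"ST{len(scheme.profiles) + 1}"
            carried.append(lineage_profiles[extra])
        n_isolates = int(rng.integers(lo, hi + 1))
        for k in range(1, n_isolates + 1):
            # the dominant (primary) strain is always among the colonies
            prof = carried[0] if k == 1 else carried[rng.integers(0, len(carried))]
            rows.append(
                {
                    "species_id": sp,
                    "individual_id": ind,
                    "family_id": fam,
                    "role": role,
                    "isolate_id": f"{ind}_iso{k:02d}",
                    **dict(zip(loci, prof)),
                }
            )
    return pd.DataFrame(rows), scheme


def sequences_from_snvs(reference: str, snvs: pd.DataFrame, genome_id: str) -> str:
    """Materialize a genome's sequence from the reference and its SNV set."""
    seq = list(reference)
    sub = snvs[snvs["genome_id"] == genome_id]
    for p, alt in zip(sub["position"], sub["alt"]):
        seq[int(p) - 1] = alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# gene matrices


def _category_probs(config, effects: dict) -> np.ndarray:
    base = np.ones(len(COG_CATEGORIES))
    for cat, mult in effects.items():
        base[COG_CATEGORIES.index(cat)] *= mult
    return base / base.sum()


def generate_gene_matrix(
    config: ScenarioConfig, genomes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene presence/absence with category labels and catalog-origin flags.

    ``genomes`` maps genome_id to species_cluster_id and completeness.
    True core genes (``core_fraction`` of the pool) are present in every
    conspecific genome before completeness-thinning; accessory gene
    frequencies follow a U-shaped Beta(0.35, 0.35). Observed presence is
    thinned by each genome's completeness. Functional categories are drawn
    from core/accessory-specific distributions encoding the configured
    enrichment effects. Returns (genes long table, gene_meta, truth table).
    """
    rng = substream(config.seed, "genes")
    p_core = _category_probs(config, config.core_category_effects)
    p_acc = _category_probs(config, config.accessory_category_effects)
    gene_rows, meta_rows, truth_rows = [], [], []
    origin_p = [
        1.0 - config.a_specific_fraction - config.b_specific_fraction,
        config.a_specific_fraction,
        config.b_specific_fraction,
    ]
    for sp, sub in genomes.groupby("species_cluster_id"):
        gids = sub["genome_id"].tolist()
        comp = sub["completeness"].to_numpy(dtype=float) / 100.0
        n_core = int(round(config.core_fraction * config.n_genes))
        for gi in range(1, config.n_genes + 1):
            gene = f"{sp}_gc{gi:05d}"
            is_core = gi <= n_core
            freq = 1.0 if is_core else rng.beta(0.35, 0.35)
            carried = rng.random(len(gids)) < freq if not is_core else np.ones(len(gids), bool)
            observed = carried & (rng.random(len(gids)) < comp)
            if not observed.any():
                continue
            for g, obs in zip(gids, observed):
                if obs:
                    gene_rows.append((sp, gene, g))
            if rng.random() < config.unannotated_fraction:
                cat = UNANNOTATED
            else:
                cat = rng.choice(COG_CATEGORIES, p=p_core if is_core else p_acc)
            origin = rng.choice(["both", "a_specific", "b_specific"], p=origin_p)
            meta_rows.append((sp, gene, cat, origin))
            truth_rows.append((sp, gene, "core" if is_core else "accessory", freq))
    genes = pd.DataFrame(gene_rows, columns=["species_id", "gene_cluster_id", "genome_id"])
    gene_meta = pd.DataFrame(meta_rows, columns=["species_id", "gene_cluster_id", "category", "origin"])
    truth = pd.DataFrame(truth_rows, columns=["species_id", "gene_cluster_id", "true_partition", "true_frequency"])
    return genes, gene_meta, truth


# ---------------------------------------------------------------------------
# read classification fractions


def generate_classification_fractions(
    config: ScenarioConfig, sample_ids: list[str] | None = None, n_samples: int | None = None
) -> pd.DataFrame:
    """Per-sample classified-read fractions under a reference database and
    a custom (catalog-augmented) database. The custom fraction applies a
    configured relative uplift (median ``improvement_median_pct`` percent)
    with noise, truncated to [0, 1]."""
    rng = substream(config.seed, "classification")
    if sample_ids is None:
        if n_samples is None:
            raise ValueError("provide sample_ids or n_samples")
        sample_ids = [f"sample{i:04d}" for i in range(1, n_samples + 1)]
    n = len(sample_ids)
    ref = np.clip(
        rng.normal(config.reference_fraction_mean, config.reference_fraction_sd, size=n),
        0.2,
        0.95,
    )
    uplift_pct = rng.normal(config.improvement_median_pct, config.improvement_sd_pct, size=n)
    uplift_pct = np.maximum(uplift_pct, 0.0)
    custom = np.clip(ref * (1.0 + uplift_pct / 100.0), 0.0, 1.0)
    return pd.DataFrame(
        {"sample_id": sample_ids, "fraction_reference": ref.round(6), "fraction_custom": custom.round(6)}
    )


# ---------------------------------------------------------------------------
# whole-scenario convenience


@dataclass
class Scenario:
    config: ScenarioConfig
    pool: pd.DataFrame
    abundance: pd.DataFrame
    meta: pd.DataFrame
    genomes: pd.DataFrame
    ani: pd.DataFrame
    recovery_truth: dict
    transmission: dict
    genes: pd.DataFrame
    gene_meta: pd.DataFrame
    gene_truth: pd.DataFrame
    classified: pd.DataFrame


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate every table of one scenario."""
    pool = generate_species_pool(config)
    abundance, meta = generate_samples_and_abundances(config, pool)
    genomes, ani, recovery_truth = generate_genome_recoveries(config, abundance, meta, pool)
    transmission = generate_strain_transmission(config, pool)
    gene_input = genomes.rename(columns={"completeness_primary": "completeness"})[
        ["genome_id", "completeness"]
    ].assign(species_cluster_id=genomes["genome_id"].map(recovery_truth["genome_species"]))
    genes, gene_meta, gene_truth = generate_gene_matrix(config, gene_input)
    classified = generate_classification_fractions(config, sample_ids=meta["sample_id"].tolist())
    return Scenario(
        config=config,
        pool=pool,
        abundance=abundance,
        meta=meta,
        genomes=genomes,
        ani=ani,
        recovery_truth=recovery_truth,
        transmission=transmission,
        genes=genes,
        gene_meta=gene_meta,
        gene_truth=gene_truth,
        classified=classified,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write every scenario table to TSV (plus truth.json); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = scenario.transmission
    paths = {
        "species_pool": io.write_table(scenario.pool, outdir / "species_pool.tsv"),
        "abundance": io.write_matrix(scenario.abundance, outdir / "abundance.tsv"),
        "samples": io.write_table(scenario.meta, outdir / "samples.tsv"),
        "genomes": io.write_table(scenario.genomes, outdir / "genomes.tsv"),
        "ani": io.write_table(scenario.ani, outdir / "ani.tsv"),
        "snv": io.write_table(t["snvs"], outdir / "snv.tsv"),
        "pairs": io.write_table(t["pairs"], outdir / "pairs.tsv"),
        "st_profiles": io.write_table(t["st_profiles"], outdir / "st_profiles.tsv"),
        "scheme": io.write_table(t["scheme"].to_frame(), outdir / "scheme.tsv"),
        "genes": io.write_table(scenario.genes, outdir / "genes.tsv"),
        "gene_meta": io.write_table(scenario.gene_meta, outdir / "gene_meta.tsv"),
        "classified": io.write_table(scenario.classified, outdir / "classified.tsv"),
        "truth": io.write_json(
            {
                "config": asdict(scenario.config),
                "genome_species": scenario.recovery_truth["genome_species"],
                "genome_lineage": scenario.recovery_truth["genome_lineage"],
                "transmitted": t["truth"]["transmitted"],
                "lineage_of": t["truth"]["lineage_of"],
                "roles": t["roles"],
            },
            outdir / "truth.json",
        ),
    }
    return paths


# ---------------------------------------------------------------------------
# composition-conditioned synthetic replicas
#
# These helpers build synthetic quality tables and typing studies with a
# *specified* ground-truth composition (e.g. so many high-quality genomes,
# so many sharing families). They are used to exercise the decision logic
# at catalog scale when no real quality table is at hand: the construction
# samples metrics from each tier's defining region independently of the
# classifier, so recovering the composition is a genuine check of the
# tier predicates.


def generate_quality_table_for_tiers(
    composition: dict[str, int], kingdom: str = "prokaryote", seed: int = 0
) -> pd.DataFrame:
    """Synthetic quality table with a given ground-truth tier composition.

    ``composition`` maps tier labels (high_quality, near_complete,
    medium_quality, fail) to genome counts. Metrics are drawn uniformly
    from each tier's defining region: the draw never consults the tier
    classifier. A tenth of medium-quality prokaryotic genomes qualify only
    through the secondary estimator (the inclusive rule path).
    """
    rng = substream(seed, f"tier_replica_{kingdom}")
    rows = []
    counter = 0
    for tier, n in composition.items():
        for _ in range(int(n)):
            counter += 1
            row = {
                "genome_id": f"{kingdom[:3]}{counter:05d}",
                "sample_id": "synthetic",
                "kingdom": kingdom,
                "rrna_5s": True,
                "rrna_ssu": True,
                "rrna_lsu": True,
                "n_unique_trnas": int(rng.integers(18, 21)),
                "n_contigs": int(rng.integers(1, 300)),
                "n50": int(rng.lognormal(10.5, 0.8)),
                "mean_depth": float(round(rng.lognormal(3.0, 0.5), 2)),
                "strain_heterogeneity": float(round(rng.exponential(0.5), 3)),
                "gunc_contamination": 0.0,
                "gunc_css": 0.0,
                "gunc_rrs": 0.0,
            }
            if tier == "high_quality":
                comp = rng.uniform(90.01, 99.99)
                cont = rng.uniform(0.0, 4.99)
            elif tier == "near_complete":
                comp = rng.uniform(90.01, 99.99)
                cont = rng.uniform(0.0, 4.99)
                # break the rRNA/tRNA requirement in a random way
                miss = rng.integers(0, 4)
                if miss == 0:
                    row["n_unique_trnas"] = int(rng.integers(0, 18))
                else:
                    row[["rrna_5s", "rrna_ssu", "rrna_lsu"][miss - 1]] = False
            elif tier == "medium_quality":
                use_secondary = kingdom == "prokaryote" and rng.random() < 0.10
                comp = rng.uniform(55.0, 89.9)
                if kingdom == "prokaryote":
                    cont = rng.uniform(0.0, min(9.99, (comp - 50.0) / 5.0) * 0.99)
                else:
                    cont = rng.uniform(0.0, 9.99)
                if use_secondary:
                    row["completeness_secondary"] = round(comp, 2)
                    row["contamination_secondary"] = round(cont, 2)
                    comp = rng.uniform(30.0, 49.9)  # primary estimate fails
                    cont = rng.uniform(10.5, 15.0)
            elif tier == "fail":
                comp = rng.uniform(10.0, 49.9)
                cont = rng.uniform(0.0, 15.0)
            else:
                raise ValueError(f"unknown tier {tier!r}")
            row["completeness_primary"] = round(comp, 2)
            row["contamination_primary"] = round(cont, 2)
            row.setdefault("completeness_secondary", round(float(np.clip(comp + rng.normal(0, 1.0), 0, 100)), 2))
            row.setdefault("contamination_secondary", round(float(np.clip(cont + rng.normal(0, 0.5), 0, 100)), 2))
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(seed) % (2**32)).reset_index(drop=True)


def generate_viral_completeness(composition: dict[str, int], seed: int = 0) -> pd.DataFrame:
    """Synthetic viral-sequence completeness values with a given
    ground-truth tier composition (complete / high_quality /
    medium_quality / low_quality)."""
    rng = substream(seed, "viral_replica")
    ranges = {
        "complete": (100.0, 100.0),
        "high_quality": (90.01, 99.99),
        "medium_quality": (50.01, 90.0),
        "low_quality": (0.0, 49.99),
    }
    rows = []
    counter = 0
    for tier, n in composition.items():
        lo, hi = ranges[tier]
        for _ in range(int(n)):
            counter += 1
            v = 100.0 if tier == "complete" else rng.uniform(lo, hi)
            rows.append({"sequence_id": f"v{counter:03d}", "completeness": round(v, 2)})
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(seed) % (2**32)).reset_index(drop=True)


def generate_st_study(
    n_families: int = 6,
    n_sharing: int = 4,
    seed: int = 0,
    n_isolates_range: tuple[int, int] = (4, 12),
) -> tuple[pd.DataFrame, "MLSTScheme"]:
    """Synthetic six-family culturing study for the ST-sharing test.

    The first ``n_sharing`` families share exactly one sequence type
    between infant and mother (and with no other family); the remaining
    families' infants and mothers carry disjoint, family-unique STs.
    Isolate counts per individual are drawn from ``n_isolates_range``.
    Returns the per-isolate allele table and its typing scheme.
    """
    from .sharing import MLSTScheme

    if n_sharing > n_families:
        raise ValueError("n_sharing cannot exceed n_families")
    rng = substream(seed, "st_study")
    loci = tuple(f"locus{i}" for i in range(1, 8))
    scheme = MLSTScheme(loci=loci)
    profiles: list[tuple[int, ...]] = []

    def fresh_profile() -> tuple[int, ...]:
        while True:
            prof = tuple(int(a) for a in rng.integers(1, 51, size=7))
            if prof not in profiles:
                profiles.append(prof)
                scheme.profiles[prof] = f"ST{len(profiles)}"
                return prof

    rows = []
    lo, hi = n_isolates_range
    for f in range(1, n_families + 1):
        fam = f"F{f}"
        shared = fresh_profile() if f <= n_sharing else None
        for role in ("infant", "mother"):
            own = fresh_profile()
            carried = [own] if shared is None else [shared, own]
            ind = f"{fam}_{role[0].upper()}"
            n_iso = int(rng.integers(lo, hi + 1))
            got_shared = False
            for k in range(1, n_iso + 1):
                prof = carried[rng.integers(0, len(carried))]
                if shared is not None and k == n_iso and not got_shared:
                    prof = shared  # guarantee the shared ST is observed
                if prof == shared:
                    got_shared = True
                rows.append(
                    {
                        "individual_id": ind,
                        "family_id": fam,
                        "role": role,
                        "isolate_id": f"{ind}_iso{k:02d}",
                        **dict(zip(loci, prof)),
                    }
                )
    return pd.DataFrame(rows), scheme
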