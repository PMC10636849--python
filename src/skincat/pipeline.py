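"""End-to-end orchestration of the catalog pipeline.

Runs the stages in dependency order — quality control, dereplication,
catalog statistics, community analysis, pan-genome enrichment and
strain-sharing — from a single config, writing every stage output as TSV
or JSON plus a manifest with seeds and input checksums. Reruns with an
identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import catalog_stats, community, derep, io, pangenome, qc, sharing

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Input paths, thresholds and seeds for a full pipeline run."""

    outdir: str
    genomes: str
    ani: str
    abundance: str
    samples: str
    classified: str | None = None
    snv: str | None = None
    pairs: str | None = None
    st_profiles: str | None = None
    scheme: str | None = None
    genes: str | None = None
    gene_meta: str | None = None
    species_pool: str | None = None
    seed: int = 0
    # thresholds (documented defaults; see the stage modules)
    redundancy_ani: float = 99.9
    species_ani: float = 95.0
    species_min_cov: float = 0.30
    min_reads: int = 800_000
    prevalence_cut: float = 0.20
    core_threshold: float = 0.90
    min_genomes_pangenome: int = 10
    min_genomes_snv: int = 10
    min_related_pairs: int = 4
    n_perm_st: int = 1000
    n_perm_rarefaction: int = 10
    gunc_rule: str = "all"
    representative_length: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "inputs": {}, "outputs": {}}

    def record_input(name, path):
        if path is not None:
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"stage input missing for {name!r}: {path}")
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
            return p
        return None

    def save(name, df_or_obj, filename):
        path = out / filename
        if isinstance(df_or_obj, pd.DataFrame):
            if filename.endswith(".tsv"):
                (io.write_matrix if df_or_obj.index.name else io.write_table)(df_or_obj, path)
            else:
                raise ValueError(filename)
        else:
            io.write_json(df_or_obj, path)
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # --- stage: qc
    genomes_path = record_input("genomes", config.genomes)
    genomes = io.read_table(genomes_path, schema="genomes")
    tiers = qc.assign_tiers(genomes, gunc_rule=config.gunc_rule)
    save("tiers", tiers, "tiers.tsv")
    kept = tiers[(tiers["tier"] != "fail") & tiers["passed_chimera_filter"]]

    # --- stage: derep
    ani_path = record_input("ani", config.ani)
    edges = io.read_table(ani_path, schema="ani")
    qc_genomes = genomes[genomes["genome_id"].isin(kept["genome_id"])]
    kept_ids = set(qc_genomes["genome_id"])
    edges = edges[edges["genome_a"].isin(kept_ids) & edges["genome_b"].isin(kept_ids)]
    result = derep.dereplicate_catalog(
        qc_genomes,
        edges,
        redundancy_ani=config.redundancy_ani,
        species_ani=config.species_ani,
        species_min_cov=config.species_min_cov,
    )
    clusters = result.to_frame()
    save("clusters", clusters, "clusters.tsv")

    # --- stage: catalog stats
    sample_of = genomes.set_index("genome_id")["sample_id"]
    genome_species = clusters[clusters["nonredundant"]][
        ["genome_id", "species_cluster_id"]
    ].assign(sample_id=lambda d: d["genome_id"].map(sample_of))
    curve = catalog_stats.rarefaction_curve(
        genome_species,
        n_perm=config.n_perm_rarefaction,
        seed=config.seed,
        exclude_singletons="by_sample",
    )
    save("rarefaction", curve, "rarefaction.tsv")
    if config.classified:
        frac = io.read_table(record_input("classified", config.classified), schema="classified")
        per_sample, summary = catalog_stats.classification_improvement(frac)
        save("improvement", per_sample, "improvement.tsv")
        save("improvement_summary", summary, "improvement_summary.json")

    # --- stage: community
    abundance = io.read_matrix(record_input("abundance", config.abundance))
    meta = io.read_table(record_input("samples", config.samples), schema="samples")
    rarefied = community.filter_low_depth_and_rarefy(
        abundance, min_reads=config.min_reads, seed=config.seed
    )
    alpha = community.alpha_diversity(rarefied)
    save("alpha", alpha, "alpha.tsv")
    dm = community.transform_and_distance(rarefied, prevalence_cut=config.prevalence_cut)
    save("braycurtis", dm.rename_axis("sample_id"), "braycurtis.tsv")
    coords, explained = community.pcoa(dm)
    save("pcoa", coords.rename_axis("sample_id"), "pcoa.tsv")
    dyads = community.dyad_dissimilarity_test(dm, meta)
    save(
        "dyads",
        {k: v for k, v in dyads.items() if k not in ("related", "unrelated")},
        "dyads.json",
    )

    # --- stage: pangenome
    if config.genes and config.gene_meta:
        genes = io.read_table(record_input("genes", config.genes), schema="genes")
        gene_meta = io.read_table(record_input("gene_meta", config.gene_meta), schema="gene_meta")
        eligible = pangenome.eligible_species(
            tiers, clusters, min_genomes=config.min_genomes_pangenome
        )
        species_map = clusters.set_index("genome_id")["species_cluster_id"]
        per_species = {}
        for sp in eligible:
            members = set(species_map[species_map == sp].index)
            sub = genes[genes["genome_id"].isin(members)]
            if sub.empty:
                continue
            freq = pangenome.gene_frequencies(sub)
            labels = pangenome.partition_core_accessory(freq, config.core_threshold)
            cats = (
                gene_meta.set_index("gene_cluster_id")["category"].reindex(labels.index).dropna()
            )
            per_species[sp] = (labels.loc[cats.index], cats)
        enrichment = pangenome.category_enrichment(per_species)
        save("enrichment", enrichment, "enrichment.tsv")

    # --- stage: sharing
    if config.snv:
        snvs = io.read_table(record_input("snv", config.snv), schema="snv")
        rep_len = {
            sp: int(config.representative_length.get(sp, 0)) or int(snvs["position"].max())
            for sp in snvs["species_id"].unique()
        }
        density = sharing.species_snv_density(snvs, rep_len, min_genomes=config.min_genomes_snv)
        save("snv_density", density, "snv_density.tsv")
        if config.pairs:
            pair_meta = io.read_table(record_input("pairs", config.pairs))
            counts = sharing.pairwise_snv_counts(snvs, pair_meta)
            save("snv_pairs", counts, "snv_pairs.tsv")
            tests = sharing.related_vs_unrelated_snv_test(
                counts, min_pairs=config.min_related_pairs
            )
            save("snv_tests", tests, "snv_tests.tsv")
    if config.st_profiles and config.scheme:
        prof_df = io.read_table(record_input("st_profiles", config.st_profiles))
        scheme = sharing.MLSTScheme.from_frame(
            io.read_table(record_input("scheme", config.scheme))
        )
        profiles = sharing.profiles_from_frame(prof_df, scheme)
        observed = sharing.st_sharing_stat(profiles)
        n_fam = len({p.family_id for p in profiles})
        test = sharing.st_permutation_test(
            profiles,
            n_perm=config.n_perm_st,
            seed=config.seed,
            mode="exact" if n_fam <= 8 else "monte_carlo",
        )
        test.pop("null", None)
        save("st_test", {"observed_sharing_families": observed, **test}, "st_test.json")

    io.write_json(manifest, out / "manifest.json")
    return manifest


def report(outdir: str | Path) -> str:
    """Render a human-readable markdown summary from a pipeline output
    directory; numbers are read back from the stage outputs."""
    out = Path(outdir)
    if not (out / "manifest.json").exists():
        raise FileNotFoundError(f"no pipeline manifest under {out}")
    lines = ["# Catalog pipeline summary", ""]
    tiers = io.read_table(out / "tiers.tsv")
    summary = qc.tier_summary(tiers)
    lines.append("## Genome quality tiers")
    for r in summary.itertuples(index=False):
        lines.append(f"- {r.kingdom} {r.tier}: {r.n}")
    clusters = io.read_table(out / "clusters.tsv", schema="clusters")
    n_species = clusters["species_cluster_id"].nunique()
    n_nonred = int(clusters["nonredundant"].sum())
    lines += [
        "",
        "## Catalog",
        f"- nonredundant genomes: {n_nonred}",
        f"- species-level clusters: {n_species}",
    ]
    if (out / "improvement_summary.json").exists():
        s = io.read_json(out / "improvement_summary.json")
        lines += [
            "",
            "## Read classification (stochastic)",
            f"- median improvement: {s['median']:.1f}% (IQR {s['q1']:.1f}-{s['q3']:.1f}) over {s['n']} samples",
        ]
    if (out / "dyads.json").exists():
        d = io.read_json(out / "dyads.json")
        lines += [
            "",
            "## Mother-infant community dyads (stochastic)",
            f"- median Bray-Curtis related {d['median_related']:.3f} vs unrelated "
            f"{d['median_unrelated']:.3f} (p = {d['p_value']:.2e}, n = {d['n_dyads']})",
        ]
    if (out / "snv_tests.tsv").exists():
        t = io.read_table(out / "snv_tests.tsv")
        sig = int((t["p_value"] < 0.01).sum())
        lines += [
            "",
            "## Strain-level SNV sharing (stochastic)",
            f"- species tested: {len(t)}; related < unrelated at p < 0.01: {sig}",
        ]
    if (out / "st_test.json").exists():
        s = io.read_json(out / "st_test.json")
        lines += [
            "",
            "## Sequence-type sharing",
            f"- families sharing >= 1 ST: {s['observed_sharing_families']} of {s['n_families']}"
            f" (p = {s['p_value']:.4f}, {s['mode']})",
        ]
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
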