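"""Generator structure, determinism and statistical oracles."""

import numpy as np
import pandas as pd
import pytest

from skincat import io, sharing
from skincat.synthetic import (
    ScenarioConfig,
    generate_classification_fractions,
    generate_genome_recoveries,
    generate_quality_table_for_tiers,
    generate_samples_and_abundances,
    generate_scenario,
    generate_species_pool,
    generate_st_study,
    generate_strain_transmission,
    generate_viral_completeness,
    write_scenario,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_species=1)
        with pytest.raises(ValueError):
            ScenarioConfig(sharing_prob=1.5)
        with pytest.raises(ValueError):
            ScenarioConfig(divergence_time_related=100, divergence_time_unrelated=10)


class TestSpeciesPool:
    def test_reproducible_under_seed(self):
        c = ScenarioConfig(n_species=10, seed=1)
        pd.testing.assert_frame_equal(generate_species_pool(c), generate_species_pool(c))

    def test_different_seeds_differ(self):
        a = generate_species_pool(ScenarioConfig(n_species=10, seed=1))
        b = generate_species_pool(ScenarioConfig(n_species=10, seed=2))
        assert not a["mean_abundance"].equals(b["mean_abundance"])

    def test_degenerate_kingdom_mixture(self):
        pool = generate_species_pool(
            ScenarioConfig(n_species=12, kingdom_props=(1.0, 0.0, 0.0), seed=3)
        )
        assert (pool["kingdom"] == "bacteria").all()

    def test_ranges(self):
        pool = generate_species_pool(ScenarioConfig(n_species=50, seed=4))
        assert ((pool["prevalence"] > 0) & (pool["prevalence"] <= 1)).all()
        assert (pool["genome_size"] > 0).all()
        assert pool["mean_abundance"].sum() == pytest.approx(1.0, abs=1e-9)


class TestSamplesAndAbundances:
    def test_design_arithmetic(self):
        c = ScenarioConfig(n_families=5, n_species=6, seed=5)
        pool = generate_species_pool(c)
        abundance, meta = generate_samples_and_abundances(c, pool)
        mothers = meta[meta["role"] == "mother"]
        infants = meta[meta["role"] == "infant"]
        assert len(mothers) == 5
        assert len(infants) <= 20
        assert (mothers["site"] == "antecubital").all()
        assert (abundance.to_numpy() >= 0).all()
        assert abundance.to_numpy().dtype.kind == "i"

    def test_null_relatedness_no_dyad_signal(self):
        """With all effects off, related and unrelated dyad Bray-Curtis
        agree on average over replicates (Monte-Carlo null check)."""
        from skincat import community

        diffs = []
        for seed in range(30):
            c = ScenarioConfig(
                n_families=8,
                n_species=10,
                relatedness_correlation=0.0,
                site_effect=0.0,
                age_effect=0.0,
                seed=seed,
            )
            pool = generate_species_pool(c)
            abundance, meta = generate_samples_and_abundances(c, pool)
            rarefied = community.filter_low_depth_and_rarefy(abundance, min_reads=1, seed=seed)
            d = community.transform_and_distance(rarefied, prevalence_cut=0.0)
            out = community.dyad_dissimilarity_test(d, meta)
            diffs.append(np.mean(out["related"]) - np.mean(out["unrelated"]))
        assert abs(np.mean(diffs)) < 0.02

    def test_high_relatedness_shrinks_dyad_distance(self):
        from skincat import community

        medians = {0.0: [], 0.9: []}
        for rho in medians:
            for seed in range(10):
                c = ScenarioConfig(
                    n_families=10,
                    n_species=10,
                    relatedness_correlation=rho,
                    site_effect=0.0,
                    age_effect=0.0,
                    seed=100 + seed,
                )
                pool = generate_species_pool(c)
                abundance, meta = generate_samples_and_abundances(c, pool)
                rarefied = community.filter_low_depth_and_rarefy(abundance, min_reads=1, seed=seed)
                d = community.transform_and_distance(rarefied, prevalence_cut=0.0)
                out = community.dyad_dissimilarity_test(d, meta)
                medians[rho].append(out["median_related"] - out["median_unrelated"])
        assert np.median(medians[0.9]) < np.median(medians[0.0])
        assert np.median(medians[0.9]) < 0


class TestGenomeRecoveries:
    def test_clean_ani_structure_separates_species(self, small_scenario):
        truth = small_scenario.recovery_truth
        edges = small_scenario.ani
        species = truth["genome_species"]
        within = edges.apply(
            lambda r: species[r["genome_a"]] == species[r["genome_b"]], axis=1
        )
        assert (edges.loc[within, "ani"] >= 95).all()
        assert (edges.loc[~within, "ani"] < 95).all()
        assert (edges.loc[within, "aligned_fraction"] >= 0.30).all()

    def test_duplicates_above_999(self, small_scenario):
        truth = small_scenario.recovery_truth
        lineage = truth["genome_lineage"]
        edges = small_scenario.ani
        dup = edges.apply(
            lambda r: lineage[r["genome_a"]] == lineage[r["genome_b"]], axis=1
        )
        assert (edges.loc[dup, "ani"] >= 99.9).all()

    def test_no_contamination_no_failures(self):
        c = ScenarioConfig(
            n_families=4, n_species=5, contamination_mean=1e-9, seed=6
        )
        pool = generate_species_pool(c)
        abundance, meta = generate_samples_and_abundances(c, pool)
        genomes, _, _ = generate_genome_recoveries(c, abundance, meta, pool)
        assert (genomes["contamination_primary"] < 0.01).all()


class TestStrainTransmission:
    def test_full_transmission_zero_divergence_zero_snv_distance(self):
        c = ScenarioConfig(
            n_families=6,
            n_species=6,
            sharing_prob=1.0,
            divergence_time_related=0.0,
            n_transmission_species=2,
            genome_length=10_000,
            seed=7,
        )
        pool = generate_species_pool(c)
        t = generate_strain_transmission(c, pool)
        counts = sharing.pairwise_snv_counts(t["snvs"], t["pairs"])
        related = counts[counts["relationship"] == "related_pair"]
        assert len(related) > 0
        assert (related["n_snvs"] == 0).all()

    def test_poisson_pairwise_expectation(self):
        """Mean pairwise SNV count matches 2 * mu * t * L within 10%."""
        c = ScenarioConfig(
            n_families=30,
            n_species=4,
            sharing_prob=1.0,  # every related pair diverged for exactly t
            mutation_rate=1e-6,
            divergence_time_related=1000.0,
            divergence_time_unrelated=1000.0,
            n_transmission_species=2,
            genome_length=1_000_000,
            seed=8,
        )
        pool = generate_species_pool(c)
        t = generate_strain_transmission(c, pool)
        counts = sharing.pairwise_snv_counts(t["snvs"], t["pairs"])
        related = counts[counts["relationship"] == "related_pair"]["n_snvs"]
        assert len(related) >= 20
        expected = 2 * 1e-6 * 1000.0 * 1_000_000
        assert related.mean() == pytest.approx(expected, rel=0.10)

    def test_saturation_warns(self):
        c = ScenarioConfig(
            n_families=2,
            n_species=3,
            mutation_rate=1e-2,
            divergence_time_unrelated=1000.0,
            n_transmission_species=1,
            genome_length=2_000,
            seed=9,
        )
        pool = generate_species_pool(c)
        with pytest.warns(UserWarning, match="saturating"):
            generate_strain_transmission(c, pool)

    def test_st_inheritance_follows_transmission(self, small_scenario):
        """Infant and mother share a sequence type exactly when the focal
        species' strain was transmitted (the primary strain is always
        cultured; extra strains are individual-specific)."""
        t = small_scenario.transmission
        profiles = sharing.profiles_from_frame(t["st_profiles"], t["scheme"])
        by_fam = {}
        for p in profiles:
            by_fam.setdefault(p.family_id, {})[p.role] = p.st_set
        sp = t["st_profiles"]["species_id"].iloc[0]
        checked = 0
        for fam, members in by_fam.items():
            if "infant" not in members or "mother" not in members:
                continue
            transmitted = t["truth"]["transmitted"][f"{sp}|{fam}"]
            shared = bool(members["infant"] & members["mother"])
            assert shared == transmitted, fam
            checked += 1
        assert checked >= 2

    def test_sequences_match_snv_table(self, small_scenario):
        from skincat.synthetic import sequences_from_snvs

        t = small_scenario.transmission
        sp = next(iter(t["references"]))
        ref = t["references"][sp]
        sub = t["snvs"][t["snvs"]["species_id"] == sp]
        gid = sub["genome_id"].iloc[0]
        seq = sequences_from_snvs(ref, sub, gid)
        calls = sharing.call_snvs_aligned(ref, seq)
        expected = sub[sub["genome_id"] == gid]
        assert len(calls) == len(expected)


class TestClassificationFractions:
    def test_zero_uplift_zero_improvement(self):
        c = ScenarioConfig(improvement_median_pct=0.0, improvement_sd_pct=0.0, seed=10)
        df = generate_classification_fractions(c, n_samples=20)
        assert (df["fraction_custom"] == df["fraction_reference"]).all()

    def test_fractions_in_range(self):
        df = generate_classification_fractions(ScenarioConfig(seed=11), n_samples=500)
        for col in ("fraction_reference", "fraction_custom"):
            assert ((df[col] >= 0) & (df[col] <= 1)).all()
        assert (df["fraction_custom"] >= df["fraction_reference"]).all()


class TestDeterminismAndRoundTrip:
    def test_full_scenario_deterministic(self, small_config, small_scenario, tmp_path):
        again = generate_scenario(small_config)
        pd.testing.assert_frame_equal(small_scenario.genomes, again.genomes)
        pd.testing.assert_frame_equal(small_scenario.abundance, again.abundance)
        pd.testing.assert_frame_equal(
            small_scenario.transmission["snvs"], again.transmission["snvs"]
        )
        pd.testing.assert_frame_equal(small_scenario.genes, again.genes)

    def test_tables_round_trip_through_tsv(self, small_scenario, tmp_path):
        paths = write_scenario(small_scenario, tmp_path)
        genomes = io.read_table(paths["genomes"], schema="genomes")
        pd.testing.assert_frame_equal(
            genomes, small_scenario.genomes, check_dtype=False
        )
        ani = io.read_table(paths["ani"], schema="ani")
        pd.testing.assert_frame_equal(ani, small_scenario.ani, check_dtype=False)
        abundance = io.read_matrix(paths["abundance"])
        pd.testing.assert_frame_equal(abundance, small_scenario.abundance, check_dtype=False)
        snv = io.read_table(paths["snv"], schema="snv")
        pd.testing.assert_frame_equal(
            snv, small_scenario.transmission["snvs"], check_dtype=False
        )


class TestCompositionReplicas:
    def test_tier_replica_counts_recovered(self):
        """The tier classifier recovers the constructed ground-truth
        composition of a synthetic quality table."""
        from skincat import qc

        composition = {"high_quality": 40, "near_complete": 60, "medium_quality": 80, "fail": 20}
        df = generate_quality_table_for_tiers(composition, seed=12)
        tiers = qc.assign_tiers(df)
        counts = tiers["tier"].value_counts().to_dict()
        assert counts == composition

    def test_viral_replica_counts_recovered(self):
        from skincat import qc

        composition = {"complete": 9, "high_quality": 20, "medium_quality": 8, "low_quality": 2}
        df = generate_viral_completeness(composition, seed=13)
        tiers = df["completeness"].map(qc.assign_viral_tier)
        assert tiers.value_counts().to_dict() == composition

    def test_st_study_structure(self):
        df, scheme = generate_st_study(n_families=6, n_sharing=4, seed=14)
        profiles = sharing.profiles_from_frame(df, scheme)
        assert sharing.st_sharing_stat(profiles) == 4
        iso_counts = df.groupby("individual_id").size()
        assert iso_counts.between(4, 12).all()
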