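"""SNV calling/density, related-vs-unrelated comparisons and MLST sharing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from skincat import sharing
from skincat.sharing import MLSTScheme, STProfile


class TestCallSNVs:
    def test_identical_sequences(self):
        assert sharing.call_snvs_aligned("ACGT", "ACGT") == []

    def test_single_substitution_one_based(self):
        assert sharing.call_snvs_aligned("ACGT", "ACTT") == [(3, "G", "T")]

    def test_n_positions_skipped(self):
        assert sharing.call_snvs_aligned("ANGT", "ATGT") == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sharing.call_snvs_aligned("ACG", "ACGT")

    def test_planted_substitutions_recovered_exactly(self):
        rng = np.random.default_rng(0)
        L, k = 5000, 37
        ref = "".join(rng.choice(list("ACGT"), L))
        pos = rng.choice(L, size=k, replace=False)
        mutated = list(ref)
        for p in pos:
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        calls = sharing.call_snvs_aligned(ref, "".join(mutated))
        assert len(calls) == k
        assert sorted(c[0] - 1 for c in calls) == sorted(pos)


def snv_frame(rows):
    return pd.DataFrame(rows, columns=["species_id", "genome_id", "position", "ref", "alt"])


class TestSNVDensity:
    def test_no_snvs_zero_density(self):
        # genomes present but identical to the representative: empty table
        # contributes no species (nothing to group), so build one shared SNV
        rows = [("sp1", f"g{i}", 1, "A", "C") for i in range(10)]
        out = sharing.species_snv_density(snv_frame(rows), {"sp1": 1000})
        assert out.iloc[0]["snv_density_per_kb"] == pytest.approx(1.0)

    def test_density_arithmetic(self):
        """10 genomes sharing the same 50 SNVs, representative 1 Mb:
        0.05 per kb for every genome and the species."""
        rows = [
            ("sp1", f"g{i}", p, "A", "G") for i in range(10) for p in range(1, 51)
        ]
        out = sharing.species_snv_density(snv_frame(rows), {"sp1": 1_000_000})
        assert out.iloc[0]["snv_density_per_kb"] == pytest.approx(0.05)

    def test_private_snvs_do_not_count(self):
        # one genome with 100 private SNVs plus a backbone of shared ones
        shared = [("sp1", f"g{i}", p, "A", "G") for i in range(10) for p in range(1, 11)]
        private = [("sp1", "g0", p, "A", "T") for p in range(1000, 1100)]
        with_private = sharing.species_snv_density(
            snv_frame(shared + private), {"sp1": 100_000}
        )
        without = sharing.species_snv_density(snv_frame(shared), {"sp1": 100_000})
        assert with_private.iloc[0]["snv_density_per_kb"] == pytest.approx(
            without.iloc[0]["snv_density_per_kb"]
        )

    def test_min_genomes_gate(self):
        rows = [("sp1", f"g{i}", 1, "A", "C") for i in range(9)]
        out = sharing.species_snv_density(snv_frame(rows), {"sp1": 1000})
        assert out.empty

    def test_invariant_to_row_order_and_relabeling(self):
        rng = np.random.default_rng(1)
        rows = [
            ("sp1", f"g{rng.integers(0, 12)}", int(rng.integers(1, 500)), "A", "G")
            for _ in range(300)
        ]
        df = snv_frame(rows).drop_duplicates()
        a = sharing.species_snv_density(df, {"sp1": 10_000})
        b = sharing.species_snv_density(df.sample(frac=1, random_state=2), {"sp1": 10_000})
        assert a.iloc[0]["snv_density_per_kb"] == pytest.approx(b.iloc[0]["snv_density_per_kb"])
        relabeled = df.assign(genome_id=df["genome_id"].str.replace("g", "genome"))
        c = sharing.species_snv_density(relabeled, {"sp1": 10_000})
        assert a.iloc[0]["snv_density_per_kb"] == pytest.approx(c.iloc[0]["snv_density_per_kb"])


class TestPairwiseAndTest:
    def test_pairwise_counts_symmetric_difference(self):
        snvs = snv_frame(
            [("sp1", "a", 1, "A", "C"), ("sp1", "a", 2, "A", "C"), ("sp1", "b", 2, "A", "C"), ("sp1", "b", 3, "A", "C")]
        )
        pairs = pd.DataFrame(
            [("sp1", "a", "b", "related_pair")],
            columns=["species_id", "genome_a", "genome_b", "relationship"],
        )
        out = sharing.pairwise_snv_counts(snvs, pairs)
        assert out.iloc[0]["n_snvs"] == 2  # positions 1 and 3

    def test_perfect_separation(self):
        rows = []
        for i in range(5):
            rows.append(("sp1", f"i{i}", f"m{i}", "related_pair", 0))
            for j in range(5):
                if j != i:
                    rows.append(("sp1", f"i{i}", f"m{j}", "unrelated_pair", 1000 + i + j))
        pairs = pd.DataFrame(
            rows, columns=["species_id", "genome_a", "genome_b", "relationship", "n_snvs"]
        )
        out = sharing.related_vs_unrelated_snv_test(pairs)
        assert out.iloc[0]["median_related"] < out.iloc[0]["median_unrelated"]
        assert out.iloc[0]["p_value"] < 0.01

    def test_min_pairs_gate(self):
        pairs = pd.DataFrame(
            [("sp1", "a", "b", "related_pair", 0)] * 3
            + [("sp1", "a", "c", "unrelated_pair", 5)] * 3,
            columns=["species_id", "genome_a", "genome_b", "relationship", "n_snvs"],
        )
        assert sharing.related_vs_unrelated_snv_test(pairs).empty


class TestSourcePartition:
    def test_all_shared(self):
        snvs = snv_frame([("sp1", "i1", 1, "A", "C"), ("sp1", "m1", 1, "A", "C")])
        out = sharing.snv_source_partition(snvs, {"i1": "infant", "m1": "mother"})
        props = out.set_index("class")["proportion"]
        assert props["shared"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        rows = [
            ("sp1", f"g{rng.integers(0, 8)}", int(rng.integers(1, 50)), "A", "G")
            for _ in range(200)
        ]
        snvs = snv_frame(rows).drop_duplicates()
        roles = {f"g{i}": ("infant" if i < 4 else "mother") for i in range(8)}
        out = sharing.snv_source_partition(snvs, roles)
        assert out["proportion"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_unlabeled_genome_rejected(self):
        snvs = snv_frame([("sp1", "gX", 1, "A", "C")])
        with pytest.raises(ValueError):
            sharing.snv_source_partition(snvs, {})


class TestMLST:
    def scheme(self):
        loci = tuple(f"l{i}" for i in range(7))
        s = MLSTScheme(loci=loci)
        s.profiles[(1, 1, 1, 1, 1, 1, 1)] = "ST1"
        s.profiles[(1, 1, 1, 1, 1, 1, 2)] = "ST2"
        return s

    def test_exact_lookup(self):
        st, dist = sharing.assign_sequence_type([1] * 7, self.scheme())
        assert (st, dist) == ("ST1", 0)

    def test_novel_with_distance(self):
        st, dist = sharing.assign_sequence_type([1, 1, 1, 1, 1, 2, 2], self.scheme())
        assert st == "novel"
        assert dist == 1

    def test_wrong_locus_count_rejected(self):
        with pytest.raises(ValueError):
            sharing.assign_sequence_type([1, 2, 3], self.scheme())

    def test_lookup_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        loci = tuple(f"l{i}" for i in range(7))
        s = MLSTScheme(loci=loci)
        profiles = {tuple(rng.integers(1, 5, 7)) for _ in range(40)}
        for i, p in enumerate(sorted(profiles)):
            s.profiles[p] = f"ST{i}"
        for _ in range(200):
            q = tuple(rng.integers(1, 5, 7))
            st, dist = sharing.assign_sequence_type(q, s)
            brute = min(sum(a != b for a, b in zip(q, p)) for p in s.profiles)
            if q in s.profiles:
                assert st == s.profiles[q] and dist == 0
            else:
                assert st == "novel" and dist == brute

    def test_scheme_round_trip(self):
        s = self.scheme()
        again = MLSTScheme.from_frame(s.to_frame())
        assert again.profiles == s.profiles


def make_profiles(st_sets):
    """st_sets: list of (infant_set, mother_set) per family."""
    out = []
    for i, (inf, mom) in enumerate(st_sets, 1):
        out.append(STProfile(f"F{i}_I", f"F{i}", "infant", frozenset(inf)))
        out.append(STProfile(f"F{i}_M", f"F{i}", "mother", frozenset(mom)))
    return out


class TestSTSharing:
    def test_disjoint_sets_zero(self):
        profiles = make_profiles([({"a"}, {"b"}), ({"c"}, {"d"})])
        assert sharing.st_sharing_stat(profiles) == 0

    def test_identical_sets_all(self):
        profiles = make_profiles([({"a"}, {"a"}), ({"b", "c"}, {"c"})])
        assert sharing.st_sharing_stat(profiles) == 2

    def test_matches_brute_force_intersections(self):
        rng = np.random.default_rng(5)
        universe = [f"ST{i}" for i in range(10)]
        for _ in range(30):
            fams = [
                (
                    set(rng.choice(universe, rng.integers(1, 4), replace=False)),
                    set(rng.choice(universe, rng.integers(1, 4), replace=False)),
                )
                for _ in range(6)
            ]
            profiles = make_profiles(fams)
            brute = sum(1 for i, m in fams if i & m)
            assert sharing.st_sharing_stat(profiles) == brute


class TestSTPermutationTest:
    def test_universal_st_gives_p_one(self):
        profiles = make_profiles([({"u"}, {"u"})] * 4)
        out = sharing.st_permutation_test(profiles, mode="exact")
        assert out["p_value"] == pytest.approx(1.0)

    def test_unique_true_pairings_exact_tail(self):
        """Six families where only true pairings share: the only
        permutation reaching the observed statistic is the identity, so the
        exact p is 1/720."""
        profiles = make_profiles([({f"st{i}"}, {f"st{i}"}) for i in range(6)])
        out = sharing.st_permutation_test(profiles, mode="exact")
        assert out["observed"] == 6
        assert out["p_value"] == pytest.approx(1 / math.factorial(6))

    def test_exact_tail_matches_direct_enumeration(self):
        # 4 of 6 families share; enumerate the null by hand
        st_sets = [({f"s{i}"}, {f"s{i}"}) for i in range(4)] + [
            ({"x1"}, {"y1"}),
            ({"x2"}, {"y2"}),
        ]
        profiles = make_profiles(st_sets)
        infants = [i for i, _ in st_sets]
        mothers = [m for _, m in st_sets]
        observed = 4
        tail = sum(
            1
            for perm in itertools.permutations(range(6))
            if sum(1 for a, b in enumerate(perm) if infants[a] & mothers[b]) >= observed
        )
        out = sharing.st_permutation_test(profiles, mode="exact")
        assert out["observed"] == observed
        assert out["p_value"] == pytest.approx(tail / math.factorial(6))
        assert tail == 2  # only permutations fixing all four sharing families

    def test_monte_carlo_close_to_exact(self):
        """Monte-Carlo p (n=1000, add-one corrected) within binomial error
        of the exact tail in >= 95% of seeds."""
        st_sets = [({f"s{i}"}, {f"s{i}"}) for i in range(3)] + [
            ({"x"}, {"y"}),
            ({"z"}, {"w"}),
            ({"q"}, {"r"}),
        ]
        profiles = make_profiles(st_sets)
        exact = sharing.st_permutation_test(profiles, mode="exact")["p_value"]
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            mc = sharing.st_permutation_test(profiles, n_perm=1000, seed=seed)["p_value"]
            hits += abs(mc - exact) <= 0.03
        assert hits / n_seeds >= 0.95

    def test_p_value_bounds(self):
        profiles = make_profiles([({"a"}, {"a"}), ({"b"}, {"c"})])
        mc = sharing.st_permutation_test(profiles, n_perm=99, seed=1)
        assert 1 / 100 <= mc["p_value"] <= 1.0
        ex = sharing.st_permutation_test(profiles, mode="exact")
        assert 0 < ex["p_value"] <= 1.0

    def test_incomplete_family_excluded(self):
        profiles = make_profiles([({"a"}, {"a"}), ({"b"}, {"b"})])
        profiles.append(STProfile("F9_I", "F9", "infant", frozenset({"zz"})))
        assert sharing.st_sharing_stat(profiles) == 2

    def test_bad_nperm_rejected(self):
        with pytest.raises(ValueError):
            sharing.st_permutation_test(make_profiles([({"a"}, {"a"})] * 3), n_perm=0)


class TestSharingFractionEstimator:
    def test_perfectly_separated(self):
        pairs = pd.DataFrame(
            {
                "relationship": ["related_pair"] * 10 + ["unrelated_pair"] * 100,
                "n_snvs": [5] * 6 + [2500] * 4 + list(np.random.default_rng(6).normal(2500, 50, 100).astype(int)),
            }
        )
        est = sharing.estimate_sharing_fraction(pairs)
        assert est == pytest.approx(0.6)
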