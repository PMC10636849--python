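# Methods

This note documents the models behind `skincat`, the defaults that
matter, and the limits of what the synthetic benchmarks demonstrate.

## Decision rules

All quality thresholds are applied with strict inequalities exactly as
conventionally printed (">90%", "<5%", ">50"), so boundary values fall
to the lower tier; the single deliberate exception is the core-gene
definition, "at least 90% of conspecific genomes", which is non-strict
(frequency ≥ 0.90 is core). A viral sequence at exactly 50%
completeness is assigned low quality (the conventional bins leave that
point unassigned; we resolve it downward for consistency with the
strict-inequality policy).

The medium-quality tier uses an inclusive rule: a genome qualifies if
the completeness/contamination/score criteria hold under *either* the
primary or the secondary estimator (two completeness estimators are
routinely run and disagree near boundaries); the high-quality and
near-complete tiers are judged on the primary estimator only. The
eukaryotic medium tier has no quality-score clause.

The chimera filter discards a genome only when all three GUNC-style
criteria trip (portion of contaminated positions > 0.05, clade
separation > 0.45, reference representation > 0.5). A literal reading
of the rule as a conjunction is the default; `rule="any"` is available
for sensitivity analysis because the phrasing is ambiguous in common
usage.

## Dereplication

Clustering is single linkage on the ANI graph, so a species cluster is
a connected component of pairs with ANI ≥ threshold and aligned
fraction ≥ the coverage gate (relative to the larger genome; when both
directions of a pair are reported the maximum ANI wins). Stage 1
(redundancy removal, 99.9%) applies no coverage gate; stage 2 (species,
95%) gates at 0.30. The representative score is the additive dRep-style
form

    score = completeness − 5·contamination
            + contamination·(strain heterogeneity / 100)
            + 0.5·log10(N50)

with weights exposed in `ScoreWeights`; the exact weighting used by any
particular catalog is rarely stated, so the default follows the cited
tool's convention and ties break lexicographically by genome id to keep
results deterministic. The ANI edge list is assumed complete for pairs
above ~90% identity (the usual pre-screen); below-threshold edges may
be arbitrarily sparse without affecting results.

## Statistics

* Rank-sum comparisons use the exact Mann–Whitney null for group sizes
  ≤ 25 without ties and the continuity-corrected normal approximation
  otherwise.
* **Calibration of the sharing tests.** Pooled pairwise values are
  dependent: every pair involving the same genome shares that strain's
  lineage, and the per-infant "unrelated" median is less dispersed than
  a single dyad distance. The analytic rank-sum p-value is therefore
  conservative under the null (its independence assumptions fail). Both
  dyad tests expose `p_mode="permutation"`: the same rank-sum statistic
  with a null built by randomly reassigning mothers to families, which
  respects the dependence structure and is calibrated by construction
  (verified against uniformity in the test suite). The analytic p
  remains the default for comparability with common practice.
* Category enrichment uses the 2×2 odds ratio (core/accessory ×
  category/other) with the Haldane–Anscombe 0.5 correction when a cell
  is zero, a two-tailed one-sample t-test of per-species log odds
  ratios against zero, and Bonferroni correction over categories. A
  two-sample variant (per-species core vs accessory category fractions)
  is available by flag since captions of this kind underdetermine the
  test; the one-sample form matches "t-test on log-transformed odds
  ratios" most directly. Unannotated genes are excluded from both axes.
* The sequence-type sharing test permutes the mother-to-infant pairing
  (the exchangeable unit under the no-sharing null). Monte-Carlo p uses
  the add-one correction (1 + #{null ≥ observed}) / (1 + n); exact mode
  enumerates all n! pairings for n ≤ 8 families and reports the tail
  probability with ties counted as extreme (≥).
* Rarefaction draws one genome permutation per replicate and reads
  species counts off prefixes, making every replicate curve (hence the
  mean) non-decreasing while each subset is still uniform without
  replacement. Default grid: 20 evenly spaced sizes plus the endpoint;
  10 permutations.
* PCoA is classical metric scaling (double-centered Gram matrix,
  eigendecomposition); negative eigenvalues are truncated and their
  total magnitude reported in the result's attrs. Bray–Curtis is
  computed on ln(x+1)-transformed counts (natural log; the base is a
  module decision) after removing taxa present in ≤ 20% of samples.

## The synthetic-data generator

The generator emulates a longitudinal mother–infant skin study: 67
families by default, each with one maternal antecubital sample and an
infant sampled at two sites (cheek, antecubital fossa) × two ages (2–3
and 12 months); 30 species spanning bacteria, fungi and viruses.

* **Community model.** Log-normal species intensities with per-species
  site and age effects (sd 1 log unit each) and subject noise (sd 1);
  mother and infant presence/abundance latents share a family component
  with weight √ρ, so the mother–infant correlation equals the
  configured `relatedness_correlation` (default 0.5). Kingdom-level
  intensity shares per sample are pinned to the configured weights
  (0.973 bacteria / 0.024 fungi / 0.003 viruses), so cross-kingdom
  composition is structural while within-kingdom structure is
  stochastic. Read totals are log-normal around ~2 million per sample
  so the 800,000-read depth filter is occasionally exercised.
* **Recoveries and ANI.** A genome is recovered from a sample with
  probability 1 − exp(−reads/5·10⁴); 15% of recoveries yield a
  duplicate (emulating single- plus pooled-sample assembly).
  Completeness is a 3:1 mixture of a high mode (70 + 30·Beta(5, 1.5))
  and a uniform tail on [40, 70]; contamination is exponential (mean 2)
  truncated at 15 — chosen to populate every tier boundary, since no
  real-data fit backs them. ANI draws are disjoint by construction:
  duplicates ≥ 99.92, conspecific strains 95.2–99.5, between species
  80–92. Related mother/infant strains are *not* given ≥ 99.9 ANI: at
  the configured divergence times their true ANI deviation is within
  the noise band, and keeping strain identity out of the dereplication
  path keeps the two analyses independent (a modeling simplification).
* **Strain transmission.** For each focal species (the 6 most prevalent
  bacterial species by default) and each family carrying it, the infant
  inherits the maternal lineage with probability q (default 0.5).
  Lineages diverge from the species representative by
  Poisson(μ·t_unrelated·L) substitutions and individuals add private
  Poisson(μ·t_related·L) drift, all at uniform distinct sites
  (infinite-sites on a fixed coordinate system; no indels or recurrent
  mutation, with a saturation guard when μtL approaches L). Defaults
  μ = 10⁻⁶ per site per time unit, t_related = 200,
  t_unrelated = 12,500, L = 10⁵ bp give related pairs ~40 pairwise
  SNVs and unrelated pairs ~2,500 (≈ 12.5 retained SNVs/kb species
  density, within the range observed for common skin species). Because
  alignment is exact by construction, SNV calling is column comparison.
* **MLST.** Seven integer-allele loci per lineage; transmitted lineages
  carry the maternal profile, fresh lineages get fresh profiles, and
  every individual may carry a private second strain (probability 0.3).
  The dominant strain is always among the 4–12 cultured isolates, so ST
  sharing mirrors transmission exactly in expectation.
* **Gene content.** A fraction `core_fraction` (default 0.5) of each
  species' 1,000 gene clusters is present in every genome
  pre-thinning; accessory frequencies are U-shaped Beta(0.35, 0.35),
  reproducing the bimodal conspecific gene-frequency spectrum. Observed
  presence is thinned by each genome's completeness. Functional
  categories are drawn from core/accessory-specific distributions with
  default enrichments (translation/metabolism in core; replication,
  defense, transcription in accessory) mirroring the qualitative
  pattern reported for host-associated pan-genomes.
* **Classification fractions.** Reference classified fractions are
  normal (mean 0.636, sd 0.08, clipped to [0.2, 0.95]); the custom
  database applies a relative uplift that is normal with median 21% and
  sd 8%, floored at 0 and truncated so fractions stay in [0, 1] —
  emulating the improvement a population-specific catalog adds over a
  generic reference.

All randomness flows through named substreams of one seed (CRC32 of the
stage name mixed into a `SeedSequence`), so outputs are byte-identical
across runs and adding a stage never perturbs another.

### Composition-conditioned replicas

For catalog-scale checks, `generate_quality_table_for_tiers`,
`generate_viral_completeness` and `generate_st_study` build synthetic
tables with a *specified* ground-truth composition — e.g. 1578
high-quality, 2593 near-complete and 5312 medium-quality prokaryotic
genomes, or a six-family culturing study in which exactly four families
share a sequence type. Metrics are sampled from each class's defining
region without consulting the classifiers, so recovering the
composition genuinely exercises the decision logic at scale (a tenth of
medium-quality prokaryotes qualify only through the secondary
estimator, covering the inclusive-rule path). These replicas stand in
for real catalog tables, which are not bundled; passing them shows the
rules are implemented exactly, not that any particular real catalog
would reproduce.

## What passing tests do and do not show

The generator's communities have no compositional closure effects
beyond multinomial sampling, no sequencing or binning error at the
contig level, no recurrent mutation or recombination, and
kingdom-pinned composition; ANI structure is idealized (disjoint
ranges). Passing tests therefore demonstrates correctness of the
decision logic and calibration of the statistics under the stated
models — not robustness to assembly artifacts, alignment error or
real-world ANI ambiguity near the 95% species boundary.

## Problem sizes

The default scenario (67 families, 30 species, 6 focal species at
L = 10⁵) generates in ~10 s and drives the acceptance script;
null-calibration suites use 8-family scenarios over 100 replicates and
power/recovery suites 40-family scenarios, sizes chosen so the full
test suite completes in about a minute while keeping every Monte-Carlo
check adequately powered.

## Known limitations

* The dereplication stage assumes the ANI edge list is complete above
  the species threshold; it does not re-screen candidate pairs.
* The differential-abundance model fit itself is out of scope; the
  community module only prepares its input filters and records the
  significance gates (`DIFFERENTIAL_ABUNDANCE_GATES`).
* Novelty counting reports novel/known species clusters; it does not
  attempt a phylogenetic-diversity expansion percentage, which is not
  well-defined from cluster counts alone.
* The exact ST permutation test enumerates n! pairings and is limited
  to 8 families; larger studies fall back to Monte-Carlo.
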