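# Methods

## Problem setting and model

The pipeline targets gene discovery for a dominant, incompletely penetrant
trait in a cohort of families ascertained through an affected proband. The
underlying genetic model is autosomal-dominant with heterozygous causal
variants: a causal allele is transmitted from a founder, each carrier
expresses the trait with penetrance π, and non-carriers may present as
phenocopies. Discovery proceeds in three stages — a per-variant filtering
funnel, a per-gene carrier burden test against a population reference, and
per-family co-segregation classification — because each stage answers a
different question (is the variant plausibly causal? is the gene enriched
in cases? does the variant track with the trait in these families?).

## Filter cascade

Stages run in a fixed order (QC → consequence → MAF → deleteriousness →
case–control → multi-family → panel); each per-variant predicate is pure,
so the surviving set is independent of record order, and the funnel trace
is non-increasing by construction.

Parameters, defaults, and rationale:

- `maf_threshold` (fraction, default **0.025**): the rarity bound applied
  as a strict `<` to the *maximum* MAF across all databases where the
  variant is observed. Maximum is the conservative aggregation; a variant
  common in any one population database is not a credible rare dominant
  allele. Absence from every database (a novel variant) counts as MAF 0
  and passes — novel alleles are the most interesting class.
- QC: `require_pass_filter` (default on), `min_gq` **20**, `min_dp` **8**
  applied to carrier genotypes — a site is only informative through its
  carriers. Upstream variant-quality recalibration is a documented
  precondition, so these are a backstop, not a replacement.
- `allowed_consequences`: all protein-altering classes (missense, in-frame
  indel, frameshift, stop gained/lost, canonical splice); synonymous and
  other non-coding classes are excluded.
- `deleterious_mode` (default `both_sift_polyphen`): scored classes need
  SIFT deleterious AND PolyPhen-2 damaging — deliberately the same rule
  that defines qualifying alleles on the reference side, so the burden
  table compares like with like. Classes the predictors cannot score
  (indels, nonsense, splice) qualify on consequence alone. Alternatives
  (`any_two` over SIFT/PolyPhen-2/MutationTaster, `cadd_ge` with
  `cadd_cutoff` 20) are offered because the case-side rule is a genuine
  design choice.
- `max_control_carriers` (default **1**): variants carried by more than
  one unaffected cohort control are excluded. The rule counts carriers,
  not alleles. The boundary is inclusive: exactly one control carrier
  survives.
- `min_probands_per_gene` (default **2**): after variant-level filters, a
  gene needs qualifying variants in more than one distinct proband; two
  variants in the same proband do not count twice.
- `panel`: optional relevance gene set (one symbol per line); disabled
  means pass-through. A curated panel file stands in for knowledge-base
  queries, which are out of scope.

Annotations (consequence class, per-database MAFs, SIFT/PolyPhen-2/
MutationTaster calls, CADD) are consumed from a sidecar TSV keyed by
(chrom, pos, ref, alt). Keeping them out of VCF INFO avoids coupling to
any annotator's INFO dialect. Coordinates are 1-based per VCF; indel
left-alignment is assumed done upstream. Multi-allelic sites are
decomposed per alt with genotypes recoded against that alt, preserving
per-sample total alt dosage across the decomposed records.

## Burden test

The 2×2 orientation is carriers-versus-non-carriers by
probands-versus-reference-individuals (a dominant carrier model in the
style of case–control collapsing tests against public allele counts).
Each family contributes its proband only, so family size cannot inflate
the case count, and a proband with several qualifying variants in a gene
counts once. Reference carriers are approximated from published qualifying
*allele* counts as one heterozygous carrier per allele, capped at the
number of reference individuals — exact for rare variants, conservative
in the cap's corner case, and the only option when the reference publishes
allele counts rather than genotypes.

Fisher's exact p is computed from the hypergeometric distribution over the
table's support. The support has at most `min(row1, col1) + 1` entries
(≈ the proband count here), so the implementation walks it with the
pairwise probability-ratio recurrence in log-space, normalises by the
summed support, and never forms a large factorial; accuracy is ~1e-13
relative even with reference margins of 60 000+. Two-sided p sums all
tables whose probability is at most the observed table's, with a relative
tolerance of 1e-7 on the comparison so equal-probability tables are
included despite round-off (the convention shared by the standard
implementations). Degenerate margins and the all-zero table give p = 1.
`greater` (enrichment in cases) is available; two-sided is the default
since prevalence comparison, not direction, is the stated test.

Multiple testing uses Benjamini–Hochberg across exactly the genes entering
the run (the panel when one is configured — 28 in the motivating design —
so genes with zero case carriers still widen the family). Candidacy is
adjusted *P* < α with α = **0.025** by default; a switch applies α to the
raw p instead, since published thresholds of this kind are often ambiguous
about adjustment. Ranking is (raw p ascending, carrier count descending,
gene name) — a total, deterministic order. Odds ratios use the Haldane
0.5 correction when any cell is zero.

## Segregation classifier

Per variant and family, with members of unknown phenotype always ignored:

- FAILS if any genotyped affected member is a non-carrier, or unaffected
  carriers exceed `allow_unaffected_carriers` (default **0**; raise it to
  tolerate incomplete penetrance).
- SEGREGATES if at least one genotyped affected carrier exists, every
  genotyped affected member carries the variant, and no affected genotype
  is missing (unless `missing_genotype_handling="ignore"`).
- INDETERMINATE otherwise — no genotyped affected member, or missing
  affected genotypes under the default `indeterminate` handling
  (`fail` is available for strict use).

Homozygous-alt affected members count as carriers but are logged, since
the model expects heterozygotes. Sex chromosomes are rejected by default
(autosomal model); a policy flag admits them. Cohort-level, a variant is
"segregating" when it SEGREGATES in at least one family and FAILS in none
of the families where it occurs; INDETERMINATE families neither support
nor disqualify. In the full pipeline, segregation runs after the burden
test, on the surviving variants of burden-candidate genes, and the final
candidate list is the burden candidates with at least one segregating
variant.

## Synthetic cohort generator

What it emulates: families ascertained through an affected proband; a
planted causal gene whose variants enter through a founder and are
transmitted Mendelianly (each child of a carrier inherits with probability
1/2); penetrance **0.9** for carriers and a **0.02** phenocopy rate for
non-carriers, so segregation and case–control logic face realistic noise;
unrelated unaffected cohort controls; per-gene rare background variation
(Poisson site counts, mean **3** qualifying and **1** non-qualifying site
per gene; MAFs log-uniform on [3e-5, 0.02] with a 10% point mass at 0.01,
truncated at 0.05); and a reference-count table drawn as
Binomial(2·N_ref, Σ qualifying MAFs) from the *same* per-gene frequencies
— the calibration that makes the no-planted-gene configuration a genuine
null for the burden test. The planted gene's reference count is never
inflated; enrichment exists only in cases. Scale defaults mirror the
motivating cohort: 67 case families, 35 controls, 28 genes, 33 000
reference individuals.

Ascertainment: in carrier families the proband is an affected carrier
child by construction — families enter such a study because the trait and
the variant co-occur in the index case. In non-carrier families the
proband is still affected (the cohort is all-affected; the planted gene
explains only part of it). Consequently "k carrier families" means k
carrier probands, which is what the burden test sees.

Randomness is a tree of substreams off one mandatory master seed: family
structure/affection/transmission per family, background site counts and
MAFs per gene, background genotypes per (gene, family) — so adding a
family or a gene never perturbs the rest, and the emitted file set is
byte-identical for a given spec and seed.

What it does **not** model, hence what passing tests do not show:
linkage disequilibrium and within-family transmission of background
variants (background genotypes are independent per individual),
haplotype/population structure between cohort and reference, de novo
mutation, consanguinity, sex-linked inheritance, genotyping error or
missingness beyond what tests construct explicitly, and variant-calling
artefacts. Recovery results therefore speak to the statistical machinery,
not to robustness against real-data confounding such as population
stratification between cases and the reference.

The worked-example fixture is fully deterministic (no RNG): one focal
gene, 12 variants, four two-generation pedigrees and 35 controls, with
annotations arranged so the funnel realises 12 → 8 → 3 → 2 with the gene
as final candidate. The counts (4 early decoys, 5 control-carried, 1
segregation failure in a variant shared by two pedigrees) are the minimal
composition that exercises every stage while reproducing the published
funnel narrative.

## Numerical and procedural choices

- Fisher two-sided tie tolerance 1e-7 (relative) on the inclusion
  comparison; p clipped into (0, 1].
- BH adjustment delegated to statsmodels' step-up implementation behind
  the package surface; verified in tests against a hand-rolled
  `min`-cascade and closed forms at ties.
- Ranking tie-breaks: (p_raw, −carriers, gene name); funnel provenance
  tie-breaks by (chrom, pos, alt).
- All writers emit deterministic byte streams (sorted keys, `repr` float
  formatting); reruns with the same inputs are byte-identical.
- Proband designation is an explicit companion list (clinical
  designation cannot be derived from a PED reliably); a fallback takes
  the first affected non-founder when no list is supplied.
- Genotype vocabulary is restricted to `0/0`, `0/1`, `1/1`, `./.`;
  half-calls are treated as missing; phase is not modelled.

## Problem sizes in tests

The test and acceptance suites use scaled study conditions chosen to keep
each statistical check well-powered at desk scale: exhaustive Fisher
oracle sweeps over all tables with margins ≤ 15 plus 1000 random tables at
cohort scale (up to 120 probands, 40 000 reference individuals);
exhaustive segregation scans over all affection and genotype assignments
for families of up to 6 members; and 100-replicate recovery/null studies
with 40 families (8 carrying the planted variant), the 28-gene panel and
the default background model. The full suite runs in well under a minute
on one CPU.

## Known limitations

- The reference-carrier approximation breaks down if qualifying alleles
  concentrate in few individuals (compound heterozygotes); with rare
  variants the bias is negligible and conservative.
- The burden test compares against a fixed external reference; it cannot
  correct for case–reference ancestry mismatch. Using a population-matched
  reference is the user's responsibility.
- The segregation classifier is rule-based, not likelihood-based; it does
  not weigh pedigree informativeness (no LOD scores) and treats each
  variant–family pair independently.
- Exact-test discreteness makes the per-gene test conservative at small
  carrier counts; the null simulations in the test suite bound, rather
  than match, the nominal type-I rate.
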