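"""Dominant-segregation classifier vs a clause-enumeration oracle."""

import itertools

import pytest

from rarefam import (
    GenotypeCall,
    Individual,
    Pedigree,
    SegregationPolicy,
    VariantRecord,
    classify_segregation,
    cohort_segregation_summary,
)
from rarefam.model import ValidationError

from conftest import make_trio, make_variant
from oracles import segregation_oracle

DEFAULT = SegregationPolicy()
_GT_CHOICES = ("0/0", "0/1", "./.")
_AFF_CHOICES = ("affected", "unaffected", "unknown")
_GT_CACHE = {gt: GenotypeCall(gt) for gt in _GT_CHOICES + ("1/1",)}


def _pedigree(n_members: int, affections, family_id="F1") -> Pedigree:
    """A family of founders plus children hanging off the first couple."""
    members = []
    ids = [f"M{i}" for i in range(n_members)]
    for i, iid in enumerate(ids):
        father = ids[0] if (i >= 2 and n_members >= 2) else None
        mother = ids[1] if (i >= 2 and n_members >= 2) else None
        members.append(Individual(
            id=iid, family_id=family_id, father_id=father, mother_id=mother,
            affection=affections[i], is_proband=(i == n_members - 1),
        ))
    return Pedigree(family_id=family_id, members=members)


def _variant(ids, gts) -> VariantRecord:
    return VariantRecord("1", 100, "A", "G", "GENE01",
                         {i: _GT_CACHE[g] for i, g in zip(ids, gts)})


class TestClassifyExamples:
    def test_clean_dominant_transmission_segregates(self):
        """Affected father and proband heterozygous, unaffected members
        reference: the textbook dominant pattern."""
        ped = make_trio()
        rec = make_variant({"F1_FA", "F1_PB"}, [m.id for m in ped.members])
        call = classify_segregation(rec, ped, DEFAULT)
        assert call.verdict == "SEGREGATES"
        assert call.affected_carriers == 2 and call.unaffected_carriers == 0

    def test_affected_noncarrier_fails(self):
        ped = make_trio()
        rec = make_variant({"F1_PB"}, [m.id for m in ped.members])  # father misses it
        assert classify_segregation(rec, ped, DEFAULT).verdict == "FAILS"

    def test_unaffected_carrier_fails_at_zero_tolerance(self):
        ped = make_trio()
        rec = make_variant({"F1_FA", "F1_MO", "F1_PB"}, [m.id for m in ped.members])
        assert classify_segregation(rec, ped, DEFAULT).verdict == "FAILS"
        lenient = SegregationPolicy(allow_unaffected_carriers=1)
        assert classify_segregation(rec, ped, lenient).verdict == "SEGREGATES"

    def test_sole_affected_untyped_is_indeterminate(self):
        ped = Pedigree("F1", [
            Individual(id="A", family_id="F1", affection="affected", is_proband=True),
            Individual(id="B", family_id="F1", affection="unaffected"),
        ])
        rec = make_variant(set(), ["A", "B"], missing={"A"})
        assert classify_segregation(rec, ped, DEFAULT).verdict == "INDETERMINATE"
        assert classify_segregation(
            rec, ped, SegregationPolicy(missing_genotype_handling="fail")).verdict == "FAILS"

    def test_missing_affected_blocks_positive_call_by_default(self):
        ped = make_trio()
        rec = make_variant({"F1_PB"}, [m.id for m in ped.members], missing={"F1_FA"})
        assert classify_segregation(rec, ped, DEFAULT).verdict == "INDETERMINATE"
        ignore = SegregationPolicy(missing_genotype_handling="ignore")
        assert classify_segregation(rec, ped, ignore).verdict == "SEGREGATES"

    def test_sex_chromosome_rejected_by_default(self):
        ped = make_trio()
        ids = [m.id for m in ped.members]
        rec = make_variant({"F1_PB"}, ids, chrom="X")
        with pytest.raises(ValidationError, match="sex chromosome"):
            classify_segregation(rec, ped, DEFAULT)
        ok = SegregationPolicy(include_sex_chromosomes=True)
        assert classify_segregation(rec, ped, ok).verdict in ("FAILS", "SEGREGATES")

    def test_family_absent_from_matrix_raises(self):
        ped = make_trio()
        rec = make_variant({"X1"}, ["X1"])
        with pytest.raises(ValidationError, match="genotype matrix"):
            classify_segregation(rec, ped, DEFAULT)


@pytest.mark.parametrize("n_members", [1, 2, 3, 4])
def test_oracle_equivalence_exhaustive_small(n_members):
    """For every affection pattern and every genotype assignment over
    {0/0, 0/1, ./.}, the classifier agrees with the clause-enumeration
    oracle (exhaustive for families of up to 4 members)."""
    ids = [f"M{i}" for i in range(n_members)]
    for affections in itertools.product(_AFF_CHOICES, repeat=n_members):
        ped = _pedigree(n_members, affections)
        for gts in itertools.product(_GT_CHOICES, repeat=n_members):
            rec = _variant(ids, gts)
            got = classify_segregation(rec, ped, DEFAULT).verdict
            want = segregation_oracle(rec, ped, DEFAULT)
            assert got == want, (affections, gts)


@pytest.mark.parametrize("policy", [
    DEFAULT,
    SegregationPolicy(allow_unaffected_carriers=1),
    SegregationPolicy(missing_genotype_handling="fail"),
    SegregationPolicy(missing_genotype_handling="ignore"),
])
def test_oracle_equivalence_six_member_families(policy):
    """Exhaustive genotype x affection scan of six-member families under
    several policies (the genotype space is the full 3^6 per pattern)."""
    n = 6
    ids = [f"M{i}" for i in range(n)]
    # a representative subset of affection patterns incl. all-affected,
    # mixed, unknowns, and no-affected corner cases
    patterns = [
        ("affected",) * 6,
        ("affected", "unaffected", "affected", "unaffected", "unknown", "affected"),
        ("unknown",) * 6,
        ("unaffected",) * 6,
        ("affected", "affected", "unknown", "unaffected", "unaffected", "affected"),
        ("unknown", "affected", "unknown", "affected", "unknown", "unaffected"),
    ]
    for affections in patterns:
        ped = _pedigree(n, affections)
        for gts in itertools.product(_GT_CHOICES, repeat=n):
            rec = _variant(ids, gts)
            got = classify_segregation(rec, ped, policy).verdict
            want = segregation_oracle(rec, ped, policy)
            assert got == want, (affections, gts)


def test_homozygous_affected_counts_as_carrier():
    ped = make_trio()
    ids = [m.id for m in ped.members]
    rec = _variant(ids, ("1/1", "0/0", "0/1"))  # affected father hom-alt
    call = classify_segregation(rec, ped, DEFAULT)
    assert call.verdict == "SEGREGATES" and call.affected_carriers == 2


def test_monotone_in_missing_affected_genotypes():
    """Filling in a missing affected genotype as a carrier never flips a
    SEGREGATES verdict to FAILS."""
    n = 4
    ids = [f"M{i}" for i in range(n)]
    for policy in (DEFAULT, SegregationPolicy(missing_genotype_handling="ignore")):
        for affections in itertools.product(_AFF_CHOICES, repeat=n):
            ped = _pedigree(n, affections)
            for gts in itertools.product(_GT_CHOICES, repeat=n):
                missing_affected = [i for i in range(n)
                                    if gts[i] == "./." and affections[i] == "affected"]
                if not missing_affected:
                    continue
                before = classify_segregation(_variant(ids, gts), ped, policy).verdict
                filled = list(gts)
                filled[missing_affected[0]] = "0/1"
                after = classify_segregation(_variant(ids, tuple(filled)), ped, policy).verdict
                assert not (before == "SEGREGATES" and after == "FAILS")


def test_unknown_phenotype_members_never_change_verdict():
    """Toggling an unknown-phenotype member's genotype leaves the verdict
    untouched."""
    n = 4
    ids = [f"M{i}" for i in range(n)]
    affections = ("affected", "unknown", "unaffected", "affected")
    ped = _pedigree(n, affections)
    for gts in itertools.product(_GT_CHOICES, repeat=n):
        base = classify_segregation(_variant(ids, gts), ped, DEFAULT).verdict
        for new_gt in _GT_CHOICES + ("1/1",):
            toggled = list(gts)
            toggled[1] = new_gt  # the unknown-phenotype member
            assert classify_segregation(_variant(ids, tuple(toggled)), ped, DEFAULT).verdict == base


class TestCohortSummary:
    def test_worked_example_two_variants_segregate(self, fixture_cohort, fixture_config):
        """Of the three variants of interest, exactly two segregate once all
        family members are genotyped."""
        from rarefam import run_cascade

        survivors, _ = run_cascade(fixture_cohort.records, fixture_cohort.annotations,
                                   fixture_cohort.pedigrees, fixture_config)
        _, segregating = cohort_segregation_summary(survivors, fixture_cohort.pedigrees)
        assert len(segregating) == 2
        assert segregating == [("14", 77491828, "A", "C"), ("14", 77493473, "AGCG", "A")]

    def test_fails_anywhere_disqualifies(self):
        peds = [make_trio("FAM1"), make_trio("FAM2")]
        samples = [m.id for p in peds for m in p.members]
        # segregates in FAM1, but FAM2's affected father lacks it
        rec = make_variant({"FAM1_FA", "FAM1_PB", "FAM2_PB"}, samples)
        calls, segregating = cohort_segregation_summary([rec], peds)
        verdicts = {c.family_id: c.verdict for c in calls[rec.key]}
        assert verdicts == {"FAM1": "SEGREGATES", "FAM2": "FAILS"}
        assert segregating == []

    def test_indeterminate_families_do_not_count_as_support(self):
        peds = [make_trio("FAM1")]
        samples = [m.id for p in peds for m in p.members]
        rec = make_variant({"FAM1_PB"}, samples, missing={"FAM1_FA"})
        _, segregating = cohort_segregation_summary([rec], peds)
        assert segregating == []

    def test_empty_input(self):
        calls, segregating = cohort_segregation_summary([], [make_trio()])
        assert calls == {} and segregating == []
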