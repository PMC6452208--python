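import pytest

from rarefam import (
    CascadeConfig,
    GenotypeCall,
    Individual,
    Pedigree,
    VariantRecord,
    make_worked_example_fixture,
)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic worked-example cohort (built once per session)."""
    return make_worked_example_fixture()


@pytest.fixture(scope="session")
def fixture_config(fixture_cohort):
    return CascadeConfig(panel=fixture_cohort.panel)


def make_variant(carriers, samples, chrom="1", pos=100, ref="A", alt="G", gene="GENE01",
                 missing=(), filter_status="PASS", gq=99, dp=30):
    """A biallelic variant with het carriers among ``samples``."""
    genotypes = {}
    for s in samples:
        if s in missing:
            genotypes[s] = GenotypeCall("./.")
        elif s in carriers:
            genotypes[s] = GenotypeCall("0/1", gq=gq, dp=dp)
        else:
            genotypes[s] = GenotypeCall("0/0", gq=gq, dp=dp)
    return VariantRecord(chrom, pos, ref, alt, gene, genotypes,
                         filter_status=filter_status)


def make_trio(family_id="F1", father_aff="affected", mother_aff="unaffected",
              child_aff="affected"):
    """Two-generation trio with the child as proband."""
    return Pedigree(family_id=family_id, members=[
        Individual(id=f"{family_id}_FA", family_id=family_id, sex="male",
                   affection=father_aff),
        Individual(id=f"{family_id}_MO", family_id=family_id, sex="female",
                   affection=mother_aff),
        Individual(id=f"{family_id}_PB", family_id=family_id, sex="male",
                   father_id=f"{family_id}_FA", mother_id=f"{family_id}_MO",
                   affection=child_aff, is_proband=True),
    ])


def make_controls(n, start=1):
    """n unrelated cohort-control singletons."""
    peds = []
    for i in range(start, start + n):
        cid = f"CTRL{i:03d}"
        peds.append(Pedigree(family_id=cid, members=[
            Individual(id=cid, family_id=cid, affection="unaffected",
                       role="cohort_control"),
        ]))
    return peds
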