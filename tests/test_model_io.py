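"""Data-model invariants and file-format round trips."""

import pytest

from rarefam import (
    Annotation,
    GenotypeCall,
    Individual,
    Pedigree,
    ReferenceGeneCounts,
    ValidationError,
    VariantRecord,
    make_worked_example_fixture,
)
from rarefam import io as rio
from rarefam.model import FilterTrace, sample_manifest


class TestTypeInvariants:
    @pytest.mark.parametrize("gt", ["0/0", "0/1", "1/1", "./."])
    def test_genotype_vocabulary_accepted(self, gt):
        GenotypeCall(gt)

    @pytest.mark.parametrize("gt", ["0|1", "1/2", "0/2", "", "1"])
    def test_genotype_vocabulary_rejected(self, gt):
        with pytest.raises(ValidationError):
            GenotypeCall(gt)

    def test_variant_must_be_biallelic_and_positive(self):
        with pytest.raises(ValidationError):
            VariantRecord("1", 10, "A", "C,T", "G1", {})
        with pytest.raises(ValidationError):
            VariantRecord("1", 0, "A", "C", "G1", {})

    @pytest.mark.parametrize("field,value", [
        ("consequence", "nonsense-word"),
        ("sift", "bad"),
        ("polyphen2", "bad"),
        ("mutationtaster", "bad"),
    ])
    def test_annotation_vocabulary_enforced(self, field, value):
        with pytest.raises(ValidationError):
            Annotation(**{"consequence": "missense", field: value})

    def test_annotation_maf_range_enforced(self):
        with pytest.raises(ValidationError):
            Annotation(consequence="missense", maf_by_db={"db": 1.5})

    def test_novel_variant_max_maf_is_zero(self):
        assert Annotation(consequence="missense").max_maf == 0.0

    def test_reference_counts_invariants(self):
        ReferenceGeneCounts("GENE1", 0, 66000)  # zero carriers implied
        with pytest.raises(ValidationError):
            ReferenceGeneCounts("GENE1", 10, 8)  # count exceeds alleles
        with pytest.raises(ValidationError):
            ReferenceGeneCounts("GENE1", 1, 7)  # odd allele total

    def test_case_family_requires_exactly_one_proband(self):
        with pytest.raises(ValidationError):
            Pedigree("F1", [Individual(id="A", family_id="F1", affection="affected")])

    def test_parent_cycle_detected(self):
        with pytest.raises(ValidationError, match="cycle"):
            Pedigree("F1", [
                Individual(id="A", family_id="F1", father_id="A",
                           affection="affected", is_proband=True),
            ])

    def test_duplicate_member_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            Pedigree("F1", [
                Individual(id="A", family_id="F1", affection="affected", is_proband=True),
                Individual(id="A", family_id="F1"),
            ])

    def test_trace_rejects_increasing_variant_counts(self):
        trace = FilterTrace()
        trace.append("input", 5, 2)
        with pytest.raises(ValidationError, match="monotone"):
            trace.append("qc", 6, 2)


MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tT,G\t50\tPASS\t.\tGT:GQ:DP\t1/2:99:30\t0/1:80:25\t2/2:60:20
"""


class TestVcfReader:
    def test_multiallelic_decomposition_preserves_dosage(self, tmp_path):
        """Decomposing a site into per-alt records conserves each sample's
        total alt dosage."""
        path = tmp_path / "multi.vcf"
        path.write_text(MULTIALLELIC_VCF)
        manifest = {"S1": "family_member", "S2": "family_member", "S3": "cohort_control"}
        records = rio.read_vcf(str(path), manifest)
        assert len(records) == 2
        assert {r.alt for r in records} == {"T", "G"}
        by_alt = {r.alt: r for r in records}
        # S1 was 1/2: one alt-T allele and one alt-G allele
        assert by_alt["T"].genotypes["S1"].gt == "0/1"
        assert by_alt["G"].genotypes["S1"].gt == "0/1"
        # S3 was 2/2: homozygous for alt G, reference against alt T
        assert by_alt["G"].genotypes["S3"].gt == "1/1"
        assert by_alt["T"].genotypes["S3"].gt == "0/0"
        original_dosage = {"S1": 2, "S2": 1, "S3": 2}
        for s, want in original_dosage.items():
            assert sum(r.genotypes[s].alt_dosage for r in records) == want

    def test_missing_manifest_sample_is_named(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(MULTIALLELIC_VCF)
        with pytest.raises(ValidationError, match="S9"):
            rio.read_vcf(str(path), {"S9": "family_member"})

    def test_header_only_vcf_yields_empty_list(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text("".join(MULTIALLELIC_VCF.splitlines(keepends=True)[:-1]))
        assert rio.read_vcf(str(path), {"S1": "family_member"}) == []

    def test_published_locus_parses(self, tmp_path, fixture_cohort):
        """The 14:77491828 A>C missense site survives a write/read cycle with
        position, alleles and rsID intact."""
        paths = fixture_cohort.write(str(tmp_path))
        manifest = sample_manifest(fixture_cohort.pedigrees)
        records = rio.read_vcf(paths["vcf"], manifest)
        rec = next(r for r in records if r.pos == 77491828)
        assert (rec.ref, rec.alt, rec.variant_id) == ("A", "C", "rs760847179")

    def test_vcf_roundtrip_identity(self, tmp_path, fixture_cohort):
        """write -> read reproduces every record field-by-field."""
        paths = fixture_cohort.write(str(tmp_path))
        manifest = sample_manifest(fixture_cohort.pedigrees)
        sidecar = rio.read_annotations(paths["annotations"])
        records = rio.read_vcf(paths["vcf"], manifest,
                               gene_by_key={k: g for k, (g, _) in sidecar.items()})
        original = {r.key: r for r in fixture_cohort.records}
        assert len(records) == len(original)
        for r in records:
            o = original[r.key]
            assert (r.gene, r.variant_id, r.filter_status) == (o.gene, o.variant_id, o.filter_status)
            assert dict(r.genotypes) == dict(o.genotypes)


class TestPedReader:
    def test_single_founder(self, tmp_path):
        p = tmp_path / "one.ped"
        p.write_text("F1\tA\t0\t0\t1\t2\n")
        peds = rio.read_ped(str(p))
        assert len(peds) == 1 and len(peds[0].members) == 1
        assert peds[0].members[0].affection == "affected"

    def test_two_generation_affected_father_and_son(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text(
            "F1\tFA\t0\t0\t1\t2\n"
            "F1\tMO\t0\t0\t2\t1\n"
            "F1\tSON\tFA\tMO\t1\t2\n"
        )
        (ped,) = rio.read_ped(str(p), proband_ids=["SON"])
        assert sum(m.affection == "affected" for m in ped.members) == 2
        assert sum(m.is_proband for m in ped.members) == 1
        assert ped.proband.id == "SON"

    def test_self_parent_raises(self, tmp_path):
        p = tmp_path / "cycle.ped"
        p.write_text("F1\tA\tA\t0\t1\t2\n")
        with pytest.raises(ValidationError, match="cycle"):
            rio.read_ped(str(p))

    def test_duplicate_id_raises(self, tmp_path):
        p = tmp_path / "dup.ped"
        p.write_text("F1\tA\t0\t0\t1\t2\nF2\tA\t0\t0\t1\t2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            rio.read_ped(str(p))

    def test_ped_roundtrip_is_identity(self, tmp_path, fixture_cohort):
        p1 = tmp_path / "a.ped"
        p2 = tmp_path / "b.ped"
        rio.write_ped(fixture_cohort.pedigrees, str(p1))
        probands = [p.proband.id for p in fixture_cohort.pedigrees if p.proband]
        peds = rio.read_ped(str(p1), proband_ids=probands)
        rio.write_ped(peds, str(p2))
        assert p1.read_bytes() == p2.read_bytes()
        by_id = {ped.family_id: ped for ped in peds}
        for ped in fixture_cohort.pedigrees:
            assert by_id[ped.family_id].members == ped.members


class TestReferenceAndResults:
    def test_reference_table_roundtrip_and_size(self, tmp_path):
        counts = {f"G{i}": ReferenceGeneCounts(f"G{i}", i, 66000) for i in range(28)}
        path = tmp_path / "ref.tsv"
        rio.write_gene_reference(counts, str(path))
        loaded = rio.read_gene_reference(str(path))
        assert len(loaded) == 28
        assert loaded == counts

    def test_invalid_reference_row_raises_on_load(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("gene\tqualifying_allele_count\ttotal_alleles\nG1\t10\t8\n")
        with pytest.raises(ValidationError):
            rio.read_gene_reference(str(path))

    def test_empty_results_yield_header_only_tsv(self, tmp_path):
        paths = rio.write_results([], FilterTrace(), str(tmp_path / "out"))
        lines = open(paths["results"]).read().splitlines()
        assert len(lines) == 1 and lines[0].startswith("gene\t")

    def test_results_row_count_and_roundtrip(self, tmp_path, fixture_cohort, fixture_config):
        from rarefam.pipeline import discover

        res = discover(fixture_cohort.records, fixture_cohort.annotations,
                       fixture_cohort.pedigrees, fixture_cohort.reference,
                       cascade_config=fixture_config)
        paths = rio.write_results(res.burden, res.trace, str(tmp_path / "out"))
        loaded = rio.read_results(paths["results"])
        assert len(loaded) == len(res.burden)
        assert loaded == sorted(res.burden, key=lambda r: r.rank)

    def test_write_results_is_byte_stable(self, tmp_path, fixture_cohort, fixture_config):
        from rarefam.pipeline import discover

        res = discover(fixture_cohort.records, fixture_cohort.annotations,
                       fixture_cohort.pedigrees, fixture_cohort.reference,
                       cascade_config=fixture_config)
        p1 = rio.write_results(res.burden, res.trace, str(tmp_path / "a"))
        p2 = rio.write_results(res.burden, res.trace, str(tmp_path / "b"))
        for k in p1:
            assert open(p1[k], "rb").read() == open(p2[k], "rb").read()

    def test_annotation_sidecar_roundtrip(self, tmp_path, fixture_cohort):
        gene_by_key = {r.key: r.gene for r in fixture_cohort.records}
        sidecar = {k: (gene_by_key[k], a) for k, a in fixture_cohort.annotations.items()}
        path = tmp_path / "ann.tsv"
        rio.write_annotations(sidecar, str(path))
        loaded = rio.read_annotations(str(path))
        assert loaded == sidecar
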