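"""Synthetic cohorts for exercising the discovery pipeline end to end.

The generator emulates the statistical structure the analysis assumes: a
set of case families ascertained through an affected proband and
segregating a dominant trait, a planted causal gene whose qualifying
variants are transmitted Mendelian-fashion from a founder with incomplete
penetrance, rare background variation sampled independently per individual
across a gene panel, a pool of unrelated unaffected cohort controls, and a
population-reference qualifying-count table drawn from the *same* per-gene
qualifying allele frequencies as the case background — so that, absent the
planted gene, case and reference carrier prevalences share a null.

Randomness is organised as substreams keyed off one master seed: family
structure, affection and planted transmission come from per-family streams,
background site counts and frequencies from per-gene streams, and
background genotypes from per-(gene, family) streams — adding a family or
a gene never perturbs the realisation of any other.

A fully deterministic worked-example fixture (no randomness at all) mirrors
the published discovery narrative for one focal gene: 12 candidate variants
across four pedigrees and 35 controls, of which 8 survive annotation
filtering, 5 are then removed for being carried by multiple cohort
controls, and of the 3 survivors exactly 2 co-segregate with the trait.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    Annotation,
    GenotypeCall,
    Individual,
    Pedigree,
    ReferenceGeneCounts,
    ValidationError,
    VariantRecord,
)
from . import io as rio

__all__ = ["CohortSpec", "TruthTable", "Cohort", "generate_cohort",
           "simulate_reference_counts", "make_worked_example_fixture"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _stream(*parts) -> np.random.Generator:
    """Derive a named substream from the master seed.

    String parts are hashed with CRC32 so streams are stable under
    insertion order of families and genes.
    """
    ints = [p if isinstance(p, int) else zlib.crc32(p.encode()) for p in parts]
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults follow the discovery cohort's scale: 67 case families (one
    proband each), 35 unaffected cohort controls, a 28-gene relevance
    panel, a 33 000-individual population reference, dominant inheritance
    with penetrance 0.9 and a 2% phenocopy rate. The planted gene carries
    2 distinct causal variants spread over 4 carrier families (the scale at
    which the focal gene first surfaced). Background qualifying variation
    arrives at ``background_rate`` sites per gene on average with MAFs
    drawn from a rare-tail log-uniform spectrum plus optional point masses,
    truncated at 0.05.
    """

    seed: int
    n_case_families: int = 67
    n_cohort_controls: int = 35
    n_genes: int = 28
    planted_gene: Optional[str] = "GENE01"
    n_planted_variants: int = 2
    n_carrier_families: int = 4
    penetrance: float = 0.9
    phenocopy_rate: float = 0.02
    children_weights: tuple = ((1, 0.4), (2, 0.4), (3, 0.2))
    background_rate: float = 3.0
    background_nonqualifying_rate: float = 1.0
    maf_tail_range: tuple = (3e-5, 0.02)
    maf_point_masses: tuple = (0.01,)
    maf_point_mass_weight: float = 0.1
    n_reference_individuals: int = 33000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValidationError(f"penetrance outside [0,1]: {self.penetrance}")
        if not (0.0 <= self.phenocopy_rate <= 1.0):
            raise ValidationError("phenocopy_rate outside [0,1]")
        if self.background_rate < 0 or self.background_nonqualifying_rate < 0:
            raise ValidationError("background rates must be >= 0")
        if self.n_carrier_families > self.n_case_families:
            raise ValidationError("more carrier families than case families")
        if not (0.0 < self.maf_tail_range[0] <= self.maf_tail_range[1] <= 0.05):
            raise ValidationError("maf_tail_range must lie within (0, 0.05]")

    @property
    def genes(self) -> list[str]:
        names = [f"GENE{i + 1:02d}" for i in range(self.n_genes)]
        if self.planted_gene is not None and self.planted_gene not in names:
            names[0] = self.planted_gene
        return names


@dataclass
class TruthTable:
    """Ground truth of one generated cohort, for recovery tests."""

    planted_gene: Optional[str]
    planted_variants: list[tuple]
    carrier_status: dict[str, bool]  # individual -> carries a planted variant
    affection: dict[str, str]
    reference_counts: dict[str, int]

    def check_consistency(self, records: Sequence[VariantRecord]) -> None:
        """Verify carriers declared here match the emitted genotypes exactly."""
        planted = {tuple(v) for v in self.planted_variants}
        observed: set[str] = set()
        for rec in records:
            if rec.key in planted:
                observed.update(rec.carriers())
        declared = {s for s, carrier in self.carrier_status.items() if carrier}
        if observed != declared:
            raise ValidationError(
                f"truth table inconsistent with VCF: declared-only "
                f"{sorted(declared - observed)}, vcf-only {sorted(observed - declared)}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_gene": self.planted_gene,
                "planted_variants": [list(v) for v in self.planted_variants],
                "carrier_status": dict(sorted(self.carrier_status.items())),
                "affection": dict(sorted(self.affection.items())),
                "reference_counts": dict(sorted(self.reference_counts.items())),
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class Cohort:
    """An in-memory cohort: the full input set for one pipeline run."""

    records: list[VariantRecord]
    annotations: dict[tuple, Annotation]
    pedigrees: list[Pedigree]
    reference: dict[str, ReferenceGeneCounts]
    panel: frozenset
    truth: Optional[TruthTable] = None

    @property
    def sample_order(self) -> list[str]:
        return [m.id for ped in self.pedigrees for m in ped.members]

    def write(self, out_dir: str) -> dict[str, str]:
        """Write the cohort as VCF + PED + sidecars; byte-stable per seed."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "vcf": os.path.join(out_dir, "cohort.vcf"),
            "ped": os.path.join(out_dir, "cohort.ped"),
            "probands": os.path.join(out_dir, "probands.txt"),
            "annotations": os.path.join(out_dir, "annotations.tsv"),
            "reference": os.path.join(out_dir, "reference_counts.tsv"),
            "panel": os.path.join(out_dir, "panel.txt"),
        }
        rio.write_vcf(self.records, paths["vcf"], self.sample_order)
        rio.write_ped(self.pedigrees, paths["ped"])
        rio.write_proband_list(
            [p.proband.id for p in self.pedigrees if p.proband is not None], paths["probands"]
        )
        gene_by_key = {r.key: r.gene for r in self.records}
        rio.write_annotations(
            {k: (gene_by_key.get(k, ""), a) for k, a in self.annotations.items()},
            paths["annotations"],
        )
        rio.write_gene_reference(self.reference, paths["reference"])
        rio.write_panel(self.panel, paths["panel"])
        if self.truth is not None:
            paths["truth"] = os.path.join(out_dir, "truth.json")
            with open(paths["truth"], "w") as fh:
                fh.write(self.truth.to_json() + "\n")
        return paths


def _draw_maf(rng: np.random.Generator, spec: CohortSpec) -> float:
    if spec.maf_point_masses and rng.random() < spec.maf_point_mass_weight:
        return float(rng.choice(spec.maf_point_masses))
    lo, hi = spec.maf_tail_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _make_family(spec: CohortSpec, index: int, carrier_family: bool) -> tuple[Pedigree, dict[str, int], str]:
    """Build one case family and its planted-variant dosage per member.

    Returns (pedigree, planted dosage by member, affection source note).
    The proband is always affected (families enter the cohort through an
    affected index case); in carrier families the proband is additionally a
    carrier, having inherited the variant from the transmitting founder.
    """
    fam_id = f"FAM{index + 1:03d}"
    rng = _stream(spec.seed, 1, fam_id)
    sizes, weights = zip(*spec.children_weights)
    n_children = int(rng.choice(sizes, p=np.asarray(weights) / sum(weights)))

    father, mother = f"{fam_id}_FA", f"{fam_id}_MO"
    children = [f"{fam_id}_C{i + 1}" for i in range(n_children)]
    proband = children[0]

    dosage: dict[str, int] = {father: 0, mother: 0}
    if carrier_family:
        transmitter = father if rng.random() < 0.5 else mother
        dosage[transmitter] = 1
    for c in children:
        parent_dose = dosage[father] + dosage[mother]
        if c == proband and carrier_family:
            dosage[c] = 1  # ascertainment: index case carries the family variant
        elif parent_dose > 0:
            dosage[c] = int(rng.random() < 0.5)
        else:
            dosage[c] = 0

    affection: dict[str, str] = {}
    for member in [father, mother] + children:
        if member == proband:
            affection[member] = "affected"
        elif dosage[member] > 0:
            affection[member] = "affected" if rng.random() < spec.penetrance else "unaffected"
        else:
            affection[member] = "affected" if rng.random() < spec.phenocopy_rate else "unaffected"

    members = [
        Individual(id=father, family_id=fam_id, sex="male", affection=affection[father]),
        Individual(id=mother, family_id=fam_id, sex="female", affection=affection[mother]),
    ]
    for c in children:
        members.append(
            Individual(
                id=c, family_id=fam_id,
                sex="male" if rng.random() < 0.5 else "female",
                father_id=father, mother_id=mother,
                affection=affection[c], is_proband=(c == proband),
            )
        )
    return Pedigree(family_id=fam_id, members=members), dosage, fam_id


def _background_sites(spec: CohortSpec, gene: str, gene_idx: int):
    """Sample background site definitions for one gene (counts + MAFs)."""
    rng = _stream(spec.seed, 2, gene)
    n_q = int(rng.poisson(spec.background_rate))
    n_nq = int(rng.poisson(spec.background_nonqualifying_rate))
    sites = []
    base_pos = (gene_idx + 1) * 1_000_000
    for j in range(n_q + n_nq):
        qualifying = j < n_q
        maf = _draw_maf(rng, spec)
        if qualifying:
            ann = Annotation(
                consequence="missense", maf_by_db={"ExAC_Fin": maf},
                sift="deleterious", polyphen2="damaging",
                mutationtaster="disease_causing", cadd=float(np.round(20 + 15 * rng.random(), 2)),
            )
        elif rng.random() < 0.5:
            ann = Annotation(consequence="synonymous", maf_by_db={"ExAC_Fin": maf})
        else:
            ann = Annotation(
                consequence="missense", maf_by_db={"ExAC_Fin": maf},
                sift="tolerated", polyphen2="benign",
            )
        sites.append((base_pos + 100 * (j + 1), maf, qualifying, ann))
    return sites


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort, deterministic given the seed.

    Case families segregate the planted variants Mendelianly; background
    variants are sampled independently per individual at their spec'd MAFs;
    the reference table is drawn from the same per-gene qualifying
    frequencies (the planted gene's count is *not* inflated — enrichment
    exists only in cases). The returned truth table is checked against the
    emitted genotypes before return.
    """
    pedigrees: list[Pedigree] = []
    planted_dosage: dict[str, int] = {}
    family_ids: list[str] = []
    family_variant_idx: dict[str, int] = {}
    for i in range(spec.n_case_families):
        carrier = spec.planted_gene is not None and i < spec.n_carrier_families
        ped, dosage, fam_id = _make_family(spec, i, carrier)
        pedigrees.append(ped)
        family_ids.append(fam_id)
        if carrier:
            planted_dosage.update(dosage)
            family_variant_idx[fam_id] = i % max(1, spec.n_planted_variants)
        else:
            planted_dosage.update({m: 0 for m in dosage})

    controls: list[Individual] = []
    for i in range(spec.n_cohort_controls):
        cid = f"CTRL{i + 1:03d}"
        controls.append(
            Individual(id=cid, family_id=cid, affection="unaffected", role="cohort_control")
        )
        pedigrees.append(Pedigree(family_id=cid, members=[controls[-1]]))
        planted_dosage[cid] = 0

    all_samples = [m.id for ped in pedigrees for m in ped.members]
    sample_family = {m.id: ped.family_id for ped in pedigrees for m in ped.members}

    records: list[VariantRecord] = []
    annotations: dict[tuple, Annotation] = {}
    reference: dict[str, ReferenceGeneCounts] = {}
    total_ref_alleles = 2 * spec.n_reference_individuals
    planted_keys: list[tuple] = []

    # planted variants: Mendelian within carrier families, absent elsewhere
    if spec.planted_gene is not None:
        gene_idx = spec.genes.index(spec.planted_gene)
        for v in range(spec.n_planted_variants):
            pos = (gene_idx + 1) * 1_000_000 + 500_000 + v
            key = ("1", pos, "A", "G")
            genotypes = {}
            for s in all_samples:
                fam = sample_family[s]
                dose = planted_dosage.get(s, 0) if family_variant_idx.get(fam) == v else 0
                genotypes[s] = GenotypeCall(_GT[dose], gq=99, dp=30)
            records.append(VariantRecord("1", pos, "A", "G", spec.planted_gene, genotypes))
            annotations[key] = Annotation(
                consequence="missense", maf_by_db={},
                sift="deleterious", polyphen2="damaging",
                mutationtaster="disease_causing", cadd=28.0,
            )
            planted_keys.append(key)

    # background variation and the matching reference table; one genotype
    # stream per (gene, family unit), consumed site by site in gene order
    units: dict[str, list[str]] = {}
    for s in all_samples:
        units.setdefault(sample_family[s], []).append(s)
    unit_ids = family_ids + [c.id for c in controls]
    for gene_idx, gene in enumerate(spec.genes):
        sites = _background_sites(spec, gene, gene_idx)
        unit_rngs = {u: _stream(spec.seed, 4, gene, u) for u in unit_ids} if sites else {}
        q_freq = 0.0
        for pos, maf, qualifying, ann in sites:
            genotypes: dict[str, GenotypeCall] = {}
            for u in unit_ids:
                members = units[u]
                doses = unit_rngs[u].binomial(2, maf, size=len(members))
                for s, dose in zip(members, doses):
                    genotypes[s] = GenotypeCall(_GT[int(dose)], gq=99, dp=30)
            key = ("1", pos, "C", "T")
            records.append(VariantRecord("1", pos, "C", "T", gene, genotypes))
            annotations[key] = ann
            if qualifying:
                q_freq += maf
        ref_rng = _stream(spec.seed, 5, gene)
        count = int(ref_rng.binomial(total_ref_alleles, min(1.0, q_freq)))
        reference[gene] = ReferenceGeneCounts(gene, count, total_ref_alleles)

    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    truth = TruthTable(
        planted_gene=spec.planted_gene,
        planted_variants=planted_keys,
        carrier_status={s: planted_dosage.get(s, 0) > 0 for s in all_samples},
        affection={m.id: m.affection for ped in pedigrees for m in ped.members},
        reference_counts={g: c.qualifying_allele_count for g, c in reference.items()},
    )
    truth.check_consistency(records)
    return Cohort(
        records=records, annotations=annotations, pedigrees=pedigrees,
        reference=reference, panel=frozenset(spec.genes), truth=truth,
    )


def simulate_reference_counts(spec: CohortSpec) -> dict[str, ReferenceGeneCounts]:
    """Reference table alone, identical to the one ``generate_cohort`` emits."""
    reference = {}
    total = 2 * spec.n_reference_individuals
    for gene_idx, gene in enumerate(spec.genes):
        q_freq = sum(maf for _, maf, qual, _ in _background_sites(spec, gene, gene_idx) if qual)
        rng = _stream(spec.seed, 5, gene)
        count = int(rng.binomial(total, min(1.0, q_freq)))
        reference[gene] = ReferenceGeneCounts(gene, count, total)
    return reference


# ---------------------------------------------------------------------------
# Deterministic worked-example fixture
# ---------------------------------------------------------------------------

_FOCAL_GENE = "EAP1"
_FIXTURE_CHROM = "14"


def _fixture_pedigrees() -> list[Pedigree]:
    """Four case families (affected parent + affected proband + unaffected
    mother and sibling) and 35 unrelated cohort controls."""
    peds = []
    for i in range(1, 5):
        fam = f"F{i}"
        peds.append(Pedigree(family_id=fam, members=[
            Individual(id=f"{fam}_FA", family_id=fam, sex="male", affection="affected"),
            Individual(id=f"{fam}_MO", family_id=fam, sex="female", affection="unaffected"),
            Individual(id=f"{fam}_PB", family_id=fam, sex="male", father_id=f"{fam}_FA",
                       mother_id=f"{fam}_MO", affection="affected", is_proband=True),
            Individual(id=f"{fam}_SB", family_id=fam, sex="female", father_id=f"{fam}_FA",
                       mother_id=f"{fam}_MO", affection="unaffected"),
        ]))
    for i in range(1, 36):
        cid = f"CTRL{i:03d}"
        peds.append(Pedigree(family_id=cid, members=[
            Individual(id=cid, family_id=cid, affection="unaffected", role="cohort_control"),
        ]))
    return peds


def _ann(consequence, mafs=None, sift="unavailable", polyphen2="unavailable",
         mutationtaster="unavailable", cadd=None) -> Annotation:
    return Annotation(consequence=consequence, maf_by_db=mafs or {},
                      sift=sift, polyphen2=polyphen2,
                      mutationtaster=mutationtaster, cadd=cadd)


#: (pos, ref, alt, rsid, annotation, het carriers) for the 12 focal-gene variants.
#: Four decoys fall at the consequence/MAF/deleteriousness stages; five
#: survivors of those stages sit in multiple cohort controls; the last three
#: reach segregation, where one (v3, in two pedigrees) fails in family F3.
_FIXTURE_VARIANTS = [
    # decoys
    (77490100, "G", "A", None, _ann("synonymous", {"ExAC_Fin": 0.001}), ["F1_PB"]),
    (77490200, "C", "T", None, _ann("missense", {"ExAC_Fin": 0.05}, "deleterious", "damaging",
                                    "disease_causing", 24.0), ["F2_PB"]),
    (77490300, "T", "C", None, _ann("missense", {"ExAC_Fin": 0.003}, "tolerated", "damaging"),
     ["F3_PB"]),
    (77490400, "A", "G", None, _ann("missense", {"ExAC_Fin": 0.002}, "deleterious", "benign"),
     ["F4_PB"]),
    # rare, predicted pathogenic, but present in multiple cohort controls
    (77490500, "G", "T", None, _ann("missense", {"ExAC_Fin": 0.004}, "deleterious", "damaging",
                                    "disease_causing", 23.1), ["F1_PB", "CTRL001", "CTRL002"]),
    (77490600, "C", "A", None, _ann("missense", {"ExAC_Fin": 0.002}, "deleterious", "damaging",
                                    "disease_causing", 25.4), ["F2_PB", "CTRL003", "CTRL004"]),
    (77490700, "A", "T", None, _ann("missense", {"ExAC_Fin": 0.008}, "deleterious", "damaging",
                                    "polymorphism", 21.7), ["F3_PB", "CTRL005", "CTRL006"]),
    (77490800, "T", "G", None, _ann("stop_gained", {"ExAC_Fin": 0.001}), ["F4_PB", "CTRL007",
                                                                          "CTRL008"]),
    (77490900, "G", "C", None, _ann("missense", {}, "deleterious", "damaging",
                                    "disease_causing", 26.0), ["F1_FA", "CTRL009", "CTRL010"]),
    # the three variants of interest
    (77491828, "A", "C", "rs760847179",
     _ann("missense", {"ExAC_Fin": 0.004}, "deleterious", "damaging", "disease_causing", 23.5),
     ["F2_FA", "F2_PB", "CTRL011"]),
    (77492500, "C", "G", None,
     _ann("missense", {"ExAC_Fin": 0.001}, "deleterious", "damaging", "disease_causing", 24.8),
     ["F3_PB", "F4_FA", "F4_PB"]),  # F3's affected father lacks it: fails segregation
    (77493473, "AGCG", "A", None, _ann("inframe_indel"), ["F1_FA", "F1_PB"]),  # novel deletion
]

_FIXTURE_REFERENCE = {
    _FOCAL_GENE: (3, 66000),
    "GENE_B": (150, 66000),
    "GENE_C": (30, 66000),
    "GENE_D": (0, 66000),
}


def make_worked_example_fixture() -> Cohort:
    """The deterministic worked-example cohort (no randomness involved).

    One focal gene, 12 candidate variants across 4 case pedigrees and 35
    controls. The funnel realises 12 -> 8 (after deleteriousness) -> 3
    (after control exclusion removes 5) -> 2 cohort-level segregating
    variants; the focal gene is the run's final candidate. Byte-identical
    across runs when written to disk.
    """
    pedigrees = _fixture_pedigrees()
    all_samples = [m.id for ped in pedigrees for m in ped.members]
    records: list[VariantRecord] = []
    annotations: dict[tuple, Annotation] = {}
    for pos, ref, alt, rsid, ann, carriers in _FIXTURE_VARIANTS:
        carrier_set = set(carriers)
        genotypes = {
            s: GenotypeCall("0/1" if s in carrier_set else "0/0", gq=99, dp=30)
            for s in all_samples
        }
        rec = VariantRecord(_FIXTURE_CHROM, pos, ref, alt, _FOCAL_GENE, genotypes,
                            variant_id=rsid)
        records.append(rec)
        annotations[rec.key] = ann
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    reference = {
        g: ReferenceGeneCounts(g, qac, tot) for g, (qac, tot) in sorted(_FIXTURE_REFERENCE.items())
    }
    seg_keys = [(_FIXTURE_CHROM, 77491828, "A", "C"), (_FIXTURE_CHROM, 77493473, "AGCG", "A")]
    truth = TruthTable(
        planted_gene=_FOCAL_GENE,
        planted_variants=seg_keys,
        carrier_status={s: any(s in {c for c in v[5]} and (_FIXTURE_CHROM, v[0], v[1], v[2]) in seg_keys
                               for v in _FIXTURE_VARIANTS) for s in all_samples},
        affection={m.id: m.affection for ped in pedigrees for m in ped.members},
        reference_counts={g: qac for g, (qac, _) in _FIXTURE_REFERENCE.items()},
    )
    truth.check_consistency(records)
    return Cohort(
        records=records, annotations=annotations, pedigrees=pedigrees,
        reference=reference, panel=frozenset(_FIXTURE_REFERENCE), truth=truth,
    )
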