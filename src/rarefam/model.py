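"""Core domain types for family-based rare-variant discovery.

The pipeline operates on a small set of validated value objects: normalized
biallelic variants with per-sample genotype calls, a pedigree graph with
affection status and proband flags, pre-computed functional annotations,
per-gene reference-population qualifying-carrier counts, and the audit
records produced by a run (filter funnel, burden results, segregation
verdicts).

All loaders validate invariants eagerly and raise ``ValidationError`` on
breach; invalid inputs are never silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "ValidationError",
    "GenotypeCall",
    "VariantRecord",
    "Annotation",
    "Individual",
    "Pedigree",
    "ReferenceGeneCounts",
    "FilterTrace",
    "GeneBurdenResult",
    "SegregationCall",
    "variant_key",
    "CONSEQUENCES",
    "PROTEIN_ALTERING",
    "SCORELESS_CONSEQUENCES",
]


class ValidationError(ValueError):
    """An input violated a documented invariant of the data model."""


#: Controlled consequence vocabulary.
CONSEQUENCES = frozenset(
    {
        "missense",
        "inframe_indel",
        "frameshift",
        "stop_gained",
        "stop_lost",
        "splice_canonical",
        "synonymous",
        "other",
    }
)

#: Protein-altering classes (default set retained by the consequence filter).
PROTEIN_ALTERING = frozenset(
    {"missense", "inframe_indel", "frameshift", "stop_gained", "stop_lost", "splice_canonical"}
)

#: Classes for which SIFT/PolyPhen-2 emit no score; they qualify on class alone.
SCORELESS_CONSEQUENCES = frozenset(
    {"inframe_indel", "frameshift", "stop_gained", "stop_lost", "splice_canonical"}
)

_GT_VALUES = frozenset({"0/0", "0/1", "1/1", "./."})
_SIFT = frozenset({"deleterious", "tolerated", "unavailable"})
_POLYPHEN = frozenset({"damaging", "benign", "unavailable"})
_MUTTASTER = frozenset({"disease_causing", "polymorphism", "unavailable"})
_AFFECTION = frozenset({"affected", "unaffected", "unknown"})
_ROLE = frozenset({"family_member", "cohort_control"})


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype call with its quality metrics.

    ``gt`` is one of ``0/0``, ``0/1``, ``1/1``, ``./.`` (unphased, alt index
    recoded against the record's single alt allele). ``gq``/``dp`` are the
    genotype quality and read depth, ``None`` when absent from the VCF.
    """

    gt: str
    gq: Optional[int] = None
    dp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gt not in _GT_VALUES:
            raise ValidationError(f"genotype {self.gt!r} not in {sorted(_GT_VALUES)}")

    @property
    def is_carrier(self) -> bool:
        """True iff at least one alt allele is called."""
        return self.gt in ("0/1", "1/1")

    @property
    def is_missing(self) -> bool:
        return self.gt == "./."

    @property
    def alt_dosage(self) -> int:
        return {"0/0": 0, "0/1": 1, "1/1": 2, "./.": 0}[self.gt]


@dataclass(frozen=True)
class Annotation:
    """Pre-computed functional annotation for one variant.

    Consequence class, per-database minor allele frequencies, and the
    categorical calls of the standard pathogenicity predictors. These are
    consumed as inputs; the pipeline never computes them.
    """

    consequence: str
    maf_by_db: Mapping[str, float] = field(default_factory=dict)
    sift: str = "unavailable"
    polyphen2: str = "unavailable"
    mutationtaster: str = "unavailable"
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        if self.sift not in _SIFT:
            raise ValidationError(f"unknown SIFT call {self.sift!r}")
        if self.polyphen2 not in _POLYPHEN:
            raise ValidationError(f"unknown PolyPhen-2 call {self.polyphen2!r}")
        if self.mutationtaster not in _MUTTASTER:
            raise ValidationError(f"unknown MutationTaster call {self.mutationtaster!r}")
        for db, maf in self.maf_by_db.items():
            if not (0.0 <= maf <= 1.0):
                raise ValidationError(f"MAF for {db!r} outside [0,1]: {maf}")
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"negative CADD score: {self.cadd}")

    @property
    def max_maf(self) -> float:
        """Maximum MAF across databases; 0.0 when unobserved everywhere (novel)."""
        return max(self.maf_by_db.values(), default=0.0)


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic variant with per-sample genotypes.

    Coordinates are 1-based fully-closed per VCF convention; indels are
    assumed left-aligned upstream. Multi-allelic sites are decomposed into
    one record per alt by the reader.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    genotypes: Mapping[str, GenotypeCall]
    variant_id: Optional[str] = None
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if "," in self.alt:
            raise ValidationError(f"record must be biallelic, got alt {self.alt!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> list[str]:
        """Sample IDs carrying at least one alt allele, in insertion order."""
        return [s for s, g in self.genotypes.items() if g.is_carrier]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Canonical (chrom, pos, ref, alt) key used to join VCF and sidecar rows."""
    return (chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    sex: str = "unknown"  # "male" | "female" | "unknown"
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    affection: str = "unknown"
    is_proband: bool = False
    role: str = "family_member"

    def __post_init__(self) -> None:
        if self.affection not in _AFFECTION:
            raise ValidationError(f"unknown affection {self.affection!r}")
        if self.role not in _ROLE:
            raise ValidationError(f"unknown role {self.role!r}")


@dataclass
class Pedigree:
    """A family graph. Case families carry exactly one proband."""

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate individual IDs in family {self.family_id}: {dupes}")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise ValidationError(
                        f"{m.id} references parent {pid!r} absent from family {self.family_id}"
                    )
        self._check_acyclic()
        if self.is_case_family:
            n_prob = sum(m.is_proband for m in self.members)
            if n_prob != 1:
                raise ValidationError(
                    f"case family {self.family_id} must have exactly one proband, found {n_prob}"
                )

    def _check_acyclic(self) -> None:
        parents = {m.id: [p for p in (m.father_id, m.mother_id) if p is not None] for m in self.members}
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {i: WHITE for i in parents}
        for start in parents:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(parents[start]))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                for nxt in it:
                    if color[nxt] == GRAY:
                        raise ValidationError(
                            f"parent cycle in family {self.family_id} involving {nxt!r}"
                        )
                    if color[nxt] == WHITE:
                        color[nxt] = GRAY
                        stack.append((nxt, iter(parents[nxt])))
                        break
                else:
                    color[node] = BLACK
                    stack.pop()

    @property
    def is_case_family(self) -> bool:
        return any(m.role == "family_member" for m in self.members)

    @property
    def proband(self) -> Optional[Individual]:
        for m in self.members:
            if m.is_proband:
                return m
        return None

    def member(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.id == individual_id:
                return m
        raise KeyError(individual_id)


@dataclass(frozen=True)
class ReferenceGeneCounts:
    """Qualifying allele counts for one gene in the population reference.

    ``qualifying_allele_count`` sums alternate allele counts of
    reference-population variants that are rare (MAF < 2.5%) and called
    deleterious by both SIFT and PolyPhen-2. ``total_alleles`` is twice the
    number of reference individuals.
    """

    gene: str
    qualifying_allele_count: int
    total_alleles: int

    def __post_init__(self) -> None:
        if self.qualifying_allele_count < 0:
            raise ValidationError("qualifying_allele_count must be non-negative")
        if self.total_alleles <= 0:
            raise ValidationError("total_alleles must be positive")
        if self.total_alleles % 2 != 0:
            raise ValidationError("total_alleles must be even (2 x individuals)")
        if self.qualifying_allele_count > self.total_alleles:
            raise ValidationError(
                f"{self.gene}: qualifying_allele_count {self.qualifying_allele_count} "
                f"exceeds total_alleles {self.total_alleles}"
            )


@dataclass
class FilterTrace:
    """Ordered funnel of (stage, surviving variants, surviving genes).

    Variant counts must be non-increasing along the declared stage order;
    this is checked on append so a buggy stage fails loudly.
    """

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    config_hash: str = ""
    seed: Optional[int] = None

    def append(self, stage: str, n_variants: int, n_genes: int) -> None:
        if n_variants < 0 or n_genes < 0:
            raise ValidationError("trace counts must be non-negative")
        if self.stages and n_variants > self.stages[-1][1]:
            raise ValidationError(
                f"funnel not monotone: {stage} has {n_variants} variants, "
                f"previous stage {self.stages[-1][0]} had {self.stages[-1][1]}"
            )
        self.stages.append((stage, n_variants, n_genes))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FilterTrace):
            return NotImplemented
        return (
            self.stages == other.stages
            and self.config_hash == other.config_hash
            and self.seed == other.seed
        )


@dataclass(frozen=True)
class GeneBurdenResult:
    """Per-gene 2x2 burden table and test results.

    a/b: case probands with/without a qualifying variant in the gene;
    c/d: reference-population carriers/non-carriers. The odds ratio uses a
    Haldane 0.5 correction when any cell is zero.
    """

    gene: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_raw: float
    p_adjusted: float
    candidate: bool
    rank: int

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            if v < 0:
                raise ValidationError(f"cell {name} negative: {v}")
        if not (0.0 < self.p_raw <= 1.0):
            raise ValidationError(f"p_raw outside (0,1]: {self.p_raw}")
        if not (0.0 < self.p_adjusted <= 1.0):
            raise ValidationError(f"p_adjusted outside (0,1]: {self.p_adjusted}")
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValidationError("p_adjusted must be >= p_raw")


@dataclass(frozen=True)
class SegregationCall:
    """Verdict for one variant in one family under a segregation policy.

    ``detail`` keeps the counts the verdict was derived from so the call is
    recomputable: affected carriers, affected non-carriers, unaffected
    carriers, and affected members with missing genotypes.
    """

    variant: tuple[str, int, str, str]
    family_id: str
    verdict: str  # SEGREGATES | FAILS | INDETERMINATE
    affected_carriers: int
    affected_noncarriers: int
    unaffected_carriers: int
    untyped_affected: int

    def __post_init__(self) -> None:
        if self.verdict not in ("SEGREGATES", "FAILS", "INDETERMINATE"):
            raise ValidationError(f"unknown verdict {self.verdict!r}")


def sample_manifest(pedigrees: Iterable[Pedigree]) -> dict[str, str]:
    """Map every individual ID to its cohort role across pedigrees."""
    manifest: dict[str, str] = {}
    for ped in pedigrees:
        for m in ped.members:
            if m.id in manifest:
                raise ValidationError(f"individual {m.id} appears in more than one family")
            manifest[m.id] = m.role
    return manifest
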