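"""Autosomal-dominant co-segregation classification.

For each candidate variant and each pedigree, classify whether the variant
tracks with affection status under a dominant model: every genotyped
affected member must carry the variant (heterozygous expected) and
unaffected carriers must not exceed a configurable tolerance. Members with
unknown phenotype never influence the verdict. A family whose affected
members are not all genotyped is INDETERMINATE under the default policy
rather than silently counted either way.

Cohort-level aggregation calls a variant "segregating" when it SEGREGATES
in at least one family and FAILS in none of the families where it occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import Pedigree, SegregationCall, ValidationError, VariantRecord

__all__ = ["SegregationPolicy", "classify_segregation", "cohort_segregation_summary"]

log = logging.getLogger(__name__)

_SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass(frozen=True)
class SegregationPolicy:
    """Clauses of the dominant-segregation rule.

    ``require_all_affected_carriers``: with the default True, an affected
    member whose genotype is missing blocks a SEGREGATES verdict (handled
    per ``missing_genotype_handling``). ``allow_unaffected_carriers`` is a
    tolerance for incomplete penetrance (default 0: any unaffected carrier
    disqualifies). Unknown-phenotype members are always ignored. Expected
    zygosity is heterozygous; homozygous-alt affected members still count
    as carriers but are logged.
    """

    require_all_affected_carriers: bool = True
    allow_unaffected_carriers: int = 0
    missing_genotype_handling: str = "indeterminate"  # | "fail" | "ignore"
    include_sex_chromosomes: bool = False

    def __post_init__(self) -> None:
        if self.allow_unaffected_carriers < 0:
            raise ValidationError("allow_unaffected_carriers must be >= 0")
        if self.missing_genotype_handling not in ("indeterminate", "fail", "ignore"):
            raise ValidationError(
                f"unknown missing_genotype_handling {self.missing_genotype_handling!r}"
            )


def classify_segregation(
    variant: VariantRecord, pedigree: Pedigree, policy: SegregationPolicy = SegregationPolicy()
) -> SegregationCall:
    """Classify one variant's segregation in one pedigree.

    Verdicts: SEGREGATES when every genotyped affected member carries the
    variant, no affected genotype is missing (unless the policy ignores
    missing genotypes), and unaffected carriers are within tolerance; FAILS
    when a genotyped affected member is a non-carrier, unaffected carriers
    exceed tolerance, or (under ``missing_genotype_handling="fail"``) an
    affected genotype is missing; INDETERMINATE otherwise — no genotyped
    affected member, or missing affected genotypes under the default policy.

    Raises ``KeyError``-like ``ValidationError`` when no pedigree member has
    a genotype in the variant's matrix.
    """
    if not policy.include_sex_chromosomes and variant.chrom in _SEX_CHROMS:
        raise ValidationError(
            f"variant {variant.key} is on a sex chromosome; the dominant model "
            "is autosomal (set include_sex_chromosomes to override)"
        )
    member_ids = [m.id for m in pedigree.members]
    if not any(m in variant.genotypes for m in member_ids):
        raise ValidationError(
            f"no member of family {pedigree.family_id} is present in the "
            f"genotype matrix of variant {variant.key}"
        )

    affected_carriers = 0
    affected_noncarriers = 0
    unaffected_carriers = 0
    untyped_affected = 0
    for m in pedigree.members:
        g = variant.genotypes.get(m.id)
        if m.affection == "unknown":
            continue
        if m.affection == "affected":
            if g is None or g.is_missing:
                untyped_affected += 1
            elif g.is_carrier:
                affected_carriers += 1
                if g.gt == "1/1":
                    log.warning(
                        "affected member %s is homozygous for %s; dominant trait "
                        "expected heterozygous carriers", m.id, variant.key,
                    )
            else:
                affected_noncarriers += 1
        else:  # unaffected
            if g is not None and g.is_carrier:
                unaffected_carriers += 1

    if affected_noncarriers > 0 or unaffected_carriers > policy.allow_unaffected_carriers:
        verdict = "FAILS"
    elif untyped_affected > 0 and policy.missing_genotype_handling == "fail":
        verdict = "FAILS"
    elif affected_carriers == 0:
        verdict = "INDETERMINATE"
    elif untyped_affected > 0 and policy.require_all_affected_carriers \
            and policy.missing_genotype_handling == "indeterminate":
        verdict = "INDETERMINATE"
    else:
        verdict = "SEGREGATES"

    return SegregationCall(
        variant=variant.key,
        family_id=pedigree.family_id,
        verdict=verdict,
        affected_carriers=affected_carriers,
        affected_noncarriers=affected_noncarriers,
        unaffected_carriers=unaffected_carriers,
        untyped_affected=untyped_affected,
    )


def _families_with_variant(variant: VariantRecord, pedigrees: Sequence[Pedigree]) -> list[Pedigree]:
    """Case families in which at least one member carries the variant."""
    out = []
    for ped in pedigrees:
        if not ped.is_case_family:
            continue
        if any(
            (g := variant.genotypes.get(m.id)) is not None and g.is_carrier
            for m in ped.members
        ):
            out.append(ped)
    return out


def cohort_segregation_summary(
    variants: Sequence[VariantRecord],
    pedigrees: Sequence[Pedigree],
    policy: SegregationPolicy = SegregationPolicy(),
) -> tuple[dict[tuple, list[SegregationCall]], list[tuple]]:
    """Per-variant verdicts across all families carrying each variant.

    Returns ``(calls, segregating_keys)`` where ``calls`` maps variant key
    to the per-family ``SegregationCall`` list and ``segregating_keys``
    lists (sorted) the variants that SEGREGATE in at least one family with
    no FAILS anywhere. Families where the verdict is INDETERMINATE count
    neither for nor against.
    """
    calls: dict[tuple, list[SegregationCall]] = {}
    segregating: list[tuple] = []
    for variant in variants:
        fam_calls = [
            classify_segregation(variant, ped, policy)
            for ped in _families_with_variant(variant, pedigrees)
        ]
        calls[variant.key] = fam_calls
        verdicts = [c.verdict for c in fam_calls]
        if "FAILS" not in verdicts and "SEGREGATES" in verdicts:
            segregating.append(variant.key)
    return calls, sorted(set(segregating))
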