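"""The staged variant-filtering funnel.

Variants from a called multi-sample VCF are pushed through a fixed cascade
of filters — quality control, protein-altering consequence, rarity (MAF),
predicted deleteriousness, case-control exclusion, multi-family support,
and biological-relevance panel membership — with a full audit trace of how
many variants and genes survive each stage.

Each per-variant filter is a pure predicate, so the surviving set is
invariant to input record order, and survivor counts are non-increasing
along the cascade by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Annotation,
    FilterTrace,
    Pedigree,
    PROTEIN_ALTERING,
    SCORELESS_CONSEQUENCES,
    ValidationError,
    VariantRecord,
)

__all__ = ["CascadeConfig", "QCConfig", "run_cascade", "qc_filter", "consequence_filter",
           "maf_filter", "deleteriousness_filter", "case_control_exclusion",
           "multi_family_filter", "panel_filter", "STAGE_ORDER"]

#: Fixed stage order of the cascade.
STAGE_ORDER = ("qc", "consequence", "maf", "deleteriousness", "case_control",
               "multi_family", "panel")


@dataclass(frozen=True)
class QCConfig:
    require_pass_filter: bool = True
    min_gq: int = 20
    min_dp: int = 8


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable thresholds of the funnel.

    Defaults implement the discovery settings: rarity below 2.5% in every
    database, protein-altering consequences only, deleterious by both SIFT
    and PolyPhen-2 (score-less classes qualify on consequence alone),
    exclusion of variants carried by more than one cohort control, genes
    supported by more than one proband, and an optional relevance panel.
    """

    maf_threshold: float = 0.025
    qc: QCConfig = field(default_factory=QCConfig)
    allowed_consequences: frozenset = PROTEIN_ALTERING
    deleterious_mode: str = "both_sift_polyphen"  # | "any_two" | "cadd_ge"
    cadd_cutoff: float = 20.0
    max_control_carriers: int = 1
    min_probands_per_gene: int = 2
    panel: Optional[frozenset] = None  # None disables the panel stage
    missing_annotation: str = "error"  # | "drop"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValidationError(f"maf_threshold outside (0,1]: {self.maf_threshold}")
        if self.max_control_carriers < 0:
            raise ValidationError("max_control_carriers must be >= 0")
        if self.min_probands_per_gene < 1:
            raise ValidationError("min_probands_per_gene must be >= 1")
        if self.deleterious_mode not in ("both_sift_polyphen", "any_two", "cadd_ge"):
            raise ValidationError(f"unknown deleterious_mode {self.deleterious_mode!r}")
        if self.missing_annotation not in ("error", "drop"):
            raise ValidationError(f"unknown missing_annotation {self.missing_annotation!r}")

    def hash(self) -> str:
        payload = {
            "maf_threshold": self.maf_threshold,
            "qc": [self.qc.require_pass_filter, self.qc.min_gq, self.qc.min_dp],
            "allowed_consequences": sorted(self.allowed_consequences),
            "deleterious_mode": self.deleterious_mode,
            "cadd_cutoff": self.cadd_cutoff,
            "max_control_carriers": self.max_control_carriers,
            "min_probands_per_gene": self.min_probands_per_gene,
            "panel": sorted(self.panel) if self.panel is not None else None,
            "missing_annotation": self.missing_annotation,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def qc_filter(record: VariantRecord, config: CascadeConfig) -> bool:
    """Keep iff FILTER is PASS (when required) and at least one carrier
    genotype meets the GQ and DP minima."""
    if config.qc.require_pass_filter and record.filter_status != "PASS":
        return False
    for g in record.genotypes.values():
        if g.is_carrier:
            gq_ok = g.gq is None or g.gq >= config.qc.min_gq
            dp_ok = g.dp is None or g.dp >= config.qc.min_dp
            if gq_ok and dp_ok:
                return True
    return False


def consequence_filter(annotation: Annotation, config: CascadeConfig) -> bool:
    return annotation.consequence in config.allowed_consequences


def maf_filter(annotation: Annotation, config: CascadeConfig) -> bool:
    """Keep iff the maximum MAF over all databases where the variant is
    observed is below the threshold. Absent everywhere (novel) counts as 0."""
    return annotation.max_maf < config.maf_threshold


def deleteriousness_filter(annotation: Annotation, config: CascadeConfig) -> bool:
    """Predicted-deleteriousness rule.

    Indels, nonsense and canonical-splice variants carry no SIFT/PolyPhen
    score and qualify on consequence class alone. For scored classes the
    default mode requires SIFT deleterious AND PolyPhen-2 damaging;
    ``any_two`` requires two of {SIFT, PolyPhen-2, MutationTaster} calling
    damage; ``cadd_ge`` requires CADD at or above the cutoff.
    """
    if annotation.consequence in SCORELESS_CONSEQUENCES:
        return True
    if config.deleterious_mode == "both_sift_polyphen":
        return annotation.sift == "deleterious" and annotation.polyphen2 == "damaging"
    if config.deleterious_mode == "any_two":
        votes = (
            (annotation.sift == "deleterious")
            + (annotation.polyphen2 == "damaging")
            + (annotation.mutationtaster == "disease_causing")
        )
        return votes >= 2
    return annotation.cadd is not None and annotation.cadd >= config.cadd_cutoff


def case_control_exclusion(
    record: VariantRecord, manifest: Mapping[str, str], config: CascadeConfig
) -> bool:
    """Keep iff the number of cohort-control samples carrying at least one
    alt allele does not exceed ``max_control_carriers`` (default 1: variants
    present in more than one unaffected control are excluded)."""
    n_control_carriers = sum(
        1
        for s, g in record.genotypes.items()
        if g.is_carrier and manifest.get(s) == "cohort_control"
    )
    return n_control_carriers <= config.max_control_carriers


def multi_family_filter(
    gene: str,
    surviving: Sequence[VariantRecord],
    pedigrees: Sequence[Pedigree],
    config: CascadeConfig,
) -> bool:
    """Keep the gene iff distinct probands carrying at least one surviving
    variant in it number at least ``min_probands_per_gene`` (default 2,
    i.e. present in more than one proband)."""
    proband_ids = {p.proband.id for p in pedigrees if p.proband is not None}
    carriers: set[str] = set()
    for rec in surviving:
        if rec.gene != gene:
            continue
        for s, g in rec.genotypes.items():
            if g.is_carrier and s in proband_ids:
                carriers.add(s)
    return len(carriers) >= config.min_probands_per_gene


def panel_filter(gene: str, config: CascadeConfig) -> bool:
    """Keep iff the gene is on the relevance panel; pass-through if disabled."""
    return config.panel is None or gene in config.panel


def _count(records: Sequence[VariantRecord]) -> tuple[int, int]:
    return len(records), len({r.gene for r in records})


def run_cascade(
    records: Sequence[VariantRecord],
    annotations: Mapping[tuple, Annotation],
    pedigrees: Sequence[Pedigree],
    config: CascadeConfig,
    manifest: Optional[Mapping[str, str]] = None,
    seed: Optional[int] = None,
) -> tuple[list[VariantRecord], FilterTrace]:
    """Run the full funnel in the fixed stage order and record the trace.

    ``annotations`` maps (chrom, pos, ref, alt) to an ``Annotation``. A
    record without an annotation raises by default (``missing_annotation=
    "drop"`` silently removes it at the consequence stage instead).
    Survivors are returned sorted by (chrom, pos, alt).
    """
    if manifest is None:
        from .model import sample_manifest

        manifest = sample_manifest(pedigrees)

    def ann_of(rec: VariantRecord) -> Optional[Annotation]:
        ann = annotations.get(rec.key)
        if ann is None and config.missing_annotation == "error":
            raise ValidationError(f"no annotation for variant {rec.key}")
        return ann

    trace = FilterTrace(config_hash=config.hash(), seed=seed)
    current = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))
    trace.append("input", *_count(current))

    current = [r for r in current if qc_filter(r, config)]
    trace.append("qc", *_count(current))

    current = [r for r in current if (a := ann_of(r)) is not None and consequence_filter(a, config)]
    trace.append("consequence", *_count(current))

    current = [r for r in current if maf_filter(annotations[r.key], config)]
    trace.append("maf", *_count(current))

    current = [r for r in current if deleteriousness_filter(annotations[r.key], config)]
    trace.append("deleteriousness", *_count(current))

    current = [r for r in current if case_control_exclusion(r, manifest, config)]
    trace.append("case_control", *_count(current))

    genes = {r.gene for r in current}
    kept_genes = {g for g in genes if multi_family_filter(g, current, pedigrees, config)}
    current = [r for r in current if r.gene in kept_genes]
    trace.append("multi_family", *_count(current))

    kept_genes = {g for g in kept_genes if panel_filter(g, config)}
    current = [r for r in current if r.gene in kept_genes]
    trace.append("panel", *_count(current))

    return current, trace
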