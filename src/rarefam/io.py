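"""Readers and writers for the pipeline's file formats.

VCF v4.2 is read and written through :mod:`pysam`. The remaining formats
are deliberately plain: 6-column tab-separated PED with a companion proband
list, an annotation sidecar TSV keyed by (chrom, pos, ref, alt), a per-gene
reference-counts TSV, one-symbol-per-line gene panels, a results TSV, and a
key-value funnel report. Annotations live in the sidecar rather than VCF
INFO so the pipeline does not depend on any annotator's INFO dialect.

All writers are bit-stable: identical in-memory inputs produce
byte-identical files.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .model import (
    Annotation,
    FilterTrace,
    GenotypeCall,
    GeneBurdenResult,
    Individual,
    Pedigree,
    ReferenceGeneCounts,
    ValidationError,
    VariantRecord,
    variant_key,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_annotations",
    "write_annotations",
    "read_gene_reference",
    "write_gene_reference",
    "read_panel",
    "write_panel",
    "write_results",
    "read_results",
    "write_funnel",
    "read_funnel",
]

_PED_SEX = {"1": "male", "2": "female", "0": "unknown", "-9": "unknown"}
_PED_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_PED_AFF = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_PED_AFF_OUT = {"unaffected": "1", "affected": "2", "unknown": "0"}


def _format_gt(alleles: tuple, alt_index: int) -> str:
    """Recode a pysam GT tuple against one alt allele (1-based alt index)."""
    if alleles is None or all(a is None for a in alleles):
        return "./."
    if any(a is None for a in alleles):  # half-calls are treated as missing
        return "./."
    coded = sorted(1 if a == alt_index else 0 for a in alleles)
    return f"{coded[0]}/{coded[1]}"


def read_vcf(
    path: str,
    manifest: Mapping[str, str],
    gene_by_key: Optional[Mapping[tuple, str]] = None,
) -> list[VariantRecord]:
    """Read a multi-sample VCF into normalized biallelic records.

    Multi-allelic sites are decomposed into one record per alt allele with
    genotypes recoded against that alt (other alts count as reference, so
    total alt dosage per sample per site is preserved across the decomposed
    records). Records are returned sorted by (chrom, pos, alt).

    ``manifest`` maps sample ID -> cohort role and must be a subset of the
    VCF header samples. ``gene_by_key`` optionally assigns gene symbols by
    (chrom, pos, ref, alt); otherwise the GENE INFO field is used when
    present, else "".

    Raises ``ValidationError`` naming the sample when a manifest sample is
    absent, or naming the 1-based record index and locus when a genotype is
    malformed (pysam does not expose raw line numbers).
    """
    with pysam.VariantFile(path) as vcf:
        header_samples = set(vcf.header.samples)
        missing = sorted(set(manifest) - header_samples)
        if missing:
            raise ValidationError(f"manifest samples absent from VCF header: {missing}")
        samples = [s for s in vcf.header.samples if s in manifest]
        gene_info_declared = "GENE" in vcf.header.info
        records: list[VariantRecord] = []
        for idx, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if alt is None or alt in ("*", "<NON_REF>"):
                    continue
                genotypes: dict[str, GenotypeCall] = {}
                for s in samples:
                    call = rec.samples[s]
                    try:
                        gt = _format_gt(call.get("GT"), ai)
                    except (TypeError, ValueError) as exc:
                        raise ValidationError(
                            f"malformed genotype for sample {s} at record {idx} "
                            f"({rec.chrom}:{rec.pos}): {exc}"
                        ) from exc
                    gq = call.get("GQ")
                    dp = call.get("DP")
                    genotypes[s] = GenotypeCall(
                        gt=gt,
                        gq=None if gq is None else int(gq),
                        dp=None if dp is None else int(dp),
                    )
                key = variant_key(rec.chrom, rec.pos, rec.ref, alt)
                if gene_by_key is not None:
                    gene = gene_by_key.get(key, "")
                elif gene_info_declared:
                    gene = str(rec.info.get("GENE", ""))
                else:
                    gene = ""
                filters = list(rec.filter.keys())
                filter_status = ";".join(filters) if filters else "PASS"
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=gene,
                        genotypes=genotypes,
                        variant_id=rec.id,
                        filter_status=filter_status,
                    )
                )
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    return records


def write_vcf(records: Sequence[VariantRecord], path: str, sample_order: Sequence[str]) -> None:
    """Write records to an uncompressed VCF v4.2 with GT/GQ/DP per sample."""
    header = pysam.VariantHeader()
    contigs = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    for c in sorted(contigs):
        header.contigs.add(c)
    header.add_meta("INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "Gene symbol")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "GQ"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Genotype quality")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Read depth")])
    header.add_meta("FILTER", items=[("ID", "LowQual"), ("Description", "Low quality")])
    for s in sample_order:
        header.add_sample(s)
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in ordered:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
                id=r.variant_id,
            )
            rec.filter.add(r.filter_status if r.filter_status else "PASS")
            if r.gene:
                rec.info["GENE"] = r.gene
            for s in sample_order:
                g = r.genotypes.get(s, GenotypeCall("./."))
                if g.gt == "./.":
                    rec.samples[s]["GT"] = (None, None)
                else:
                    a, b = g.gt.split("/")
                    rec.samples[s]["GT"] = (int(a), int(b))
                if g.gq is not None:
                    rec.samples[s]["GQ"] = g.gq
                if g.dp is not None:
                    rec.samples[s]["DP"] = g.dp
            out.write(rec)


def read_ped(
    path: str,
    proband_ids: Optional[Iterable[str]] = None,
    control_family_prefix: str = "CTRL",
) -> list[Pedigree]:
    """Read a 6-column PED file into pedigrees grouped by family ID.

    Columns: family, individual, father (0 = founder), mother, sex
    (1=male, 2=female, 0/-9=unknown), affection (1=unaffected, 2=affected,
    0/-9=unknown). Probands are flagged from ``proband_ids`` when given
    (the recommended, explicit convention); otherwise the first affected
    non-founder of each case family, falling back to the first affected
    member. Families whose ID starts with ``control_family_prefix`` hold
    unrelated cohort controls.
    """
    rows: list[tuple[str, str, Optional[str], Optional[str], str, str]] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValidationError(f"{path}:{ln}: expected 6 tab-separated columns")
            fam, iid, fid, mid, sex, aff = parts
            if iid in seen_ids:
                raise ValidationError(f"{path}:{ln}: duplicate individual ID {iid!r}")
            seen_ids.add(iid)
            if sex not in _PED_SEX:
                raise ValidationError(f"{path}:{ln}: bad sex code {sex!r}")
            if aff not in _PED_AFF:
                raise ValidationError(f"{path}:{ln}: bad affection code {aff!r}")
            rows.append((fam, iid, fid if fid != "0" else None, mid if mid != "0" else None,
                         _PED_SEX[sex], _PED_AFF[aff]))

    probands = set(proband_ids) if proband_ids is not None else None
    by_family: dict[str, list[tuple]] = {}
    for row in rows:
        by_family.setdefault(row[0], []).append(row)

    pedigrees: list[Pedigree] = []
    for fam, fam_rows in by_family.items():
        is_control = fam.startswith(control_family_prefix)
        role = "cohort_control" if is_control else "family_member"
        fam_proband: Optional[str] = None
        if not is_control:
            if probands is not None:
                flagged = [r[1] for r in fam_rows if r[1] in probands]
                if len(flagged) > 1:
                    raise ValidationError(f"family {fam}: multiple probands flagged: {flagged}")
                fam_proband = flagged[0] if flagged else None
            if fam_proband is None:
                affected_children = [r[1] for r in fam_rows
                                     if r[5] == "affected" and (r[2] or r[3])]
                affected_any = [r[1] for r in fam_rows if r[5] == "affected"]
                if probands is not None:
                    raise ValidationError(f"family {fam}: no proband in the supplied list")
                fam_proband = (affected_children or affected_any or [None])[0]
                if fam_proband is None:
                    raise ValidationError(f"family {fam}: no affected member to take as proband")
        members = [
            Individual(
                id=iid, family_id=fam, sex=sex, father_id=fid, mother_id=mid,
                affection=aff, is_proband=(iid == fam_proband), role=role,
            )
            for fam, iid, fid, mid, sex, aff in fam_rows
        ]
        pedigrees.append(Pedigree(family_id=fam, members=members))
    return pedigrees


def write_ped(pedigrees: Sequence[Pedigree], path: str) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write("\t".join([
                    ped.family_id, m.id, m.father_id or "0", m.mother_id or "0",
                    _PED_SEX_OUT[m.sex], _PED_AFF_OUT[m.affection],
                ]) + "\n")


_ANN_HEADER = ["chrom", "pos", "ref", "alt", "gene", "consequence", "mafs",
               "sift", "polyphen2", "mutationtaster", "cadd"]


def read_annotations(path: str) -> dict[tuple, tuple[str, Annotation]]:
    """Read the sidecar TSV into {(chrom,pos,ref,alt): (gene, Annotation)}.

    The ``mafs`` column holds ``db=freq`` pairs joined by ``;`` (empty for a
    variant unobserved in every database). Vocabulary and range invariants
    are enforced by the ``Annotation`` constructor.
    """
    out: dict[tuple, tuple[str, Annotation]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANN_HEADER:
            raise ValidationError(f"{path}: bad annotation header {header}")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_ANN_HEADER):
                raise ValidationError(f"{path}:{ln}: expected {len(_ANN_HEADER)} columns")
            chrom, pos, ref, alt, gene, csq, mafs, sift, pp2, mt, cadd = parts
            maf_by_db: dict[str, float] = {}
            if mafs:
                for pair in mafs.split(";"):
                    db, _, freq = pair.partition("=")
                    if not db or not freq:
                        raise ValidationError(f"{path}:{ln}: bad maf entry {pair!r}")
                    maf_by_db[db] = float(freq)
            ann = Annotation(
                consequence=csq,
                maf_by_db=maf_by_db,
                sift=sift,
                polyphen2=pp2,
                mutationtaster=mt,
                cadd=None if cadd in ("", ".") else float(cadd),
            )
            key = variant_key(chrom, pos, ref, alt)
            if key in out:
                raise ValidationError(f"{path}:{ln}: duplicate annotation for {key}")
            out[key] = (gene, ann)
    return out


def write_annotations(annotations: Mapping[tuple, tuple[str, Annotation]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANN_HEADER) + "\n")
        for key in sorted(annotations):
            gene, ann = annotations[key]
            chrom, pos, ref, alt = key
            mafs = ";".join(f"{db}={_fmt_float(f)}" for db, f in sorted(ann.maf_by_db.items()))
            fh.write("\t".join([
                chrom, str(pos), ref, alt, gene, ann.consequence, mafs,
                ann.sift, ann.polyphen2, ann.mutationtaster,
                "" if ann.cadd is None else _fmt_float(ann.cadd),
            ]) + "\n")


def read_gene_reference(path: str) -> dict[str, ReferenceGeneCounts]:
    """Read the per-gene reference counts TSV, enforcing count invariants."""
    out: dict[str, ReferenceGeneCounts] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene", "qualifying_allele_count", "total_alleles"]:
            raise ValidationError(f"{path}: bad reference header {header}")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            gene, qac, tot = line.split("\t")
            if gene in out:
                raise ValidationError(f"{path}:{ln}: duplicate gene {gene!r}")
            out[gene] = ReferenceGeneCounts(gene, int(qac), int(tot))
    return out


def write_gene_reference(counts: Mapping[str, ReferenceGeneCounts], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tqualifying_allele_count\ttotal_alleles\n")
        for gene in sorted(counts):
            c = counts[gene]
            fh.write(f"{c.gene}\t{c.qualifying_allele_count}\t{c.total_alleles}\n")


def read_panel(path: str) -> set[str]:
    """Read a gene panel: one symbol per line, '#' comments allowed."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_panel(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_proband_list(path: str) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_proband_list(proband_ids: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for pid in proband_ids:
            fh.write(pid + "\n")


_RESULTS_HEADER = ["gene", "a", "b", "c", "d", "odds_ratio", "p_raw", "p_adjusted",
                   "candidate", "rank"]


def _fmt_float(x: float) -> str:
    """Shortest round-trip float formatting; deterministic across runs."""
    if x == math.inf:
        return "inf"
    return repr(float(x))


def write_results(results: Sequence[GeneBurdenResult], trace: FilterTrace, path_prefix: str) -> dict[str, str]:
    """Write ranked burden results and the machine-readable funnel report.

    Produces ``<prefix>.results.tsv`` and ``<prefix>.funnel.txt``; returns
    the paths written. Output is byte-identical given identical inputs.
    """
    os.makedirs(os.path.dirname(os.path.abspath(path_prefix)), exist_ok=True)
    results_path = path_prefix + ".results.tsv"
    funnel_path = path_prefix + ".funnel.txt"
    with open(results_path, "w") as fh:
        fh.write("\t".join(_RESULTS_HEADER) + "\n")
        for r in sorted(results, key=lambda r: r.rank):
            fh.write("\t".join([
                r.gene, str(r.a), str(r.b), str(r.c), str(r.d),
                _fmt_float(r.odds_ratio), _fmt_float(r.p_raw), _fmt_float(r.p_adjusted),
                "true" if r.candidate else "false", str(r.rank),
            ]) + "\n")
    write_funnel(trace, funnel_path)
    return {"results": results_path, "funnel": funnel_path}


def read_results(path: str) -> list[GeneBurdenResult]:
    out: list[GeneBurdenResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _RESULTS_HEADER:
            raise ValidationError(f"{path}: bad results header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, a, b, c, d, orr, praw, padj, cand, rank = line.split("\t")
            out.append(GeneBurdenResult(
                gene=gene, a=int(a), b=int(b), c=int(c), d=int(d),
                odds_ratio=float(orr), p_raw=float(praw), p_adjusted=float(padj),
                candidate=(cand == "true"), rank=int(rank),
            ))
    return out


def write_funnel(trace: FilterTrace, path: str) -> None:
    """Serialize a FilterTrace as a key-value stage table."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={trace.config_hash}\n")
        fh.write(f"# seed={'' if trace.seed is None else trace.seed}\n")
        fh.write("stage\tn_variants\tn_genes\n")
        for stage, nv, ng in trace.stages:
            fh.write(f"{stage}\t{nv}\t{ng}\n")


def read_funnel(path: str) -> FilterTrace:
    trace = FilterTrace()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# config_hash="):
                trace.config_hash = line.split("=", 1)[1]
            elif line.startswith("# seed="):
                val = line.split("=", 1)[1]
                trace.seed = int(val) if val else None
            elif not line or line.startswith("stage\t"):
                continue
            else:
                stage, nv, ng = line.split("\t")
                trace.append(stage, int(nv), int(ng))
    return trace
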