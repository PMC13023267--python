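"""VCF 4.2 reading/writing into the internal record model, plus MNP
decomposition.

Backed by :mod:`pysam`.  Per-genotype fields handled are GT, AD (two
values: ref, alt), DP and GQ; "." round-trips to ``None``.  Multi-allelic
ALT fields are kept as one record classified ``MULTIALLELIC`` (never
split): the catalog is biallelic-SNP only, so these records are carried
just far enough to be counted and excluded.  Genotype dosages are only
defined for biallelic records; a multi-allelic record's entries keep
DP/GQ but no dosage.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pysam

from .genome import GenomeLayout
from .model import (
    GenotypeEntry,
    VariantClass,
    VariantKey,
    VariantRecord,
    classify_variant,
)

_GT_BY_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1), None: (None, None)}


def _build_header(samples: Sequence[str], layout: GenomeLayout) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in layout:
        header.contigs.add(chrom.name, length=chrom.length_bp)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    samples: Sequence[str],
    records: Iterable[VariantRecord],
    path,
    layout: GenomeLayout,
) -> None:
    """Write records as VCF 4.2 with contig headers and FORMAT GT:AD:DP:GQ.

    Absent values are written as "."; records must be sorted by
    (layout chromosome order, position).
    """
    header = _build_header(samples, layout)
    mode = "wz" if str(path).endswith(".gz") else "w"
    with pysam.VariantFile(str(path), mode, header=header) as vf:
        for record in records:
            key = record.key
            rec = vf.new_record(
                contig=key.chrom,
                start=key.pos - 1,
                alleles=(key.ref, *key.alt.split(",")),
            )
            for s in samples:
                entry = record.entry(s)
                fmt = rec.samples[s]
                fmt["GT"] = _GT_BY_DOSAGE[entry.gt if "," not in key.alt else None]
                if entry.ad_ref is not None and entry.ad_alt is not None:
                    fmt["AD"] = (entry.ad_ref, entry.ad_alt)
                if entry.dp is not None:
                    fmt["DP"] = entry.dp
                if entry.gq is not None:
                    fmt["GQ"] = int(round(entry.gq))
            vf.write(rec)


def _parse_entry(fmt, multiallelic: bool) -> GenotypeEntry:
    gt = None
    if not multiallelic:
        alleles = fmt.get("GT", (None,))
        if alleles and all(a is not None for a in alleles):
            gt = sum(alleles)
    ad = fmt.get("AD")
    ad_ref = ad_alt = None
    if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
        ad_ref, ad_alt = int(ad[0]), int(ad[1])
    dp = fmt.get("DP")
    gq = fmt.get("GQ")
    return GenotypeEntry(
        gt=gt,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=None if dp is None else int(dp),
        gq=None if gq is None else float(gq),
    )


def read_vcf(path, layout: GenomeLayout) -> tuple[list[str], list[VariantRecord]]:
    """Read a multi-sample VCF into (sample list, sorted record list).

    Chromosomes absent from the layout and out-of-order records are
    rejected.  Fields a record does not carry come back as ``None``.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        last: tuple[int, int] | None = None
        for rec in vf:
            if rec.chrom not in layout:
                raise ValueError(
                    f"{path}: chromosome {rec.chrom!r} not in genome layout"
                )
            here = (layout.chrom_order[rec.chrom], rec.pos)
            if last is not None and here < last:
                raise ValueError(f"{path}: records not sorted at {rec.chrom}:{rec.pos}")
            last = here
            if not rec.alts:
                continue
            key = VariantKey(rec.chrom, rec.pos, rec.ref, ",".join(rec.alts))
            vclass = classify_variant(key)
            multi = vclass is VariantClass.MULTIALLELIC
            entries = {s: _parse_entry(rec.samples[s], multi) for s in samples}
            records.append(VariantRecord(key, vclass, entries))
    return samples, records


def decompose_mnp(record: VariantRecord) -> list[VariantRecord]:
    """Split a multi-nucleotide polymorphism into per-base SNP records.

    One SNP is emitted at each offset where ref and alt bases differ;
    positions where they agree emit nothing.  Genotype entries are
    inherited verbatim (perfect linkage within the MNP is assumed).
    """
    if record.variant_class is not VariantClass.MNP:
        raise ValueError("decompose_mnp requires an MNP record")
    key = record.key
    out = []
    for offset, (r, a) in enumerate(zip(key.ref, key.alt)):
        if r != a:
            snp_key = VariantKey(key.chrom, key.pos + offset, r, a)
            out.append(VariantRecord(snp_key, VariantClass.SNP, dict(record.entries)))
    return out


def normalize_mnps(records: Iterable[VariantRecord], layout: GenomeLayout) -> list[VariantRecord]:
    """Decompose every MNP record in a call set; re-sort the result."""
    out: list[VariantRecord] = []
    for record in records:
        if record.variant_class is VariantClass.MNP:
            out.extend(decompose_mnp(record))
        else:
            out.append(record)
    order = layout.chrom_order
    out.sort(key=lambda r: r.key.sort_tuple(order))
    return out
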