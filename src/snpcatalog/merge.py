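"""Intersect the three filtered call sets and apply chromosome-class
merge rules.

Variant identity is allele-aware: (chrom, pos, ref, alt) must all match
for a variant to be shared between datasets.  The default rule table
retains autosomal and X variants only when present in all three
datasets, Y variants from the male short-read set (S1) — the only one
carrying Y data — and mitochondrial variants present in both short-read
sets (the long-read set has no MT records).  Rules are data, not code:
any class can be mapped to a different required-dataset set.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .genome import GenomeLayout
from .model import (
    ABSENT,
    SampleMeta,
    VariantKey,
    VariantRecord,
)

DATASET_TAGS = ("S1", "S2", "L")

#: chrom_class -> set of datasets that must all contain the key.
#: An empty set means "any membership accepted".
MergeRules = Mapping[str, frozenset[str]]

DEFAULT_MERGE_RULES: MergeRules = {
    "AUTOSOME": frozenset({"S1", "S2", "L"}),
    "X": frozenset({"S1", "S2", "L"}),
    "Y": frozenset({"S1"}),
    "MT": frozenset({"S1", "S2"}),
}


def partition_membership(
    s1_keys: Iterable[VariantKey],
    s2_keys: Iterable[VariantKey],
    l_keys: Iterable[VariantKey],
) -> dict[VariantKey, frozenset[str]]:
    """Exact set-union partition: key -> subset of datasets containing it."""
    membership: dict[VariantKey, set[str]] = {}
    for tag, keys in zip(DATASET_TAGS, (s1_keys, s2_keys, l_keys)):
        seen: set[VariantKey] = set()
        for key in keys:
            if key in seen:
                raise ValueError(f"duplicate key within dataset {tag}: {key}")
            seen.add(key)
            membership.setdefault(key, set()).add(tag)
    return {k: frozenset(v) for k, v in membership.items()}


def apply_merge_rules(
    partition: Mapping[VariantKey, frozenset[str]],
    layout: GenomeLayout,
    rules: MergeRules = DEFAULT_MERGE_RULES,
) -> list[VariantKey]:
    """Retain keys whose chromosome class's required datasets are all present.

    Returns keys sorted by (layout chromosome order, pos, ref, alt).
    """
    kept = []
    order = layout.chrom_order
    for key, subset in partition.items():
        if key.chrom not in layout:
            raise KeyError(f"key chromosome {key.chrom!r} not in layout")
        cls = layout.chrom_class(key.chrom)
        if cls not in rules:
            raise ValueError(f"no merge rule for chromosome class {cls!r}")
        if rules[cls] <= subset:
            kept.append(key)
    kept.sort(key=lambda k: k.sort_tuple(order))
    return kept


def membership_table(
    partition: Mapping[VariantKey, frozenset[str]],
    layout: GenomeLayout,
    path,
) -> None:
    """Write an audit table: key columns plus one 0/1 flag per dataset."""
    order = layout.chrom_order
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tS1\tS2\tL\n")
        for key in sorted(partition, key=lambda k: k.sort_tuple(order)):
            flags = "\t".join(str(int(t in partition[key])) for t in DATASET_TAGS)
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{flags}\n")


def merge_genotypes(
    final_keys: Sequence[VariantKey],
    dataset_records: Mapping[str, Sequence[VariantRecord]],
    metadata: Sequence[SampleMeta],
) -> list[VariantRecord]:
    """Join the per-dataset call sets into one record per key over all samples.

    Each sample's entry comes from its dataset of origin; samples whose
    dataset lacks the key get an all-absent entry.  A sample appearing
    in two datasets is a metadata error.
    """
    seen: dict[str, str] = {}
    for m in metadata:
        if m.sample_id in seen:
            raise ValueError(
                f"sample {m.sample_id!r} present in datasets "
                f"{seen[m.sample_id]} and {m.dataset}"
            )
        seen[m.sample_id] = m.dataset
    by_key: dict[str, dict[VariantKey, VariantRecord]] = {
        tag: {r.key: r for r in records} for tag, records in dataset_records.items()
    }
    samples_by_tag = {
        tag: [m.sample_id for m in metadata if m.dataset == tag]
        for tag in dataset_records
    }
    merged = []
    for key in final_keys:
        entries = {}
        vclass = None
        for tag, index in by_key.items():
            record = index.get(key)
            for s in samples_by_tag[tag]:
                entries[s] = record.entry(s) if record is not None else ABSENT
            if record is not None:
                vclass = record.variant_class
        if vclass is None:
            raise KeyError(f"final key {key} absent from every dataset")
        merged.append(VariantRecord(key, vclass, entries))
    return merged


def dataset_presence(
    final_keys: Sequence[VariantKey],
    partition: Mapping[VariantKey, frozenset[str]],
) -> dict[VariantKey, frozenset[str]]:
    """Membership restricted to the final catalog (for call-rate eligibility)."""
    return {k: partition[k] for k in final_keys}
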