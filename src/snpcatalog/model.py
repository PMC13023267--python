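"""Core record types shared by every stage of the catalog pipeline.

The in-memory model mirrors what a multi-sample VCF carries per site:
a variant identity (chrom, pos, ref, alt) plus, per sample, the called
genotype and the read-depth evidence behind it (AD/DP) and its quality
(GQ).  Genotypes are stored as alternate-allele dosages (0, 1, 2) with
``None`` for missing; absence of a field is ``None``, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    MNP = "MNP"
    MULTIALLELIC = "MULTIALLELIC"
    OTHER = "OTHER"


GROUPS = ("MED", "RIV", "SWA")
DATASETS = ("S1", "S2", "L")

_BASES = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Allele-aware variant identity: (chrom, 1-based pos, ref, alt).

    Two call sets share a variant only when all four fields agree; a
    site with the same position but a different alternate allele is a
    different key.  Multi-allelic records keep a comma-joined ``alt``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")

    def sort_tuple(self, chrom_order: Mapping[str, int]) -> tuple:
        return (chrom_order[self.chrom], self.pos, self.ref, self.alt)


def classify_variant(key: VariantKey) -> VariantClass:
    """Classify a key as SNP / MNP / INDEL / MULTIALLELIC / OTHER.

    SNP: both alleles single bases.  MNP: equal length > 1.  INDEL:
    unequal lengths.  A comma in the alt marks a multi-allelic site.
    """
    ref, alt = key.ref, key.alt
    if "," in alt:
        return VariantClass.MULTIALLELIC
    if not (_BASES.issuperset(ref) and _BASES.issuperset(alt)):
        return VariantClass.OTHER
    if len(ref) == len(alt):
        return VariantClass.SNP if len(ref) == 1 else VariantClass.MNP
    return VariantClass.INDEL


@dataclass(frozen=True, slots=True)
class GenotypeEntry:
    """One sample's call at one site.

    ``gt`` is the alternate-allele dosage (0, 1, 2) or ``None`` when the
    genotype is missing.  ``ad_ref``/``ad_alt``/``dp``/``gq`` are ``None``
    when the caller did not emit the field — absent is distinct from 0.
    """

    gt: int | None = None
    ad_ref: int | None = None
    ad_alt: int | None = None
    dp: int | None = None
    gq: float | None = None

    def masked(self) -> "GenotypeEntry":
        """Copy with the genotype set missing; evidence fields retained."""
        return replace(self, gt=None)

    @property
    def is_absent(self) -> bool:
        return (
            self.gt is None
            and self.ad_ref is None
            and self.ad_alt is None
            and self.dp is None
            and self.gq is None
        )


ABSENT = GenotypeEntry()


@dataclass(slots=True)
class VariantRecord:
    key: VariantKey
    variant_class: VariantClass
    entries: dict[str, GenotypeEntry] = field(default_factory=dict)

    def entry(self, sample_id: str) -> GenotypeEntry:
        return self.entries.get(sample_id, ABSENT)


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Sample identity: genetic group, sex, dataset of origin, pooling.

    ``pool_size`` is the number of individuals contributing DNA; 1 for
    a single individual.  Pools carry read evidence (AD/DP) but no
    meaningful per-individual genotype.
    """

    sample_id: str
    group: str
    sex: str
    dataset: str
    is_pool: bool = False
    pool_size: int = 1

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.dataset not in DATASETS:
            raise ValueError(f"unknown dataset {self.dataset!r}")
        if self.pool_size > 1 and not self.is_pool:
            raise ValueError("pool_size > 1 requires is_pool")
        if self.is_pool and self.pool_size < 2:
            raise ValueError("a pool needs pool_size >= 2")


def write_metadata(samples: Iterable[SampleMeta], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\tsex\tdataset\tis_pool\tpool_size\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.group}\t{s.sex}\t{s.dataset}\t"
                f"{int(s.is_pool)}\t{s.pool_size}\n"
            )


def read_metadata(path) -> list[SampleMeta]:
    samples = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "group", "sex", "dataset", "is_pool", "pool_size"]
        if header != expected:
            raise ValueError(f"metadata header must be {expected}, got {header}")
        for line in fh:
            sid, group, sex, dataset, is_pool, pool_size = line.rstrip("\n").split("\t")
            samples.append(
                SampleMeta(sid, group, sex, dataset, bool(int(is_pool)), int(pool_size))
            )
    return samples
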