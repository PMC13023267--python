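"""Per-dataset genotype- and site-level QC.

Two separable effects, composable in either order:

* genotype masking — set individual genotypes missing on depth/quality
  thresholds, keeping the read evidence (AD/DP) in place;
* site filtering — drop whole sites on missingness or carrier counts,
  leaving surviving genotypes untouched.

Each sequencing dataset gets its own composition of these primitives
(see :func:`dataset_pipeline`): the low-depth short-read set masks on
DP>=5 with pools exempt, the high-depth short-read set on GQ>=30 and
DP>=10 after MNP normalization, and the long-read set on GQ>20 and DP>5
(strict inequalities) plus an alt-carrier minimum of 2 of 8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .genome import GenomeLayout
from .model import SampleMeta, VariantClass, VariantRecord
from .vcfio import normalize_mnps

logger = logging.getLogger(__name__)

MissingDialect = str  # "PROSE" | "VCFTOOLS"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for one dataset's genotype masking.

    ``strict`` switches the comparison from "keep if value >= threshold"
    (the vcftools ``--minDP``/``--minGQ`` convention) to "keep if value >
    threshold" (a literal reading of "more than").  Samples in
    ``exempt_samples`` (e.g. DNA pools) are never masked.  A genotype
    whose thresholded field is absent is masked — silent pass-through
    would inflate downstream call rates.
    """

    min_dp: int | None = None
    min_gq: float | None = None
    strict: bool = False
    exempt_samples: frozenset[str] = field(default_factory=frozenset)


def _fails(value, threshold, strict: bool) -> bool:
    if threshold is None:
        return False
    if value is None:
        return True  # absent field with a set threshold: mask, conservatively
    return value <= threshold if strict else value < threshold


def mask_genotypes(
    records: Sequence[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Mask genotypes failing DP/GQ thresholds; never drops a site.

    Returns new records (inputs are not mutated); AD/DP/GQ fields are
    retained on masked entries so allele-frequency sums still see them.
    """
    n_masked = n_absent = 0
    out = []
    for record in records:
        entries = {}
        for sample_id, entry in record.entries.items():
            if (
                entry.gt is not None
                and sample_id not in config.exempt_samples
                and (
                    _fails(entry.dp, config.min_dp, config.strict)
                    or _fails(entry.gq, config.min_gq, config.strict)
                )
            ):
                if (config.min_dp is not None and entry.dp is None) or (
                    config.min_gq is not None and entry.gq is None
                ):
                    n_absent += 1
                entries[sample_id] = entry.masked()
                n_masked += 1
            else:
                entries[sample_id] = entry
        out.append(VariantRecord(record.key, record.variant_class, entries))
    if n_masked:
        logger.info(
            "mask_genotypes: masked %d genotypes (%d on absent fields)",
            n_masked,
            n_absent,
        )
    return out


def site_missingness_filter(
    records: Sequence[VariantRecord],
    max_missing_fraction: float,
    eligible_samples: Sequence[str],
    dialect: MissingDialect = "PROSE",
) -> list[VariantRecord]:
    """Keep sites by genotype missingness among the eligible samples.

    PROSE dialect: keep sites whose missing fraction is <= the threshold.
    VCFTOOLS dialect: the threshold is the *minimum called fraction*
    (vcftools ``--max-missing`` counts calls, inverting the name): keep
    sites whose called fraction is >= the threshold.
    """
    if not eligible_samples:
        raise ValueError("site_missingness_filter needs a nonempty eligible set")
    if dialect not in ("PROSE", "VCFTOOLS"):
        raise ValueError(f"unknown missingness dialect {dialect!r}")
    n = len(eligible_samples)
    out = []
    for record in records:
        called = sum(1 for s in eligible_samples if record.entry(s).gt is not None)
        if dialect == "PROSE":
            keep = (n - called) / n <= max_missing_fraction
        else:
            keep = called / n >= max_missing_fraction
        if keep:
            out.append(record)
    return out


def min_carrier_filter(
    records: Sequence[VariantRecord],
    min_carriers: int,
    mode: str = "alt_carriers",
) -> list[VariantRecord]:
    """Keep sites seen in at least ``min_carriers`` samples.

    ``alt_carriers`` (default, the stricter reading) counts samples with
    a non-missing genotype carrying the alternate allele; ``genotyped``
    counts any non-missing genotype.
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    if mode not in ("alt_carriers", "genotyped"):
        raise ValueError(f"unknown carrier mode {mode!r}")
    out = []
    for record in records:
        if mode == "alt_carriers":
            n = sum(1 for e in record.entries.values() if e.gt is not None and e.gt > 0)
        else:
            n = sum(1 for e in record.entries.values() if e.gt is not None)
        if n >= min_carriers:
            out.append(record)
    return out


def sample_missingness(
    records: Sequence[VariantRecord], samples: Sequence[str]
) -> dict[str, float]:
    """Fraction of sites with a missing genotype, per sample.

    Pools report 1.0 by construction: they carry no genotypes.
    """
    if not records:
        raise ValueError("sample_missingness needs at least one record")
    n = len(records)
    return {
        s: sum(1 for r in records if r.entry(s).gt is None) / n for s in samples
    }


def keep_biallelic_snps(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    return [r for r in records if r.variant_class is VariantClass.SNP]


#: Default masking thresholds per sequencing dataset.
DATASET_FILTERS: Mapping[str, FilterConfig] = {
    "S1": FilterConfig(min_dp=5),
    "S2": FilterConfig(min_gq=30, min_dp=10),
    "L": FilterConfig(min_gq=20, min_dp=5, strict=True),
}
MAX_MISSING_FRACTION = 0.1
L_MIN_CARRIERS = 2


def dataset_pipeline(
    dataset_tag: str,
    records: Sequence[VariantRecord],
    metadata: Sequence[SampleMeta],
    layout: GenomeLayout,
    *,
    filters: Mapping[str, FilterConfig] | None = None,
    max_missing_fraction: float | None = MAX_MISSING_FRACTION,
    min_carriers: int | None = L_MIN_CARRIERS,
    missing_dialect: MissingDialect = "PROSE",
) -> list[VariantRecord]:
    """Run one dataset's QC composition; returns biallelic SNPs only.

    S1: DP mask (pools exempt) then site missingness over non-pool
    samples.  S2: MNP normalization, GQ/DP mask, site missingness.
    L: strict GQ/DP mask then the alt-carrier minimum.  Pass ``None``
    for ``max_missing_fraction``/``min_carriers`` to disable the site
    filters (the masking stage is disabled by an all-``None`` config).
    """
    filters = dict(DATASET_FILTERS) if filters is None else filters
    ds_samples = [m for m in metadata if m.dataset == dataset_tag]
    if dataset_tag == "S1":
        pools = frozenset(m.sample_id for m in ds_samples if m.is_pool)
        config = replace(filters["S1"], exempt_samples=filters["S1"].exempt_samples | pools)
        masked = mask_genotypes(records, config)
        eligible = [m.sample_id for m in ds_samples if not m.is_pool]
        if max_missing_fraction is not None:
            masked = site_missingness_filter(
                masked, max_missing_fraction, eligible, missing_dialect
            )
    elif dataset_tag == "S2":
        normalized = normalize_mnps(records, layout)
        masked = mask_genotypes(normalized, filters["S2"])
        eligible = [m.sample_id for m in ds_samples]
        if max_missing_fraction is not None:
            masked = site_missingness_filter(
                masked, max_missing_fraction, eligible, missing_dialect
            )
    elif dataset_tag == "L":
        masked = mask_genotypes(records, filters["L"])
        masked = keep_biallelic_snps(masked)
        if min_carriers is not None:
            masked = min_carrier_filter(masked, min_carriers)
    else:
        raise ValueError(f"unknown dataset tag {dataset_tag!r}")
    return keep_biallelic_snps(masked)
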