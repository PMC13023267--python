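"""Synthetic three-dataset study generator with known ground truth.

The generator emulates the structure of a multi-technology variant
discovery study in water buffalo: three genetic groups (MED, RIV, SWA)
with divergent allele frequencies, and three call sets with different
depth regimes and dropouts —

* ``S1``: short-read individuals from all three groups at low-to-high
  depth (3–40×) plus two MED DNA pools (AD/DP but no genotypes),
* ``S2``: 24 MED females at high depth (28–56×), so no Y records, with
  a handful of MNP records that downstream normalization must split,
* ``L``: 8 MED males on long reads (25–63×), with no mitochondrial
  records and a higher per-read error rate.

Group divergence follows the Balding–Nichols model: each group's
frequency is Beta-distributed around the ancestral frequency ``p`` with
variance ``FST · p(1 − p)``.  Genotypes are Hardy–Weinberg draws at the
group frequency (haploid on Y, male X and MT, encoded as homozygous
diploid calls); read evidence is Poisson depth with binomial allele
counts perturbed by a per-read base error.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, default_layout
from .model import (
    ABSENT,
    GROUPS,
    GenotypeEntry,
    SampleMeta,
    VariantClass,
    VariantKey,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))

#: Balding–Nichols divergence from the ancestral pool, per group.  MED
#: is the reference breed (low drift); RIV shares river-type ancestry
#: (moderate); SWA is the independently domesticated swamp type (high).
DEFAULT_FST: Mapping[str, float] = {"MED": 0.05, "RIV": 0.10, "SWA": 0.35}


@dataclass(frozen=True)
class DatasetProfile:
    """Noise/coverage regime of one sequencing dataset.

    ``mean_depth_range`` spreads per-sample mean depths evenly across
    the printed coverage range; ``dropout_rate`` is the fraction of
    true sites the dataset's caller never reports (dataset-specific
    discovery); ``drop_mt`` removes the mitochondrial contig from the
    dataset's site list entirely.
    """

    mean_depth_range: tuple[float, float]
    genotype_error_rate: float = 0.0
    base_error_rate: float = 0.0
    dropout_rate: float = 0.0
    drop_mt: bool = False
    gq_missing: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.mean_depth_range
        if lo > hi or lo < 0:
            raise ValueError("invalid mean_depth_range")
        for p in (self.genotype_error_rate, self.base_error_rate, self.dropout_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities")


DEFAULT_PROFILES: Mapping[str, DatasetProfile] = {
    "S1": DatasetProfile((3, 40), genotype_error_rate=0.02, base_error_rate=0.005,
                         dropout_rate=0.10),
    "S2": DatasetProfile((28, 56), genotype_error_rate=0.01, base_error_rate=0.005,
                         dropout_rate=0.08),
    "L": DatasetProfile((25, 63), genotype_error_rate=0.03, base_error_rate=0.02,
                        dropout_rate=0.30, drop_mt=True),
}


@dataclass
class TruthTable:
    """Simulator ground truth: per-variant group frequencies and, once a
    study is generated, per-sample true genotypes (−1 = missing)."""

    variants: pd.DataFrame  # chrom pos ref alt ancestral_freq freq_<group>...
    genotypes: pd.DataFrame | None = None  # rows align with variants

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), r, a)
            for c, p, r, a in self.variants[["chrom", "pos", "ref", "alt"]].itertuples(
                index=False
            )
        ]

    def group_freq(self, group: str) -> np.ndarray:
        return self.variants[f"freq_{group}"].to_numpy()

    def to_tsv(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


def simulate_truth(
    layout: GenomeLayout,
    n_variants: int,
    fst: Mapping[str, float] = DEFAULT_FST,
    seed: int | np.random.SeedSequence = 0,
    groups: Sequence[str] = GROUPS,
) -> TruthTable:
    """Draw variant positions and per-group allele frequencies.

    Ancestral frequencies are uniform on [0.05, 0.95]; each group's
    frequency is Beta with mean ``p`` and variance ``FST·p(1 − p)``
    (exactly ``p`` when its FST is 0).  Positions are uniform without
    replacement within chromosomes, allocated proportionally to length.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    for g in groups:
        if not 0 <= fst[g] < 1:
            raise ValueError(f"fst[{g}] must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lengths = np.array([c.length_bp for c in layout], dtype=float)
    if n_variants > lengths.sum():
        raise ValueError("n_variants exceeds available genome positions")
    # proportional allocation (largest remainder), capped at chromosome size
    raw = n_variants * lengths / lengths.sum()
    counts = np.floor(raw).astype(int)
    rema = raw - counts
    for i in np.argsort(-rema):
        if counts.sum() == n_variants:
            break
        counts[i] += 1
    rows = []
    for chrom, count in zip(layout, counts):
        count = min(count, chrom.length_bp)
        pos = np.sort(rng.choice(chrom.length_bp, size=count, replace=False)) + 1
        ref_i = rng.integers(0, 4, size=count)
        alt_i = (ref_i + rng.integers(1, 4, size=count)) % 4
        p = rng.uniform(0.05, 0.95, size=count)
        freqs = {}
        for g in groups:
            f = fst[g]
            if f == 0:
                freqs[g] = p.copy()
            else:
                a = p * (1 - f) / f
                b = (1 - p) * (1 - f) / f
                freqs[g] = rng.beta(a, b)
        for j in range(count):
            rows.append(
                (
                    chrom.name,
                    int(pos[j]),
                    _BASES[ref_i[j]],
                    _BASES[alt_i[j]],
                    p[j],
                    *(freqs[g][j] for g in groups),
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "ancestral_freq"]
        + [f"freq_{g}" for g in groups],
    )
    return TruthTable(frame)


def _ploidy_codes(truth: TruthTable, layout: GenomeLayout, sex: str) -> np.ndarray:
    """Per-variant code: 2 diploid, 1 haploid, 0 absent (female Y)."""
    classes = truth.variants["chrom"].map(layout.chrom_class)
    codes = np.full(len(truth), 2, dtype=int)
    codes[classes == "MT"] = 1
    if sex == "M":
        codes[(classes == "X") | (classes == "Y")] = 1
    else:
        codes[np.asarray(classes == "Y")] = 0
    return codes


def draw_true_genotypes(
    truth: TruthTable,
    sample: SampleMeta,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hardy–Weinberg dosage draw for one individual (−1 where the
    chromosome is absent for the sample's sex).  Haploid calls carry
    dosage 0 or 2 (emitted later as homozygous diploid genotypes)."""
    p = truth.group_freq(sample.group)
    codes = _ploidy_codes(truth, layout, sample.sex)
    dosage = rng.binomial(2, p)
    hap = rng.random(len(p)) < p
    dosage = np.where(codes == 1, hap.astype(int) * 2, dosage)
    dosage = np.where(codes == 0, -1, dosage)
    return dosage


def _gq_from_dp(dp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Monotone-in-depth quality score with noise, clipped to [0, 99]."""
    gq = 3.0 * dp + rng.normal(0, 6, size=dp.shape)
    return np.clip(np.round(gq), 0, 99)


def _wrong_genotype(
    dosage: np.ndarray, haploid: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """A uniformly random *other* genotype, respecting ploidy."""
    shift = rng.integers(1, 3, size=dosage.shape)
    wrong_dip = (dosage + shift) % 3
    wrong_hap = 2 - dosage  # swaps 0 <-> 2
    return np.where(haploid, wrong_hap, wrong_dip)


def simulate_individual_calls(
    truth: TruthTable,
    samples: Sequence[SampleMeta],
    profile: DatasetProfile,
    layout: GenomeLayout,
    seed: int | np.random.SeedSequence = 0,
    mean_depths: Mapping[str, float] | None = None,
    site_mask: np.ndarray | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Emit per-individual calls for every truth site (or ``site_mask``).

    Per sample and site: DP ~ Poisson(sample mean depth); alt reads
    Binomial(DP, d/2·(1−e) + (1−d/2)·e) at dosage ``d`` and base error
    ``e``; the emitted genotype equals the true one with probability
    1 − genotype_error_rate (a random other genotype otherwise) and is
    missing whenever DP = 0.  Returns the records and the table of true
    genotypes for all truth sites.
    """
    if any(m.is_pool for m in samples):
        raise ValueError("simulate_individual_calls takes individuals only")
    rng = np.random.default_rng(seed)
    n = len(truth)
    if site_mask is None:
        site_mask = np.ones(n, dtype=bool)
    if mean_depths is None:
        lo, hi = profile.mean_depth_range
        spread = np.linspace(lo, hi, num=max(len(samples), 2))[: len(samples)]
        mean_depths = {m.sample_id: float(d) for m, d in zip(samples, spread)}
    e = profile.base_error_rate
    per_sample: dict[str, tuple] = {}
    truth_gt = {}
    for m in samples:
        dosage = draw_true_genotypes(truth, m, layout, rng)
        codes = _ploidy_codes(truth, layout, m.sex)
        dp = rng.poisson(mean_depths[m.sample_id], size=n)
        d = np.maximum(dosage, 0)
        p_read = (d / 2.0) * (1 - e) + (1 - d / 2.0) * e
        ad_alt = rng.binomial(dp, p_read)
        wrong = rng.random(n) < profile.genotype_error_rate
        gt = np.where(wrong, _wrong_genotype(dosage, codes == 1, rng), dosage)
        gq = _gq_from_dp(dp, rng)
        per_sample[m.sample_id] = (dosage, codes, dp, ad_alt, gt, gq)
        truth_gt[m.sample_id] = dosage
    records = []
    keys = truth.keys()
    for i in np.flatnonzero(site_mask):
        entries = {}
        for m in samples:
            dosage, codes, dp, ad_alt, gt, gq = per_sample[m.sample_id]
            if codes[i] == 0:  # chromosome absent for this sex: no reads
                entries[m.sample_id] = ABSENT
                continue
            missing = dp[i] == 0 or dosage[i] < 0
            entries[m.sample_id] = GenotypeEntry(
                gt=None if missing else int(gt[i]),
                ad_ref=int(dp[i] - ad_alt[i]),
                ad_alt=int(ad_alt[i]),
                dp=int(dp[i]),
                gq=None if profile.gq_missing else float(gq[i]),
            )
        records.append(VariantRecord(keys[i], VariantClass.SNP, entries))
    genotypes = pd.DataFrame(truth_gt)
    return records, genotypes


def simulate_pool_calls(
    truth: TruthTable,
    pool_meta: SampleMeta,
    profile: DatasetProfile,
    layout: GenomeLayout,
    seed: int | np.random.SeedSequence = 0,
    mean_depth: float = 30.0,
    site_mask: np.ndarray | None = None,
) -> list[VariantRecord]:
    """Pooled-DNA calls: AD/DP from the pool's sampled haplotypes, no
    genotype and no quality score.

    The pool's alt-read probability is the drawn alt-haplotype fraction
    shifted by the base error.  Haplotype count respects ploidy (males:
    ``pool_size`` haplotypes on X/Y, ``2·pool_size`` on autosomes).
    """
    if not pool_meta.is_pool:
        raise ValueError("simulate_pool_calls requires a pool sample")
    if pool_meta.pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(truth)
    if site_mask is None:
        site_mask = np.ones(n, dtype=bool)
    p = truth.group_freq(pool_meta.group)
    codes = _ploidy_codes(truth, layout, pool_meta.sex)
    n_hap = np.where(codes == 1, pool_meta.pool_size, 2 * pool_meta.pool_size)
    n_hap = np.where(codes == 0, 0, n_hap)
    k_alt = rng.binomial(n_hap, p)
    frac = np.divide(k_alt, n_hap, out=np.zeros(n), where=n_hap > 0)
    e = profile.base_error_rate
    dp = rng.poisson(mean_depth, size=n)
    ad_alt = rng.binomial(dp, frac * (1 - e) + (1 - frac) * e)
    records = []
    keys = truth.keys()
    for i in np.flatnonzero(site_mask):
        if codes[i] == 0:
            entry = ABSENT
        else:
            entry = GenotypeEntry(
                gt=None,
                ad_ref=int(dp[i] - ad_alt[i]),
                ad_alt=int(ad_alt[i]),
                dp=int(dp[i]),
                gq=None,
            )
        records.append(
            VariantRecord(keys[i], VariantClass.SNP, {pool_meta.sample_id: entry})
        )
    return records


# --------------------------------------------------------------------------
# whole-study generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Composition and noise regime of the synthetic study.

    Defaults mirror the real study's design: S1 carries 11 MED, 5 RIV
    and 6 SWA male individuals plus two MED pools of 18 and 3 bulls;
    S2 is 24 MED females; L is 8 MED males.
    """

    n_variants: int = 3000
    fst: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FST))
    n_med_s1: int = 11
    n_riv: int = 5
    n_swa: int = 6
    pool_sizes: tuple[int, ...] = (18, 3)
    pool_depth: float = 30.0
    n_s2: int = 24
    n_l: int = 8
    n_mnp_s2: int = 20
    profiles: Mapping[str, DatasetProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def lossless(self) -> "StudyConfig":
        """Noise-free variant of this config: no dropout, no errors.

        Depth ranges are kept away from zero so every site has reads.
        """
        profiles = {
            tag: replace(
                p,
                genotype_error_rate=0.0,
                base_error_rate=0.0,
                dropout_rate=0.0,
                mean_depth_range=(max(p.mean_depth_range[0], 20), p.mean_depth_range[1]),
            )
            for tag, p in self.profiles.items()
        }
        return replace(self, profiles=profiles, n_mnp_s2=self.n_mnp_s2)


@dataclass
class StudyResult:
    layout: GenomeLayout
    metadata: list[SampleMeta]
    truth: TruthTable
    datasets: dict[str, tuple[list[str], list[VariantRecord]]]  # tag -> (samples, records)


def _study_samples(config: StudyConfig) -> list[SampleMeta]:
    samples = []
    samples += [
        SampleMeta(f"MED_S1_{i:02d}", "MED", "M", "S1") for i in range(1, config.n_med_s1 + 1)
    ]
    samples += [SampleMeta(f"RIV_{i:02d}", "RIV", "M", "S1") for i in range(1, config.n_riv + 1)]
    samples += [SampleMeta(f"SWA_{i:02d}", "SWA", "M", "S1") for i in range(1, config.n_swa + 1)]
    samples += [
        SampleMeta(f"MED_POOL_{i}", "MED", "M", "S1", is_pool=True, pool_size=size)
        for i, size in enumerate(config.pool_sizes, start=1)
    ]
    samples += [
        SampleMeta(f"MED_S2_{i:02d}", "MED", "F", "S2") for i in range(1, config.n_s2 + 1)
    ]
    samples += [SampleMeta(f"MED_L_{i:02d}", "MED", "M", "L") for i in range(1, config.n_l + 1)]
    return samples


def _inject_mnps(
    truth: TruthTable,
    layout: GenomeLayout,
    sample_ids: list[str],
    n_mnp: int,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Build MNP records at positions clear of the truth sites.

    Their decomposed SNPs are dataset-private, so they exercise the
    normalization step without perturbing the shared-site truth.
    """
    taken = {
        (c, int(p))
        for c, p in truth.variants[["chrom", "pos"]].itertuples(index=False)
    }
    autosomes = layout.names({"AUTOSOME"})
    records = []
    attempts = 0
    while len(records) < n_mnp and attempts < 50 * max(n_mnp, 1):
        attempts += 1
        chrom = autosomes[rng.integers(len(autosomes))]
        length = int(rng.integers(2, 4))
        pos = int(rng.integers(1, layout.length(chrom) - length))
        if any((chrom, pos + off) in taken for off in range(length)):
            continue
        for off in range(length):
            taken.add((chrom, pos + off))
        ref_i = rng.integers(0, 4, size=length)
        alt_i = ref_i.copy()
        diff = rng.random(length) < 0.7
        diff[rng.integers(length)] = True  # at least one differing base
        alt_i[diff] = (ref_i[diff] + rng.integers(1, 4, size=int(diff.sum()))) % 4
        key = VariantKey(chrom, pos, "".join(_BASES[ref_i]), "".join(_BASES[alt_i]))
        entries = {}
        for s in sample_ids:
            dp = int(rng.poisson(40))
            dosage = int(rng.binomial(2, 0.3))
            ad_alt = int(rng.binomial(dp, dosage / 2)) if dp else 0
            entries[s] = GenotypeEntry(
                gt=None if dp == 0 else dosage,
                ad_ref=dp - ad_alt,
                ad_alt=ad_alt,
                dp=dp,
                gq=float(np.clip(round(3 * dp + rng.normal(0, 6)), 0, 99)),
            )
        records.append(VariantRecord(key, VariantClass.MNP, entries))
    return records


def simulate_study(
    config: StudyConfig = StudyConfig(),
    seed: int = 0,
    layout: GenomeLayout | None = None,
) -> StudyResult:
    """Generate the full three-dataset study deterministically.

    Per dataset, the site list is the truth list minus that dataset's
    random dropouts, minus the Y chromosome for the all-female S2 and
    the mitochondrial contig for L.
    """
    layout = layout or default_layout()
    root = np.random.SeedSequence(seed)
    ss_truth, ss_s1, ss_s2, ss_l, ss_pool, ss_drop, ss_mnp = root.spawn(7)
    truth = simulate_truth(layout, config.n_variants, config.fst, ss_truth)
    samples = _study_samples(config)
    classes = truth.variants["chrom"].map(layout.chrom_class).to_numpy()
    drop_rng = np.random.default_rng(ss_drop)
    datasets: dict[str, tuple[list[str], list[VariantRecord]]] = {}
    genotype_frames = []
    for tag, ss in (("S1", ss_s1), ("S2", ss_s2), ("L", ss_l)):
        profile = config.profiles[tag]
        ds_meta = [m for m in samples if m.dataset == tag]
        individuals = [m for m in ds_meta if not m.is_pool]
        mask = drop_rng.random(len(truth)) > profile.dropout_rate
        if all(m.sex == "F" for m in ds_meta):
            mask &= classes != "Y"
        if profile.drop_mt:
            mask &= classes != "MT"
        records, genotypes = simulate_individual_calls(
            truth, individuals, profile, layout, ss, site_mask=mask
        )
        genotype_frames.append(genotypes)
        pools = [m for m in ds_meta if m.is_pool]
        if pools:
            for pool, ss_p in zip(pools, ss_pool.spawn(len(pools))):
                pool_records = simulate_pool_calls(
                    truth, pool, profile, layout, ss_p,
                    mean_depth=config.pool_depth, site_mask=mask,
                )
                for rec, prec in zip(records, pool_records):
                    rec.entries.update(prec.entries)
        if tag == "S2" and config.n_mnp_s2:
            mnp_rng = np.random.default_rng(ss_mnp)
            records += _inject_mnps(
                truth, layout, [m.sample_id for m in individuals],
                config.n_mnp_s2, mnp_rng,
            )
            order = layout.chrom_order
            records.sort(key=lambda r: r.key.sort_tuple(order))
        datasets[tag] = ([m.sample_id for m in ds_meta], records)
    truth.genotypes = pd.concat(genotype_frames, axis=1)
    return StudyResult(layout, samples, truth, datasets)
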