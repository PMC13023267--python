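import numpy as np
import pytest

from snpcatalog.filters import (
    DATASET_FILTERS,
    FilterConfig,
    dataset_pipeline,
    keep_biallelic_snps,
    mask_genotypes,
    min_carrier_filter,
    sample_missingness,
    site_missingness_filter,
)
from snpcatalog.model import (
    GenotypeEntry,
    SampleMeta,
    VariantClass,
    VariantKey,
    VariantRecord,
)


def _site(pos, entries, ref="A", alt="G", vclass=VariantClass.SNP):
    return VariantRecord(VariantKey("chr1", pos, ref, alt), vclass, entries)


def _entry(gt=1, dp=20, gq=50.0, ad_alt=None):
    ad_alt = dp // 2 if ad_alt is None else ad_alt
    return GenotypeEntry(gt=gt, ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp, gq=gq)


class TestMaskGenotypes:
    def test_low_depth_masked_evidence_kept(self):
        records = [_site(1, {"a": _entry(gt=1, dp=4)})]
        (out,) = mask_genotypes(records, FilterConfig(min_dp=5))
        entry = out.entry("a")
        assert entry.gt is None and entry.dp == 4 and entry.ad_alt == 2

    def test_gq_threshold_masks(self):
        records = [_site(1, {"a": _entry(gt=1, dp=12, gq=25.0)})]
        (out,) = mask_genotypes(records, DATASET_FILTERS["S2"])
        assert out.entry("a").gt is None

    def test_threshold_boundary_semantics(self):
        """minDP keeps values at the threshold; the strict variant masks them."""
        records = [_site(1, {"a": _entry(dp=10, gq=30.0)})]
        (kept,) = mask_genotypes(records, DATASET_FILTERS["S2"])  # >= 30, >= 10
        assert kept.entry("a").gt == 1
        records = [_site(1, {"a": _entry(dp=5, gq=20.0)})]
        (masked,) = mask_genotypes(records, DATASET_FILTERS["L"])  # > 20, > 5
        assert masked.entry("a").gt is None

    def test_no_thresholds_is_identity(self):
        records = [_site(1, {"a": _entry()})]
        assert mask_genotypes(records, FilterConfig()) [0].entries == records[0].entries

    def test_absent_field_is_masked(self):
        records = [_site(1, {"a": GenotypeEntry(gt=1)})]
        (out,) = mask_genotypes(records, FilterConfig(min_dp=5))
        assert out.entry("a").gt is None

    def test_exempt_samples_untouched(self):
        records = [_site(1, {"pool": _entry(gt=1, dp=1)})]
        config = FilterConfig(min_dp=5, exempt_samples=frozenset({"pool"}))
        assert mask_genotypes(records, config)[0].entry("pool").gt == 1

    def test_site_count_never_changes(self):
        records = [_site(p, {"a": _entry(dp=d)}) for p, d in [(1, 1), (2, 50)]]
        assert len(mask_genotypes(records, FilterConfig(min_dp=5))) == 2

    def test_monotone_in_threshold(self, layout, small_truth):
        from snpcatalog.simulate import DatasetProfile, simulate_individual_calls

        samples = [SampleMeta(f"m{i}", "MED", "M", "S1") for i in range(6)]
        records, _ = simulate_individual_calls(
            small_truth, samples, DatasetProfile((3, 20)), layout, seed=5
        )
        eligible = [s.sample_id for s in samples]

        def surviving(min_dp):
            masked = mask_genotypes(records, FilterConfig(min_dp=min_dp))
            kept = site_missingness_filter(masked, 0.2, eligible)
            return {r.key for r in kept}

        assert surviving(10) <= surviving(5) <= surviving(1)


class TestSiteMissingness:
    def _ten_sample_site(self, n_missing):
        entries = {
            f"s{i}": _entry(gt=None) if i < n_missing else _entry() for i in range(10)
        }
        return _site(1, entries), [f"s{i}" for i in range(10)]

    def test_prose_dialect_drops(self):
        site, eligible = self._ten_sample_site(2)
        assert site_missingness_filter([site], 0.1, eligible, "PROSE") == []

    def test_vcftools_dialect_keeps(self):
        """vcftools --max-missing 0.1 means called fraction >= 0.1."""
        site, eligible = self._ten_sample_site(2)
        assert len(site_missingness_filter([site], 0.1, eligible, "VCFTOOLS")) == 1
        site9, _ = self._ten_sample_site(10)
        assert site_missingness_filter([site9], 0.1, eligible, "VCFTOOLS") == []

    def test_vacuous_threshold_keeps_all(self):
        site, eligible = self._ten_sample_site(10)
        assert len(site_missingness_filter([site], 1.0, eligible, "PROSE")) == 1

    def test_empty_eligible_set_rejected(self):
        site, _ = self._ten_sample_site(0)
        with pytest.raises(ValueError):
            site_missingness_filter([site], 0.1, [])


class TestMinCarrierFilter:
    def test_threshold_inclusive(self):
        def site_with_carriers(k):
            entries = {f"s{i}": _entry(gt=1 if i < k else 0) for i in range(8)}
            return _site(1, entries)

        assert len(min_carrier_filter([site_with_carriers(2)], 2)) == 1
        assert min_carrier_filter([site_with_carriers(1)], 2) == []

    def test_one_carrier_drops_ref_only_sites(self):
        rng = np.random.default_rng(1)
        records = []
        for pos in range(1, 101):
            entries = {f"s{i}": _entry(gt=int(g)) for i, g in enumerate(rng.integers(0, 3, 4))}
            records.append(_site(pos, entries))
        kept = min_carrier_filter(records, 1)
        expected = [
            r for r in records
            if any(e.gt is not None and e.gt > 0 for e in r.entries.values())
        ]
        assert [r.key for r in kept] == [r.key for r in expected]


class TestSampleMissingness:
    def test_fraction(self):
        records = [
            _site(p, {"a": _entry(gt=None if p <= 3 else 1), "pool": GenotypeEntry(dp=30, ad_ref=20, ad_alt=10)})
            for p in range(1, 11)
        ]
        frac = sample_missingness(records, ["a", "pool"])
        assert frac["a"] == pytest.approx(0.3)
        assert frac["pool"] == 1.0


class TestDatasetPipelines:
    def test_l_carrier_rule_end_to_end(self):
        entries = {f"l{i}": _entry(gt=1 if i == 0 else 0, dp=30, gq=60.0) for i in range(8)}
        meta = [SampleMeta(f"l{i}", "MED", "M", "L") for i in range(8)]
        from snpcatalog.genome import default_layout

        out = dataset_pipeline("L", [_site(1, entries)], meta, default_layout())
        assert out == []  # survives masking, fails the 2-of-8 carrier rule

    def test_s2_mnp_decomposed_and_masked(self, layout):
        meta = [SampleMeta("f1", "MED", "F", "S2"), SampleMeta("f2", "MED", "F", "S2")]
        mnp = _site(
            100,
            {
                "f1": _entry(gt=1, dp=30, gq=80.0),
                "f2": _entry(gt=1, dp=30, gq=10.0),  # fails GQ >= 30
            },
            ref="AT",
            alt="GC",
            vclass=VariantClass.MNP,
        )
        out = dataset_pipeline("S2", [mnp], meta, layout, max_missing_fraction=None)
        assert [(r.key.pos, r.key.ref, r.key.alt) for r in out] == [
            (100, "A", "G"),
            (101, "T", "C"),
        ]
        for r in out:
            assert r.entry("f1").gt == 1 and r.entry("f2").gt is None

    def test_filter_free_limit_is_biallelic_subset(self, layout, study):
        _, records = study.datasets["S1"]
        out = dataset_pipeline(
            "S1",
            records,
            study.metadata,
            layout,
            filters={"S1": FilterConfig()},
            max_missing_fraction=None,
        )
        assert [r.key for r in out] == [r.key for r in keep_biallelic_snps(records)]

    def test_unknown_tag_rejected(self, layout):
        with pytest.raises(ValueError):
            dataset_pipeline("S9", [], [], layout)

    def test_masking_and_site_filters_commute(self, layout, small_truth):
        from snpcatalog.simulate import DatasetProfile, simulate_individual_calls

        samples = [SampleMeta(f"m{i}", "MED", "M", "S1") for i in range(8)]
        records, _ = simulate_individual_calls(
            small_truth, samples, DatasetProfile((4, 25)), layout, seed=9
        )
        eligible = [s.sample_id for s in samples]
        config = FilterConfig(min_dp=8)
        mask_then_select = site_missingness_filter(
            mask_genotypes(records, config), 0.25, eligible
        )
        # selecting on post-mask missingness first, then masking, must agree
        keys = {r.key for r in mask_then_select}
        select_then_mask = mask_genotypes(
            [r for r in records if r.key in keys], config
        )
        assert [r.entries for r in mask_then_select] == [
            r.entries for r in select_then_mask
        ]


def test_brute_force_reference_agrees(layout, small_truth):
    """Site survival matches an independent per-record loop on 400 sites."""
    from snpcatalog.simulate import DatasetProfile, simulate_individual_calls

    samples = [SampleMeta(f"m{i}", "MED", "M", "S1") for i in range(10)]
    records, _ = simulate_individual_calls(
        small_truth, samples, DatasetProfile((3, 30)), layout, seed=21
    )
    eligible = [s.sample_id for s in samples]
    out = site_missingness_filter(
        mask_genotypes(records, FilterConfig(min_dp=6)), 0.2, eligible
    )
    survivors = set()
    for r in records:  # independent reference: explicit loop, no library calls
        n_missing = 0
        for s in eligible:
            e = r.entry(s)
            called = e.gt is not None and e.dp is not None and e.dp >= 6
            n_missing += 0 if called else 1
        if n_missing / len(eligible) <= 0.2:
            survivors.add(r.key)
    assert {r.key for r in out} == survivors
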