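"""Group-wise call rate and read-depth allele frequency; marker
selection and cross-group carry-over.

Call rate counts individuals' genotypes; AAF is the ratio of summed
alt-read depth to summed depth over all group members including DNA
pools.  High-confidence markers are those reliable (CR > 0.9) and
polymorphic (AAF in [0.02, 0.98]) in the MED reference group; the
carry-over fraction asks how many of them stay polymorphic in the
other groups.
"""

from snpcatalog.groupstats import (
    compute_group_stats,
    cross_group_carryover,
    select_high_confidence,
)
from snpcatalog.filters import dataset_pipeline
from snpcatalog.merge import (
    apply_merge_rules,
    dataset_presence,
    merge_genotypes,
    partition_membership,
)
from snpcatalog.simulate import StudyConfig, simulate_study

study = simulate_study(StudyConfig(n_variants=2000), seed=42)
filtered = {
    tag: dataset_pipeline(tag, records, study.metadata, study.layout)
    for tag, (_, records) in study.datasets.items()
}
partition = partition_membership(*([r.key for r in filtered[t]] for t in ("S1", "S2", "L")))
final_keys = apply_merge_rules(partition, study.layout)
merged = merge_genotypes(final_keys, filtered, study.metadata)

stats = compute_group_stats(
    merged, study.metadata, presence=dataset_presence(final_keys, partition)
)
med = stats[stats["group"] == "MED"]
selected = select_high_confidence(med)
print(f"catalog {len(final_keys)}; selected in MED: {len(selected)} "
      f"({100 * len(selected) / len(final_keys):.1f}%)")
for group in ("RIV", "SWA"):
    co = cross_group_carryover(selected, stats[stats["group"] == group])
    print(f"carry-over in {group}: {100 * co:.1f}%")

# Carry-over drops with divergence: RIV (river type, like MED) retains
# most markers; the strongly diverged SWA retains far fewer.
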