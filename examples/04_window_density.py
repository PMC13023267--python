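"""Per-chromosome density, inter-marker spacing, and 1-Mbp window counts.

The density-implied spacing is the reciprocal of markers/Mbp: a
chromosome at 6282 markers/Mbp has a marker every 159 bp.
"""

from snpcatalog.genome import make_windows
from snpcatalog.simulate import StudyConfig, simulate_study
from snpcatalog.windows import (
    chromosome_summaries,
    extreme_windows,
    genome_mean_density,
    implied_gap_bp,
    window_counts,
)

print(f"published-scale check: 6282/Mbp -> {implied_gap_bp(6282)} bp; "
      f"5108/Mbp -> {implied_gap_bp(5108)} bp")

study = simulate_study(StudyConfig(n_variants=2000), seed=42)
keys = study.truth.keys()
summaries = chromosome_summaries(keys, study.layout, classes={"AUTOSOME"})
print(summaries.round(2).to_string(index=False))

windows = make_windows(study.layout, 1_000_000, {"AUTOSOME"})
auto = {w.chrom for w in windows}
counts = window_counts([k for k in keys if k.chrom in auto], windows)
mean, sd = genome_mean_density(counts)
print(f"mean autosomal density {mean:.1f}/Mbp (sd {sd:.1f}); "
      f"implied spacing {1e6 / mean:.0f} bp")
top, bottom = extreme_windows(counts, 3, 3)
print("densest windows:\n", top.to_string(index=False))
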