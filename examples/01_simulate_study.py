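"""Generate the three synthetic call sets with known ground truth.

Three genetic groups (MED, RIV, SWA) diverge from a shared ancestral
population under the Balding-Nichols model; each dataset sees the truth
through its own depth regime and dropout.
"""

from snpcatalog.simulate import StudyConfig, simulate_study

study = simulate_study(StudyConfig(n_variants=2000), seed=42)

print(f"truth variants: {len(study.truth)}")
for tag, (samples, records) in study.datasets.items():
    chroms = sorted({r.key.chrom for r in records})
    print(f"{tag}: {len(samples)} samples, {len(records)} records, contigs={chroms}")
print(study.truth.variants.head(3).to_string(index=False))

# S2 is all-female (no Y records); L is long-read (no MT records).  The
# freq_* columns are the group allele frequencies each dataset's reads
# were drawn from -- downstream estimates can be checked against them.
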