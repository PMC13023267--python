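"""End-to-end orchestration: simulate → filter → merge → stats →
windows → chip → pca, with plain-text outputs and a run manifest.

Every tabular output is tab-separated text with a header; the manifest
records the seed, a config digest and per-stage row counts, so two runs
with the same config and seed are byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chip import availability_report, score_markers, selection_table, window_budget
from .filters import FilterConfig, dataset_pipeline, sample_missingness
from .genome import GenomeLayout, make_windows
from .groupstats import (
    SelectionThresholds,
    compute_group_stats,
    cross_group_carryover,
    select_high_confidence,
)
from .merge import (
    DEFAULT_MERGE_RULES,
    MergeRules,
    apply_merge_rules,
    dataset_presence,
    membership_table,
    merge_genotypes,
    partition_membership,
)
from .model import GROUPS, read_metadata, write_metadata
from .simulate import StudyConfig, StudyResult, simulate_study
from .structure import (
    build_dosage_matrix,
    dendrogram_newick,
    hierarchical_clusters,
    pca,
)
from .vcfio import read_vcf, write_vcf
from .windows import (
    chromosome_summaries,
    genome_mean_density,
    window_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str | Path = "snpcatalog_run"
    seed: int = 0
    # simulate mode (default) generates inputs; otherwise the three VCF
    # paths, the metadata table and the layout table must be given.
    simulate: bool = True
    study: StudyConfig = field(default_factory=StudyConfig)
    vcf_paths: dict[str, str] | None = None
    metadata_path: str | None = None
    layout_path: str | None = None
    filters_enabled: bool = True  # off: biallelic-SNP subset passes untouched
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    merge_rules: MergeRules = field(default_factory=lambda: dict(DEFAULT_MERGE_RULES))
    density_window_bp: int = 1_000_000
    chip_window_bp: int = 100_000
    chip_quota: int = 3
    chip_min_spacing: int = 0
    chip_weights: tuple[float, float] = (0.5, 0.5)
    pca_components: int = 10
    run_chip: bool = True
    run_pca: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML mapping.

        Nested ``study`` and ``thresholds`` mappings populate
        :class:`StudyConfig` and :class:`SelectionThresholds`; scalar keys
        map directly onto this dataclass's fields.
        """
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "study" in data:
            data["study"] = StudyConfig(**data["study"])
        if "thresholds" in data:
            data["thresholds"] = SelectionThresholds(**data["thresholds"])
        if "merge_rules" in data:
            data["merge_rules"] = {
                cls_name: frozenset(tags) for cls_name, tags in data["merge_rules"].items()
            }
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        fields = {k: v for k, v in vars(self).items() if k != "out_dir"}
        return hashlib.sha256(repr(sorted(fields.items())).encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; returns the manifest dict.

    All outputs land under ``config.out_dir``.  Stage order:
    simulate/load → per-dataset filters → membership partition and
    merge rules → group statistics and marker selection → density
    windows → chip budgeting → PCA/clustering.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
    }

    # ---- inputs -----------------------------------------------------
    if config.simulate:
        study: StudyResult = simulate_study(config.study, seed=config.seed)
        layout = study.layout
        metadata = study.metadata
        layout.to_tsv(out / "layout.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        study.truth.to_tsv(out / "truth.tsv")
        raw = {}
        for tag, (samples, records) in study.datasets.items():
            write_vcf(samples, records, out / f"{tag.lower()}.vcf", layout)
            raw[tag] = (samples, records)
        manifest["stages"]["simulate"] = {
            "n_truth_variants": len(study.truth),
            "records": {tag: len(r) for tag, (_, r) in raw.items()},
        }
    else:
        layout = GenomeLayout.from_tsv(config.layout_path)
        metadata = read_metadata(config.metadata_path)
        raw = {tag: read_vcf(path, layout) for tag, path in config.vcf_paths.items()}
        study = None
        manifest["stages"]["load"] = {
            "records": {tag: len(r) for tag, (_, r) in raw.items()}
        }

    # ---- per-dataset QC --------------------------------------------
    filtered = {}
    for tag in ("S1", "S2", "L"):
        samples, records = raw[tag]
        if config.filters_enabled:
            filtered[tag] = dataset_pipeline(tag, records, metadata, layout)
        else:
            filtered[tag] = dataset_pipeline(
                tag,
                records,
                metadata,
                layout,
                filters={t: FilterConfig() for t in ("S1", "S2", "L")},
                max_missing_fraction=None,
                min_carriers=None,
            )
        logger.info("filter %s: %d -> %d records", tag, len(records), len(filtered[tag]))
    manifest["stages"]["filter"] = {tag: len(r) for tag, r in filtered.items()}

    # ---- intersection and merge rules ------------------------------
    partition = partition_membership(
        [r.key for r in filtered["S1"]],
        [r.key for r in filtered["S2"]],
        [r.key for r in filtered["L"]],
    )
    membership_table(partition, layout, out / "membership.tsv")
    final_keys = apply_merge_rules(partition, layout, config.merge_rules)
    merged = merge_genotypes(final_keys, filtered, metadata)
    all_samples = [m.sample_id for m in metadata]
    write_vcf(all_samples, merged, out / "catalog.vcf", layout)
    manifest["stages"]["merge"] = {
        "n_union": len(partition),
        "n_final": len(final_keys),
    }

    # ---- group statistics and selection ----------------------------
    presence = dataset_presence(final_keys, partition)
    stats = compute_group_stats(merged, metadata, GROUPS, presence=presence)
    stats.to_csv(out / "group_stats.tsv", sep="\t", index=False)
    med = stats[stats["group"] == "MED"]
    selected = select_high_confidence(med, config.thresholds)
    carryover = {
        g: cross_group_carryover(
            selected, stats[stats["group"] == g], config.thresholds
        )
        for g in ("RIV", "SWA")
        if selected
    }
    missing = sample_missingness(merged, all_samples)
    pd.DataFrame(
        {"sample_id": list(missing), "missing_fraction": list(missing.values())}
    ).to_csv(out / "sample_missingness.tsv", sep="\t", index=False)
    manifest["stages"]["stats"] = {
        "n_selected_med": len(selected),
        "carryover": {g: round(v, 6) for g, v in carryover.items()},
    }

    # ---- density windows -------------------------------------------
    summaries = chromosome_summaries(final_keys, layout)
    summaries.to_csv(out / "chrom_summaries.tsv", sep="\t", index=False)
    auto_windows = make_windows(layout, config.density_window_bp, {"AUTOSOME"})
    auto_chroms = {w.chrom for w in auto_windows}
    counts = window_counts(
        [k for k in final_keys if k.chrom in auto_chroms], auto_windows
    )
    counts.to_csv(out / "window_counts.tsv", sep="\t", index=False)
    mean_density, sd_density = genome_mean_density(counts)
    manifest["stages"]["windows"] = {
        "mean_density_per_mbp": round(mean_density, 3),
        "sd_density_per_mbp": round(sd_density, 3),
    }

    # ---- chip candidates -------------------------------------------
    if config.run_chip and selected:
        selected_list = sorted(selected, key=lambda k: k.sort_tuple(layout.chrom_order))
        avail, mean_avail = availability_report(
            selected_list, layout, config.chip_window_bp
        )
        avail.to_csv(out / "chip_availability.tsv", sep="\t", index=False)
        selected_tuples = {(k.chrom, k.pos, k.ref, k.alt) for k in selected}
        sel_rows = med[
            [
                tuple(t) in selected_tuples
                for t in med[["chrom", "pos", "ref", "alt"]].itertuples(index=False)
            ]
        ]
        scored = score_markers(sel_rows, config.chip_weights)
        selections = window_budget(
            scored,
            layout,
            config.chip_window_bp,
            config.chip_quota,
            config.chip_min_spacing,
        )
        selection_table(selections).to_csv(
            out / "chip_selection.tsv", sep="\t", index=False
        )
        manifest["stages"]["chip"] = {
            "mean_available_per_window": round(mean_avail, 3),
            "n_windows_deficit": sum(s.deficit_flag for s in selections),
        }

    # ---- population structure --------------------------------------
    if config.run_pca:
        individuals = [m.sample_id for m in metadata if not m.is_pool]
        keep = [
            s for s in individuals if missing[s] <= config.thresholds.sample_missing_max
        ]
        matrix = build_dosage_matrix(merged, keep)
        result = pca(matrix, config.pca_components)
        coords = pd.DataFrame(
            result.coordinates,
            columns=[f"PC{i+1}" for i in range(result.coordinates.shape[1])],
        )
        coords.insert(0, "sample_id", result.samples)
        coords.to_csv(out / "pca_coordinates.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(result.variance_explained))],
                "variance_explained": result.variance_explained,
            }
        ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        linkage = hierarchical_clusters(matrix)
        (out / "dendrogram.nwk").write_text(
            dendrogram_newick(linkage, matrix.samples) + "\n"
        )
        manifest["stages"]["pca"] = {
            "n_samples": len(keep),
            "pc1_variance": round(float(result.variance_explained[0]), 6),
            "pc2_variance": round(float(result.variance_explained[1]), 6),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
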