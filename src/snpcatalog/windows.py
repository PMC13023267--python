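"""Marker density, inter-marker spacing, and fixed-width window counts.

Two spacing notions are computed: the empirical mean gap between
successive markers on a chromosome, and the density-implied gap
10^6 / (markers per Mbp).  The two are near-identical for dense,
uniform catalogs; the implied form is what the headline per-chromosome
numbers report, so it is the default display.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Window, make_windows
from .model import VariantKey

logger = logging.getLogger(__name__)

MBP = 1_000_000


def implied_gap_bp(density_per_mbp: float) -> int:
    """Density-implied inter-marker distance, rounded to the nearest bp."""
    if density_per_mbp <= 0:
        raise ValueError("density must be positive")
    return int(round(MBP / density_per_mbp))


def chromosome_summaries(
    keys: Sequence[VariantKey],
    layout: GenomeLayout,
    classes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome marker count, density per Mbp (over assembly
    length), empirical mean gap, and density-implied gap.

    Chromosomes with no markers are omitted; the empirical gap needs at
    least two markers and is NaN otherwise.
    """
    names = layout.names(classes)
    positions: dict[str, list[int]] = {n: [] for n in names}
    for key in keys:
        if key.chrom in positions:
            positions[key.chrom].append(key.pos)
    rows = []
    for name in names:
        pos = sorted(positions[name])
        if not pos:
            continue
        length = layout.length(name)
        density = len(pos) / (length / MBP)
        gaps = np.diff(pos)
        rows.append(
            (
                name,
                len(pos),
                length,
                density,
                float(np.mean(gaps)) if len(gaps) else np.nan,
                implied_gap_bp(density),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "n_snps",
            "length_bp",
            "density_per_mbp",
            "mean_gap_bp",
            "implied_gap_bp",
        ],
    )


def window_counts(
    keys: Sequence[VariantKey],
    windows: Sequence[Window],
) -> pd.DataFrame:
    """Exact marker count per window (chrom, start_bp, end_bp, n_snps).

    Every key must fall inside some window; window totals conserve the
    catalog size restricted to the windowed chromosomes.
    """
    starts: dict[str, list[int]] = {}
    index: dict[tuple[str, int], int] = {}
    for i, w in enumerate(windows):
        starts.setdefault(w.chrom, []).append(w.start_bp)
        index[(w.chrom, w.start_bp)] = i
    counts: Counter[int] = Counter()
    for key in keys:
        chrom_starts = starts.get(key.chrom)
        if chrom_starts is None:
            raise ValueError(f"key {key.chrom}:{key.pos} outside all windows")
        j = np.searchsorted(chrom_starts, key.pos, side="right") - 1
        if j < 0:
            raise ValueError(f"key {key.chrom}:{key.pos} before first window")
        w = windows[index[(key.chrom, chrom_starts[j])]]
        if key.pos > w.end_bp:
            raise ValueError(f"key {key.chrom}:{key.pos} outside all windows")
        counts[index[(key.chrom, chrom_starts[j])]] += 1
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start_bp": [w.start_bp for w in windows],
            "end_bp": [w.end_bp for w in windows],
            "span_bp": [w.span_bp for w in windows],
            "n_snps": [counts[i] for i in range(len(windows))],
        }
    )


def extreme_windows(
    counts: pd.DataFrame, k_top: int, k_bottom: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k densest and bottom-k sparsest windows (nonzero only for the
    bottom list); ties broken by table order (chrom order, start).
    """
    if counts.empty:
        raise ValueError("extreme_windows needs nonempty counts")
    nonzero = counts[counts["n_snps"] > 0]
    if k_top > len(counts) or k_bottom > len(nonzero):
        logger.info("extreme_windows: k exceeds available windows; truncating")
    top = counts.sort_values("n_snps", ascending=False, kind="stable").head(k_top)
    bottom = nonzero.sort_values("n_snps", ascending=True, kind="stable").head(k_bottom)
    return top.reset_index(drop=True), bottom.reset_index(drop=True)


def genome_mean_density(
    counts: pd.DataFrame, raw: bool = False
) -> tuple[float, float]:
    """Mean and population SD of per-window density, per Mbp.

    By default each window's count is scaled by its actual covered
    width; ``raw=True`` averages the raw counts instead (equivalent for
    full-width 1-Mbp windows, and the form the headline ±SD uses).
    """
    if counts.empty:
        raise ValueError("genome_mean_density needs at least one window")
    if raw:
        values = counts["n_snps"].to_numpy(dtype=float)
    else:
        values = counts["n_snps"].to_numpy(dtype=float) / (
            counts["span_bp"].to_numpy(dtype=float) / MBP
        )
    return float(np.mean(values)), float(np.std(values))


def window_bed_table(counts: pd.DataFrame, path) -> None:
    """Write counts as a BED-like table (0-based half-open start)."""
    out = counts.assign(start=counts["start_bp"] - 1)[
        ["chrom", "start", "end_bp", "n_snps"]
    ]
    out.to_csv(path, sep="\t", header=False, index=False)


def autosomal_window_counts(
    keys: Sequence[VariantKey],
    layout: GenomeLayout,
    width_bp: int = MBP,
    classes: set[str] = frozenset({"AUTOSOME"}),
) -> pd.DataFrame:
    """Convenience: tile the selected classes and count the keys there."""
    windows = make_windows(layout, width_bp, set(classes))
    chroms = {w.chrom for w in windows}
    return window_counts([k for k in keys if k.chrom in chroms], windows)
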