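"""Per-window candidate budgeting and spacing-constrained marker
selection for array design.

The budgeting step is pure counting: how many high-confidence
polymorphic markers fall in each fixed-width (default 100-kbp) window,
versus the per-window quota an array design implies (a 90K chip over a
~2.7-Gbp genome is roughly 3 markers per 100-kbp window; a
high-density chip about 26).  Selection then ranks candidates by a
composite of reliability (call rate) and informativeness
(1 − |2·AAF − 1|, maximal at AAF 0.5) and picks greedily under a
minimum-spacing constraint.  Greedy is not guaranteed optimal but with
dense candidates and small quotas the gap is negligible; a count-only
availability report reproduces the pure budget argument with no
scoring at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Window, make_windows
from .groupstats import KEY_COLUMNS
from .model import VariantKey
from .windows import window_counts


@dataclass(frozen=True)
class WindowSelection:
    window: Window
    candidates_available: int
    selected: tuple[VariantKey, ...]
    deficit_flag: bool


def score_markers(
    med_stats: pd.DataFrame, weights: tuple[float, float] = (0.5, 0.5)
) -> pd.DataFrame:
    """Score each marker: composite = w_cr·CR + w_info·(1 − |2·AAF − 1|).

    ``med_stats`` is the reference-group stat table restricted to the
    high-confidence set; weights must sum to 1.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    w_cr, w_info = weights
    out = med_stats[KEY_COLUMNS + ["call_rate", "aaf"]].copy()
    out["informativeness"] = 1.0 - np.abs(2.0 * out["aaf"] - 1.0)
    out["composite"] = w_cr * out["call_rate"] + w_info * out["informativeness"]
    return out


def window_budget(
    scored: pd.DataFrame,
    layout: GenomeLayout,
    window_width: int = 100_000,
    quota: int = 3,
    min_spacing: int = 0,
    classes: set[str] = frozenset({"AUTOSOME"}),
) -> list[WindowSelection]:
    """Greedy per-window selection under quota and spacing constraints.

    Candidates are taken highest-composite first (ties by position,
    ref, alt) and accepted only if at least ``min_spacing`` bp from
    every already-accepted marker in the window; ``deficit_flag`` marks
    windows that could not fill the quota.
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    if "composite" not in scored.columns:
        scored = score_markers(scored)
    windows = make_windows(layout, window_width, set(classes))
    by_window: dict[int, list[tuple]] = {i: [] for i in range(len(windows))}
    starts: dict[str, list[tuple[int, int]]] = {}
    for i, w in enumerate(windows):
        starts.setdefault(w.chrom, []).append((w.start_bp, i))
    for row in scored.itertuples(index=False):
        chrom_starts = starts.get(row.chrom)
        if chrom_starts is None:
            continue
        j = np.searchsorted([s for s, _ in chrom_starts], row.pos, side="right") - 1
        if j < 0:
            continue
        i = chrom_starts[j][1]
        if row.pos <= windows[i].end_bp:
            by_window[i].append(row)
    selections = []
    for i, w in enumerate(windows):
        candidates = sorted(
            by_window[i], key=lambda r: (-r.composite, r.pos, r.ref, r.alt)
        )
        picked: list = []
        for row in candidates:
            if len(picked) == quota:
                break
            if all(abs(row.pos - p.pos) >= min_spacing for p in picked):
                picked.append(row)
        picked.sort(key=lambda r: (r.pos, r.ref, r.alt))
        selections.append(
            WindowSelection(
                window=w,
                candidates_available=len(candidates),
                selected=tuple(
                    VariantKey(r.chrom, int(r.pos), r.ref, r.alt) for r in picked
                ),
                deficit_flag=len(picked) < quota,
            )
        )
    return selections


def availability_report(
    keys: list[VariantKey],
    layout: GenomeLayout,
    window_width: int = 100_000,
    classes: set[str] = frozenset({"AUTOSOME"}),
) -> tuple[pd.DataFrame, float]:
    """Count candidates per window; return (table, mean per window).

    The mean equals the genome mean per-Mbp density divided by
    (1 Mbp / window width) when all windows are full width.
    """
    windows = make_windows(layout, window_width, set(classes))
    chroms = {w.chrom for w in windows}
    table = window_counts([k for k in keys if k.chrom in chroms], windows)
    return table, float(table["n_snps"].mean())


def mean_availability_from_density(
    mean_density_per_mbp: float, window_width: int = 100_000
) -> float:
    """Mean candidates per window implied by a genome mean density."""
    return mean_density_per_mbp * window_width / 1_000_000


def selection_table(selections: list[WindowSelection]) -> pd.DataFrame:
    rows = []
    for sel in selections:
        for rank, key in enumerate(sel.selected, start=1):
            rows.append(
                (
                    sel.window.chrom,
                    sel.window.start_bp,
                    sel.window.end_bp,
                    rank,
                    key.chrom,
                    key.pos,
                    key.ref,
                    key.alt,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "window_chrom",
            "window_start",
            "window_end",
            "rank",
            "chrom",
            "pos",
            "ref",
            "alt",
        ],
    )
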