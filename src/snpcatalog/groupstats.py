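"""Per-variant, per-group call rate and read-depth-based allele frequency.

Two deliberately different denominators:

* call rate (CR) counts non-missing genotypes over *individuals* only —
  pools carry no genotypes and are excluded;
* alternative allele frequency (AAF) is the ratio of summed alt-read
  depth to summed total depth over *all* group members, pools included,
  skipping samples whose AD or DP is absent.  Zero total depth leaves
  the AAF undefined (NaN), never 0 — no reads carry no frequency
  information.

The polymorphism/reliability selection keeps variants whose group call
rate exceeds ``cr_min`` and whose AAF lies inside [``aaf_lo``,
``aaf_hi``]; the carry-over statistic asks what fraction of one group's
selected markers remain polymorphic in another group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GROUPS, SampleMeta, VariantKey, VariantRecord

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class SelectionThresholds:
    """Reliability/polymorphism cutoffs for the high-confidence marker set."""

    cr_min: float = 0.9  # strict: call rate must exceed this
    aaf_lo: float = 0.02
    aaf_hi: float = 0.98
    sample_missing_max: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.aaf_lo < self.aaf_hi <= 1:
            raise ValueError("need 0 <= aaf_lo < aaf_hi <= 1")


def compute_group_stats(
    records: Sequence[VariantRecord],
    metadata: Sequence[SampleMeta],
    groups: Sequence[str] = GROUPS,
    *,
    presence: Mapping[VariantKey, frozenset[str]] | None = None,
    aaf_respects_masking: bool = False,
) -> pd.DataFrame:
    """One row per (variant, group): n_eligible, n_called, call_rate,
    sum_ad_alt, sum_dp, aaf.

    ``presence`` maps each key to the datasets that contain it; when
    given, samples whose dataset lacks the key are excluded from the
    call-rate denominator (they are missing by merge rule, not by
    genotyping failure).  With ``aaf_respects_masking`` the AD/DP of
    individuals whose genotype is missing are left out of the AAF sums;
    by default they are kept, as the frequencies are read straight from
    the depth fields as reported.
    """
    members: dict[str, list[SampleMeta]] = {g: [] for g in groups}
    for m in metadata:
        if m.group in members:
            members[m.group].append(m)
    for g in groups:
        if not members[g]:
            raise ValueError(f"group {g!r} has no members")
    rows = []
    for record in records:
        key = record.key
        tags = presence.get(key) if presence is not None else None
        for g in groups:
            n_eligible = n_called = sum_ad_alt = sum_dp = 0
            for m in members[g]:
                if tags is not None and m.dataset not in tags:
                    continue
                entry = record.entry(m.sample_id)
                if not m.is_pool:
                    n_eligible += 1
                    if entry.gt is not None:
                        n_called += 1
                if aaf_respects_masking and not m.is_pool and entry.gt is None:
                    continue
                if entry.ad_alt is not None and entry.dp is not None:
                    sum_ad_alt += entry.ad_alt
                    sum_dp += entry.dp
            rows.append(
                (
                    key.chrom,
                    key.pos,
                    key.ref,
                    key.alt,
                    g,
                    n_eligible,
                    n_called,
                    n_called / n_eligible if n_eligible else np.nan,
                    sum_ad_alt,
                    sum_dp,
                    sum_ad_alt / sum_dp if sum_dp else np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=KEY_COLUMNS
        + ["group", "n_eligible", "n_called", "call_rate", "sum_ad_alt", "sum_dp", "aaf"],
    )


def _keys(frame: pd.DataFrame) -> set[VariantKey]:
    return {
        VariantKey(c, int(p), r, a)
        for c, p, r, a in frame[KEY_COLUMNS].itertuples(index=False)
    }


def select_high_confidence(
    med_stats: pd.DataFrame, thresholds: SelectionThresholds = SelectionThresholds()
) -> set[VariantKey]:
    """Keys reliable and polymorphic in the reference group.

    Call rate strictly greater than ``cr_min``; AAF within the closed
    polymorphism band.  Undefined AAF (zero group depth) never passes.
    """
    mask = (
        (med_stats["call_rate"] > thresholds.cr_min)
        & (med_stats["aaf"] >= thresholds.aaf_lo)
        & (med_stats["aaf"] <= thresholds.aaf_hi)
    )
    return _keys(med_stats[mask.fillna(False)])


def cross_group_carryover(
    selected_keys: set[VariantKey],
    other_stats: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> float:
    """Fraction of the selected markers still polymorphic in another group.

    Keys with undefined AAF in the other group count in the denominator
    but never in the numerator.
    """
    if not selected_keys:
        raise ValueError("cross_group_carryover needs a nonempty selected set")
    frame = other_stats[
        [
            VariantKey(c, int(p), r, a) in selected_keys
            for c, p, r, a in other_stats[KEY_COLUMNS].itertuples(index=False)
        ]
    ]
    poly = (frame["aaf"] >= thresholds.aaf_lo) & (frame["aaf"] <= thresholds.aaf_hi)
    n_defined = int(frame["aaf"].notna().sum())
    if n_defined == 0:
        logger.warning("cross_group_carryover: no defined AAF in the other group")
        return 0.0
    return float(poly.fillna(False).sum()) / len(selected_keys)


def _histogram(values: np.ndarray, bins: Sequence[float]) -> pd.DataFrame:
    edges = np.asarray(bins, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(values, bins=edges)  # left-closed; last bin closed
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def cr_distribution(stats: pd.DataFrame, bins: Sequence[float]) -> pd.DataFrame:
    """Histogram of per-variant call rate (one group's rows)."""
    if stats.empty:
        raise ValueError("cr_distribution needs nonempty stats")
    return _histogram(stats["call_rate"].dropna().to_numpy(), bins)


def aaf_spectrum(stats: pd.DataFrame, bins: Sequence[float]) -> pd.DataFrame:
    """Histogram of per-variant AAF; undefined AAFs are excluded."""
    if stats.empty:
        raise ValueError("aaf_spectrum needs nonempty stats")
    return _histogram(stats["aaf"].dropna().to_numpy(), bins)
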