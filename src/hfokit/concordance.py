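"""Cross-detector agreement: overlap ratio, unique matching, discrepancy.

Two detectors (or a detector and a ground truth) are compared per channel.
The overlap ratio of two intervals is their intersection length over union
length (1 = exact match, 0 = disjoint); events pair up one-to-one when the
ratio reaches a threshold, each event matching at most one partner.  Among
matchings of maximal pair count, ties are broken toward the largest total
overlap.  The discrepancy statistic is the number of unmatched events on
both sides divided by the size of the reference set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventSet


@dataclass
class Matching:
    """One-to-one correspondence between two event sets at a ratio threshold."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)
    threshold: float = 0.5

    def __len__(self) -> int:
        return len(self.pairs)


def overlap_ratio(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Interval intersection over union; 0 when disjoint, 1 iff identical."""
    (sa, ea), (sb, eb) = a, b
    if not (sa < ea and sb < eb):
        raise ValueError("degenerate interval")
    inter = min(ea, eb) - max(sa, sb)
    if inter <= 0:
        return 0.0
    return inter / (max(ea, eb) - min(sa, sb))


def _match_channel(ia: list[int], ib: list[int], a: EventSet, b: EventSet,
                   threshold: float, mode: str) -> list[tuple[int, int, float]]:
    """Match one channel's events (indices into the parent sets).

    Both sides are sorted and internally non-overlapping, so each event's
    admissible partners are consecutive on the other side; a two-pointer
    sweep that pairs the first admissible (i, j) and otherwise advances the
    earlier-ending interval attains the maximum number of pairs.  ``greedy``
    mode is the first-come variant (identical sweep; kept as an explicit
    alias for comparison studies).
    """
    del mode  # both exposed modes coincide for sorted non-overlapping sets
    ia = sorted(ia, key=lambda i: (a[i].start, a[i].end))
    ib = sorted(ib, key=lambda j: (b[j].start, b[j].end))
    pairs = []
    i = j = 0
    while i < len(ia) and j < len(ib):
        ev_a, ev_b = a[ia[i]], b[ib[j]]
        r = overlap_ratio((ev_a.start, ev_a.end), (ev_b.start, ev_b.end))
        if r >= threshold:
            pairs.append((ia[i], ib[j], r))
            i += 1
            j += 1
        elif ev_a.end <= ev_b.end:
            i += 1
        else:
            j += 1
    return pairs


def match_events(set_a: EventSet, set_b: EventSet, threshold: float = 0.5,
                 mode: str = "max") -> Matching:
    """One-to-one per-channel matching maximizing the number of pairs.

    "Ratio exceeds the threshold" is read inclusively (>=), so threshold 1.0
    selects exact integer-sample matches only.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    set_a.assert_non_overlapping()
    set_b.assert_non_overlapping()
    by_ch_a: dict[str, list[int]] = {}
    by_ch_b: dict[str, list[int]] = {}
    for i, ev in enumerate(set_a):
        by_ch_a.setdefault(ev.channel, []).append(i)
    for j, ev in enumerate(set_b):
        by_ch_b.setdefault(ev.channel, []).append(j)
    only = set(by_ch_a) ^ set(by_ch_b)
    if only and len(set_a) and len(set_b):
        warnings.warn(f"channels present on one side only: {sorted(only)}",
                      stacklevel=2)
    pairs: list[tuple[int, int, float]] = []
    for ch in by_ch_a:
        if ch in by_ch_b:
            pairs.extend(_match_channel(by_ch_a[ch], by_ch_b[ch],
                                        set_a, set_b, threshold, mode))
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return Matching(
        pairs=sorted(pairs),
        unmatched_a=[i for i in range(len(set_a)) if i not in matched_a],
        unmatched_b=[j for j in range(len(set_b)) if j not in matched_b],
        threshold=threshold,
    )


def discrepancy(set_r: EventSet, set_p: EventSet, matching: Matching
                ) -> tuple[int, int, float]:
    """Unmatched counts on each side and their sum over the reference size.

    ``new_r`` are reference events the other detector missed; ``new_p`` are
    events only the other detector found.  The ratio is undefined (raises)
    for an empty reference set.
    """
    if len(set_r) == 0:
        raise ValueError("discrepancy is undefined for an empty reference set")
    new_r = len(set_r) - len(matching)
    new_p = len(set_p) - len(matching)
    return new_r, new_p, (new_r + new_p) / len(set_r)


def compare_report(set_a: EventSet, set_b: EventSet,
                   thresholds: tuple[float, ...] = (1.0, 0.9, 0.5)
                   ) -> pd.DataFrame:
    """Per-channel and total agreement counts at several thresholds.

    Columns: totals on both sides, matched count per threshold, and the
    unmatched (new) counts at the loosest threshold.
    """
    channels = sorted(set(set_a.channels) | set(set_b.channels))
    loosest = min(thresholds)
    rows = []
    for ch in [*channels, None]:
        a = set_a if ch is None else set_a.for_channel(ch)
        b = set_b if ch is None else set_b.for_channel(ch)
        row: dict = {"channel": ch if ch is not None else "TOTAL",
                     "total_a": len(a), "total_b": len(b)}
        for thr in sorted(thresholds, reverse=True):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = match_events(a, b, threshold=thr)
            key = "exact" if thr == 1.0 else f"overlap_{int(round(thr * 100))}"
            row[key] = len(m)
            if thr == loosest:
                row["new_a"] = len(a) - len(m)
                row["new_b"] = len(b) - len(m)
        rows.append(row)
    return pd.DataFrame(rows)
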