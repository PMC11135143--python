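"""Event containers shared by detectors, classifiers and concordance analysis.

Sample coordinates are 0-based and half-open: an event occupies samples
``start <= i < end``.  Time in seconds is ``sample / sample_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

#: final labels an event can carry after classification
LABELS = ("artifact", "spkHFO", "non-spkHFO")


@dataclass(frozen=True)
class HfoEvent:
    """A detected oscillatory event on one channel, in sample coordinates."""

    channel: str
    start: int
    end: int
    detector: str = ""
    label: str | None = None
    probability: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid event interval [{self.start}, {self.end}) on {self.channel!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def center(self) -> float:
        """Midpoint of the half-open interval, in (fractional) samples."""
        return (self.start + self.end) / 2.0

    def with_label(self, label: str, probability: float | None = None) -> "HfoEvent":
        return replace(self, label=label, probability=probability)


@dataclass
class EventSet:
    """An ordered collection of events plus the metadata needed to interpret them.

    ``sample_rate`` converts sample coordinates to seconds; ``meta`` carries a
    free-form record of the detector and parameters that produced the events.
    """

    events: list[HfoEvent] = field(default_factory=list)
    sample_rate: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[HfoEvent]:
        return iter(self.events)

    def __getitem__(self, i: int) -> HfoEvent:
        return self.events[i]

    @property
    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.channel, None)
        return list(seen)

    def for_channel(self, channel: str) -> "EventSet":
        return EventSet(
            [ev for ev in self.events if ev.channel == channel],
            sample_rate=self.sample_rate,
            meta=self.meta,
        )

    def sorted(self) -> "EventSet":
        evs = sorted(self.events, key=lambda e: (e.channel, e.start, e.end))
        return EventSet(evs, sample_rate=self.sample_rate, meta=self.meta)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": [e.channel for e in self.events],
                "start": np.array([e.start for e in self.events], dtype=np.int64),
                "end": np.array([e.end for e in self.events], dtype=np.int64),
                "detector": [e.detector for e in self.events],
                "label": [e.label if e.label is not None else "" for e in self.events],
                "probability": np.array(
                    [e.probability if e.probability is not None else np.nan for e in self.events],
                    dtype=float,
                ),
            }
        )

    def assert_non_overlapping(self) -> None:
        """Raise if two events on the same channel overlap (detector contract)."""
        for ch in self.channels:
            evs = sorted(self.for_channel(ch).events, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping events on {ch!r}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
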