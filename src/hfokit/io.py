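"""Calibrated EEG input/output.

Reads EDF/EDF+ recordings, converting stored digital integers into physical
units with the affine calibration used by mainstream EEG software::

    V = R * D_raw + O,   R = (V_max - V_min) / (D_max - D_min),
                         O = V_min - R * D_min

(in contrast with gain-only readers that drop the offset ``O`` and leave a DC
shift in the data).  Also wraps raw numeric arrays, derives bipolar montages,
and exports/loads event sets as NPZ or Excel workbooks.

The EDF layout handled here is the continuous 16-bit one: ASCII headers of
256 bytes (global) + 256 bytes per signal, followed by little-endian int16
data records.  EDF+ annotation channels and discontinuities are ignored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventSet, HfoEvent


class EdfHeaderError(ValueError):
    """Raised for malformed or unsupported EDF headers."""


# ---------------------------------------------------------------------------
# recording container


@dataclass
class Recording:
    """Multichannel signal matrix in physical units with a single sampling rate."""

    channel_names: list[str]
    sample_rate: float
    signals: np.ndarray  # (n_channels, n_samples), physical units

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (channels x samples) array")
        if len(self.channel_names) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} names for {self.signals.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
        return self.signals[idx]

    def pick(self, names: list[str]) -> "Recording":
        data = np.stack([self.channel(n) for n in names])
        return Recording(list(names), self.sample_rate, data)


@dataclass
class CalibrationInfo:
    """Per-channel digital-to-physical calibration ranges from an EDF header."""

    v_min: np.ndarray
    v_max: np.ndarray
    d_min: np.ndarray
    d_max: np.ndarray

    def __post_init__(self) -> None:
        self.v_min = np.asarray(self.v_min, dtype=np.float64)
        self.v_max = np.asarray(self.v_max, dtype=np.float64)
        self.d_min = np.asarray(self.d_min, dtype=np.float64)
        self.d_max = np.asarray(self.d_max, dtype=np.float64)
        if np.any(self.d_max <= self.d_min):
            raise EdfHeaderError("degenerate calibration: digital max must exceed digital min")
        if np.any(self.v_max == self.v_min):
            raise EdfHeaderError("degenerate calibration: physical max equals physical min")

    def pick(self, indices: list[int]) -> "CalibrationInfo":
        return CalibrationInfo(
            self.v_min[indices], self.v_max[indices], self.d_min[indices], self.d_max[indices]
        )

    def gain_offset(self, channel: int = 0) -> tuple[float, float]:
        r = (self.v_max[channel] - self.v_min[channel]) / (
            self.d_max[channel] - self.d_min[channel]
        )
        o = self.v_min[channel] - r * self.d_min[channel]
        return float(r), float(o)


def calibrate(d_raw: np.ndarray, cal: CalibrationInfo, channel: int = 0) -> np.ndarray:
    """Map digital values to physical units: ``V = R * d_raw + O``.

    The map is affine and exact at both range endpoints
    (``d_min -> v_min``, ``d_max -> v_max``).
    """
    r, o = cal.gain_offset(channel)
    return r * np.asarray(d_raw, dtype=np.float64) + o


# ---------------------------------------------------------------------------
# EDF reading / writing


def _ascii(b: bytes) -> str:
    return b.decode("ascii", errors="replace").strip()


def read_edf(path: str | os.PathLike, channels: list[str] | None = None
             ) -> tuple[Recording, CalibrationInfo]:
    """Read a continuous EDF/EDF+ file into a calibrated :class:`Recording`.

    ``channels`` selects a subset by name, preserved in request order.  All
    selected channels must share one sampling rate; files mixing rates among
    the selected channels are rejected rather than resampled.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise EdfHeaderError(f"truncated EDF header in {path}")
        try:
            n_records = int(_ascii(hdr[236:244]))
            ns = int(_ascii(hdr[252:256]))
        except ValueError as exc:
            raise EdfHeaderError(f"malformed EDF header in {path}") from exc
        if ns <= 0:
            raise EdfHeaderError("EDF header reports no signals")
        try:
            record_dur = float(_ascii(hdr[244:252]))
        except ValueError as exc:
            raise EdfHeaderError("malformed record duration") from exc

        sig_hdr = fh.read(ns * 256)
        if len(sig_hdr) < ns * 256:
            raise EdfHeaderError("truncated EDF signal headers")

        def fld(offset: int, width: int, i: int) -> str:
            base = offset * ns + i * width
            return _ascii(sig_hdr[base:base + width])

        labels = [fld(0, 16, i) for i in range(ns)]
        try:
            phys_min = np.array([float(fld(104, 8, i)) for i in range(ns)])
            phys_max = np.array([float(fld(112, 8, i)) for i in range(ns)])
            dig_min = np.array([float(fld(120, 8, i)) for i in range(ns)])
            dig_max = np.array([float(fld(128, 8, i)) for i in range(ns)])
            samples_per_rec = np.array([int(fld(216, 8, i)) for i in range(ns)])
        except ValueError as exc:
            raise EdfHeaderError("malformed EDF signal header fields") from exc

        data = np.fromfile(fh, dtype="<i2")

    # drop EDF+ annotation channels
    keep = [i for i in range(ns) if labels[i] != "EDF Annotations"]
    if channels is not None:
        if not channels:
            raise ValueError("empty channel request")
        by_name = {labels[i]: i for i in keep}
        missing = [c for c in channels if c not in by_name]
        if missing:
            raise KeyError(f"channels not in file: {missing}")
        keep = [by_name[c] for c in channels]

    rates = {samples_per_rec[i] / record_dur for i in keep}
    if len(rates) != 1:
        raise EdfHeaderError(
            "channels with heterogeneous sampling rates are not supported; "
            "pick a homogeneous subset via the channels argument"
        )
    sample_rate = rates.pop()

    rec_len = int(samples_per_rec.sum())
    if n_records < 0:  # -1 means "unknown" per the EDF spec
        n_records = data.size // rec_len
    data = data[: n_records * rec_len].reshape(n_records, rec_len)
    offsets = np.concatenate([[0], np.cumsum(samples_per_rec)])

    cal = CalibrationInfo(phys_min[keep], phys_max[keep], dig_min[keep], dig_max[keep])
    signals = np.empty((len(keep), n_records * int(samples_per_rec[keep[0]])))
    for out_i, i in enumerate(keep):
        dig = data[:, offsets[i]:offsets[i + 1]].reshape(-1)
        signals[out_i] = calibrate(dig, cal, out_i)
    names = [labels[i] for i in keep]
    if len(set(names)) != len(names):
        names = [f"{n}#{i}" if names.count(n) > 1 else n for i, n in enumerate(names)]
    return Recording(names, sample_rate, signals), cal


def write_edf(path: str | os.PathLike, rec: Recording,
              physical_range: tuple[float, float] | None = None) -> CalibrationInfo:
    """Write a :class:`Recording` as a 16-bit continuous EDF file.

    Quantizes each channel onto the full int16 digital range against a shared
    physical range (default: symmetric range covering the data).  Returns the
    calibration actually written, so round-trip error can be bounded by one
    quantization step.
    """
    fs = rec.sample_rate
    # one record per second when fs is integral, else a single record
    if abs(fs - round(fs)) < 1e-9 and rec.n_samples % int(round(fs)) == 0:
        spr = int(round(fs))
        record_dur = 1.0
    else:
        spr = rec.n_samples
        record_dur = rec.n_samples / fs
    n_records = rec.n_samples // spr

    if physical_range is None:
        vmax = float(np.max(np.abs(rec.signals)))
        vmax = vmax if vmax > 0 else 1.0
        physical_range = (-vmax, vmax)
    v_min, v_max = physical_range
    d_min, d_max = -32768, 32767
    ns = rec.n_channels
    cal = CalibrationInfo(
        np.full(ns, v_min), np.full(ns, v_max), np.full(ns, d_min), np.full(ns, d_max)
    )
    r, o = cal.gain_offset(0)
    dig = np.clip(np.round((rec.signals - o) / r), d_min, d_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8), pad("EDF+C", 44),
        pad(str(n_records), 8), pad(f"{record_dur:g}", 8), pad(str(ns), 4),
    ])
    cols: list[tuple[int, list[str]]] = [
        (16, list(rec.channel_names)),
        (80, ["EEG"] * ns),
        (8, ["uV"] * ns),
        (8, [f"{v_min:g}"] * ns),
        (8, [f"{v_max:g}"] * ns),
        (8, [str(d_min)] * ns),
        (8, [str(d_max)] * ns),
        (80, [""] * ns),
        (8, [str(spr)] * ns),
        (32, [""] * ns),
    ]
    sig_hdr = b"".join(b"".join(pad(v, w) for v in vals) for w, vals in cols)

    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(sig_hdr)
        for rec_i in range(n_records):
            sl = slice(rec_i * spr, (rec_i + 1) * spr)
            fh.write(dig[:, sl].tobytes())
    return cal


# ---------------------------------------------------------------------------
# array input and montages


def from_array(values: np.ndarray, sample_rate: float, names: list[str]) -> Recording:
    """Wrap an already-physical channels x samples matrix as a Recording."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("values must be 2-D (channels x samples)")
    if not names:
        raise ValueError("channel name list is empty")
    return Recording(list(names), sample_rate, values)


def make_bipolar(rec: Recording, pairs: list[tuple[str, str]]) -> Recording:
    """Derive a bipolar montage: each output channel is anode - cathode."""
    names, rows = [], []
    for anode, cathode in pairs:
        rows.append(rec.channel(anode) - rec.channel(cathode))
        names.append(f"{anode}-{cathode}")
    return Recording(names, rec.sample_rate, np.stack(rows))


# ---------------------------------------------------------------------------
# NPZ recording container


def save_recording_npz(path: str | os.PathLike, rec: Recording) -> None:
    np.savez(path, signals=rec.signals, sample_rate=rec.sample_rate,
             channel_names=np.array(rec.channel_names))


def load_recording_npz(path: str | os.PathLike) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(
            [str(n) for n in z["channel_names"]], float(z["sample_rate"]), z["signals"]
        )


# ---------------------------------------------------------------------------
# event export / import


def _summary_frame(events: EventSet) -> pd.DataFrame:
    df = events.to_dataframe()
    rows = []
    for ch in events.channels:
        sub = df[df.channel == ch]
        rows.append({
            "channel": ch,
            "total": len(sub),
            "artifact": int((sub.label == "artifact").sum()),
            "spkHFO": int((sub.label == "spkHFO").sum()),
            "non-spkHFO": int((sub.label == "non-spkHFO").sum()),
        })
    return pd.DataFrame(rows, columns=["channel", "total", "artifact", "spkHFO", "non-spkHFO"])


def export_events(events: EventSet, path: str | os.PathLike, format: str | None = None) -> None:
    """Write an EventSet as ``xlsx`` (two sheets: channels, events) or ``npz``.

    The NPZ layout holds parallel arrays (channel, start, end, detector,
    label, probability) plus sample rate and metadata, and reloads losslessly
    via :func:`load_events_npz`.
    """
    path = os.fspath(path)
    if format is None:
        format = "xlsx" if path.endswith(".xlsx") else "npz"
    if format == "xlsx":
        with pd.ExcelWriter(path) as xw:
            _summary_frame(events).to_excel(xw, sheet_name="channels", index=False)
            events.to_dataframe().to_excel(xw, sheet_name="events", index=False)
    elif format == "npz":
        df = events.to_dataframe()
        meta_keys = sorted(events.meta)
        np.savez(
            path,
            channel=df.channel.to_numpy(dtype="U64"),
            start=df.start.to_numpy(),
            end=df.end.to_numpy(),
            detector=df.detector.to_numpy(dtype="U16"),
            label=df.label.to_numpy(dtype="U16"),
            probability=df.probability.to_numpy(),
            sample_rate=events.sample_rate,
            meta_keys=np.array(meta_keys, dtype="U64"),
            meta_values=np.array([str(events.meta[k]) for k in meta_keys], dtype="U256"),
        )
    else:
        raise ValueError(f"unknown export format {format!r}")


def load_events_npz(path: str | os.PathLike) -> EventSet:
    with np.load(path, allow_pickle=False) as z:
        events = [
            HfoEvent(
                channel=str(ch), start=int(s), end=int(e), detector=str(det),
                label=str(lab) if str(lab) else None,
                probability=float(p) if np.isfinite(p) else None,
            )
            for ch, s, e, det, lab, p in zip(
                z["channel"], z["start"], z["end"], z["detector"], z["label"], z["probability"]
            )
        ]
        meta = {str(k): str(v) for k, v in zip(z["meta_keys"], z["meta_values"])}
        return EventSet(events, sample_rate=float(z["sample_rate"]), meta=meta)
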