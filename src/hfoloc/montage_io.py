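"""Core data containers, recording I/O, bipolar montage, and SOZ label handling.

Intracranial EEG for HFO analysis arrives as a multichannel recording
(subdural grids/strips and depth electrodes), is re-referenced to a bipolar
montage within each electrode, and is analyzed in a set of fixed-length
epochs.  This module defines the in-memory containers shared by the rest of
the package (:class:`Recording`, :class:`ChannelLabels`, :class:`Event`,
:class:`EventSet`) and the plain-text interchange formats used for them.

Conventions
-----------
* All event times are seconds, recording-relative, half-open ``[start, stop)``.
* Sample values are microvolts.
* An electrode group is an ordered list of contacts belonging to one physical
  electrode (grid, strip, or depth); bipolar pairing never crosses groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeGroup",
    "Recording",
    "ChannelLabels",
    "Event",
    "EventSet",
    "read_recording",
    "write_recording",
    "bipolar_rereference",
    "propagate_soz",
    "slice_recording",
    "read_labels",
    "write_labels",
]

EVENT_COLUMNS = ["channel", "start_s", "stop_s", "source", "confidence"]


@dataclass(frozen=True)
class ElectrodeGroup:
    """One physical electrode: ordered contacts plus geometry.

    ``kind`` is one of ``grid | strip | depth``.  For grids, ``shape``
    gives (rows, cols) with ``channels`` listed row-major; bipolar pairs are
    formed along rows.  Strips and depths are 1-D and pair consecutively.
    """

    name: str
    channels: tuple[str, ...]
    kind: str = "depth"
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("grid", "strip", "depth"):
            raise ValueError(f"unknown electrode kind {self.kind!r}")
        if self.kind == "grid":
            shape = self.shape or (1, len(self.channels))
            if shape[0] * shape[1] != len(self.channels):
                raise ValueError(
                    f"grid {self.name}: shape {shape} does not match "
                    f"{len(self.channels)} contacts"
                )
            object.__setattr__(self, "shape", shape)

    def rows(self) -> list[tuple[str, ...]]:
        """Contact rows along which bipolar pairs are formed."""
        if self.kind == "grid" and self.shape is not None:
            r, c = self.shape
            return [tuple(self.channels[i * c : (i + 1) * c]) for i in range(r)]
        return [tuple(self.channels)]


@dataclass
class Recording:
    """A multichannel iEEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Samples in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel labels, ordered as the rows of ``data``.
    groups : list of ElectrodeGroup
        Partition of ``channels`` into electrode groups.
    epochs : list of (float, float)
        Analysis windows in seconds, non-overlapping and within the record.
        ``None`` means one epoch covering the whole record.
    pairs : dict or None
        For bipolar recordings: channel label -> (anode, cathode) contact
        labels of the original montage.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    groups: list[ElectrodeGroup] = field(default_factory=list)
    epochs: list[tuple[float, float]] | None = None
    pairs: dict[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel count does not match data rows")
        if not self.groups:
            self.groups = [
                ElectrodeGroup(name="ALL", channels=tuple(self.channels))
            ]
        grouped = [c for g in self.groups for c in g.channels]
        if sorted(grouped) != sorted(self.channels):
            raise ValueError("groups must partition the channel set exactly")
        if self.epochs is None:
            self.epochs = [(0.0, self.n_samples / self.fs)]
        self._check_epochs()

    def _check_epochs(self) -> None:
        assert self.epochs is not None
        dur = self.n_samples / self.fs
        prev_stop = -np.inf
        for start, stop in sorted(self.epochs):
            if stop <= start:
                raise ValueError(f"empty epoch ({start}, {stop})")
            if start < prev_stop:
                raise ValueError("epochs overlap")
            if start < 0 or stop > dur + 1e-9:
                raise ValueError(f"epoch ({start}, {stop}) outside record")
            prev_stop = stop

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def total_minutes(self) -> float:
        assert self.epochs is not None
        return sum(stop - start for start, stop in self.epochs) / 60.0

    def channel_index(self, channel: str) -> int:
        return self.channels.index(channel)

    def get(self, channel: str) -> np.ndarray:
        return self.data[self.channel_index(channel)]

    def group_of(self, channel: str) -> ElectrodeGroup:
        for g in self.groups:
            if channel in g.channels:
                return g
        raise KeyError(channel)

    def epoch_slice(self, epoch: tuple[float, float]) -> slice:
        start, stop = epoch
        i0 = int(round(start * self.fs))
        i1 = min(int(round(stop * self.fs)), self.n_samples)
        return slice(i0, i1)


@dataclass(frozen=True)
class ChannelLabels:
    """SOZ / non-SOZ partition of the analyzed channels."""

    soz: frozenset[str]
    nsoz: frozenset[str]

    def __post_init__(self) -> None:
        if self.soz & self.nsoz:
            raise ValueError("soz and nsoz overlap")

    @classmethod
    def from_soz(cls, soz: Iterable[str], channels: Iterable[str]) -> "ChannelLabels":
        soz = frozenset(soz)
        channels = frozenset(channels)
        missing = soz - channels
        if missing:
            raise ValueError(f"SOZ labels not among channels: {sorted(missing)}")
        return cls(soz=soz, nsoz=channels - soz)

    @property
    def channels(self) -> frozenset[str]:
        return self.soz | self.nsoz

    def is_soz(self, channel: str) -> bool:
        return channel in self.soz


@dataclass(frozen=True, order=True)
class Event:
    """A per-channel time interval ``[start, stop)`` in seconds."""

    channel: str
    start: float
    stop: float
    source: str = "automatic"  # automatic | visual | truth
    confidence: str = "n/a"  # high | low | n/a
    n_peaks: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.stop > self.start:
            raise ValueError(f"event stop must exceed start: {self}")

    @property
    def duration(self) -> float:
        return self.stop - self.start


class EventSet:
    """An ordered collection of :class:`Event`, sorted by (channel, start)."""

    def __init__(self, events: Iterable[Event] = ()) -> None:
        self.events: list[Event] = sorted(events, key=lambda e: (e.channel, e.start, e.stop))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventSet):
            return NotImplemented
        return self.events == other.events

    def __repr__(self) -> str:
        return f"EventSet(n={len(self)})"

    def for_channel(self, channel: str) -> list[Event]:
        return [e for e in self.events if e.channel == channel]

    @property
    def channels(self) -> list[str]:
        return sorted({e.channel for e in self.events})

    def within(self, start: float, stop: float) -> "EventSet":
        """Events whose interval lies entirely inside ``[start, stop)``."""
        return EventSet(e for e in self.events if e.start >= start and e.stop <= stop)

    def filter(self, pred) -> "EventSet":
        return EventSet(e for e in self.events if pred(e))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.channel] = out.get(e.channel, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.channel, e.start, e.stop, e.source, e.confidence) for e in self.events],
            columns=EVENT_COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventSet":
        events = [
            Event(
                channel=str(row.channel),
                start=float(row.start_s),
                stop=float(row.stop_s),
                source=str(row.source),
                confidence=str(row.confidence),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(events)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "EventSet":
        frame = pd.read_csv(path, keep_default_na=False)  # keep "n/a" literal
        missing = set(EVENT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"event file {path} lacks columns {sorted(missing)}")
        return cls.from_frame(frame)


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    for ext in (".json", ".yaml", ".yml"):
        cand = path.with_suffix(ext)
        if cand.exists():
            return cand
    return path.with_suffix(".json")


def _load_sidecar(path: Path) -> dict:
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return json.load(fh)


def _groups_from_meta(meta: dict, channels: list[str]) -> list[ElectrodeGroup]:
    groups = []
    for g in meta.get("groups", []):
        groups.append(
            ElectrodeGroup(
                name=g["name"],
                channels=tuple(g["channels"]),
                kind=g.get("kind", "depth"),
                shape=tuple(g["shape"]) if g.get("shape") else None,
            )
        )
    return groups


def read_recording(path: str | Path, format: str = "auto") -> Recording:
    """Read a recording from EDF or a delimited numeric matrix.

    The matrix format is a headered CSV with one column per channel and one
    row per sample, accompanied by a JSON/YAML sidecar (same stem) carrying
    ``fs``, ``groups`` and optionally ``epochs``.  EDF files are read through
    :mod:`mne`; every signal must share one sampling rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        channels = list(raw.ch_names)
        return Recording(data=data, fs=float(raw.info["sfreq"]), channels=channels)
    if format != "matrix":
        raise ValueError(f"unknown format {format!r}")
    frame = pd.read_csv(path)
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"sidecar metadata for {path} not found")
    meta = _load_sidecar(meta_path)
    if "fs" not in meta:
        raise ValueError(f"sidecar {meta_path} lacks 'fs'")
    channels = meta.get("channels", list(frame.columns))
    if list(frame.columns) != list(channels):
        raise ValueError("sidecar channel list does not match matrix columns")
    epochs = [tuple(e) for e in meta["epochs"]] if meta.get("epochs") else None
    return Recording(
        data=frame.to_numpy().T,
        fs=float(meta["fs"]),
        channels=list(channels),
        groups=_groups_from_meta(meta, list(channels)),
        epochs=epochs,
    )


def write_recording(rec: Recording, path: str | Path, fmt: str = "%.6f") -> None:
    """Write a recording as delimited matrix + JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame(rec.data.T, columns=rec.channels)
    frame.to_csv(path, index=False, float_format=fmt)
    meta = {
        "fs": rec.fs,
        "channels": rec.channels,
        "groups": [
            {
                "name": g.name,
                "channels": list(g.channels),
                "kind": g.kind,
                "shape": list(g.shape) if g.shape else None,
            }
            for g in rec.groups
        ],
        "epochs": [list(e) for e in (rec.epochs or [])],
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_labels(path: str | Path, channels: Iterable[str] | None = None) -> ChannelLabels:
    """Read a ``channel,soz`` CSV (soz coded 0/1)."""
    frame = pd.read_csv(path)
    soz = {str(r.channel) for r in frame.itertuples(index=False) if int(r.soz)}
    chans = channels if channels is not None else [str(c) for c in frame["channel"]]
    return ChannelLabels.from_soz(soz, chans)


def write_labels(labels: ChannelLabels, path: str | Path) -> None:
    frame = pd.DataFrame(
        [(c, int(c in labels.soz)) for c in sorted(labels.channels)],
        columns=["channel", "soz"],
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Bipolar montage
# ---------------------------------------------------------------------------


def bipolar_pairs(groups: Sequence[ElectrodeGroup]) -> list[tuple[str, str, str]]:
    """(bipolar label, anode, cathode) triples for each group.

    Pairs are consecutive contacts in contact order; grids pair along rows of
    their stated geometry.  Groups with a single contact are skipped with a
    warning.
    """
    out: list[tuple[str, str, str]] = []
    for g in groups:
        made_any = False
        for row in g.rows():
            for a, b in zip(row[:-1], row[1:]):
                out.append((f"{a}-{b}", a, b))
                made_any = True
        if not made_any:
            warnings.warn(f"group {g.name} has a single contact; skipped")
    return out


def bipolar_rereference(rec: Recording) -> Recording:
    """Re-reference to a bipolar montage.

    Each group of N ordered contacts yields N-1 channels, contact_i minus
    contact_{i+1}, labeled ``A1-A2``.  Group structure is preserved (a group's
    bipolar channels form the new group); the pair mapping is stored on the
    returned recording for SOZ label propagation.
    """
    new_channels: list[str] = []
    new_rows: list[np.ndarray] = []
    new_groups: list[ElectrodeGroup] = []
    pairs: dict[str, tuple[str, str]] = {}
    for g in rec.groups:
        glabels: list[str] = []
        for row in g.rows():
            for a, b in zip(row[:-1], row[1:]):
                label = f"{a}-{b}"
                new_channels.append(label)
                glabels.append(label)
                new_rows.append(rec.get(a) - rec.get(b))
                pairs[label] = (a, b)
        if not glabels:
            warnings.warn(f"group {g.name} has a single contact; skipped")
            continue
        new_groups.append(ElectrodeGroup(name=g.name, channels=tuple(glabels), kind=g.kind))
    if not new_rows:
        raise ValueError("no bipolar channels could be formed")
    return Recording(
        data=np.vstack(new_rows),
        fs=rec.fs,
        channels=new_channels,
        groups=new_groups,
        epochs=list(rec.epochs or []),
        pairs=pairs,
    )


def propagate_soz(
    labels: ChannelLabels,
    pairs: "Recording | dict[str, tuple[str, str]]",
) -> ChannelLabels:
    """Propagate contact-level SOZ labels to bipolar channels.

    A bipolar channel is SOZ iff at least one of its member contacts is SOZ
    (e.g. an SOZ at contact RAH4 makes RAH3-4 and RAH4-5 both SOZ).
    ``pairs`` may be a bipolar :class:`Recording` or its pair mapping.
    """
    if isinstance(pairs, Recording):
        if pairs.pairs is None:
            raise ValueError("recording carries no bipolar pair mapping")
        mapping = pairs.pairs
    else:
        mapping = pairs
    covered = {c for pair in mapping.values() for c in pair}
    stray = labels.soz - covered
    if stray:
        warnings.warn(f"SOZ contacts absent from every bipolar pair: {sorted(stray)}")
    soz = {lab for lab, (a, b) in mapping.items() if a in labels.soz or b in labels.soz}
    return ChannelLabels.from_soz(soz, mapping.keys())


def slice_recording(rec: Recording, start: float, stop: float) -> Recording:
    """Extract ``[start, stop)`` seconds as a new single-epoch recording.

    Event times in the slice remain relative to the slice start.
    """
    if not 0 <= start < stop <= rec.duration + 1e-9:
        raise ValueError(f"slice ({start}, {stop}) outside record")
    i0 = int(round(start * rec.fs))
    i1 = min(int(round(stop * rec.fs)), rec.n_samples)
    return Recording(
        data=rec.data[:, i0:i1].copy(),
        fs=rec.fs,
        channels=list(rec.channels),
        groups=list(rec.groups),
        epochs=[(0.0, (i1 - i0) / rec.fs)],
        pairs=dict(rec.pairs) if rec.pairs else None,
    )
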