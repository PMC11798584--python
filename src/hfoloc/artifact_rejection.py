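"""Automatic rejection of artifactual HFO candidates.

Two complementary rules clean the raw detector output:

* **PopDet** targets DC shifts and fast transients.  A true ripple-band HFO
  is band-limited, whereas a filtered step or pop carries power at very high
  frequencies.  The rule filters the channel at 850-990 Hz, tiles each epoch
  into 0.1 s windows, and flags a window when its line length exceeds the
  mean + 5 SD of the line lengths in the preceding 5 s.  Any candidate whose
  interval intersects a flagged window is rejected.

* **BkgStabaDet** targets spatially diffuse events, which contradict the
  expectation that HFOs are focal.  The RMS detector (default parameters) is
  run on the common average of each electrode group; any single-channel
  detection within 100 ms of a common-average detection is rejected.

Both rules keep their default parameters for every recording and every
detector parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage_io import Event, EventSet, Recording
from .rms_detector import DetectorParams, bandpass, detect_in_filtered

__all__ = [
    "popdet",
    "common_average",
    "common_average_events",
    "bkgstaba_reject",
    "rejection_stats",
    "apply_artifact_rejection",
    "RejectionReport",
]

POP_BAND = (850.0, 990.0)
POP_WIN_S = 0.1
POP_BASELINE_S = 5.0
POP_NSD = 5.0
BKG_WINDOW_S = 0.1


def popdet(
    x: np.ndarray,
    fs: float,
    win_s: float = POP_WIN_S,
    baseline_s: float = POP_BASELINE_S,
    nsd: float = POP_NSD,
    band: tuple[float, float] = POP_BAND,
) -> list[tuple[float, float]]:
    """Flag 0.1 s windows with excessive very-high-frequency line length.

    The signal is filtered to ``band`` and split into consecutive
    non-overlapping ``win_s`` tiles; tile *i* is flagged when its line length
    ``L = sum |x[k+1]-x[k]|`` exceeds mean + ``nsd``*SD of the tile line
    lengths over the preceding ``baseline_s`` seconds.  The first
    ``baseline_s`` of the signal has no baseline and is never flagged.
    Returns flagged windows as (start, stop) seconds relative to the signal.
    """
    if fs < 2.0 * band[1]:
        raise ValueError(f"fs={fs} too low for band {band}")
    filt = bandpass(np.asarray(x, dtype=float), fs, band)
    w = int(round(win_s * fs))
    n_win = filt.size // w
    if n_win == 0:
        return []
    ll = np.abs(np.diff(filt[: n_win * w])).reshape(-1)
    # per-tile line length; the diff spanning a tile boundary belongs to no tile
    tile = np.arange(n_win * w - 1) // w
    line = np.zeros(n_win)
    np.add.at(line, tile, ll)
    n_base = int(round(baseline_s / win_s))
    flagged: list[tuple[float, float]] = []
    cs = np.concatenate(([0.0], np.cumsum(line)))
    cs2 = np.concatenate(([0.0], np.cumsum(line**2)))
    for i in range(n_base, n_win):
        m = (cs[i] - cs[i - n_base]) / n_base
        var = (cs2[i] - cs2[i - n_base]) / n_base - m * m
        sd = np.sqrt(max(var, 0.0))
        if line[i] > m + nsd * sd:
            flagged.append((i * w / fs, (i + 1) * w / fs))
    return flagged


def common_average(group_signals: np.ndarray) -> np.ndarray:
    """Arithmetic mean across a group's channels at each sample."""
    group_signals = np.asarray(group_signals, dtype=float)
    if group_signals.ndim != 2 or group_signals.shape[0] == 0:
        raise ValueError("expected a non-empty (channels x samples) array")
    return group_signals.mean(axis=0)


def common_average_events(rec: Recording, params: DetectorParams | None = None) -> EventSet:
    """Detect HFOs on the common average of each electrode group.

    Events carry the group name in the channel field; detection uses the
    default detector parameters regardless of the parameter set under test.
    """
    params = params or DetectorParams()
    events = []
    assert rec.epochs is not None
    for g in rec.groups:
        idx = [rec.channel_index(c) for c in g.channels]
        ca = common_average(rec.data[idx])
        for epoch in rec.epochs:
            sl = rec.epoch_slice(epoch)
            filt = bandpass(ca[sl], rec.fs, params.band)
            t0 = sl.start / rec.fs
            for cand in detect_in_filtered(filt, rec.fs, params):
                events.append(
                    Event(
                        channel=g.name,
                        start=t0 + cand.start / rec.fs,
                        stop=t0 + cand.stop / rec.fs,
                        source="automatic",
                        n_peaks=cand.n_peaks,
                    )
                )
    return EventSet(events)


def _within(a: Event, b: Event, window_s: float) -> bool:
    """Boundary-to-boundary distance at most ``window_s``; overlap counts."""
    gap = max(a.start - b.stop, b.start - a.stop, 0.0)
    return gap <= window_s


def bkgstaba_reject(
    events: EventSet,
    ca_events: EventSet,
    group_of: dict[str, str],
    window_ms: float = 100.0,
) -> EventSet:
    """Remove events within ``window_ms`` of a common-average detection.

    ``ca_events`` channels are group names; ``group_of`` maps each data
    channel to its group.  Removal is idempotent and output is a subset of
    the input.
    """
    window_s = window_ms / 1000.0
    by_group: dict[str, list[Event]] = {}
    for e in ca_events:
        by_group.setdefault(e.channel, []).append(e)
    kept = []
    for e in events:
        ca = by_group.get(group_of.get(e.channel, ""), ())
        if not any(_within(e, c, window_s) for c in ca):
            kept.append(e)
    return EventSet(kept)


def rejection_stats(
    n_candidates: int,
    pop_flagged: set,
    bkg_flagged: set,
) -> dict:
    """Rejection percentages; the two percentages can sum past 100.

    ``%pop = 100 |pop| / n``, ``%bkg = 100 |bkg| / n``; the overall removed
    count is the union.  With zero candidates the percentages are reported
    as 0 with ``no_candidates`` flagged.
    """
    if n_candidates == 0:
        return {
            "pct_pop": 0.0,
            "pct_bkg": 0.0,
            "n_removed": 0,
            "n_candidates": 0,
            "no_candidates": True,
        }
    return {
        "pct_pop": 100.0 * len(pop_flagged) / n_candidates,
        "pct_bkg": 100.0 * len(bkg_flagged) / n_candidates,
        "n_removed": len(pop_flagged | bkg_flagged),
        "n_candidates": n_candidates,
        "no_candidates": False,
    }


@dataclass
class RejectionReport:
    """Outcome of artifact rejection on one event set."""

    kept: EventSet
    report: pd.DataFrame  # channel, event_start, event_stop, rejected_by
    stats: dict


def apply_artifact_rejection(
    rec: Recording,
    events: EventSet,
    pop_windows: dict[str, list[tuple[float, float]]] | None = None,
    ca_events: EventSet | None = None,
) -> RejectionReport:
    """Run PopDet and BkgStabaDet on detector output.

    ``pop_windows`` / ``ca_events`` may be supplied to reuse precomputed
    flags across parameter sets (both are parameter-set independent).
    """
    assert rec.epochs is not None
    if pop_windows is None:
        pop_windows = {}
        for ch in rec.channels:
            x = rec.get(ch)
            wins: list[tuple[float, float]] = []
            for epoch in rec.epochs:
                sl = rec.epoch_slice(epoch)
                t0 = sl.start / rec.fs
                wins.extend((t0 + a, t0 + b) for a, b in popdet(x[sl], rec.fs))
            pop_windows[ch] = wins
    if ca_events is None:
        ca_events = common_average_events(rec)
    group_of = {c: g.name for g in rec.groups for c in g.channels}

    pop_flagged: set[Event] = set()
    for e in events:
        for a, b in pop_windows.get(e.channel, ()):
            if e.start < b and a < e.stop:
                pop_flagged.add(e)
                break
    after_bkg = set(bkgstaba_reject(events, ca_events, group_of).events)
    bkg_flagged = {e for e in events if e not in after_bkg}

    kept = EventSet(e for e in events if e not in pop_flagged and e not in bkg_flagged)
    rows = []
    for e in events:
        tag = ("pop" if e in pop_flagged else "") + ("bkg" if e in bkg_flagged else "")
        if tag == "popbkg":
            tag = "both"
        if tag:
            rows.append((e.channel, e.start, e.stop, tag))
    report = pd.DataFrame(rows, columns=["channel", "event_start", "event_stop", "rejected_by"])
    stats = rejection_stats(len(events), pop_flagged, bkg_flagged)
    return RejectionReport(kept=kept, report=report, stats=stats)
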