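"""Visual-marking-based detector parameter optimization.

Automatic detections are compared with a reviewer's marks on the same
one-minute segment using a 50%-overlap rule: two events on the same channel
match when the intersection covers at least half of the shorter one.
Matching is one-to-one, so one long automatic detection spanning two visual
marks yields one true positive and one false negative.  The detection F1

    F1 = TP / (TP + 0.5 (FP + FN))

is computed for every (nSD1, RMS_win) cell of the parameter grid; the cell
with the highest F1 is the "visually optimized" parameter set.  Ties are
broken toward the lowest nSD1 and then the highest RMS_win (the most
sensitive of the tied settings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage_io import Event, EventSet, Recording
from .rms_detector import (
    GRID_NSD1,
    GRID_RMS_WIN,
    DetectorParams,
    bandpass,
    detect_in_filtered,
    moving_rms,
)
from .artifact_rejection import apply_artifact_rejection, common_average_events, popdet

__all__ = [
    "events_overlap",
    "match_events",
    "detection_f1",
    "optimize_params",
    "detect_grid",
    "OverlapResult",
    "F1Surface",
    "DEFAULT_GRID",
]

#: (nSD1 values, RMS_win values in ms) swept during optimization.
DEFAULT_GRID: dict[str, tuple] = {"nSD1": GRID_NSD1, "rms_win": GRID_RMS_WIN}

OVERLAP_MIN_FRAC = 0.5  # inclusive


def events_overlap(a: Event, b: Event, min_frac: float = OVERLAP_MIN_FRAC) -> bool:
    """50%-overlap rule: intersection >= ``min_frac`` of the shorter event.

    Events on different channels never overlap.  The boundary case (exactly
    half the shorter event) counts as overlapping.
    """
    if a.channel != b.channel:
        return False
    inter = min(a.stop, b.stop) - max(a.start, b.start)
    if inter <= 0:
        return False
    return inter >= min_frac * min(a.duration, b.duration)


@dataclass
class OverlapResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[Event, Event]] = field(default_factory=list)  # (visual, automatic)


def _greedy_match(vis: list[Event], aut: list[Event]) -> list[tuple[int, int]]:
    """One-to-one greedy matching in start-time order."""
    pairs = []
    used = [False] * len(aut)
    for i, v in enumerate(vis):
        for j, a in enumerate(aut):
            if used[j]:
                continue
            if a.start - v.stop > 0:  # aut sorted; nothing later can overlap
                break
            if events_overlap(v, a):
                pairs.append((i, j))
                used[j] = True
                break
    return pairs


def _optimal_match(vis: list[Event], aut: list[Event]) -> list[tuple[int, int]]:
    """Maximum-cardinality bipartite matching (for small sets)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    rows, cols = [], []
    for i, v in enumerate(vis):
        for j, a in enumerate(aut):
            if events_overlap(v, a):
                rows.append(i)
                cols.append(j)
    if not rows:
        return []
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(vis), len(aut))
    )
    col_of_row = maximum_bipartite_matching(graph, perm_type="column")
    return [(i, int(j)) for i, j in enumerate(col_of_row) if j >= 0]


def match_events(
    visual: EventSet, automatic: EventSet, optimal: bool = False
) -> OverlapResult:
    """Match automatic to visual detections channel-by-channel.

    Matched pairs are true positives; unmatched visual events are false
    negatives and unmatched automatic events false positives.  The default
    is greedy one-to-one matching in time order; ``optimal=True`` uses
    maximum-cardinality bipartite matching instead.
    """
    tp = fp = fn = 0
    pairs: list[tuple[Event, Event]] = []
    channels = sorted(set(visual.channels) | set(automatic.channels))
    for ch in channels:
        vis = visual.for_channel(ch)
        aut = automatic.for_channel(ch)
        idx_pairs = _optimal_match(vis, aut) if optimal else _greedy_match(vis, aut)
        tp += len(idx_pairs)
        fn += len(vis) - len(idx_pairs)
        fp += len(aut) - len(idx_pairs)
        pairs.extend((vis[i], aut[j]) for i, j in idx_pairs)
    return OverlapResult(tp=tp, fp=fp, fn=fn, pairs=pairs)


def detection_f1(tp: int, fp: int, fn: int) -> float:
    """F1 = TP / (TP + (FP+FN)/2); NaN when no events exist at all."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + fn
    if total == 0:
        return float("nan")
    return tp / (tp + 0.5 * (fp + fn))


@dataclass
class F1Surface:
    """Overlap-F1 over the (nSD1, RMS_win) grid and the selected optimum."""

    table: pd.DataFrame  # index nSD1, columns rms_win (ms)
    best: tuple[float, float]  # (nSD1, rms_win)
    best_f1: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def detect_grid(
    rec: Recording,
    grid: dict[str, tuple] | None = None,
    base_params: DetectorParams | None = None,
    artifact_rejection: bool = True,
) -> dict[tuple[float, float], EventSet]:
    """Detector output at every (nSD1, rms_win) grid cell.

    Shares the bandpassed signal across all cells and the RMS envelope
    across nSD1 values, and reuses the parameter-set-independent artifact
    flags (PopDet windows, common-average detections), so a full sweep costs
    little more than a handful of single runs.
    """
    grid = grid or DEFAULT_GRID
    base = base_params or DetectorParams()
    assert rec.epochs is not None

    pop_windows: dict[str, list[tuple[float, float]]] | None = None
    ca_events = None
    if artifact_rejection:
        pop_windows = {}
        for ch in rec.channels:
            x = rec.get(ch)
            wins: list[tuple[float, float]] = []
            for epoch in rec.epochs:
                sl = rec.epoch_slice(epoch)
                t0 = sl.start / rec.fs
                wins.extend((t0 + a, t0 + b) for a, b in popdet(x[sl], rec.fs))
            pop_windows[ch] = wins
        ca_events = common_average_events(rec, base)

    raw: dict[tuple[float, float], list[Event]] = {
        (n, w): [] for n in grid["nSD1"] for w in grid["rms_win"]
    }
    for ch in rec.channels:
        x = rec.get(ch)
        for epoch in rec.epochs:
            sl = rec.epoch_slice(epoch)
            filt = bandpass(x[sl], rec.fs, base.band)
            t0 = sl.start / rec.fs
            for w in grid["rms_win"]:
                rms = moving_rms(filt, w, rec.fs)
                for n in grid["nSD1"]:
                    params = base.with_grid_point(nSD1=n, rms_win=w)
                    for cand in detect_in_filtered(filt, rec.fs, params, rms=rms):
                        raw[(n, w)].append(
                            Event(
                                channel=ch,
                                start=t0 + cand.start / rec.fs,
                                stop=t0 + cand.stop / rec.fs,
                                source="automatic",
                                n_peaks=cand.n_peaks,
                            )
                        )
    out: dict[tuple[float, float], EventSet] = {}
    for cell, events in raw.items():
        es = EventSet(events)
        if artifact_rejection:
            es = apply_artifact_rejection(
                rec, es, pop_windows=pop_windows, ca_events=ca_events
            ).kept
        out[cell] = es
    return out


def optimize_params(
    rec: Recording,
    visual: EventSet,
    grid: dict[str, tuple] | None = None,
    base_params: DetectorParams | None = None,
    artifact_rejection: bool = True,
    cell_detections: dict[tuple[float, float], EventSet] | None = None,
) -> F1Surface:
    """Select the grid cell whose detections best match the visual marks.

    ``rec`` should be the same (typically one-minute) segment the reviewer
    marked.  ``cell_detections`` may carry precomputed per-cell detector
    output for that segment; otherwise :func:`detect_grid` is run.  Cells
    where neither detections nor marks exist have undefined F1 and are
    excluded from the argmax; if every cell scores 0 (or is undefined) the
    most sensitive cell (lowest nSD1, highest RMS_win) is returned.
    """
    if len(visual) == 0:
        raise ValueError("optimization undefined without visual marks")
    grid = grid or DEFAULT_GRID
    if cell_detections is None:
        cell_detections = detect_grid(rec, grid, base_params, artifact_rejection)

    nsd_vals = sorted(grid["nSD1"])
    win_vals = sorted(grid["rms_win"])
    table = pd.DataFrame(index=nsd_vals, columns=win_vals, dtype=float)
    table.index.name = "nSD1"
    table.columns.name = "rms_win_ms"
    for n in nsd_vals:
        for w in win_vals:
            res = match_events(visual, cell_detections[(n, w)])
            table.loc[n, w] = detection_f1(res.tp, res.fp, res.fn)

    values = table.to_numpy(dtype=float)
    if np.all(np.isnan(values)) or np.nanmax(values) == 0.0:
        best = (min(nsd_vals), max(win_vals))
        best_f1 = 0.0 if not np.all(np.isnan(values)) else float("nan")
        return F1Surface(table=table, best=best, best_f1=best_f1)
    best_f1 = float(np.nanmax(values))
    # tie-break: lowest nSD1 first, then highest RMS_win
    candidates = [
        (n, w)
        for n in nsd_vals
        for w in win_vals
        if not np.isnan(table.loc[n, w]) and table.loc[n, w] == best_f1
    ]
    best = min(candidates, key=lambda cell: (cell[0], -cell[1]))
    return F1Surface(table=table, best=best, best_f1=best_f1)
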