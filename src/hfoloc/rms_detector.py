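"""Reduced RMS detector for ripple-band (100-500 Hz) high-frequency oscillations.

The detector is the classic RMS-amplitude algorithm: bandpass the broadband
iEEG, compute a short moving-window RMS envelope, and flag periods where the
envelope exceeds ``mean + nSD1 * SD`` of the RMS series for at least
``min_dur`` ms.  Supra-threshold runs separated by less than ``gap`` ms are
joined into one candidate.  A candidate is retained only if at least
``min_pk`` rectified-signal peaks inside it exceed a second threshold on the
rectified filtered data.  In the reduced form used throughout this package
the second threshold reuses the first multiplier (nSD2 = nSD1), leaving five
parameters: RMS_win, nSD1, min_dur, gap, min_pk.

Baseline statistics (mean/SD of the RMS and of the rectified signal) are
computed per channel per epoch, so thresholds are data-relative and the
detector is invariant to per-channel amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .montage_io import Event, EventSet, Recording

__all__ = [
    "DetectorParams",
    "CandidateInterval",
    "bandpass",
    "moving_rms",
    "threshold_stats",
    "detect_candidates",
    "peak_criterion",
    "detect_hfos",
]

DEFAULT_BAND = (100.0, 500.0)

#: Table of the parameter grid swept during optimization / sensitivity runs.
GRID_NSD1 = tuple(range(1, 16))
GRID_RMS_WIN = (2.0, 3.0, 5.0, 7.0, 9.0, 11.0, 15.0, 17.0, 20.0)
GRID_MIN_DUR = (6.0, 12.0)


@dataclass(frozen=True)
class DetectorParams:
    """Detector parameters.  Times in ms; thresholds in SD multiples.

    ``nSD2 = None`` selects the reduced detector (nSD2 follows nSD1); setting
    it explicitly restores the full two-threshold form.
    ``join_before_min_dur`` controls whether gap-joining happens before the
    minimum-duration gate (default) or after.
    """

    rms_win: float = 3.0
    nSD1: float = 5.0
    min_dur: float = 6.0
    gap: float = 10.0
    min_pk: int = 6
    nSD2: float | None = None
    band: tuple[float, float] = DEFAULT_BAND
    join_before_min_dur: bool = True

    def __post_init__(self) -> None:
        if min(self.rms_win, self.nSD1, self.min_dur, self.gap) <= 0 or self.min_pk <= 0:
            raise ValueError("all detector parameters must be positive")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"invalid band {self.band}")

    @property
    def nsd2_effective(self) -> float:
        return self.nSD1 if self.nSD2 is None else self.nSD2

    def with_grid_point(self, nSD1: float, rms_win: float) -> "DetectorParams":
        return replace(self, nSD1=nSD1, rms_win=rms_win)


@dataclass(frozen=True)
class CandidateInterval:
    """A supra-threshold candidate, sample-indexed within one epoch."""

    start: int  # sample index, inclusive
    stop: int  # sample index, exclusive
    n_peaks: int = 0


@lru_cache(maxsize=32)
def _bandpass_kernel(fs: float, low: float, high: float) -> np.ndarray:
    # Hamming-window FIR sized for a ~25 Hz transition at fs = 2000, scaled
    # proportionally with fs; self-convolved so that a single linear
    # convolution realizes the zero-phase forward-backward response.
    width = 25.0 * fs / 2000.0
    numtaps = int(np.ceil(3.3 * fs / width))
    numtaps += 1 - numtaps % 2  # odd length -> symmetric, integer delay
    nyq = fs / 2.0
    high = min(high, nyq * 0.999)
    taps = sps.firwin(numtaps, [low, high], fs=fs, pass_zero=False, window="hamming")
    return np.convolve(taps, taps)


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Zero-phase FIR bandpass; same length as the input.

    Raises if the sampling rate cannot represent the band.
    """
    if fs < 2.0 * band[0]:
        raise ValueError(f"fs={fs} too low for band {band}")
    x = np.asarray(x, dtype=float)
    kernel = _bandpass_kernel(float(fs), float(band[0]), float(band[1]))
    if x.size == 0:
        return x.copy()
    return sps.fftconvolve(x, kernel, mode="same")


def moving_rms(x: np.ndarray, rms_win: float, fs: float) -> np.ndarray:
    """Centered moving-window RMS with shrinking windows at the edges.

    ``rms_win`` is in ms.  The window covers ``[i - w//2, i - w//2 + w)``
    clipped to the record, so edge samples average over fewer points rather
    than over padding.
    """
    x = np.asarray(x, dtype=float)
    w = max(1, int(round(rms_win * fs / 1000.0)))
    n = x.size
    if w > n:
        raise ValueError(f"RMS window ({w} samples) longer than signal ({n})")
    cs = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx - w // 2 + w, 0, n)
    return np.sqrt((cs[hi] - cs[lo]) / (hi - lo))


def threshold_stats(series: np.ndarray) -> tuple[float, float]:
    """Population mean and SD of a series (the detector's baseline scope)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    return float(series.mean()), float(series.std())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open sample intervals."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    stops = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [mask.size]))
    return list(zip(starts.tolist(), stops.tolist()))


def detect_candidates(
    rms: np.ndarray,
    mean: float,
    sd: float,
    params: DetectorParams,
    fs: float,
) -> list[CandidateInterval]:
    """Threshold the RMS envelope into candidate intervals.

    Samples with ``rms > mean + nSD1*sd`` (strict) form runs; runs separated
    by less than ``gap`` ms are joined, then runs shorter than ``min_dur`` ms
    are discarded.  With ``join_before_min_dur=False`` the two steps swap.
    """
    mask = np.asarray(rms, dtype=float) > mean + params.nSD1 * sd
    runs = _runs(mask)
    gap_s = params.gap / 1000.0
    min_dur_s = params.min_dur / 1000.0

    def join(rr: list[tuple[int, int]]) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for s, e in rr:
            if out and (s - out[-1][1]) / fs < gap_s:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
        return out

    def long_enough(rr: list[tuple[int, int]]) -> list[tuple[int, int]]:
        return [(s, e) for s, e in rr if (e - s) / fs >= min_dur_s]

    if params.join_before_min_dur:
        runs = long_enough(join(runs))
    else:
        runs = join(long_enough(runs))
    return [CandidateInterval(s, e) for s, e in runs]


def _local_max_indices(x: np.ndarray) -> np.ndarray:
    """Strict local maxima; plateau ties resolved to the leftmost sample."""
    n = x.size
    if n < 3:
        return np.empty(0, dtype=int)
    d = np.diff(x)
    s = np.sign(d)
    m = s.size
    # plateau diffs (zeros) inherit the sign of the next nonzero slope, so a
    # rise-plateau-fall peaks at the plateau's leftmost sample
    nxt = np.where(s != 0, np.arange(m), m)
    nxt = np.minimum.accumulate(nxt[::-1])[::-1]
    s_eff = np.where(nxt < m, s[np.minimum(nxt, m - 1)], -1.0)
    peaks = np.flatnonzero((s[:-1] > 0) & (s_eff[1:] < 0)) + 1
    return peaks


def peak_criterion(
    rectified: np.ndarray,
    interval: CandidateInterval,
    mean_r: float,
    sd_r: float,
    params: DetectorParams,
) -> tuple[bool, int]:
    """Count supra-threshold rectified peaks inside a candidate.

    Returns (retained?, n_peaks): retained iff at least ``min_pk`` strict
    local maxima of the rectified filtered signal inside the interval exceed
    ``mean_r + nSD2*sd_r``.
    """
    seg = np.asarray(rectified, dtype=float)[interval.start : interval.stop]
    thr = mean_r + params.nsd2_effective * sd_r
    idx = _local_max_indices(seg)
    n_peaks = int(np.count_nonzero(seg[idx] > thr)) if idx.size else 0
    return n_peaks >= params.min_pk, n_peaks


def detect_in_filtered(
    filtered: np.ndarray,
    fs: float,
    params: DetectorParams,
    rms: np.ndarray | None = None,
) -> list[CandidateInterval]:
    """Detection stages downstream of the bandpass, on one channel-epoch.

    Exposed separately so sweeps can reuse the filtered signal (and the RMS
    envelope, which depends only on ``rms_win``) across parameter sets.
    """
    if rms is None:
        rms = moving_rms(filtered, params.rms_win, fs)
    mean, sd = threshold_stats(rms)
    rectified = np.abs(filtered)
    mean_r, sd_r = threshold_stats(rectified)
    out: list[CandidateInterval] = []
    for cand in detect_candidates(rms, mean, sd, params, fs):
        keep, n_pk = peak_criterion(rectified, cand, mean_r, sd_r, params)
        if keep:
            out.append(CandidateInterval(cand.start, cand.stop, n_pk))
    return out


def detect_hfos(rec: Recording, params: DetectorParams | None = None) -> EventSet:
    """Run the full detector on every channel and epoch of a recording.

    Each epoch is processed independently: bandpass -> moving RMS ->
    per-epoch baseline statistics -> candidate thresholding -> rectified-peak
    gate.  Events are reported in recording time, source ``automatic``.
    """
    params = params or DetectorParams()
    events: list[Event] = []
    assert rec.epochs is not None
    for ch in rec.channels:
        x = rec.get(ch)
        for epoch in rec.epochs:
            sl = rec.epoch_slice(epoch)
            filt = bandpass(x[sl], rec.fs, params.band)
            t0 = sl.start / rec.fs
            for cand in detect_in_filtered(filt, rec.fs, params):
                events.append(
                    Event(
                        channel=ch,
                        start=t0 + cand.start / rec.fs,
                        stop=t0 + cand.stop / rec.fs,
                        source="automatic",
                        n_peaks=cand.n_peaks,
                    )
                )
    return EventSet(events)
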