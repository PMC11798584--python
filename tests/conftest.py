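"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately naive (loops, enumeration, closed forms)
and independent of the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from hfoloc.montage_io import ElectrodeGroup, Recording
from hfoloc.rms_detector import CandidateInterval, DetectorParams


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def pink_noise(rng: np.random.Generator, n: int, fs: float, alpha: float = 1.0) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = amp * np.exp(1j * rng.uniform(0, 2 * np.pi, freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def make_recording(
    n_channels: int = 2,
    seconds: float = 10.0,
    fs: float = 2000.0,
    seed: int = 0,
    group_size: int | None = None,
) -> Recording:
    """Pink-noise recording with one or more depth groups."""
    rng = np.random.default_rng(seed)
    n = int(seconds * fs)
    data = np.vstack([pink_noise(rng, n, fs) for _ in range(n_channels)]) * 50.0
    names = [f"C{i+1:02d}" for i in range(n_channels)]
    gsize = group_size or n_channels
    groups = [
        ElectrodeGroup(name=f"G{g+1}", channels=tuple(names[g * gsize : (g + 1) * gsize]))
        for g in range((n_channels + gsize - 1) // gsize)
    ]
    return Recording(data=data, fs=fs, channels=names, groups=groups)


@pytest.fixture
def small_rec() -> Recording:
    return make_recording(n_channels=2, seconds=10.0, seed=7)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def naive_candidates(
    rms: np.ndarray, mean: float, sd: float, params: DetectorParams, fs: float
) -> list[CandidateInterval]:
    """Loop-based run-length reference for candidate detection."""
    thr = mean + params.nSD1 * sd
    runs: list[list[int]] = []
    in_run = False
    for i, v in enumerate(rms):
        if v > thr:
            if not in_run:
                runs.append([i, i + 1])
                in_run = True
            else:
                runs[-1][1] = i + 1
        else:
            in_run = False

    def join(rr):
        out = []
        for s, e in rr:
            if out and (s - out[-1][1]) / fs < params.gap / 1000.0:
                out[-1] = [out[-1][0], e]
            else:
                out.append([s, e])
        return out

    def gate(rr):
        return [[s, e] for s, e in rr if (e - s) / fs >= params.min_dur / 1000.0]

    runs = gate(join(runs)) if params.join_before_min_dur else join(gate(runs))
    return [CandidateInterval(s, e) for s, e in runs]


def pairwise_auc(soz: np.ndarray, nsoz: np.ndarray) -> float:
    """Tie-corrected rank statistic P(r_soz > r_nsoz) + 0.5 P(=), all pairs."""
    total = 0.0
    for a in soz:
        for b in nsoz:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(soz) * len(nsoz))


def exhaustive_max_f1(soz: np.ndarray, nsoz: np.ndarray) -> float:
    """Max F1 over every threshold that yields a distinct prediction set."""
    rates = np.concatenate([soz, nsoz])
    thresholds = np.concatenate(([-np.inf], np.unique(rates), [np.inf]))
    best = -1.0
    for t in thresholds:
        tp = int((soz > t).sum())
        fp = int((nsoz > t).sum())
        fn = len(soz) - tp
        if tp + fp == 0:
            continue
        best = max(best, tp / (tp + 0.5 * (fp + fn)))
    return best


def exact_wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments.

    Assumes no zero differences and no tied |differences|.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    assert np.all(d != 0) and len(set(np.abs(d))) == len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        ws.append(w)
    ws = np.array(ws)
    cdf = (ws <= w_obs).mean()
    sf = (ws >= w_obs).mean()
    return min(1.0, 2.0 * min(cdf, sf))
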