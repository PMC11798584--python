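"""Seeded synthetic intracranial EEG with ground-truth HFOs.

The generator emulates the statistical structure of an interictal iEEG
study: a multichannel recording organized as five 3-minute epochs sampled at
2000 Hz, with 1/f background activity, band-limited HFO bursts occurring as
Poisson events at a higher rate on designated SOZ channels, two artifact
classes (fast DC transients with broadband power, and spatially diffuse
bursts common to a whole electrode group), and imperfect "visual markings"
— a high-specificity, partially sensitive, time-jittered subset of the
ground truth restricted to the first minute of data.

HFO amplitude is specified as a multiple of the background SD measured in
the 100-500 Hz band of the same channel-epoch, so the signal-to-noise ratio
is interpretable regardless of the 1/f exponent or sampling rate.  Every
output is fully determined by ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage_io import ChannelLabels, ElectrodeGroup, Event, EventSet, Recording
from .rms_detector import DEFAULT_BAND, bandpass

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_background",
    "inject_hfo",
    "inject_artifacts",
    "generate_dataset",
    "simulate_visual_markings",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults describe the reference condition used throughout the test
    suite: 20 channels in two 10-contact depth groups, 4 SOZ channels,
    SOZ HFO rate 10/min vs 1/min elsewhere, bursts of 4-9 cycles at
    120-300 Hz with amplitude 5x the ripple-band background SD.
    """

    fs: float = 2000.0
    n_epochs: int = 5
    epoch_len: float = 180.0
    groups: tuple[tuple[str, int], ...] = (("A", 10), ("B", 10))
    n_soz: int = 4
    rate_soz: float = 10.0  # truth HFOs per minute on SOZ channels
    rate_nsoz: float = 1.0
    hfo_freq: tuple[float, float] = (120.0, 300.0)
    hfo_cycles: tuple[int, int] = (4, 9)
    hfo_amp: float = 5.0  # x background SD in the 100-500 Hz band
    alpha: float = 1.0  # 1/f^alpha background exponent
    background_sd: float = 50.0  # broadband SD, microvolts
    pop_rate: float = 0.2  # DC-transient artifacts per minute per channel
    diffuse_rate: float = 0.3  # diffuse bursts per minute per group
    marking_sensitivity: float = 0.6
    marking_false_rate: float = 1.0  # false marks per minute per channel
    marking_jitter_ms: float = 10.0
    marking_window: float = 60.0  # seconds of data the reviewer marks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_soz < 0 or self.rate_nsoz < 0:
            raise ValueError("rates must be non-negative")
        if self.hfo_cycles[0] < 4:
            raise ValueError("HFOs must have at least 4 oscillations")
        if min(self.epoch_len, self.fs, self.marking_window) <= 0:
            raise ValueError("durations must be positive")

    @property
    def channel_names(self) -> list[str]:
        return [f"{g}{i+1:02d}" for g, n in self.groups for i in range(n)]

    @property
    def soz_channels(self) -> list[str]:
        return self.channel_names[: self.n_soz]

    @property
    def epochs(self) -> list[tuple[float, float]]:
        return [(i * self.epoch_len, (i + 1) * self.epoch_len) for i in range(self.n_epochs)]


@dataclass
class GroundTruth:
    """Everything the generator knows that a detector must recover."""

    events: EventSet  # true HFOs, source="truth"
    artifacts: list[tuple[Event, str]]  # (event, "pop" | "diffuse")
    labels: ChannelLabels


def _one_over_f(rng: np.random.Generator, n: int, fs: float, alpha: float, sd: float) -> np.ndarray:
    """Gaussian 1/f^alpha noise of length n, scaled to broadband SD ``sd``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def generate_background(config: SimConfig, rng: np.random.Generator | None = None) -> Recording:
    """Independent 1/f^alpha background on every channel, epoch by epoch."""
    rng = rng or np.random.default_rng(config.seed)
    n_ep = int(round(config.epoch_len * config.fs))
    n_total = n_ep * config.n_epochs
    names = config.channel_names
    data = np.empty((len(names), n_total))
    for i in range(len(names)):
        for e in range(config.n_epochs):
            data[i, e * n_ep : (e + 1) * n_ep] = _one_over_f(
                rng, n_ep, config.fs, config.alpha, config.background_sd
            )
    groups = []
    start = 0
    for gname, n in config.groups:
        groups.append(
            ElectrodeGroup(name=gname, channels=tuple(names[start : start + n]), kind="depth")
        )
        start += n
    return Recording(
        data=data, fs=config.fs, channels=names, groups=groups, epochs=config.epochs
    )


def hfo_waveform(
    fs: float, freq: float, n_cycles: int, amplitude: float, phase: float = 0.0
) -> np.ndarray:
    """Hann-windowed sinusoid of ``n_cycles`` at ``freq`` (peak amp = amplitude)."""
    dur = n_cycles / freq
    n = max(1, int(round(dur * fs)))
    t = np.arange(n) / fs
    return amplitude * np.hanning(n) * np.sin(2 * np.pi * freq * t + phase)


def inject_hfo(
    signal: np.ndarray,
    fs: float,
    t0: float,
    freq: float,
    n_cycles: int,
    amplitude: float,
    phase: float = 0.0,
) -> tuple[float, float]:
    """Add a burst in place; returns the exact (start, stop) truth interval."""
    burst = hfo_waveform(fs, freq, n_cycles, amplitude, phase)
    i0 = int(round(t0 * fs))
    if i0 < 0 or i0 + burst.size > signal.size:
        raise ValueError("burst does not fit inside the signal")
    signal[i0 : i0 + burst.size] += burst
    return i0 / fs, (i0 + burst.size) / fs


def _draw_times(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    dur: np.ndarray,
    occupied: list[tuple[float, float]],
    max_tries: int = 100,
) -> list[float]:
    """Start times in [lo, hi - dur] avoiding overlap with occupied intervals."""
    starts: list[float] = []
    taken = list(occupied)
    for k in range(n):
        for _ in range(max_tries):
            t0 = rng.uniform(lo, hi - dur[k])
            t1 = t0 + dur[k]
            if all(t1 <= a or t0 >= b for a, b in taken):
                taken.append((t0, t1))
                starts.append(t0)
                break
        else:
            raise RuntimeError("event density too high; could not place event")
    return starts


def band_sd(x: np.ndarray, fs: float, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Background SD in the ripple band — the amplitude reference for bursts."""
    return float(bandpass(x, fs, band).std())


def generate_dataset(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Full synthetic study: background + Poisson HFOs + artifacts + labels.

    Per channel-epoch the number of true HFOs is Poisson with mean
    ``rate * epoch_len`` (rate_soz on SOZ channels); burst frequency,
    cycle count and phase are drawn uniformly from the configured ranges and
    burst amplitude is ``hfo_amp`` times that channel-epoch's ripple-band
    background SD.  Artifacts: "pop" events are 0.3 s DC-shift boxcars with
    discontinuous edges; "diffuse" events are one burst waveform added
    identically to every channel of a group.
    """
    rng = np.random.default_rng(config.seed)
    rec = generate_background(config, rng)
    labels = ChannelLabels.from_soz(config.soz_channels, rec.channels)
    truth_events: list[Event] = []
    artifacts: list[tuple[Event, str]] = []
    occupied: dict[str, list[tuple[float, float]]] = {c: [] for c in rec.channels}

    # truth HFOs
    for ch in rec.channels:
        rate = config.rate_soz if ch in labels.soz else config.rate_nsoz
        sig = rec.get(ch)
        for (e0, e1) in rec.epochs:
            sl = rec.epoch_slice((e0, e1))
            sd = band_sd(sig[sl], config.fs)
            n = rng.poisson(rate * (e1 - e0) / 60.0)
            if n == 0:
                continue
            freqs = rng.uniform(*config.hfo_freq, n)
            cycles = rng.integers(config.hfo_cycles[0], config.hfo_cycles[1] + 1, n)
            phases = rng.uniform(0, 2 * np.pi, n)
            durs = cycles / freqs
            starts = _draw_times(rng, n, e0, e1, durs, occupied[ch])
            for k, t0 in enumerate(starts):
                a, b = inject_hfo(
                    sig, config.fs, t0, freqs[k], int(cycles[k]),
                    config.hfo_amp * sd, phases[k],
                )
                truth_events.append(Event(channel=ch, start=a, stop=b, source="truth"))
                occupied[ch].append((a, b))

    inject_artifacts(rec, config, artifacts, rng, occupied)
    truth = GroundTruth(events=EventSet(truth_events), artifacts=artifacts, labels=labels)
    return rec, truth


def inject_artifacts(
    rec: Recording,
    config: SimConfig,
    artifacts: list[tuple[Event, str]],
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[float, float]]] | None = None,
) -> Recording:
    """Add pop-class DC transients and group-wide diffuse bursts in place."""
    occupied = occupied if occupied is not None else {c: [] for c in rec.channels}
    assert rec.epochs is not None
    # pop class: per-channel DC-shift boxcars with sharp edges
    for ch in rec.channels:
        sig = rec.get(ch)
        for (e0, e1) in rec.epochs:
            n = rng.poisson(config.pop_rate * (e1 - e0) / 60.0)
            if n == 0:
                continue
            durs = np.full(n, 0.3)
            starts = _draw_times(rng, n, e0, e1, durs, occupied[ch])
            for t0 in starts:
                i0 = int(round(t0 * config.fs))
                i1 = int(round((t0 + 0.3) * config.fs))
                sign = rng.choice([-1.0, 1.0])
                sig[i0:i1] += sign * 8.0 * config.background_sd
                # the fast transient riding the shift edge carries the
                # broadband (850-990 Hz) energy the PopDet rule keys on
                sig[i0] += sign * 20.0 * config.background_sd
                ev = Event(channel=ch, start=t0, stop=t0 + 0.3, source="truth")
                artifacts.append((ev, "pop"))
                occupied[ch].append((t0, t0 + 0.3))
    # diffuse class: identical burst on every channel of a group
    for g in rec.groups:
        for (e0, e1) in rec.epochs:
            n = rng.poisson(config.diffuse_rate * (e1 - e0) / 60.0)
            if n == 0:
                continue
            freqs = rng.uniform(*config.hfo_freq, n)
            cycles = rng.integers(config.hfo_cycles[0], config.hfo_cycles[1] + 1, n)
            phases = rng.uniform(0, 2 * np.pi, n)
            durs = cycles / freqs
            taken = [iv for c in g.channels for iv in occupied[c]]
            starts = _draw_times(rng, n, e0, e1, durs, taken)
            sl = rec.epoch_slice((e0, e1))
            sd = float(np.mean([band_sd(rec.get(c)[sl], config.fs) for c in g.channels]))
            for k, t0 in enumerate(starts):
                for c in g.channels:
                    a, b = inject_hfo(
                        rec.get(c), config.fs, t0, freqs[k], int(cycles[k]),
                        config.hfo_amp * sd, phases[k],
                    )
                    occupied[c].append((a, b))
                ev = Event(channel=g.name, start=a, stop=b, source="truth")
                artifacts.append((ev, "diffuse"))
    return rec


def simulate_visual_markings(
    truth: GroundTruth,
    config: SimConfig,
    seed: int | None = None,
) -> EventSet:
    """Imperfect reviewer marks on the first ``marking_window`` seconds.

    Each truth event fully inside the window is kept with probability
    ``marking_sensitivity``; kept boundaries are jittered by up to
    ``marking_jitter_ms``.  False marks (HFO-like durations at random times)
    are added per channel as a Poisson process with ``marking_false_rate``.
    All marks carry source ``visual`` and confidence ``high``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    w = config.marking_window
    j = config.marking_jitter_ms / 1000.0
    marks: list[Event] = []
    for e in truth.events.within(0.0, w):
        if rng.uniform() >= config.marking_sensitivity:
            continue
        start = max(0.0, e.start + rng.uniform(-j, j))
        stop = min(w, e.stop + rng.uniform(-j, j))
        if stop <= start:
            start, stop = e.start, e.stop
        marks.append(Event(channel=e.channel, start=start, stop=stop,
                           source="visual", confidence="high"))
    for ch in sorted(truth.labels.channels):
        n = rng.poisson(config.marking_false_rate * w / 60.0)
        for _ in range(n):
            freq = rng.uniform(*config.hfo_freq)
            dur = rng.integers(config.hfo_cycles[0], config.hfo_cycles[1] + 1) / freq
            t0 = rng.uniform(0.0, w - dur)
            marks.append(Event(channel=ch, start=t0, stop=t0 + dur,
                               source="visual", confidence="high"))
    return EventSet(marks)
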