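# Methods

`hfoloc` implements an interictal high-frequency-oscillation (HFO) analysis
pipeline for intracranial EEG: ripple-band HFO detection with an RMS-envelope
detector, automatic artifact rejection, optimization of detector parameters
against visual markings, and seizure-onset-zone (SOZ) localization scored by
ROC-AUC and precision-recall maximal F1 over per-channel HFO rates.  A seeded
synthetic-data module generates multichannel recordings with known ground
truth so that every stage can be validated end to end.

## Recording model and montage

A recording is a channels × samples matrix in µV with a sampling rate
(≥ 2000 Hz for ripple-band work), a partition of channels into electrode
groups (grid / strip / depth with ordered contacts), and a list of
non-overlapping analysis epochs — by convention five 3-minute epochs,
15 minutes in total.  All event times are seconds, recording-relative,
half-open `[start, stop)`.

Bipolar re-referencing subtracts consecutive contacts within a group
(`A1-A2 = A1 − A2`); grids pair along the rows of their stated geometry
(an 8×8 grid yields 8 rows of 7 pairs).  Row-wise pairing for 2-D grids is a
package choice — column-wise pairing would be equally defensible — and is
recorded in the sidecar metadata.  Contact-level SOZ labels propagate to any
bipolar channel containing an SOZ contact, so an SOZ at contact 4 of a depth
electrode marks both the 3-4 and 4-5 pairs.

## The reduced RMS detector

Per channel and epoch:

1. bandpass 100–500 Hz (zero phase; see *Numerical choices*);
2. moving-window RMS envelope, window `RMS_win` (default 3 ms), centered,
   with shrinking windows at the record edges rather than padding;
3. threshold `mean + nSD1·SD` (strict `>`) of the envelope, with mean/SD
   computed over that channel-epoch (default `nSD1 = 5`);
4. supra-threshold runs separated by less than `gap = 10` ms are joined,
   then runs shorter than `min_dur = 6` ms are dropped.  Joining before the
   duration gate lets two short runs survive as one event; the opposite
   order is available as `join_before_min_dur=False`;
5. a candidate is retained only if at least `min_pk = 6` strict local maxima
   of the rectified filtered signal inside the candidate interval exceed a
   second threshold `mean + nSD2·SD` of the rectified signal.  In the
   reduced detector `nSD2` follows `nSD1`; passing `nSD2` explicitly
   restores the full two-threshold detector.

Because every threshold is data-relative, detections are invariant to
per-channel amplitude scaling.  Baseline statistics are computed per
channel-epoch (not over the whole record): this adapts to slow
nonstationarity and keeps epochs independent, at the price of slightly
noisier thresholds on short epochs.  Plateau maxima count once, at their
leftmost sample.

The optimization/sweep grid covers `nSD1 ∈ {1..15}` and
`RMS_win ∈ {2,3,5,7,9,11,15,17,20}` ms; `min_dur` supports 6 and 12 ms;
`gap` and `min_pk` are held at their defaults, since gap-joining is a
post-processing step and the peak count is largely redundant with the
duration gate for long events.

A practical consequence of the reduced form worth knowing: for short bursts
the peak gate is the binding constraint, not `min_dur`.  With
`nSD2 = nSD1 = 5` the rectified threshold sits near 3.8× the band-limited
background SD, so a Hann-enveloped burst at 5× background SD exposes only
its central third above threshold — roughly 0.65 supra-threshold peaks per
cycle.  Events need ≳ 8–9 cycles (or higher SNR) to pass `min_pk = 6`
reliably; at 8× background SD, 8-cycle bursts are recovered almost
completely.  Detection probability depends only on burst morphology, not on
the channel, so rate *contrasts* between channels — all that localization
uses — survive this thinning intact.

## Artifact rejection

Two rules with fixed default parameters, applied identically for every
detector parameter set:

* **PopDet** (DC shifts / fast transients): filter 850–990 Hz, tile each
  epoch into consecutive non-overlapping 0.1 s windows, and flag a window
  when its line length `Σ|x[i+1] − x[i]|` exceeds mean + 5 SD of the line
  lengths over the preceding 5 s (50 windows, previously flagged windows
  included in the baseline).  The first 5 s of an epoch have no baseline and
  are never flagged.  A candidate is rejected if its interval intersects a
  flagged window.
* **BkgStabaDet** (spatially diffuse events): run the detector at default
  parameters on the common average of each electrode group; reject any
  single-channel detection whose boundary-to-boundary distance to a
  common-average detection is ≤ 100 ms (overlap counts).  A burst common to
  all N channels of a group survives averaging at full amplitude and is
  rejected everywhere; a focal burst is attenuated N-fold in the average and
  survives.

Rejection percentages are reported per rule relative to all candidates, so
the two percentages can sum beyond 100; the overall removed count is the
union.

## Matching detections to visual marks and parameter optimization

Automatic and visual events on the same channel match when their
intersection covers at least 50% of the shorter event (inclusive at exactly
50%).  Matching is one-to-one and greedy in start-time order; an exhaustive
maximum-cardinality matcher is available for small sets
(`match_events(..., optimal=True)`).  Matched pairs are TP, unmatched visual
marks FN, unmatched automatic detections FP, and the detection F1 is
`TP / (TP + (FP + FN)/2)` — no true negatives exist in this comparison.

Optimization evaluates the detector (including artifact rejection) at every
(`nSD1`, `RMS_win`) cell on the same one-minute segment the reviewer marked
and selects the cell with maximal F1; ties resolve to the lowest `nSD1`,
then the highest `RMS_win` (the most sensitive tied setting).  Cells where
neither detections nor marks exist are undefined and excluded; an all-zero
surface falls back to the most sensitive cell.

## SOZ localization

Per-channel rates are events per minute pooled over all epochs.  A channel
is predicted SOZ when its rate strictly exceeds a threshold; sweeping the
threshold over all observed rates (with ±∞ sentinels so (0,0) and (1,1)
always lie on the ROC) yields TPR/FPR and precision/recall per threshold.
AUC is the trapezoidal area (equal, by construction, to the tie-corrected
rank statistic `P(r_SOZ > r_nSOZ) + ½P(=)`); the PR curve is summarized by
its maximal F1, skipping — not zeroing — thresholds where no channel is
predicted positive.  The two views are complementary: with many more nSOZ
than SOZ channels, FPR stays low while precision collapses, so AUC can look
favorable while maximal F1 does not; with balanced classes the gap shrinks.

Across-patient method comparison uses the two-sided Wilcoxon signed-rank
test on paired AUC and maximal-F1 vectors (exact distribution when
available, zero differences dropped; an all-zero difference vector is
reported as degenerate rather than p = 1) and the Pearson correlation of
maximal F1 (undefined, and reported as such, for constant vectors).

## Synthetic data: what it emulates and what it does not

Each channel-epoch is independent Gaussian `1/f^α` noise (α = 1, broadband
SD 50 µV).  True HFOs are Hann-windowed sinusoids injected as Poisson events
— 10/min on SOZ channels and 1/min elsewhere in the reference condition —
with frequency uniform on 120–300 Hz, 4–9 cycles, random phase, and peak
amplitude `hfo_amp` (default 5) times the 100–500 Hz background SD of that
channel-epoch.  Specifying amplitude relative to the band-limited SD makes
SNR comparable across sampling rates and spectral exponents.  Artifacts come
in two classes: "pop" events (0.3 s DC-shift boxcars, 8× broadband SD, with
a 20× single-sample fast transient at the onset edge carrying the broadband
energy PopDet keys on) at 0.2/min per channel, and "diffuse" events (one
burst waveform added identically to every channel of a group) at 0.3/min per
group.  Simulated visual marking covers the first 60 s: each in-window truth
event is kept with probability 0.6, boundaries jittered by ±10 ms, and
false marks with HFO-like durations are added at 1/min per channel; only
high-confidence-style marks are simulated.  The marking sensitivity, false
rate and jitter were chosen once to produce the high-specificity, partially
sensitive reviewer behaviour typical of one-minute visual review; lowering
the sensitivity drives overlap-F1 surfaces into the low regime seen with
real reviewers.

What the generator does **not** model: spikes and sharp waves in the
background (sharp confounders enter only through the artifact injector),
physiological (non-epileptic) HFOs, spatial correlation of background
activity within an electrode, HFO rate fluctuation over time, sleep staging,
and inter-reviewer variability.  Passing the end-to-end checks therefore
demonstrates internal consistency of the pipeline under clean, stationary
conditions — not clinical-grade performance on real iEEG.

## Numerical choices

* **Filter**: Hamming-window FIR sized for a ≈ 25 Hz transition at 2000 Hz
  (order scales with fs), self-convolved and applied once by FFT convolution
  (`mode='same'`).  A symmetric FIR applied this way is exactly zero-phase
  and algebraically identical to a forward–backward pass away from the
  record edges, at a fraction of the cost on 36-million-sample recordings.
  The same design serves the 850–990 Hz PopDet band.
* **Strictness**: both detector thresholds use strict `>`; the ROC predicts
  SOZ at rate `> t`; the overlap rule is inclusive (`≥ 50%`).
* **Degenerate inputs**: empty epochs, empty event sets, single-contact
  groups (skipped with a warning), zero candidates in rejection statistics,
  constant vectors in correlation, and all-zero difference vectors in the
  Wilcoxon test are all handled explicitly rather than producing NaNs.
* **Determinism**: every stochastic component draws from a
  `numpy.random.Generator` seeded from a single configuration seed; fixed
  seed implies bit-identical recordings, truth, marks, and results.

## Problem sizes used in validation

The validation suite runs the full reference condition (20 channels,
5 × 180 s at 2000 Hz) for ten seeds per condition, and smaller seeded
configurations (2–8 channels, 30–90 s) for stage-level checks; the
acceptance script runs five independent full studies per condition.  These
sizes give stable means for the stochastic checks while keeping a complete
run of the suite in the minutes range on one CPU.

## Known limitations

* EDF files are read through `mne` (install the `edf` extra); EDF writing is
  not supported — the text matrix + JSON sidecar is the interchange format.
* The full two-threshold detector is available only via the `nSD2` override;
  fast-ripple bands (> 500 Hz) are out of scope.
* Greedy one-to-one matching can undercount TP on pathological overlap
  patterns; the optimal matcher is provided but not the default.
* With per-epoch baselines, a channel-epoch dominated by continuous
  high-amplitude oscillations raises its own threshold and suppresses
  detections there — the same behaviour real RMS detectors show on
  pathological channels.
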