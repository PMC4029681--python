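# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic data does and does
not establish.

## Segment grid and spectra

Analysis operates on mono audio resampled to 8 kHz (polyphase rational
resampling) and peak-normalized on load — recording chains differ in gain, so
all trainable thresholds live on the normalized scale. Segments are
`N = 512` samples (64 ms), hop `round(N·(1−overlap))` = 256 samples (32 ms at
the default 50% overlap); trailing samples that do not fill a segment are
discarded. Each segment is multiplied by a *periodic* Hamming window (the
STFT convention) and transformed with a real FFT; the one-sided bins 0…N/2
carry the power spectrum `P = Re² + Im²`, amplitude `A = √P`, and — only when
a consumer asks for it — the phase `Φ ∈ (−π, π]`. The phase is requested by
the tonality detector alone; the cost model prices it at an arctangent per
bin, so it is not computed speculatively.

The analysis band defaults to 60–950 Hz: the lower edge excludes heart
sounds, which sit below 60 Hz, and the upper edge covers the range where
wheeze fundamentals and their audible harmonics carry energy in lung
recordings. At the default grid this maps to inclusive bins
`ceil(60/15.625) = 4` through `floor(950/15.625) = 60`, i.e. 57 bins — the
band width all the characteristic cost figures assume. Both edges are
configurable.

## Features

**Energy gate.** `E[m] = Σ_band P[m,k]`; the extrema `E_min, E_max` are taken
over a ring buffer of the last `M_E` energies *including* the current one.
`M_E = 156` segments ≈ 5 s at the 32 ms hop, enough to always contain at
least one full respiratory cycle, hence both a pause and a breath. A segment
is active iff `E > E_min + C_pause·(E_max − E_min)` with `C_pause = 0.1`
(trainable). Degenerate histories fail open to *active*: both when
`E_min = E_max` and when the stored dynamic range is below 0.1% of the level,
since the rule is meant for the orders-of-magnitude drop between breath sound
and inter-respiratory silence, not for numerical ripple on a steady signal.
Note a consequence of the rule: the minimum-energy segment of the window is
always gated, whatever `C_pause`.

**Tonality.** Amplitude and phase spectra of the two preceding segments give
linear extrapolations `Â = 2A[m−1] − A[m−2]`, `φ̂ = 2φ[m−1] − φ[m−2]`
(phase wrapping is harmless: the extrapolated angle is used only through
cos/sin). The per-bin unpredictability is

    W = √((Re X − Re X̂)² + (Im X − Im X̂)²) / (A + |Â|)

and `T = log₂((E_w + ε)/(E + ε))` with `E_w = Σ W·P`. A perfectly
predictable complex tone drives `W → 0` and `T` to the clamp floor; broadband
noise gives `W = O(1)` and `T` near zero. A *real* windowed tone does not
reach the floor — each bin is the sum of positive- and negative-frequency
phasors, and the residual twin-phasor leakage bounds `T` around −9 at
realistic parameters — but that is still far below anything noise produces.
The decision direction is therefore **tonal iff `T < C_T`** with `C_T`
negative (default −2.0, trainable). Wheezing is declared for tonal runs of
length between `M_dur,min` and `M_dur,max`. The two-segment spectral history
is maintained across gated pauses so the predictor is primed the moment the
gate reopens, but a pause resets the tonal run.

**Peaks, entropy.** Peaks are strict local maxima of the in-band power
spectrum (band-edge bins excluded). The peak entropy is the Shannon entropy
in bits of the peak magnitudes normalized to unit mass; zero peaks or zero
mass define `En = 0`. The entropy ratio `En[m]/En[m−1]` is the sentinel
`NaN` when the previous entropy is ~0, and the classifier treats the sentinel
as "no transition". The transition test is two-sided —
`max(ratio, 1/ratio) > C_ent` — because clustering transitions happen in both
directions (onset: entropy drops; offset: entropy recovers) and a single
threshold `C_ent ≥ 1` covers both.

**Crest models.** The crest band around a peak spans the inclusive bins
`[k − B_crest/2, k + B_crest/2]`, clipped at the analysis-band edges. The
moments model accepts a peak when `P_peak > C_m·mean + C_s·std` over that
band, with the *population* standard deviation (the convention of fixed-point
DSP statistics routines; the difference from the sample deviation is a
constant factor absorbed by training `C_s`). The energy model compares the
crest energy against *annular* narrow and wide surroundings — the bins within
`B_narrow/2` (respectively `B_wide/2`) Hz of the peak, excluding the crest
bins. Annular rather than nested surroundings are required for thresholds
above 1 to be meaningful: a nested band always contains the crest, capping
the ratio at 1. If a surrounding holds no energy at all, the peak is accepted
(a pure tone on silence is the clearest crest there is). Defaults:
`B_crest = 6` bins for the moments model; for the energy model
`B_crest = 2` bins with `B_narrow = 80` Hz and `B_wide = 120` Hz, so the
surroundings are strictly wider than the crest and a flat spectrum is
rejected at any threshold ≥ the bin-count ratio.

**Crest tracking.** Crests are matched to live tracks greedily by nearest
bin distance, ties broken toward the lower-frequency crest, then the
lower-frequency track; greedy nearest-neighbour is deterministic and cheap,
and nothing in the problem calls for a global assignment. A crest may join a
track only within `C_cont[1]` bins — without a gate, an arbitrarily large
jump would inherit the old track's age instead of starting a new component.
Matched tracks extend (duration +1, bin history appended), unmatched crests
spawn fresh tracks, unmatched tracks die; tracks also die through gated
pauses (early termination skips crest extraction entirely). A track is
*continuous* when its deviations `|k[m] − k[m−j]| < C_cont[j]` hold for all
available lags `j ≤ min(M_cont, duration−1)`, and it marks wheezing while its
duration lies in `[M_dur,min, M_dur,max]` with `M_dur,min = M_cont` (the
duration at which all continuity lags first exist). Defaults: `M_cont = 4`,
`C_cont = 3` bins per lag (a drift of ≤ 1 bin per hop — about 490 Hz/s at the
default grid — stays continuous), `M_dur,max = 150` segments ≈ 4.8 s, on the
order of a respiratory cycle. The crest-count gate `1 ≤ N_c ≤ C_crests`
(default 7) discards comb-like segments: a wheeze is one to a few harmonic
components, not twenty.

## Classification, training, scoring

Each algorithm is a deterministic streaming function of the frame sequence;
all temporal state (energy ring buffer, two-frame spectral history, tracks,
tonal run, previous entropy) lives in one state object. Gated pauses are
normal under every tree.

Training is exhaustive grid search over the trainable thresholds of the
chosen algorithm, maximizing the product `SE·SP` of pooled sensitivity and
specificity over the training recordings; ties go to the first grid point in
lexicographic order, and the full ROC point cloud (FPR, TPR per grid point)
is returned alongside the winner. The default objective pools counts
segment-wise; a phase-wise (event) objective is a switch. The evaluation
protocol is leave-one-recording-out; since the training objective is a pooled
sum over recordings, per-recording per-grid-point counts are computed once
and folds differ only in which recording is excluded, so the protocol costs
one classification pass per grid point.

Segment-wise scoring takes the reference class of a segment to be the
annotation label at the segment's *center* time (annotations are continuous
intervals; the center is the least biased single point). Phase-wise scoring
scores only inspiratory/expiratory phases: a phase overlapping any annotated
wheeze interval is a reference positive, and a single positively classified
segment inside a phase makes it detected (true positive if the phase is
positive, false positive otherwise). Metrics with empty denominators are
reported as absent, never coerced to zero.

**Default grids.** Moments model: `C_m ∈ {1, 1.5, 2, 3} × C_s ∈ {0.5, 1, 2, 3}`;
energy model: `C_narrow ∈ {0.8, 1.2, 1.6, 2.4} × C_wide ∈ {1, 1.5, 2, 3}`;
tonality: `C_T ∈ {−6 … −1}`; entropy: `C_ent ∈ {1.2 … 4}`. These are
deliberately modest: the acceptance demonstrations must train 26 folds in
seconds, and the thresholds' useful ranges are known from the feature
definitions (ratios near 1, tonality a few bits below zero). The entropy
detector is best trained under the event objective: it is a *transition*
detector by construction, so the segment-wise objective rewards indiscriminate
firing inside wheeze intervals, whereas the phase-wise objective (one hit per
phase suffices, every false firing burns a normal phase) selects the high
threshold at which its positives sit at wheeze onsets and offsets.

## Complexity model

Costs are exact integer pairs (multiplications, additions), worst case,
multiplicative constants kept, additive constants dropped. Elementary
functions are priced as iterative approximations (Newton–Raphson division,
Newton square root, Taylor log₂/sin/cos/arctg) with per-function iteration
counts; the FFT is radix-2 decimation-in-time at `2N log₂N` multiplications
and `3N log₂N` additions, plus `N` window multiplications as a separate
block. An algorithm's total is defined *compositionally* — the sum of the
blocks on its decision-tree path. The published per-algorithm closed forms
are also evaluated verbatim (`algorithm_cost_printed`) but are known to be
internally inconsistent with their own per-block constituents in three
places (the crest-continuity additions term, and the tonality-path additions
coefficient); `table5_discrepancies` enumerates the differences rather than
silently correcting either side. At the characteristic parameter set
(`N = 512`, `N_b = 57`, `N_p = 20`, `B_crest = 6`, `N_c = 7`, `M_cont = 4`,
`B_narrow = 8`, `B_wide = 12` bins, Newton–Raphson/Newton at 3/5 iterations,
Taylor at 5/3/3/3 terms) the totals rank entropy < crest-moments <
crest-energy < tonality.

Efficiency divides a classification metric in percent by the processing
duty-cycle `D_exec = 100·cycles_exec/cycles_total`, both as percent numbers;
an option rounds the duty cycle to a fixed number of decimals first,
reproducing published arithmetic that divides by a duty cycle printed to two
decimals. Cycle counts are *inputs* (measured on hardware); this package
never profiles cycles itself.

## Synthetic data

The generator emulates the qualitative signal model with the simplest
standard shapes: white noise shaped by a 4th-order Butterworth band-pass
(default 100–250 Hz, the band where lung-field breath noise concentrates),
amplitude-modulated by a respiratory-cycle envelope (inspiration 1.5 s at
amplitude 1, expiration 1.0 s at 0.6 — inspiration louder and longer —
pause 0.5 s at 0.015, raised-cosine transitions ≈ 50 ms), and wheezes as 1–3
harmonic stacks with linearly drifting fundamental and 20 ms edge ramps.
Wheeze level is set as a local SNR: tone power over noise power, both
band-passed to the 60–950 Hz analysis band and measured inside the wheeze
interval, so detector difficulty is directly the configured number. Dataset
generation (default 13 normal + 13 wheeze-containing recordings of 9 s,
mirroring the reference dataset's shape) places 2–4 wheezes per pathological
recording inside randomly chosen inspiratory/expiratory phases with a 0.15 s
edge margin, fundamentals 150–900 Hz (inside the default analysis band;
the full 100–1,500 Hz range is available per-wheeze), durations 0.5–1.2 s,
drifts within ±20 Hz/s, and 15 dB SNR. Everything is reproducible from one
master seed.

What the synthetic data does *not* emulate: patient- and site-dependent
transfer characteristics, heart sounds, friction and movement artifacts,
crackles and other non-wheeze adventitious sounds, irregular breathing
rhythms, amplitude-modulated or polyphonic wheezes with crossing components,
and recording-chain noise. Passing the synthetic acceptance checks therefore
demonstrates that the pipeline recovers the signal model it was built
against — a parameter-recovery result, not a clinical performance claim.
Published accuracies on real recordings are stored as reference *inputs* for
the efficiency arithmetic, not reproduced here.

## Numerical conventions

- `ε = 1e−12` guards every division and logarithm; the tonality index is
  clamped to ±30 (so the all-zero-spectrum case yields exactly 0 through the
  guard, and perfect predictability yields the floor, not −∞).
- Population standard deviation throughout the moments model.
- Resampling is `scipy.signal.resample_poly` with the rational factor in
  lowest terms; output length may differ from `duration × rate` by one
  sample at unfriendly rate ratios.
- The complexity model is pure integer arithmetic end to end.
- All randomness flows from explicit seeds (`numpy.random.default_rng`);
  classification itself is fully deterministic.

## Known limitations

- The fixed-point threshold magnitudes published for the reference DSP
  deployment (e.g. tonality 27,500; entropy 12,600) presuppose an unstated
  integer scaling and are not usable on this floating-point pipeline;
  thresholds must be retrained, and the shipped defaults/grids are tuned to
  the floating-point feature scales.
- The energy gate's window rule always gates the minimum-energy segment of
  the window; on pause-free audio the relative-range guard keeps the gate
  open, but pathological energy profiles between those regimes can gate a
  quiet breath segment.
- Greedy track matching can mis-assign crests when two components cross in
  frequency; a global assignment would cost more and is not needed for
  non-crossing wheezes.
- Leave-one-out ROC curves are emitted per fold as point clouds; averaging
  across folds can be done point-wise or by pooling counts, and both views
  are derivable from the returned structures.
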