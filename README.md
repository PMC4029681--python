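# wheezekit

Detection of asthmatic wheezing in respiratory sound, built for the
low-power regime: four lightweight per-segment decision trees over a common
short-time Fourier transform front-end, together with the training and
evaluation protocol for them, an exact operation-count complexity model, and
a synthetic annotated respiratory-sound generator so the whole stack can be
exercised and tested without any clinical recordings.

It is aimed at people building or studying wearable respiratory-sound
monitors: biomedical signal-processing researchers comparing wheeze
detectors, and engineers budgeting DSP cycles for on-sensor classification.

## The signal model and the four detectors

Breath sound is modeled as cyclostationary band-limited noise (energy
concentrated around 100–250 Hz over the lung fields), amplitude-modulated by
the respiratory cycle, with near-silent inter-respiratory pauses. A wheeze is
a continuous tonal adventitious sound: one to a few harmonic components in
100–1,500 Hz, drifting slowly, lasting tens of milliseconds to seconds. In
the short-time spectrum a wheeze appears as a *spectral crest* — a flattened
band of elevated magnitude around a local maximum that persists across
segments with small frequency deviation.

The front-end frames the signal into `N = 512`-sample segments (64 ms at
8 kHz) overlapped by 50%, applies a periodic Hamming window, and computes the
one-sided spectrum `X[m,k]`, with power `P[m,k] = |X[m,k]|²`, amplitude
`A = √P` and phase `Φ = arg X`. Analysis is restricted to a 60–950 Hz band
(57 bins), which excludes heart sounds concentrated below 60 Hz.

All four classifiers share a root *energy gate*: the segment energy
`E[m] = Σ_k P[m,k]` is compared against the extrema of the last `M_E`
segment energies, and segments near the stored minimum (inter-respiratory
pauses) are declared normal with no further work. The branches differ:

1. **Crest tracking, moments model** — a spectral peak is a crest when
   `P_peak > C_m·mean + C_s·std` of its surrounding `B_crest+1`-bin band;
   crests are tracked through time and a track that stays within per-lag
   frequency-deviation thresholds `C_cont[1..M_cont]` for between
   `M_dur,min = M_cont` and `M_dur,max` segments marks wheezing.
2. **Crest tracking, energy model** — same tree, but a peak is a crest when
   its crest-band energy dominates annular narrow (80 Hz) and wide (120 Hz)
   surroundings: `E_crest/E_narrow > C_narrow` and `E_crest/E_wide > C_wide`.
3. **Tonality tracking** — the tonality index
   `T = log₂(E_w/E)`, with `E_w` the energy weighted by the per-bin
   unpredictability `W = |X − X̂| / (A + |Â|)` (amplitude and phase linearly
   extrapolated from the two previous segments), is deeply negative for
   predictable tonal content; runs of `T < C_T` of admissible duration mark
   wheezing.
4. **Entropy change** — the Shannon entropy `En = −Σ p·log₂ p` of the
   normalized spectral-peak magnitudes drops when energy clusters into few
   peaks; a segment-to-segment entropy ratio departing from 1 by more than
   `C_ent` (either direction) flags a wheeze onset or offset.

Thresholds are trained by exhaustive grid search maximizing the product
`SE·SP` of pooled sensitivity and specificity, and evaluated leave-one-out in
two scenarios: segment-wise (wheeze *duration tracking*) and per respiratory
phase (wheeze *event detection*, where one positive segment flags the whole
phase). The complexity model counts worst-case multiplications and additions
per program block (FFT by radix-2, division by Newton–Raphson, square root by
Newton's algorithm, transcendentals by truncated Taylor series) and the
efficiency metrics divide classification quality by the processing duty-cycle
`D_exec = 100·N_cycl,exec / N_cycl,tot`.

## Worked example

Generate a small annotated synthetic dataset, train the energy-model crest
tracker, and classify one recording:

```sh
$ wheezekit simulate --n-normal 2 --n-wheeze 2 --seed 7 --out demo/data
wrote 4 recordings to demo/data

$ wheezekit train demo/data --algorithm 2 --out demo/alg2.yaml
best SE*SP = 0.8604; config -> demo/alg2.yaml

$ wheezekit detect demo/data/W01.wav --algorithm 2 --config demo/alg2.yaml --out demo/labels.tsv
$ head -4 demo/labels.tsv
m	start_s	label
0	0.000	N
1	0.032	N
2	0.064	N
```

`best SE*SP = 0.8604` is the training objective at the selected thresholds —
the product of pooled sensitivity and specificity over the four training
recordings. The detection output has one row per 64 ms segment (hop 32 ms);
65 of the 280 segments of `W01.wav` are labeled `W`, covering its two
simulated wheezes. Leave-one-out evaluation prints per-fold and pooled
metrics in percent (`-` marks a metric whose denominator is empty, e.g.
sensitivity on a recording with no wheezes):

```sh
$ wheezekit evaluate demo/data --algorithm 2
fold	SE%	SP%	AC%
N01	-	99.29	99.29
N02	-	99.29	99.29
W01	88.00	100.00	96.79
W02	81.58	100.00	97.50
pooled-wheeze	85.84	100.00	97.14
pooled-normal	-	99.29	99.29
pooled-overall	85.84	99.60	98.21
```

The complexity budget for the entropy detector at the characteristic
parameter set, with a measured cycle count supplied for the efficiency rows:

```sh
$ wheezekit budget --algorithm 4 --cycles 59998
block	multiplications	additions
windowing	512	0
stft	9216	13824
power_spectrum	114	57
energy	57	171
peaks	0	514
entropy	669	243
total	10568	14809
duty_cycle_pct	1.87
mu_SE	44.14
mu_SP	44.73
mu_AC	44.81
```

The duty cycle 1.87% means the classifier needs under 2% of the 3.2×10⁶
cycles available between successive segments; `mu_AC = 44.81` is accuracy
percent per duty-cycle percent — the efficiency figure of merit.

The same functionality is available as a library, including sklearn-style
estimators:

```python
from wheezekit import CrestEnergyDetector, generate_dataset

dataset = generate_dataset(n_normal=2, n_wheeze=2, seed=7)
det = CrestEnergyDetector().fit(dataset)
labels = det.predict(dataset[2][0])   # boolean label per 64 ms segment
```

## Layout

- `src/wheezekit/audio_io.py` — WAV loading/resampling, segment framing, annotation TSV
- `src/wheezekit/spectral.py` — windowed one-sided STFT, analysis-band selection
- `src/wheezekit/features.py` — energy history, tonality, peaks, entropy, crest models, tracking
- `src/wheezekit/classifiers.py` — the four decision trees and their configuration
- `src/wheezekit/detectors.py` — sklearn-style estimator facade (fit = grid search)
- `src/wheezekit/evaluation.py` — scoring in both scenarios, grid search, leave-one-out
- `src/wheezekit/complexity.py` — operation-count model and efficiency metrics
- `src/wheezekit/benchmarks.py` — published reference figures used as inputs
- `src/wheezekit/synthetic.py` — annotated synthetic respiratory-sound generator
- `src/wheezekit/cli.py` — the `wheezekit` command

See `docs/methods.md` for the modeling choices, defaults and limitations.
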