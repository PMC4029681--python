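"""Synthetic annotated respiratory recordings.

The generator emulates the standard signal model of auscultated breath sound:
band-limited colored noise (energy concentrated around 100-250 Hz over the
lung fields), amplitude-modulated by the respiratory cycle -- inspiration
louder and longer than expiration, near-silent inter-respiratory pauses --
with wheezes superimposed as one to three slowly drifting harmonic components
in the 100-1500 Hz range, lasting from tens of milliseconds to seconds.

Wheeze level is controlled as a local signal-to-noise ratio: tone power over
noise power, both measured inside the wheeze interval after band-passing to
the analysis band, so detector difficulty is directly the configured SNR.
Ground-truth wheeze intervals and phase boundaries are emitted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from .audio_io import Annotation, Recording

__all__ = ["WheezeSpec", "SimConfig", "generate_recording", "generate_dataset"]

_ANALYSIS_BAND = (60.0, 950.0)


@dataclass(frozen=True)
class WheezeSpec:
    """One wheeze: a harmonic stack with linearly drifting fundamental."""

    start_s: float
    duration_s: float
    f0_hz: float
    n_harmonics: int = 1
    drift_hz_s: float = 0.0
    snr_db: float = 15.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("wheeze duration must be positive")
        if not 1 <= self.n_harmonics <= 3:
            raise ValueError("n_harmonics must be 1..3")
        if not 100.0 <= self.f0_hz <= 1500.0:
            raise ValueError("f0 must lie in [100, 1500] Hz")


@dataclass
class SimConfig:
    """Study conditions for one synthetic recording."""

    duration_s: float = 9.0
    sample_rate: int = 8_000
    # respiratory cycle: inspiration louder and longer than expiration
    insp_s: float = 1.5
    exp_s: float = 1.0
    pause_s: float = 0.5
    exp_amplitude_ratio: float = 0.6
    pause_amplitude: float = 0.015
    noise_band_hz: tuple[float, float] = (100.0, 250.0)
    wheezes: list[WheezeSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample rate must be positive")
        nyq = self.sample_rate / 2
        for w in self.wheezes:
            if w.start_s + w.duration_s > self.duration_s:
                raise ValueError(f"wheeze at {w.start_s}s extends past the recording")
            if w.f0_hz * w.n_harmonics >= nyq:
                raise ValueError("wheeze harmonics exceed Nyquist")

    def phase_plan(self) -> list[tuple[float, float, str]]:
        """(start, end, phase) covering [0, duration]."""
        plan: list[tuple[float, float, str]] = []
        t = 0.0
        while t < self.duration_s:
            for length, name in (
                (self.insp_s, "insp"),
                (self.exp_s, "exp"),
                (self.pause_s, "pause"),
            ):
                end = min(t + length, self.duration_s)
                if end > t:
                    plan.append((t, end, name))
                t = end
                if t >= self.duration_s:
                    break
        return plan


def _envelope(cfg: SimConfig, n: int) -> np.ndarray:
    """Respiratory-cycle amplitude envelope with raised-cosine transitions."""
    fs = cfg.sample_rate
    amp = {"insp": 1.0, "exp": cfg.exp_amplitude_ratio, "pause": cfg.pause_amplitude}
    env = np.empty(n)
    for start, end, name in cfg.phase_plan():
        i0, i1 = int(round(start * fs)), min(int(round(end * fs)), n)
        env[i0:i1] = amp[name]
    # smooth the step function into raised-cosine ramps (~50 ms each side)
    ramp = int(0.1 * fs)
    if ramp > 1:
        kernel = np.hanning(ramp)
        kernel /= kernel.sum()
        env = np.convolve(np.pad(env, ramp, mode="edge"), kernel, mode="same")[ramp:-ramp]
    return env


def _band_power(x: np.ndarray, fs: int, band: tuple[float, float]) -> float:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sosfilt(sos, x)
    return float(np.mean(y**2))


def _wheeze_tone(w: WheezeSpec, fs: int, n_total: int) -> np.ndarray:
    """Unit-scale harmonic stack with linear drift and 20 ms edge ramps."""
    i0 = int(round(w.start_s * fs))
    n = int(round(w.duration_s * fs))
    n = min(n, n_total - i0)
    tau = np.arange(n) / fs
    f_inst = w.f0_hz + w.drift_hz_s * tau
    phase = 2 * np.pi * np.cumsum(f_inst) / fs
    tone = np.zeros(n)
    for h in range(1, w.n_harmonics + 1):
        tone += np.sin(h * phase) / h
    ramp = min(int(0.02 * fs), n // 4)
    if ramp > 0:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        tone[:ramp] *= win
        tone[-ramp:] *= win[::-1]
    out = np.zeros(n_total)
    out[i0 : i0 + n] = tone
    return out


def generate_recording(
    cfg: SimConfig, rec_id: str = "sim", return_parts: bool = False
):
    """Synthesize one annotated recording.

    Returns ``(Recording, Annotation)``; with ``return_parts`` also a dict of
    the unscaled ``noise`` and ``tones`` components (before peak
    normalization) for SNR verification.
    """
    fs = cfg.sample_rate
    n = int(round(cfg.duration_s * fs))
    rng = np.random.default_rng(cfg.seed)

    white = rng.standard_normal(n)
    sos = butter(4, cfg.noise_band_hz, btype="bandpass", fs=fs, output="sos")
    colored = sosfilt(sos, white)
    colored /= np.sqrt(np.mean(colored**2)) + 1e-30
    noise = colored * _envelope(cfg, n)

    tones = np.zeros(n)
    for w in cfg.wheezes:
        tone = _wheeze_tone(w, fs, n)
        i0 = int(round(w.start_s * fs))
        i1 = min(i0 + int(round(w.duration_s * fs)), n)
        p_noise = _band_power(noise[i0:i1], fs, _ANALYSIS_BAND)
        p_tone = _band_power(tone[i0:i1], fs, _ANALYSIS_BAND)
        if p_tone > 0:
            scale = np.sqrt(10 ** (w.snr_db / 10.0) * p_noise / p_tone)
            tones += scale * tone

    x = noise + tones
    peak = np.max(np.abs(x))
    samples = 0.95 * x / peak if peak > 0 else x
    rec = Recording(samples=samples, sample_rate=fs, id=rec_id)
    annot = Annotation(
        intervals=[(w.start_s, w.start_s + w.duration_s, "W") for w in cfg.wheezes],
        phases=cfg.phase_plan(),
    )
    if return_parts:
        return rec, annot, {"noise": noise, "tones": tones}
    return rec, annot


DEFAULT_RANGES = {
    "n_wheezes": (2, 4),
    "f0_hz": (150.0, 900.0),
    "duration_s": (0.5, 1.2),
    "n_harmonics": (1, 2),
    "drift_hz_s": (-20.0, 20.0),
    "snr_db": (15.0, 15.0),
}


def generate_dataset(
    n_normal: int = 13,
    n_wheeze: int = 13,
    ranges: dict | None = None,
    seed: int = 0,
) -> list[tuple[Recording, Annotation]]:
    """Generate a labeled dataset of normal and wheeze-containing recordings.

    Wheezes are placed inside randomly chosen inspiratory/expiratory phases
    with a 0.15 s margin from the phase edges. Per-recording seeds are drawn
    from the master seed, so the dataset is reproducible as a whole.
    """
    r = dict(DEFAULT_RANGES)
    r.update(ranges or {})
    master = np.random.default_rng(seed)
    out: list[tuple[Recording, Annotation]] = []

    def sub_seed() -> int:
        return int(master.integers(0, 2**31 - 1))

    for i in range(n_normal):
        cfg = SimConfig(seed=sub_seed())
        rec, annot = generate_recording(cfg, rec_id=f"N{i + 1:02d}")
        out.append((rec, annot))

    for i in range(n_wheeze):
        s = sub_seed()
        local = np.random.default_rng(s + 1)
        base = SimConfig(seed=s)
        resp = [(a, b) for a, b, name in base.phase_plan() if name in ("insp", "exp")]
        k = int(local.integers(r["n_wheezes"][0], r["n_wheezes"][1] + 1))
        k = min(k, len(resp))
        chosen = sorted(local.choice(len(resp), size=k, replace=False))
        wheezes = []
        for idx in chosen:
            ps, pe = resp[idx]
            margin = 0.15
            avail = pe - ps - 2 * margin
            if avail < 0.3:
                continue
            dur = float(np.clip(local.uniform(*r["duration_s"]), 0.3, avail))
            start = ps + margin + local.uniform(0, avail - dur)
            wheezes.append(
                WheezeSpec(
                    start_s=float(start),
                    duration_s=dur,
                    f0_hz=float(local.uniform(*r["f0_hz"])),
                    n_harmonics=int(
                        local.integers(r["n_harmonics"][0], r["n_harmonics"][1] + 1)
                    ),
                    drift_hz_s=float(local.uniform(*r["drift_hz_s"])),
                    snr_db=float(local.uniform(*r["snr_db"])),
                )
            )
        cfg = SimConfig(seed=s, wheezes=wheezes)
        rec, annot = generate_recording(cfg, rec_id=f"W{i + 1:02d}")
        out.append((rec, annot))
    return out
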