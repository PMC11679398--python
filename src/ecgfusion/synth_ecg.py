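"""Synthetic lead-II heartbeats and annotated multi-beat ECG records.

Beats are sums of Gaussian bumps (the standard dynamical-ECG
simplification) for the P, Q, R, S and T waves, with class-specific
recipes over the five AAMI beat groups:

* **N** — full PQRST morphology;
* **S** — supraventricular ectopic: P wave merged into a slightly
  narrowed QRS, typically arriving on a shortened RR interval;
* **V** — ventricular ectopic: no P wave, QRS width doubled, T inverted;
* **F** — fusion beat: pointwise mean of the N and V templates;
* **Q** — paced/unknown: N morphology plus a short rectangular pacing
  spike 60 ms before the R peak.

Records concatenate beats with Gaussian RR jitter, additive white noise
and a low-frequency sinusoidal baseline wander, and carry ground-truth
R-peak annotations, so the whole downstream pipeline (filtering, peak
detection, segmentation, feature extraction, training) is testable
without any database download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import ECGRecord

CLASSES = ("N", "S", "V", "F", "Q")

# (center s relative to R, width s, amplitude a.u.) for P, Q, R, S, T.
# Fixed constants; amplitudes keep R as the global maximum of every class.
_N_BUMPS = {
    "P": (-0.200, 0.025, 0.15),
    "Q": (-0.035, 0.010, -0.10),
    "R": (0.000, 0.012, 1.00),
    "S": (0.035, 0.012, -0.20),
    "T": (0.160, 0.050, 0.30),
}


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology recipe for one AAMI class."""

    class_label: str
    bump_params: dict  # wave -> (center s, width s, amplitude)
    qrs_width_scale: float = 1.0
    has_p_wave: bool = True
    pacing_spike: bool = False
    t_sign: float = 1.0


def _make_templates() -> dict[str, BeatTemplate]:
    n = BeatTemplate("N", dict(_N_BUMPS))
    s_bumps = dict(_N_BUMPS)
    del s_bumps["P"]  # P merged into the QRS complex
    s = BeatTemplate("S", s_bumps, qrs_width_scale=0.8, has_p_wave=False)
    v_bumps = dict(_N_BUMPS)
    del v_bumps["P"]
    v = BeatTemplate("V", v_bumps, qrs_width_scale=2.0, has_p_wave=False,
                     t_sign=-1.0)
    f = BeatTemplate("F", {}, qrs_width_scale=1.5)  # rendered as mean(N, V)
    q = BeatTemplate("Q", dict(_N_BUMPS), pacing_spike=True)
    return {"N": n, "S": s, "V": v, "F": f, "Q": q}


TEMPLATES = _make_templates()

_QRS_WAVES = ("Q", "R", "S")
_PACING_SPIKE_LEAD_S = 0.060   # spike onset before R
_PACING_SPIKE_SAMPLES = 4
_PACING_SPIKE_AMP = 0.55


def _render(template: BeatTemplate, t: np.ndarray, fs: float) -> np.ndarray:
    if template.class_label == "F":
        return 0.5 * (_render(TEMPLATES["N"], t, fs)
                      + _render(TEMPLATES["V"], t, fs))
    y = np.zeros_like(t)
    for wave, (c, w, a) in template.bump_params.items():
        if wave in _QRS_WAVES:
            c = c * template.qrs_width_scale
            w = w * template.qrs_width_scale
        if wave == "T":
            a = a * template.t_sign
        y += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    if template.pacing_spike:
        start = -_PACING_SPIKE_LEAD_S
        stop = start + _PACING_SPIKE_SAMPLES / fs
        y += np.where((t >= start) & (t < stop), _PACING_SPIKE_AMP, 0.0)
    return y


def generate_beat(class_label: str, fs: float, duration: float,
                  seed: int = 0) -> np.ndarray:
    """One beat waveform with the R peak at the window center.

    A small seed-controlled amplitude/width jitter (±5%) gives per-beat
    variability while keeping classes cleanly separable.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    n = int(round(duration * fs))
    if n < 50:
        raise ValueError("duration*fs must be at least 50 samples")
    rng = np.random.default_rng(seed)
    t = (np.arange(n) - n // 2) / fs
    amp = 1.0 + 0.05 * rng.standard_normal()
    stretch = 1.0 + 0.03 * rng.standard_normal()
    y = amp * _render(TEMPLATES[class_label], t * stretch, fs)
    return y


@dataclass
class SynthRecordConfig:
    """Study conditions for one synthetic record."""

    n_beats: int = 100
    class_mix: tuple = (0.6, 0.1, 0.15, 0.05, 0.1)  # N,S,V,F,Q
    mean_rr: float = 0.8          # s
    rr_jitter_sd: float = 0.05    # s
    noise_sd: float = 0.02        # a.u. (R amplitude is ~1)
    baseline_wander_amp: float = 0.1  # a.u., 0.3 Hz sinusoid
    fs: float = 250.0             # Hz
    seed: int = 0

    def __post_init__(self):
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (5,) or np.any(mix < 0) or abs(mix.sum() - 1) > 1e-9:
            raise ValueError("class_mix must be a 5-class probability vector")
        if self.mean_rr <= 0 or self.fs <= 0 or self.n_beats < 1:
            raise ValueError("invalid SynthRecordConfig")


def generate_record(config: SynthRecordConfig) -> ECGRecord:
    """Annotated multi-beat record: jittered RR, noise, baseline wander.

    Each annotation stores the true R-peak sample index and class symbol.
    For S beats the preceding RR interval is shortened by 25% (premature
    arrival).
    """
    rng = np.random.default_rng(config.seed)
    labels = rng.choice(5, size=config.n_beats, p=np.asarray(config.class_mix))
    symbols = [CLASSES[i] for i in labels]

    rr = config.mean_rr + config.rr_jitter_sd * rng.standard_normal(
        config.n_beats)
    rr = np.maximum(rr, 0.3)
    rr[np.array(symbols) == "S"] *= 0.75
    r_times = 0.5 + np.cumsum(np.concatenate([[0.0], rr[1:]]))

    fs = config.fs
    total = int(round((r_times[-1] + 0.6) * fs))
    signal = np.zeros(total)
    half = 0.45  # beat support ±0.45 s around R
    peaks = []
    for k, sym in enumerate(symbols):
        center = int(round(r_times[k] * fs))
        peaks.append(center)
        nwin = int(round(2 * half * fs))
        t = (np.arange(nwin) - nwin // 2) / fs
        beat_seed = int(rng.integers(2**31))
        y = generate_beat(sym, fs, 2 * half, seed=beat_seed)
        lo = center - nwin // 2
        hi = lo + nwin
        s0 = max(0, -lo)
        s1 = nwin - max(0, hi - total)
        signal[max(0, lo):min(total, hi)] += y[s0:s1]

    if config.baseline_wander_amp > 0:
        tt = np.arange(total) / fs
        signal += config.baseline_wander_amp * np.sin(2 * np.pi * 0.3 * tt)
    if config.noise_sd > 0:
        signal += config.noise_sd * rng.standard_normal(total)

    annotations = list(zip(peaks, symbols))
    return ECGRecord(samples=signal, fs=fs, channel_name="MLII",
                     annotations=annotations)
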