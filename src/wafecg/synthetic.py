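"""Synthetic single-lead ECG generator for four rhythm classes.

Beats are sums of Gaussian bumps for the P, Q, R, S and T waves placed at
physiological offsets inside each RR interval — a standard simplification
that is sufficient to give each rhythm class a distinct subband-energy
signature without a stiff dynamical model. RR intervals are lognormal
(always positive) with a class-specific mean heart rate and coefficient of
variation.

Class presets (artifact choices, not clinical claims):

* NSR  — regular rhythm (CV 3%), full PQRST morphology.
* CHF  — faster, more irregular rhythm with reduced R amplitude, broadened
  QRS and flattened T, shifting energy toward lower-frequency subbands.
* AF   — irregular rhythm (CV 25%), absent P waves, and an 8-12 Hz
  fibrillatory baseline oscillation.
* PEB  — NSR-like rhythm where a random fraction of beats is replaced by
  premature wide-QRS, large-amplitude, P-less ectopic beats.

Every segment also carries measurement noise at a preset SNR floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ECGSegment

__all__ = ["RhythmPreset", "PRESETS", "synth_beat", "synth_segment", "synth_dataset"]

_WAVES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class RhythmPreset:
    """Parameters controlling one rhythm class's synthetic morphology.

    Amplitudes are relative units (R of the NSR preset = 1); widths are
    Gaussian standard deviations in seconds; ``mean_hr`` in beats/min;
    ``rr_jitter_cv`` is the coefficient of variation of the lognormal RR
    distribution; ``fibrillatory_amp`` adds an 8-12 Hz baseline (AF);
    ``ectopic_rate`` is the per-beat probability of an ectopic replacement
    (PEB); ``noise_floor_snr_db`` sets the measurement-noise level.
    """

    class_label: str
    mean_hr: float
    rr_jitter_cv: float
    wave_amplitudes: dict[str, float]
    wave_widths: dict[str, float]
    p_wave_present: bool = True
    fibrillatory_amp: float = 0.0
    ectopic_rate: float = 0.0
    noise_floor_snr_db: float = 30.0

    def __post_init__(self) -> None:
        if not 30 <= self.mean_hr <= 220:
            raise ValueError(f"mean_hr {self.mean_hr} outside the physiological 30-220 bpm")
        if self.rr_jitter_cv < 0:
            raise ValueError("rr_jitter_cv must be nonnegative")
        for w in _WAVES:
            if not math.isfinite(self.wave_amplitudes.get(w, 0.0)):
                raise ValueError(f"amplitude of wave {w} is not finite")


_NSR_AMPS = {"P": 0.15, "Q": -0.10, "R": 1.00, "S": -0.20, "T": 0.35}
_NSR_WIDTHS = {"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.010, "T": 0.060}

PRESETS: dict[str, RhythmPreset] = {
    "NSR": RhythmPreset(
        "NSR", mean_hr=72.0, rr_jitter_cv=0.03,
        wave_amplitudes=dict(_NSR_AMPS), wave_widths=dict(_NSR_WIDTHS),
    ),
    "CHF": RhythmPreset(
        "CHF", mean_hr=95.0, rr_jitter_cv=0.11,
        wave_amplitudes={"P": 0.10, "Q": -0.08, "R": 0.55, "S": -0.28, "T": 0.20},
        wave_widths={"P": 0.030, "Q": 0.018, "R": 0.028, "S": 0.020, "T": 0.080},
    ),
    "AF": RhythmPreset(
        "AF", mean_hr=110.0, rr_jitter_cv=0.25,
        wave_amplitudes={"P": 0.0, "Q": -0.10, "R": 1.00, "S": -0.20, "T": 0.30},
        wave_widths=dict(_NSR_WIDTHS),
        p_wave_present=False, fibrillatory_amp=0.15,
    ),
    "PEB": RhythmPreset(
        "PEB", mean_hr=72.0, rr_jitter_cv=0.05,
        wave_amplitudes=dict(_NSR_AMPS), wave_widths=dict(_NSR_WIDTHS),
        ectopic_rate=0.25,
    ),
}

# ectopic replacement beat: wide, tall, P-less, discordant T
_ECTOPIC_AMPS = {"P": 0.0, "Q": -0.05, "R": 1.30, "S": -0.35, "T": -0.25}
_ECTOPIC_WIDTHS = {"P": 0.025, "Q": 0.020, "R": 0.040, "S": 0.025, "T": 0.080}

# wave-center offsets relative to the R peak, seconds
_OFFSETS = {"P": -0.17, "Q": -0.04, "R": 0.0, "S": 0.04, "T": 0.28}


def synth_beat(
    preset: RhythmPreset,
    rr: float,
    fs: float,
    rng: np.random.Generator | None = None,
    amplitudes: dict[str, float] | None = None,
    widths: dict[str, float] | None = None,
) -> np.ndarray:
    """One beat of length round(rr*fs): Gaussian P, Q, R, S, T bumps.

    The R peak lands exactly on a sample so a lone unit R bump attains its
    nominal amplitude on the grid. Offsets are compressed when the RR
    interval is too short to hold the full complex.
    """
    amplitudes = amplitudes if amplitudes is not None else preset.wave_amplitudes
    widths = widths if widths is not None else preset.wave_widths
    n = int(round(rr * fs))
    if n <= 0:
        return np.zeros(0)
    t = np.arange(n) / fs
    squeeze = min(1.0, rr / 0.8)  # compress the complex into short RR intervals
    t_r = round(0.3 * rr * fs) / fs  # snap the R peak to the sample grid
    beat = np.zeros(n)
    for w in _WAVES:
        a = amplitudes.get(w, 0.0)
        if a == 0.0 or (w == "P" and not preset.p_wave_present):
            continue
        center = t_r + _OFFSETS[w] * squeeze
        sigma = widths[w]
        beat += a * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return beat


def _lognormal_rr(rng: np.random.Generator, mean_rr: float, cv: float) -> float:
    if cv == 0:
        return mean_rr
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean_rr) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def synth_segment(
    preset: RhythmPreset,
    duration_s: float = 10.0,
    fs: float = 250.0,
    seed: int = 0,
) -> ECGSegment:
    """Generate one labelled segment: concatenated beats + class artifacts.

    Deterministic for a fixed seed. The AF preset adds a sinusoidal
    fibrillatory baseline with frequency drawn uniformly in 8-12 Hz; the
    PEB preset replaces beats with ectopic morphology at ``ectopic_rate``;
    all presets add Gaussian measurement noise at ``noise_floor_snr_db``.
    """
    rng = np.random.default_rng(seed)
    n_target = int(round(duration_s * fs))
    mean_rr = 60.0 / preset.mean_hr
    chunks: list[np.ndarray] = []
    total = 0
    while total < n_target:
        rr = _lognormal_rr(rng, mean_rr, preset.rr_jitter_cv)
        rr = min(max(rr, 0.25), 3.0)  # clamp to physiological extremes
        if preset.ectopic_rate > 0 and rng.random() < preset.ectopic_rate:
            beat = synth_beat(preset, rr, fs, rng, _ECTOPIC_AMPS, _ECTOPIC_WIDTHS)
        else:
            beat = synth_beat(preset, rr, fs, rng)
        if beat.size == 0:
            continue
        chunks.append(beat)
        total += beat.size
    x = np.concatenate(chunks)[:n_target]
    if preset.fibrillatory_amp > 0:
        f_fib = rng.uniform(8.0, 12.0)
        phase = rng.uniform(0, 2 * math.pi)
        t = np.arange(n_target) / fs
        x = x + preset.fibrillatory_amp * np.sin(2 * math.pi * f_fib * t + phase)
    if math.isfinite(preset.noise_floor_snr_db):
        p_signal = float(np.mean(x**2))
        if p_signal > 0:
            p_noise = p_signal / 10.0 ** (preset.noise_floor_snr_db / 10.0)
            x = x + rng.normal(0.0, math.sqrt(p_noise), n_target)
    return ECGSegment(
        x,
        fs=fs,
        lead="synthetic",
        label=preset.class_label,
        source_id=f"synthetic:{preset.class_label}:seed={seed}",
    )


def synth_dataset(
    presets: list[RhythmPreset],
    n_per_class: int,
    duration_s: float = 10.0,
    fs: float = 250.0,
    seed: int = 0,
) -> list[ECGSegment]:
    """Generate n_per_class labelled segments per preset, in preset order.

    Per-segment seeds are derived from the master seed, so the collection
    is reproducible and no two segments share a noise realization.
    """
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=len(presets) * n_per_class)
    out = []
    k = 0
    for preset in presets:
        for _ in range(n_per_class):
            out.append(synth_segment(preset, duration_s, fs, int(seeds[k])))
            k += 1
    return out
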