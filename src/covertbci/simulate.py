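"""Synthetic EEG cohorts with planted class-dependent oscillatory effects.

The generator emulates the statistical structure the downstream analysis
assumes: per-channel 1/f background noise, plus band-limited induced
oscillations whose amplitude differs between "yes" and "no" trials, localized
in time and over a scalp channel group.  Effects are realized as band-passed
white noise (random per-trial phase, hence induced rather than phase-locked
power) under a cosine-ramped time envelope, spread over channels with a
Gaussian footprint around the group centroid.

Defaults mirror the study conditions: 23 subjects, 100 trials per class,
500 samples/s, epochs -500..1300 ms, a stronger 9-12 Hz oscillation over
right centroparietal channels at 300-1200 ms for "no", and a stronger
6-10 Hz oscillation over right frontal channels at 200-800 ms for "no".
Effect amplitudes are calibration choices (no ground-truth effect sizes
exist), fixed so that group-mean best-subwindow decoding accuracy lands
near 0.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .epochs import ChannelMontage, EpochSet, standard_montage

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "pink_noise",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class EffectSpec:
    """One band-limited, time-windowed, spatially localized class effect.

    ``amplitude_no`` / ``amplitude_yes`` are the RMS amplitudes (µV) of the
    oscillation at the footprint peak for the two trial classes;
    ``spatial_decay`` is the Gaussian width (unit-disc distance) of the
    leakage to neighboring channels.
    """

    band_hz: tuple[float, float]
    window_ms: tuple[float, float]
    channels: str | tuple[str, ...]
    amplitude_no: float
    amplitude_yes: float
    spatial_decay: float = 0.35

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError(f"invalid frequency band {self.band_hz}")
        if self.amplitude_no < 0 or self.amplitude_yes < 0:
            raise ValueError("effect amplitudes must be >= 0")
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError(f"invalid time window {self.window_ms}")


def _default_effects() -> tuple[EffectSpec, ...]:
    return (
        EffectSpec(band_hz=(9.0, 12.0), window_ms=(300.0, 1200.0),
                   channels="right_centroparietal",
                   amplitude_no=10.4, amplitude_yes=2.6),
        EffectSpec(band_hz=(6.0, 10.0), window_ms=(200.0, 800.0),
                   channels="right_frontal",
                   amplitude_no=9.4, amplitude_yes=2.4),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters; ``seed`` fixes everything."""

    n_subjects: int = 23
    n_trials_per_class: int = 100
    fs: float = 500.0
    epoch_ms: tuple[float, float] = (-500.0, 1300.0)
    noise_exponent: float = 1.0
    noise_rms: float = 10.0
    effects: tuple[EffectSpec, ...] = field(default_factory=_default_effects)
    inter_subject_sd: float = 0.25
    seed: int = 0
    montage: ChannelMontage | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_class < 1:
            raise ValueError("subject and trial counts must be >= 1")
        if self.noise_rms <= 0:
            raise ValueError("noise_rms must be positive")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        for eff in self.effects:
            if eff.band_hz[1] >= self.fs / 2:
                raise ValueError(
                    f"effect band {eff.band_hz} reaches the Nyquist "
                    f"frequency {self.fs / 2}"
                )
            if not (self.epoch_ms[0] <= eff.window_ms[0]
                    < eff.window_ms[1] <= self.epoch_ms[1]):
                raise ValueError(
                    f"effect window {eff.window_ms} outside epoch {self.epoch_ms}"
                )

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_ms[1] - self.epoch_ms[0]) * self.fs / 1000.0))

    def get_montage(self) -> ChannelMontage:
        return self.montage if self.montage is not None else standard_montage()


def pink_noise(n_samples: int, exponent: float, rms: float,
               seed, shape: tuple[int, ...] = ()) -> np.ndarray:
    """Zero-mean noise with power spectrum proportional to 1/f^exponent.

    Shaped in the frequency domain (Gaussian spectral coefficients scaled by
    f^(-exponent/2), DC removed) and normalized to the requested RMS exactly.
    ``seed`` may be an int or a numpy Generator; ``shape`` prepends leading
    axes so whole trial blocks draw in one call.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nf = n_samples // 2 + 1
    coef = rng.standard_normal(shape + (nf,)) + 1j * rng.standard_normal(shape + (nf,))
    f = np.arange(nf, dtype=float)
    gain = np.zeros(nf)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(coef * gain, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    norm = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return rms * x / norm


def _cosine_ramp_envelope(times_ms: np.ndarray, window_ms: tuple[float, float],
                          ramp_ms: float = 50.0) -> np.ndarray:
    """1 inside the window, cosine ramps of ``ramp_ms`` at the edges, 0 outside."""
    t0, t1 = window_ms
    env = np.zeros_like(times_ms)
    inside = (times_ms >= t0) & (times_ms < t1)
    env[inside] = 1.0
    up = inside & (times_ms < t0 + ramp_ms)
    env[up] = 0.5 * (1 - np.cos(np.pi * (times_ms[up] - t0) / ramp_ms))
    down = inside & (times_ms >= t1 - ramp_ms)
    env[down] = 0.5 * (1 - np.cos(np.pi * (t1 - times_ms[down]) / ramp_ms))
    return env


def _effect_footprint(montage: ChannelMontage, eff: EffectSpec) -> np.ndarray:
    """Per-channel gain: Gaussian of scalp distance from the group centroid."""
    if isinstance(eff.channels, str):
        centroid = montage.group_centroid(eff.channels)
    else:
        idx = [montage.index(n) for n in eff.channels]
        centroid = montage.positions[idx].mean(axis=0)
    d = np.linalg.norm(montage.positions - centroid, axis=1)
    return np.exp(-0.5 * (d / eff.spatial_decay) ** 2)


def _band_limited_burst(rng: np.random.Generator, n_trials: int, n_samples: int,
                        fs: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-passed white noise, independent per trial."""
    x = rng.standard_normal((n_trials, n_samples))
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    return y / np.sqrt(np.mean(y**2, axis=-1, keepdims=True))


def generate_subject(config: SimulationConfig, subject_index: int) -> EpochSet:
    """Simulate one subject's balanced EpochSet.

    Deterministic in ``(config.seed, subject_index)``: the same pair always
    yields bit-identical data, whether called directly or via
    :func:`generate_cohort`.
    """
    montage = config.get_montage()
    n_ch = len(montage)
    n_per = config.n_trials_per_class
    n_trials = 2 * n_per
    n_samp = config.n_samples
    times = config.epoch_ms[0] + 1000.0 * np.arange(n_samp) / config.fs

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(subject_index)])
    )
    # Per-subject effect amplitude multipliers (log-normal, one per effect).
    subj_gain = np.exp(config.inter_subject_sd * rng.standard_normal(len(config.effects)))

    labels = np.array(["yes"] * n_per + ["no"] * n_per)
    data = pink_noise(n_samp, config.noise_exponent, config.noise_rms,
                      rng, shape=(n_trials, n_ch))

    for eff, gain in zip(config.effects, subj_gain):
        footprint = _effect_footprint(montage, eff)
        env = _cosine_ramp_envelope(times, eff.window_ms)
        burst = _band_limited_burst(rng, n_trials, n_samp, config.fs, eff.band_hz)
        amp = np.where(labels == "no", eff.amplitude_no, eff.amplitude_yes) * gain
        data += (amp[:, None, None] * footprint[None, :, None]
                 * (burst[:, None, :] * env[None, None, :]))

    # Shuffle trial order so class blocks are not contiguous.
    perm = rng.permutation(n_trials)
    return EpochSet(data[perm], labels[perm], config.fs, config.epoch_ms[0], montage)


def generate_cohort(config: SimulationConfig) -> list[EpochSet]:
    """Simulate ``config.n_subjects`` independent subjects."""
    if config.n_subjects < 2:
        warnings.warn(
            "fewer than 2 subjects: group statistics are undefined",
            UserWarning, stacklevel=2,
        )
    return [generate_subject(config, i) for i in range(config.n_subjects)]


def null_config(config: SimulationConfig | None = None, **kwargs) -> SimulationConfig:
    """A label-exchangeable variant: every effect equal in the two classes."""
    cfg = config if config is not None else SimulationConfig(**kwargs)
    effects = tuple(
        replace(e, amplitude_no=0.5 * (e.amplitude_no + e.amplitude_yes),
                amplitude_yes=0.5 * (e.amplitude_no + e.amplitude_yes))
        for e in cfg.effects
    )
    return replace(cfg, effects=effects)
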