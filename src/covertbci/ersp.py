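"""Event-related spectral perturbation via complex Morlet wavelets.

Power is estimated with a continuous wavelet transform whose cycle count
increases linearly with frequency (4 cycles at 1 Hz to 13.5 cycles at
100 Hz), trading temporal for spectral resolution on a linear frequency
axis.  Induced (non-phase-locked) power is the average over trials of
single-trial power maps.  Maps are normalized as the relative change with
respect to a pre-onset baseline, (P - B) / B with B the mean power over
-300..0 ms, computed per channel and frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .epochs import EpochSet

__all__ = [
    "TimeFrequencyMap",
    "morlet_cycles",
    "morlet_wavelet",
    "single_trial_power",
    "induced_power",
    "baseline_normalize",
]


@dataclass
class TimeFrequencyMap:
    """Power on a (channel, frequency, time) grid.

    ``values`` has shape (n_channels, n_freqs, n_times).  ``normalized``
    marks baseline-ratio maps, whose baseline-interval mean is ~0 per
    channel x frequency by construction.
    """

    values: np.ndarray
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    channels: tuple[str, ...]
    baseline_ms: tuple[float, float] = (-300.0, 0.0)
    normalized: bool = False
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.shape != (len(self.channels), self.freqs_hz.size,
                                 self.times_ms.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.channels)}, {self.freqs_hz.size}, {self.times_ms.size})"
            )
        if np.any(np.diff(self.freqs_hz) <= 0) or np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("frequency and time axes must be strictly increasing")

    def crop_times(self, t_start_ms: float, t_end_ms: float) -> "TimeFrequencyMap":
        """Keep time bins with t_start_ms <= t <= t_end_ms (inclusive grid)."""
        keep = (self.times_ms >= t_start_ms - 1e-9) & (self.times_ms <= t_end_ms + 1e-9)
        return replace(self, values=self.values[:, :, keep],
                       times_ms=self.times_ms[keep])


def morlet_cycles(f: float | np.ndarray) -> np.ndarray:
    """Cycle count for the wavelet at frequency ``f`` (Hz).

    Linear schedule n(f) = 4 + 9.5 (f - 1) / 99, i.e. 4 cycles at 1 Hz and
    13.5 at 100 Hz; frequencies outside [1, 100] are clamped with a warning.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 1.0) or np.any(f > 100.0):
        warnings.warn("frequency outside [1, 100] Hz; cycle count clamped",
                      UserWarning, stacklevel=2)
        f = np.clip(f, 1.0, 100.0)
    return 4.0 + 9.5 * (f - 1.0) / 99.0


def morlet_wavelet(f: float, fs: float, n_cycles: float | None = None) -> np.ndarray:
    """Complex Morlet wavelet, Gaussian SD in time sigma_t = n_cycles/(2 pi f).

    Support is +-5 sigma_t, odd length; L2-normalized so power units are
    consistent across frequencies.
    """
    if n_cycles is None:
        n_cycles = float(morlet_cycles(f))
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    w -= w.mean()  # zero-mean correction (negligible above ~3 cycles)
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def _cwt_power(block: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """|CWT|^2 for a (..., n_samples) block at each frequency.

    FFT-based convolution, one forward FFT of the data shared across
    frequencies; returns (..., n_freqs, n_samples).
    """
    n = block.shape[-1]
    wavelets = [morlet_wavelet(f, fs) for f in freqs]
    longest = max(w.size for w in wavelets)
    if longest > n:
        f_bad = freqs[int(np.argmax([w.size for w in wavelets]))]
        raise ValueError(
            f"wavelet at {f_bad:g} Hz ({longest} samples) is longer than the "
            f"epoch ({n} samples)"
        )
    nfft = int(2 ** np.ceil(np.log2(n + longest - 1)))
    Xf = np.fft.fft(block, n=nfft, axis=-1)
    out = np.empty(block.shape[:-1] + (len(wavelets), n))
    for j, w in enumerate(wavelets):
        Wf = np.fft.fft(w, n=nfft)
        conv = np.fft.ifft(Xf * Wf, axis=-1)
        start = (w.size - 1) // 2
        out[..., j, :] = np.abs(conv[..., start : start + n]) ** 2
    return out


def single_trial_power(trial: np.ndarray, freqs: np.ndarray, fs: float,
                       times_ms: np.ndarray | None = None,
                       channels: tuple[str, ...] | None = None,
                       t0_ms: float = 0.0) -> TimeFrequencyMap:
    """Squared-magnitude Morlet transform of one (channel x time) trial."""
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be (n_channels, n_samples)")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")
    power = _cwt_power(trial, freqs, fs)
    if times_ms is None:
        times_ms = t0_ms + 1000.0 * np.arange(trial.shape[-1]) / fs
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(trial.shape[0]))
    return TimeFrequencyMap(power, freqs, np.asarray(times_ms, float), channels)


def induced_power(epochs: EpochSet, freqs, decim_ms: float = 5.0,
                  t_range_ms: tuple[float, float] = (-300.0, 1200.0),
                  classes: tuple[str, ...] | None = None,
                  ) -> dict[str, TimeFrequencyMap]:
    """Per-class induced power: trial-wise Morlet power averaged over trials.

    The transform runs on the full epoch (so edge effects stay outside the
    reported range) and is then subsampled onto the analysis grid
    ``t_range_ms`` with step ``decim_ms``; the default grid -300..1200 ms
    covers the baseline interval.  With the default 0-1200 ms crop at 5 ms
    and 5-30 Hz at 1 Hz the analysis grid has 241 x 26 bins per channel.
    """
    freqs = np.asarray(freqs, dtype=float)
    if classes is None:
        classes = tuple(sorted(np.unique(epochs.labels), reverse=True))
    grid_times = np.arange(t_range_ms[0], t_range_ms[1] + decim_ms / 2, decim_ms)
    sample_times = epochs.times_ms
    if grid_times[0] < sample_times[0] - 1e-9 or grid_times[-1] > sample_times[-1] + 1e-9:
        raise ValueError(
            f"analysis range {t_range_ms} outside epoch "
            f"[{sample_times[0]:g}, {sample_times[-1]:g}] ms"
        )
    idx = np.round((grid_times - epochs.t0_ms) * epochs.fs / 1000.0).astype(int)
    idx = np.clip(idx, 0, epochs.n_samples - 1)
    out = {}
    for label in classes:
        tr = epochs.class_indices(label)
        if tr.size < 1:
            raise ValueError(f"no trials of class {label!r}")
        power = _cwt_power(epochs.data[tr], freqs, epochs.fs)
        mean_power = power.mean(axis=0)[:, :, idx]
        out[label] = TimeFrequencyMap(mean_power, freqs, grid_times,
                                      epochs.montage.names, condition=label)
    return out


def baseline_normalize(tfmap: TimeFrequencyMap) -> TimeFrequencyMap:
    """Relative change (P - B)/B with B the mean power over the baseline
    interval, per channel and frequency."""
    if tfmap.normalized:
        raise ValueError("map is already baseline-normalized")
    b0, b1 = tfmap.baseline_ms
    mask = (tfmap.times_ms >= b0 - 1e-9) & (tfmap.times_ms < b1 - 1e-9)
    if not np.any(mask):
        raise ValueError(
            f"map times do not cover the baseline interval [{b0}, {b1}) ms"
        )
    B = tfmap.values[:, :, mask].mean(axis=-1, keepdims=True)
    if np.any(B <= 0):
        raise ValueError("baseline power is zero for some channel x frequency")
    return replace(tfmap, values=(tfmap.values - B) / B, normalized=True)
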