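"""Epoched multichannel EEG container and scalp montage.

The pipeline currency is :class:`EpochSet`: a ``(n_trials, n_channels,
n_samples)`` block of epoched EEG in microvolts, with per-trial class labels
("yes"/"no"), a sampling rate, the time of the first sample relative to
critical-word onset, and a :class:`ChannelMontage` carrying 2-D scalp
coordinates and named channel groups.

Time convention: sample ``i`` sits at ``t0_ms + 1000 * i / fs`` milliseconds
relative to critical-word onset; cropping windows are half-open
``[start, end)`` so adjacent subwindows never share samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelMontage",
    "EpochSet",
    "standard_montage",
    "STANDARD_29",
    "select_channels",
    "crop_time",
    "save_epochs",
    "load_epochs",
]

#: The 29-channel 10-20 subset used for decoding.
STANDARD_29 = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

# (azimuth deg from nose, clockwise toward the right ear; inclination deg from
# vertex).  Textbook 10-20/10-10 angles; projected to the unit disc with
# radius = inclination / 90, nose = +y.
_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (-18, 72), "Fpz": (0, 72), "Fp2": (18, 72),
    "F7": (-54, 72), "F3": (-39, 50), "Fz": (0, 36), "F4": (39, 50), "F8": (54, 72),
    "FC5": (-69, 54), "FC1": (-21, 31), "FC2": (21, 31), "FC6": (69, 54),
    "T7": (-90, 72), "C3": (-90, 36), "Cz": (0, 0), "C4": (90, 36), "T8": (90, 72),
    "CP5": (-111, 54), "CP1": (-159, 31), "CP2": (159, 31), "CP6": (111, 54),
    "P7": (-126, 72), "P3": (-141, 50), "Pz": (180, 36), "P4": (141, 50), "P8": (126, 72),
    "O1": (-162, 72), "Oz": (180, 72), "O2": (162, 72),
}

#: Channel groups carrying the class effects reported for this task.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "right_frontal": ("FC2", "FC6", "C4"),
    "right_centroparietal": ("CP2", "Pz", "P4"),
}


def _disc_position(azimuth_deg: float, inclination_deg: float) -> tuple[float, float]:
    r = inclination_deg / 90.0
    a = np.deg2rad(azimuth_deg)
    return (r * float(np.sin(a)), r * float(np.cos(a)))


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered channel labels with 2-D scalp coordinates on the unit disc.

    Parameters
    ----------
    names : tuple of str
        Unique channel labels, in recording order.
    positions : ndarray of shape (n_channels, 2)
        Flat scalp projection; nose points toward +y, radius <= 1.
    groups : dict
        Named channel subsets, e.g. ``right_frontal = (FC2, FC6, C4)``.
    """

    names: tuple[str, ...]
    positions: np.ndarray
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(names)} channels"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("channel positions must be finite")
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) > 1.0 + 1e-9):
            raise ValueError("channel positions must lie within the unit disc")
        for gname, members in self.groups.items():
            missing = [m for m in members if m not in names]
            if missing:
                raise ValueError(f"group {gname!r} contains unknown channels {missing}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def subset(self, names: list[str] | tuple[str, ...]) -> "ChannelMontage":
        idx = [self.index(n) for n in names]
        keep = set(names)
        groups = {
            g: tuple(m for m in members if m in keep)
            for g, members in self.groups.items()
        }
        groups = {g: m for g, m in groups.items() if m}
        return ChannelMontage(tuple(names), self.positions[idx], groups)

    def group_centroid(self, group: str) -> np.ndarray:
        idx = [self.index(n) for n in self.groups[group]]
        return self.positions[idx].mean(axis=0)


def standard_montage(names: tuple[str, ...] = STANDARD_29) -> ChannelMontage:
    """Montage for a subset of the 10-20/10-10 labels known to this package."""
    unknown = [n for n in names if n not in _ANGLES]
    if unknown:
        raise KeyError(f"no stored scalp position for channels {unknown}")
    pos = np.array([_disc_position(*_ANGLES[n]) for n in names])
    groups = {
        g: tuple(m for m in members if m in names)
        for g, members in DEFAULT_GROUPS.items()
    }
    groups = {g: m for g, m in groups.items() if m}
    return ChannelMontage(tuple(names), pos, groups)


@dataclass
class EpochSet:
    """Labeled single-trial EEG epochs.

    Attributes
    ----------
    data : ndarray (n_trials, n_channels, n_samples)
        Signal in microvolts.
    labels : ndarray of str
        Per-trial class, "yes" or "no".
    fs : float
        Sampling rate, samples/s.
    t0_ms : float
        Time of the first sample relative to critical-word onset, ms.
    montage : ChannelMontage
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    t0_ms: float
    montage: ChannelMontage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U8")
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[1] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[1]} channels but montage has "
                f"{len(self.montage)}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length must equal n_trials")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample times relative to critical-word onset, ms."""
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.fs

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), labels=self.labels.copy())


def select_channels(epochs: EpochSet, names: list[str] | tuple[str, ...]) -> EpochSet:
    """Return an EpochSet restricted to ``names``, in the requested order."""
    missing = [n for n in names if n not in epochs.montage.names]
    if missing:
        raise KeyError(f"unknown channel(s) {missing} not in montage")
    idx = [epochs.montage.index(n) for n in names]
    return EpochSet(
        epochs.data[:, idx, :],
        epochs.labels.copy(),
        epochs.fs,
        epochs.t0_ms,
        epochs.montage.subset(names),
    )


def crop_time(epochs: EpochSet, t_start_ms: float, t_end_ms: float) -> EpochSet:
    """Keep samples with time in the half-open window [t_start_ms, t_end_ms)."""
    t_end_epoch = epochs.t0_ms + 1000.0 * epochs.n_samples / epochs.fs
    if not (epochs.t0_ms <= t_start_ms < t_end_ms <= t_end_epoch + 1e-9):
        raise ValueError(
            f"crop window [{t_start_ms}, {t_end_ms}) outside epoch "
            f"[{epochs.t0_ms}, {t_end_epoch})"
        )
    i0 = int(round((t_start_ms - epochs.t0_ms) * epochs.fs / 1000.0))
    n = int(round((t_end_ms - t_start_ms) * epochs.fs / 1000.0))
    return EpochSet(
        epochs.data[:, :, i0 : i0 + n],
        epochs.labels.copy(),
        epochs.fs,
        epochs.t0_ms + 1000.0 * i0 / epochs.fs,
        epochs.montage,
    )


def save_epochs(epochs: EpochSet, path) -> None:
    """Write an EpochSet to a single ``.npz`` archive (bit-exact round trip)."""
    meta = {
        "fs": epochs.fs,
        "t0_ms": epochs.t0_ms,
        "groups": {g: list(m) for g, m in epochs.montage.groups.items()},
    }
    np.savez(
        path,
        data=epochs.data,
        labels=epochs.labels,
        names=np.array(epochs.montage.names),
        positions=epochs.montage.positions,
        meta=np.array(json.dumps(meta)),
    )


def load_epochs(path) -> EpochSet:
    """Read an EpochSet written by :func:`save_epochs`."""
    with np.load(path, allow_pickle=False) as f:
        for key in ("data", "labels", "names", "positions", "meta"):
            if key not in f:
                raise ValueError(f"epoch archive missing field {key!r}")
        meta = json.loads(str(f["meta"]))
        montage = ChannelMontage(
            tuple(str(n) for n in f["names"]),
            f["positions"],
            {g: tuple(m) for g, m in meta.get("groups", {}).items()},
        )
        return EpochSet(f["data"], f["labels"], float(meta["fs"]),
                        float(meta["t0_ms"]), montage)
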