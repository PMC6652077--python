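"""Mass-univariate paired analysis with cluster-based permutation correction.

Pipeline for one frequency band of interest:

1. Paired t tests over every (channel, frequency, time) bin of the
   per-subject condition maps; electrodes are screened by averaging t over
   the band and analysis window and keeping the top 10 % (ceil(0.1 C)).
2. Per-subject condition maps are averaged over the screened electrodes;
   paired t tests over the resulting time-frequency bins are thresholded at
   p < 0.05, contiguous bins (4-neighbour adjacency, sign-homogeneous) are
   clustered if they contain a run of at least ``min_run`` successive bins
   along the time or the frequency axis, and each cluster is scored by
   t_mass, the sum of its t values.
3. The null distribution of the maximum |t_mass| is built from surrogates in
   which each subject's condition labels are independently swapped
   (sign-flips of the paired differences), re-running steps 1-2 per
   surrogate; a cluster is significant when its |t_mass| lands above the
   highest alpha fraction of the null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .ersp import TimeFrequencyMap

__all__ = [
    "Cluster",
    "ClusterResult",
    "stack_maps",
    "paired_t_map",
    "screen_electrodes",
    "form_clusters",
    "permutation_null",
]

_ADJACENCY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Cluster:
    """One contiguous time-frequency cluster with its summed t statistic."""

    bins: np.ndarray          # (n_bins, 2) indices into (freq, time)
    t_mass: float
    p_value: float = math.nan
    significant: bool = False


@dataclass
class ClusterResult:
    """Outcome of the banded cluster-permutation analysis."""

    band: str
    band_hz: tuple[float, float]
    selected_electrodes: tuple[str, ...]
    t_threshold: float            # screening cut implied by the top-10% rule
    t_grid: np.ndarray            # (n_freqs, n_times) observed t over screened electrodes
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    clusters: list[Cluster]
    null_distribution: np.ndarray
    alpha: float

    @property
    def null_quantile(self) -> float:
        if self.null_distribution.size == 0:
            return math.nan
        return float(np.quantile(self.null_distribution, 1.0 - self.alpha))

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def stack_maps(maps: list[TimeFrequencyMap]) -> np.ndarray:
    """Stack per-subject maps into (n_subjects, n_channels, n_freqs, n_times),
    verifying the grids agree."""
    ref = maps[0]
    for m in maps[1:]:
        if (m.channels != ref.channels
                or not np.array_equal(m.freqs_hz, ref.freqs_hz)
                or not np.array_equal(m.times_ms, ref.times_ms)):
            raise ValueError("subject maps are not on a common grid")
    return np.stack([m.values for m in maps])


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Paired t along axis 0; df = n - 1."""
    n = diff.shape[0]
    if n < 2:
        raise ValueError("paired t test needs >= 2 subjects")
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd == 0, np.sign(mean) * np.inf, mean * np.sqrt(n)
                     / np.where(sd == 0, 1.0, sd))
    return np.where((sd == 0) & (mean == 0), 0.0, t)


def paired_t_map(cond_a, cond_b) -> np.ndarray:
    """Paired t per (channel, frequency, time) bin between two conditions.

    Accepts lists of per-subject :class:`TimeFrequencyMap` (same subjects,
    same grid) or pre-stacked arrays.
    """
    A = stack_maps(cond_a) if not isinstance(cond_a, np.ndarray) else cond_a
    B = stack_maps(cond_b) if not isinstance(cond_b, np.ndarray) else cond_b
    if A.shape != B.shape:
        raise ValueError(f"condition shapes differ: {A.shape} vs {B.shape}")
    return _paired_t(A - B)


def _n_screened(n_electrodes: int) -> int:
    return max(1, math.ceil(0.10 * n_electrodes))


def screen_electrodes(t_map: np.ndarray, freqs_hz: np.ndarray,
                      times_ms: np.ndarray, band_hz: tuple[float, float],
                      window_ms: tuple[float, float] | None = None,
                      channels: tuple[str, ...] | None = None,
                      ) -> tuple[np.ndarray, float]:
    """Top-10% electrode screen on band/window-averaged t values.

    Returns the selected electrode indices (descending t order) and the
    implied threshold (the smallest selected average t).
    """
    t_map = np.asarray(t_map)
    fmask = (freqs_hz >= band_hz[0] - 1e-9) & (freqs_hz <= band_hz[1] + 1e-9)
    if not np.any(fmask):
        raise ValueError(f"band {band_hz} Hz does not intersect the grid")
    if window_ms is None:
        tmask = np.ones(times_ms.size, dtype=bool)
    else:
        tmask = (times_ms >= window_ms[0] - 1e-9) & (times_ms <= window_ms[1] + 1e-9)
        if not np.any(tmask):
            raise ValueError(f"window {window_ms} ms does not intersect the grid")
    avg = t_map[:, fmask][:, :, tmask].mean(axis=(1, 2))
    k = _n_screened(t_map.shape[0])
    order = np.argsort(-avg, kind="stable")
    selected = order[:k]
    return selected, float(avg[selected[-1]])


def _max_run(coords: np.ndarray) -> int:
    """Longest run of consecutive bins along either axis of a component."""
    best = 1
    for axis in (0, 1):
        other = 1 - axis
        for fixed in np.unique(coords[:, other]):
            vals = np.sort(coords[coords[:, other] == fixed, axis])
            run = 1
            for a, b in zip(vals[:-1], vals[1:]):
                run = run + 1 if b == a + 1 else 1
                best = max(best, run)
    return best


def form_clusters(p_mask: np.ndarray, t_grid: np.ndarray,
                  min_run: int = 3, sign_homogeneous: bool = True) -> list[Cluster]:
    """Connected components of the significance mask, scored by t_mass.

    Components use 4-neighbour adjacency over the (frequency, time) grid and
    are retained only if they contain at least ``min_run`` successive bins
    along one axis.  With ``sign_homogeneous`` (default) positive and
    negative t bins form separate clusters.
    """
    p_mask = np.asarray(p_mask, dtype=bool)
    t_grid = np.asarray(t_grid, dtype=float)
    if p_mask.shape != t_grid.shape:
        raise ValueError("mask and t grid shapes differ")
    masks = ([p_mask & (t_grid > 0), p_mask & (t_grid < 0)]
             if sign_homogeneous else [p_mask])
    clusters: list[Cluster] = []
    for mask in masks:
        lab, n = ndimage.label(mask, structure=_ADJACENCY)
        for comp in range(1, n + 1):
            coords = np.argwhere(lab == comp)
            if coords.shape[0] < min_run or _max_run(coords) < min_run:
                continue
            clusters.append(Cluster(
                bins=coords,
                t_mass=float(t_grid[coords[:, 0], coords[:, 1]].sum()),
            ))
    clusters.sort(key=lambda c: -abs(c.t_mass))
    return clusters


def _step2(diff_sel: np.ndarray, p_threshold: float, min_run: int,
           two_sided: bool) -> tuple[np.ndarray, list[Cluster]]:
    """Steps after electrode averaging: t grid, p mask, clusters.

    ``diff_sel``: (n_subjects, n_freqs, n_times) paired differences averaged
    over the screened electrodes.
    """
    n = diff_sel.shape[0]
    t_grid = _paired_t(diff_sel)
    if two_sided:
        t_crit = stats.t.ppf(1.0 - p_threshold / 2.0, df=n - 1)
        mask = np.abs(t_grid) > t_crit
    else:
        t_crit = stats.t.ppf(1.0 - p_threshold, df=n - 1)
        mask = t_grid > t_crit
    return t_grid, form_clusters(mask, t_grid, min_run=min_run,
                                 sign_homogeneous=two_sided)


def permutation_null(cond_a: list[TimeFrequencyMap], cond_b: list[TimeFrequencyMap],
                     band_hz: tuple[float, float], band_name: str = "",
                     n_perm: int = 5000, alpha: float = 0.05, seed=0,
                     p_threshold: float = 0.05, min_run: int = 3,
                     two_sided: bool = True, freeze_electrodes: bool = False,
                     window_ms: tuple[float, float] | None = None,
                     ) -> ClusterResult:
    """Full banded analysis with a sign-flip permutation null.

    Surrogates swap each subject's two condition maps independently; by
    default the electrode screen is recomputed inside every surrogate
    (``freeze_electrodes=True`` reuses the observed screen instead).  The
    null records the maximum |t_mass| per surrogate (0 when a surrogate has
    no retained cluster); cluster p values are (1 + #{null >= |t_mass|}) /
    (n_perm + 1) and significance is p <= alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    A = stack_maps(cond_a)
    B = stack_maps(cond_b)
    if A.shape != B.shape:
        raise ValueError(f"condition shapes differ: {A.shape} vs {B.shape}")
    n_sub, n_ch = A.shape[0], A.shape[1]
    ref = cond_a[0]
    diff = A - B  # (n_sub, n_ch, n_f, n_t)
    if n_sub < np.log2(1.0 / alpha):
        warnings.warn(
            f"only 2**{n_sub} sign patterns exist; permutation p-values are "
            "resolution-limited", UserWarning, stacklevel=2,
        )

    def analyze(d: np.ndarray, electrodes=None):
        t3 = _paired_t(d)
        if electrodes is None:
            electrodes, t_cut = screen_electrodes(
                t3, ref.freqs_hz, ref.times_ms, band_hz, window_ms)
        else:
            t_cut = math.nan
        diff_sel = d[:, electrodes].mean(axis=1)
        t_grid, clusters = _step2(diff_sel, p_threshold, min_run, two_sided)
        return electrodes, t_cut, t_grid, clusters

    obs_elec, t_cut, t_grid, clusters = analyze(diff)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    frozen = obs_elec if freeze_electrodes else None
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        d = diff * signs[:, None, None, None]
        _, _, _, sclusters = analyze(d, electrodes=frozen)
        if sclusters:
            null[i] = max(abs(c.t_mass) for c in sclusters)

    for c in clusters:
        c.p_value = float((1 + np.sum(null >= abs(c.t_mass))) / (n_perm + 1))
        c.significant = c.p_value <= alpha

    return ClusterResult(
        band=band_name or f"{band_hz[0]:g}-{band_hz[1]:g}Hz",
        band_hz=tuple(band_hz),
        selected_electrodes=tuple(ref.channels[j] for j in obs_elec),
        t_threshold=t_cut,
        t_grid=t_grid,
        freqs_hz=ref.freqs_hz,
        times_ms=ref.times_ms,
        clusters=clusters,
        null_distribution=null,
        alpha=alpha,
    )
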