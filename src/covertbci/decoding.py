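"""Single-trial yes/no decoding over a time-frequency subwindow grid.

The decoding machinery: the overall range (0-1200 ms, 4-50 Hz by default) is
tiled into 200 ms x 2 Hz subwindows.  Within each subwindow, single trials
are band-pass filtered with a linear-phase FIR filter (order 512), cropped to
the subwindow's time range, spatially filtered by CSP (m = 2, hence 4
log-variance features), and classified by an RBF-kernel support vector
machine.  Accuracy is estimated by balanced 10-fold cross-validation with
CSP and classifier fitted on training folds only.  Subwindows whose
group-mean accuracy exceeds mean + 2 SD over the accuracy map are selected,
and their features concatenated for a combined decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .csp import CSP
from .epochs import EpochSet, crop_time

__all__ = [
    "SubwindowGrid",
    "DecodingResult",
    "make_grid",
    "bandpass_fir",
    "WindowDecoder",
    "decode_subwindow",
    "decode_combined",
    "accuracy_map",
    "AccuracyMap",
    "select_subwindows",
    "chance_threshold",
    "train_classifier",
    "predict",
]

POSITIVE_CLASS = "no"   # sensitivity = correct "no" rate (fact-violation trials)
NEGATIVE_CLASS = "yes"  # specificity = correct "yes" rate
CLASS_ORDER = (NEGATIVE_CLASS, POSITIVE_CLASS)  # class 1 = "yes", class 2 = "no"


@dataclass(frozen=True)
class SubwindowGrid:
    """Non-overlapping tiling of a time x frequency range."""

    time_edges_ms: tuple[float, ...]
    freq_edges_hz: tuple[float, ...]
    windows: tuple[tuple[float, float, float, float], ...]

    @property
    def n_time(self) -> int:
        return len(self.time_edges_ms) - 1

    @property
    def n_freq(self) -> int:
        return len(self.freq_edges_hz) - 1

    def __len__(self) -> int:
        return len(self.windows)


def make_grid(t_range_ms: tuple[float, float] = (0.0, 1200.0),
              f_range_hz: tuple[float, float] = (4.0, 50.0),
              dt_ms: float = 200.0, df_hz: float = 2.0) -> SubwindowGrid:
    """Tile the ranges exactly; time-major window order."""
    nt = (t_range_ms[1] - t_range_ms[0]) / dt_ms
    nf = (f_range_hz[1] - f_range_hz[0]) / df_hz
    if abs(nt - round(nt)) > 1e-9 or round(nt) < 1:
        raise ValueError(f"dt_ms={dt_ms} does not divide time range {t_range_ms}")
    if abs(nf - round(nf)) > 1e-9 or round(nf) < 1:
        raise ValueError(f"df_hz={df_hz} does not divide frequency range {f_range_hz}")
    nt, nf = int(round(nt)), int(round(nf))
    t_edges = tuple(t_range_ms[0] + i * dt_ms for i in range(nt + 1))
    f_edges = tuple(f_range_hz[0] + j * df_hz for j in range(nf + 1))
    windows = tuple(
        (t_edges[i], t_edges[i + 1], f_edges[j], f_edges[j + 1])
        for i in range(nt) for j in range(nf)
    )
    return SubwindowGrid(t_edges, f_edges, windows)


def _fir_kernel(f_low: float, f_high: float, fs: float, order: int) -> np.ndarray:
    # order-N linear-phase FIR has N+1 symmetric taps; scale=True gives unit
    # gain at the band centre.
    return signal.firwin(order + 1, [f_low, f_high], pass_zero=False, fs=fs,
                         scale=True)


def bandpass_fir(epochs: EpochSet, f_low: float, f_high: float,
                 order: int = 512) -> EpochSet:
    """Zero-phase band-pass with a linear-phase FIR filter of the given order.

    The symmetric impulse response is applied by centered convolution, which
    exactly compensates the (order/2)-sample group delay; shape is preserved.
    Filter the full epoch before cropping so edge transients never reach the
    analyzed subwindow.
    """
    if not (0 < f_low < f_high < epochs.fs / 2):
        raise ValueError(
            f"band ({f_low}, {f_high}) Hz invalid for fs={epochs.fs}"
        )
    taps = _fir_kernel(f_low, f_high, epochs.fs, order)
    out = signal.fftconvolve(epochs.data, taps[None, None, :], mode="same",
                             axes=-1)
    return EpochSet(out, epochs.labels.copy(), epochs.fs, epochs.t0_ms,
                    epochs.montage)


@dataclass
class DecodingResult:
    """Cross-validated decoding metrics for one subwindow (or "combined")."""

    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    sensitivity: float
    specificity: float
    window: str
    n_test_per_class: float

    def as_dict(self) -> dict:
        return {
            "window": self.window,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "n_test_per_class": self.n_test_per_class,
        }


def _rbf_gamma(features: np.ndarray) -> float:
    """Kernel width 1/(p * median per-feature variance) of the training set."""
    med = float(np.median(features.var(axis=0)))
    if med <= 0:
        return 1.0
    return 1.0 / (features.shape[1] * med)


def train_classifier(features: np.ndarray, labels, penalty: float = 1.0,
                     gamma: float | str = "auto-median") -> SVC:
    """RBF-kernel soft-margin SVM (penalty P weighs slack against margin)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set contains a single class")
    if gamma == "auto-median":
        gamma = _rbf_gamma(features)
    clf = SVC(C=penalty, kernel="rbf", gamma=gamma)
    clf.fit(features, labels)
    return clf


def predict(model: SVC, features: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(features, dtype=float))


class WindowDecoder(ClassifierMixin, BaseEstimator):
    """CSP + RBF-SVM classifier for one band-passed, cropped trial block.

    Operates on raw feature input ``X`` of shape
    ``(n_trials, n_channels, n_samples)`` that has already been band-pass
    filtered and cropped to the subwindow; composing the filtering into the
    estimator would re-filter identically for every CV fold.
    """

    def __init__(self, m: int = 2, penalty: float = 1.0,
                 gamma: float | str = "auto-median"):
        self.m = m
        self.penalty = penalty
        self.gamma = gamma

    def fit(self, X, y):
        y = np.asarray(y)
        self.csp_ = CSP(m=self.m, class_order=CLASS_ORDER
                        if set(np.unique(y)) == set(CLASS_ORDER) else None)
        self.csp_.fit(X, y)
        feats = self.csp_.transform(X)
        self.svm_ = train_classifier(feats, y, penalty=self.penalty,
                                     gamma=self.gamma)
        self.classes_ = self.svm_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.predict(self.csp_.transform(X))


def _balanced_folds(labels: np.ndarray, n_folds: int, seed) -> list[np.ndarray]:
    """Per-class random split into n_folds near-equal folds (seed-determined)."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected 2 classes, got {classes.tolist()}")
    short = counts < n_folds
    if np.any(short):
        raise ValueError(
            "cannot build balanced folds: class counts "
            f"{dict(zip(classes.tolist(), counts.tolist()))} with {n_folds} folds"
        )
    per_class = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        per_class.append(np.array_split(rng.permutation(idx), n_folds))
    return [np.sort(np.concatenate([per_class[0][k], per_class[1][k]]))
            for k in range(n_folds)]


def _cross_validate(data_by_window: list[np.ndarray], labels: np.ndarray,
                    window_tag: str, m: int, n_folds: int, seed,
                    penalty: float, gamma) -> DecodingResult:
    """Shared CV engine: one CSP per window per fold, concatenated features,
    one SVM.  ``data_by_window`` holds pre-filtered, pre-cropped blocks."""
    folds = _balanced_folds(labels, n_folds, seed)
    accs = np.empty(n_folds)
    hits = {POSITIVE_CLASS: 0, NEGATIVE_CLASS: 0}
    totals = {POSITIVE_CLASS: 0, NEGATIVE_CLASS: 0}
    n_test = []
    all_idx = np.arange(labels.size)
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        tr_feats, te_feats = [], []
        for block in data_by_window:
            csp = CSP(m=m, class_order=CLASS_ORDER
                      if set(np.unique(labels)) == set(CLASS_ORDER) else None)
            csp.fit(block[train_idx], labels[train_idx])
            tr_feats.append(csp.transform(block[train_idx]))
            te_feats.append(csp.transform(block[test_idx]))
        Xtr = np.hstack(tr_feats)
        Xte = np.hstack(te_feats)
        clf = train_classifier(Xtr, labels[train_idx], penalty=penalty,
                               gamma=gamma)
        pred = clf.predict(Xte)
        truth = labels[test_idx]
        accs[k] = float(np.mean(pred == truth))
        for c in (POSITIVE_CLASS, NEGATIVE_CLASS):
            mask = truth == c
            hits[c] += int(np.sum(pred[mask] == c))
            totals[c] += int(np.sum(mask))
        n_test.append(test_idx.size / 2.0)
    sens = hits[POSITIVE_CLASS] / totals[POSITIVE_CLASS] if totals[POSITIVE_CLASS] else np.nan
    spec = hits[NEGATIVE_CLASS] / totals[NEGATIVE_CLASS] if totals[NEGATIVE_CLASS] else np.nan
    return DecodingResult(
        per_fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if n_folds > 1 else 0.0,
        sensitivity=float(sens),
        specificity=float(spec),
        window=window_tag,
        n_test_per_class=float(np.mean(n_test)),
    )


def _window_block(epochs: EpochSet, window: tuple[float, float, float, float],
                  fir_order: int) -> np.ndarray:
    t0, t1, f0, f1 = window
    filtered = bandpass_fir(epochs, f0, f1, order=fir_order)
    return crop_time(filtered, t0, t1).data


def _window_tag(window: tuple[float, float, float, float]) -> str:
    t0, t1, f0, f1 = window
    return f"{t0:g}-{t1:g}ms_{f0:g}-{f1:g}Hz"


def decode_subwindow(epochs: EpochSet, window: tuple[float, float, float, float],
                     m: int = 2, n_folds: int = 10, seed=0,
                     penalty: float = 1.0, gamma="auto-median",
                     fir_order: int = 512) -> DecodingResult:
    """Balanced k-fold CV decoding within one time-frequency subwindow.

    Per fold, CSP and SVM are fitted on the nine training folds only and
    evaluated on the held-out fold; folds are drawn per class so every fold
    is class balanced.
    """
    block = _window_block(epochs, window, fir_order)
    return _cross_validate([block], epochs.labels, _window_tag(window),
                           m, n_folds, seed, penalty, gamma)


def decode_combined(epochs: EpochSet, windows, m: int = 2, n_folds: int = 10,
                    seed=0, penalty: float = 1.0, gamma="auto-median",
                    fir_order: int = 512) -> DecodingResult:
    """CV decoding with features concatenated across the selected subwindows.

    Per fold, one CSP per window is fitted on the training folds; the 2m
    features per window are concatenated (e.g. 3 windows x 4 = 12 features)
    and a single SVM is trained on the combined vector.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one selected subwindow")
    blocks = [_window_block(epochs, w, fir_order) for w in windows]
    return _cross_validate(blocks, epochs.labels, "combined", m, n_folds,
                           seed, penalty, gamma)


@dataclass
class AccuracyMap:
    """Group accuracy map: per-subject and group-mean accuracy per subwindow."""

    grid: SubwindowGrid
    per_subject: np.ndarray          # (n_subjects, n_windows)
    results: list = field(repr=False, default_factory=list)

    @property
    def mean(self) -> np.ndarray:
        return self.per_subject.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        if self.per_subject.shape[0] < 2:
            return np.zeros(self.per_subject.shape[1])
        return self.per_subject.std(axis=0, ddof=1)

    def best_window(self) -> tuple[float, float, float, float]:
        return self.grid.windows[int(np.argmax(self.mean))]

    def to_frame(self):
        import pandas as pd

        rows = []
        for j, w in enumerate(self.grid.windows):
            rows.append({
                "t_start_ms": w[0], "t_end_ms": w[1],
                "f_low_hz": w[2], "f_high_hz": w[3],
                "mean_accuracy": self.mean[j], "sd_accuracy": self.sd[j],
                **{f"subject_{i}": self.per_subject[i, j]
                   for i in range(self.per_subject.shape[0])},
            })
        return pd.DataFrame(rows)


def accuracy_map(cohort: list[EpochSet], grid: SubwindowGrid, m: int = 2,
                 n_folds: int = 10, seed=0, penalty: float = 1.0,
                 gamma="auto-median", fir_order: int = 512) -> AccuracyMap:
    """Cross-validated accuracy for every subject and every subwindow.

    Filtering is done once per frequency tile per subject and shared across
    that tile's time windows.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    n_w = len(grid)
    acc = np.empty((len(cohort), n_w))
    results: list[list[DecodingResult]] = []
    freq_of = {}
    for j, w in enumerate(grid.windows):
        freq_of.setdefault((w[2], w[3]), []).append(j)
    for i, epochs in enumerate(cohort):
        subj_seed = np.random.SeedSequence([_seed_int(seed), i])
        subj_results: list[DecodingResult | None] = [None] * n_w
        for (f0, f1), js in freq_of.items():
            filtered = bandpass_fir(epochs, f0, f1, order=fir_order)
            for j in js:
                w = grid.windows[j]
                block = crop_time(filtered, w[0], w[1]).data
                res = _cross_validate([block], epochs.labels, _window_tag(w),
                                      m, n_folds, subj_seed, penalty, gamma)
                acc[i, j] = res.mean_accuracy
                subj_results[j] = res
        results.append(subj_results)
    return AccuracyMap(grid, acc, results)


def _seed_int(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.entropy if np.isscalar(seed.entropy) else seed.entropy[0])
    return int(seed)


def select_subwindows(amap: AccuracyMap, n_sd: float = 2.0,
                      floor: float | None = None) -> list[tuple[float, float, float, float]]:
    """Subwindows whose group-mean accuracy strictly exceeds mean + n_sd * SD
    computed over all subwindows of the map (optionally also an absolute
    floor such as the binomial chance threshold)."""
    means = amap.mean
    thresh = float(means.mean() + n_sd * means.std(ddof=0))
    sel = [w for w, a in zip(amap.grid.windows, means)
           if a > thresh and (floor is None or a > floor)]
    return sel


def chance_threshold(n_test_per_class: int, alpha: float = 0.05) -> float:
    """Accuracy above the upper binomial confidence limit of guessing.

    Smallest k with P(X >= k) < alpha for X ~ Binomial(2n, 1/2), returned as
    a fraction k / (2n).  With 10 test trials per class at alpha = 0.05 this
    is 15/20 = 0.75.  A value above 1 signals that no accuracy reaches
    significance at this test-set size.
    """
    if n_test_per_class < 1:
        raise ValueError("n_test_per_class must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = 2 * int(n_test_per_class)
    # P(X >= k) = sf(k - 1); find smallest such k
    k = np.arange(n + 1)
    tail = stats.binom.sf(k - 1, n, 0.5)
    hit = np.flatnonzero(tail < alpha)
    k_min = int(hit[0]) if hit.size else n + 1
    return k_min / n
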