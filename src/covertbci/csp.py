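"""Common spatial patterns by simultaneous diagonalization.

CSP finds a projection matrix W whose columns w_k simultaneously diagonalize
the two class covariance matrices, W' S1 W = L1 and W' S2 W = L2 with
L1 + L2 = I.  The filters are solutions of the generalized eigenproblem
S1 w = lambda (S1 + S2) w; sorting eigenvalues lambda_1k descending puts the
projection with maximal class-1 variance (and minimal class-2 variance)
first and the converse last, so the first m and last m projections carry the
discriminative variance.  Features are the log of the normalized variances
of the selected projected time series:

    f_p = log( var(Z_p) / sum_i var(Z_i) ),   p = 1..2m,

so that sum_p exp(f_p) = 1 by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .epochs import EpochSet

__all__ = [
    "CSP",
    "class_covariance",
    "fit_csp",
    "apply_and_featurize",
    "pattern_difference",
]


def _trial_covariances(X: np.ndarray, trace_norm: bool) -> np.ndarray:
    # X: (n_trials, n_channels, n_samples)
    cov = np.einsum("tcs,tds->tcd", X, X) / X.shape[-1]
    if trace_norm:
        tr = np.trace(cov, axis1=1, axis2=2)
        if np.any(tr <= 0):
            bad = int(np.flatnonzero(tr <= 0)[0])
            raise ValueError(f"trial {bad} has zero variance; cannot trace-normalize")
        cov = cov / tr[:, None, None]
    return cov


def class_covariance(epochs: EpochSet, label: str, *, trace_norm: bool = True) -> np.ndarray:
    """Average spatial covariance over all single trials of one class.

    Each trial's channel-by-channel covariance is divided by its trace before
    averaging (``trace_norm=True``, the classic convention that removes
    trial-amplitude confounds).
    """
    idx = epochs.class_indices(label)
    if idx.size < 2:
        raise ValueError(f"need >= 2 trials of class {label!r}, found {idx.size}")
    if epochs.n_samples < 2:
        raise ValueError("need >= 2 samples per trial")
    return _trial_covariances(epochs.data[idx], trace_norm).mean(axis=0)


class CSP(TransformerMixin, BaseEstimator):
    """Common-spatial-pattern spatial filtering with log-variance features.

    scikit-learn-compatible transformer over trial blocks of shape
    ``(n_trials, n_channels, n_samples)``.

    Parameters
    ----------
    m : int, default=2
        Projections kept per side; the feature vector has ``2 * m`` entries
        (first ``m`` and last ``m`` filters after the descending eigenvalue
        sort).
    class_order : tuple of 2 labels, or None
        Which label plays class 1 (maximal variance under the first filter).
        ``None`` uses the sorted unique labels.  The decoding pipeline passes
        ``("yes", "no")`` so the last pattern column belongs to "no".
    trace_norm : bool, default=True
        Trace-normalize per-trial covariances before averaging.
    reg : float, default=1e-9
        Tikhonov factor (times mean eigenvalue) added to the composite
        covariance when its condition number exceeds ``cond_threshold``.
    cond_threshold : float, default=1e10
        Condition-number trigger for regularization; narrow-band filtered
        data are near rank-deficient.

    Attributes
    ----------
    filters_ : ndarray (n_channels, n_channels)
        Projection matrix W, one filter per column, eigenvalue-sorted.
    patterns_ : ndarray (n_channels, n_channels)
        Spatial patterns, ``patterns_ @ filters_.T == I``; column k is the
        scalp topography of filter k.
    eigvals_class1_, eigvals_class2_ : ndarray (n_channels,)
        Per-projection variances lambda_1k (descending) and lambda_2k;
        their sum is 1.
    selected_ : ndarray (2 m,)
        Indices of the first m and last m projections.
    """

    def __init__(self, m: int = 2, class_order: tuple[str, str] | None = None,
                 trace_norm: bool = True, reg: float = 1e-9,
                 cond_threshold: float = 1e10):
        self.m = m
        self.class_order = class_order
        self.trace_norm = trace_norm
        self.reg = reg
        self.cond_threshold = cond_threshold

    def fit(self, X: np.ndarray, y) -> "CSP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, n_channels, n_samples)")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"CSP needs exactly 2 classes, got {classes.tolist()}")
        if self.class_order is not None:
            order = tuple(self.class_order)
            if set(order) != set(classes.tolist()):
                raise ValueError(
                    f"class_order {order} does not match labels {classes.tolist()}"
                )
        else:
            order = tuple(classes.tolist())
        covs = []
        for label in order:
            idx = np.flatnonzero(y == label)
            if idx.size < 2:
                raise ValueError(f"need >= 2 trials of class {label!r}")
            covs.append(_trial_covariances(X[idx], self.trace_norm).mean(axis=0))
        self.classes_ = np.asarray(order)
        self._fit_from_covariances(covs[0], covs[1], X.shape[1])
        return self

    def _fit_from_covariances(self, sigma1: np.ndarray, sigma2: np.ndarray,
                              n_channels: int) -> None:
        if 2 * self.m > n_channels:
            raise ValueError(f"2*m = {2 * self.m} exceeds {n_channels} channels")
        sigma1 = np.asarray(sigma1, dtype=float)
        sigma2 = np.asarray(sigma2, dtype=float)
        if sigma1.shape != sigma2.shape or sigma1.shape != (n_channels, n_channels):
            raise ValueError("covariance matrices must both be C x C")
        comp = sigma1 + sigma2
        cond = np.linalg.cond(comp)
        if cond > self.cond_threshold:
            comp = comp + self.reg * (np.trace(comp) / n_channels) * np.eye(n_channels)
            if np.linalg.cond(comp) > 1e15:
                raise np.linalg.LinAlgError(
                    f"composite covariance is singular (condition number {cond:.3g})"
                )
        # Generalized symmetric eigenproblem S1 w = lambda (S1+S2) w; eigh
        # returns eigenvalues ascending with w' (S1+S2) w = 1.
        lam, W = linalg.eigh(sigma1, comp)
        order = np.argsort(-lam, kind="stable")
        lam, W = np.clip(lam[order], 0.0, 1.0), W[:, order]
        patterns = np.linalg.inv(W.T)  # mixing matrix: patterns @ W.T = I
        # Sign convention: largest-|entry| of each pattern column positive.
        flip = np.where(
            patterns[np.argmax(np.abs(patterns), axis=0), np.arange(n_channels)] < 0,
            -1.0, 1.0,
        )
        self.filters_ = W * flip
        self.patterns_ = patterns * flip
        self.eigvals_class1_ = lam
        self.eigvals_class2_ = 1.0 - lam
        self.selected_ = np.concatenate(
            [np.arange(self.m), np.arange(n_channels - self.m, n_channels)]
        )

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project trials and return the 2m log-normalized-variance features."""
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.filters_.shape[0]:
            raise ValueError(
                f"X must be (n_trials, {self.filters_.shape[0]}, n_samples)"
            )
        W_sel = self.filters_[:, self.selected_]
        Z = np.einsum("ck,tcs->tks", W_sel, X)
        var = Z.var(axis=-1)
        total = var.sum(axis=-1)
        if np.any(total <= 0):
            bad = int(np.flatnonzero(total <= 0)[0])
            raise ValueError(f"trial {bad} has zero projected variance")
        return np.log(var / total[:, None])

    def pattern_difference(self) -> np.ndarray:
        """Last minus first spatial-pattern column (class-2 minus class-1
        topography), the scalp map contrasting the two extreme projections."""
        check_is_fitted(self, "patterns_")
        return self.patterns_[:, -1] - self.patterns_[:, 0]


def fit_csp(sigma1: np.ndarray, sigma2: np.ndarray, m: int = 2, **kwargs) -> CSP:
    """Fit a :class:`CSP` model directly from two class covariance matrices."""
    model = CSP(m=m, **kwargs)
    sigma1 = np.asarray(sigma1, dtype=float)
    model._fit_from_covariances(sigma1, np.asarray(sigma2, dtype=float),
                                sigma1.shape[0])
    return model


def apply_and_featurize(model: CSP, epochs: EpochSet) -> np.ndarray:
    """Per-trial log-variance features (n_trials, 2m) for an EpochSet."""
    return model.transform(epochs.data)


def pattern_difference(model: CSP) -> np.ndarray:
    """Functional alias for :meth:`CSP.pattern_difference`."""
    return model.pattern_difference()
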