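"""PCA/LDA recognition models with outlier rejection, and their evaluation.

The classifier mirrors the model-building stage of the single-cell workflow:

1. mean-center the library rows and reduce by PCA, keeping the smallest
   number of components whose cumulative explained variance reaches
   ``variance_kept`` (default 95%, capped at rows − 1);
2. fit multiclass Fisher LDA in PCA space — directions maximize between-class
   relative to pooled within-class scatter and are scaled to unit pooled
   within-class variance;
3. classify a spectrum by the nearest class centroid (Euclidean distance) in
   discriminant space. In *outlier* mode a spectrum farther than
   ``multiplier × dispersion`` (default multiplier 3) from its winning
   centroid is left unassigned (``OUTLIER``); *force* mode always assigns
   the nearest class.

A class's dispersion is the root-mean-square distance of its training points
from its centroid, i.e. the square root of the summed per-direction
variances — a scalar "standard deviation" of the class cloud. (Comparing the
full Euclidean distance against a single per-direction SD instead would flag
most of the training data itself once the discriminant space has more than a
few directions.) A small floor keyed to the centroid scale keeps the rule
meaningful for noiseless, perfectly duplicated training classes.

Evaluation follows the study design: stratified fivefold cross-validation and
a per-class 2/3–1/3 train/validation holdout, each reporting the
classification rate excluding outliers (correct / non-outlier) and including
outliers (correct / all, outliers counted as errors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.model_selection import StratifiedKFold

from .library_builder import SpectralLibrary
from .preprocess import BinGrid, FeatureVector

OUTLIER = "OUTLIER"

__all__ = ["OUTLIER", "RecognitionModel", "CVReport", "fit_model", "classify",
           "crossval", "holdout_validate"]


@dataclass
class RecognitionModel:
    """A deployable PCA/LDA classifier with per-class outlier thresholds."""

    grid: BinGrid
    level: str
    mean_: np.ndarray                 # (bins,)
    components_: np.ndarray           # (k, bins) orthonormal PCA basis
    explained_variance_ratio_: np.ndarray
    scalings_: np.ndarray             # (k, d) PCA space -> LDA space
    class_labels: list[str]
    centroids_: np.ndarray            # (C, d)
    dispersions_: np.ndarray          # (C,) scalar SD per class
    outlier_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.outlier_multiplier <= 0:
            raise ValueError("outlier multiplier must be positive")
        if np.any(self.dispersions_ <= 0):
            raise ValueError("class dispersions must be positive")

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]

    @property
    def n_discriminants(self) -> int:
        return self.scalings_.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        """Map binned spectra (n × bins) into discriminant space (n × d)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.grid.n_bins:
            raise ValueError(
                f"vector length {X.shape[1]} does not match model grid "
                f"({self.grid.n_bins} bins)"
            )
        return (X - self.mean_) @ self.components_.T @ self.scalings_

    def to_mapping(self) -> dict:
        return {
            "grid": {"lo": self.grid.lo, "hi": self.grid.hi, "width": self.grid.width},
            "level": self.level,
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "scalings": self.scalings_.tolist(),
            "class_labels": list(self.class_labels),
            "centroids": self.centroids_.tolist(),
            "dispersions": self.dispersions_.tolist(),
            "outlier_multiplier": self.outlier_multiplier,
        }

    @classmethod
    def from_mapping(cls, m: dict) -> "RecognitionModel":
        return cls(
            grid=BinGrid(**m["grid"]),
            level=m["level"],
            mean_=np.array(m["mean"]),
            components_=np.array(m["components"]),
            explained_variance_ratio_=np.array(m["explained_variance_ratio"]),
            scalings_=np.array(m["scalings"]),
            class_labels=list(m["class_labels"]),
            centroids_=np.array(m["centroids"]),
            dispersions_=np.array(m["dispersions"]),
            outlier_multiplier=float(m["outlier_multiplier"]),
        )


def fit_model(
    library: SpectralLibrary,
    level: str = "cell_line",
    variance_kept: float = 0.95,
    outlier_multiplier: float = 3.0,
    seed: int = 0,
) -> RecognitionModel:
    """Fit the PCA/LDA recognition model on a spectral library.

    Requires at least two classes at the chosen label level and at least two
    rows per class. ``seed`` is accepted for interface symmetry; the fit
    itself is deterministic.
    """
    y = library.labels(level).astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes at level {level!r}, got {len(classes)}")
    for cls in classes:
        if np.sum(y == cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 library rows")
    X = library.X
    n = X.shape[0]

    mean = X.mean(axis=0)
    Xc = X - mean
    # PCA by thin SVD; components capped at n-1 (centering removes one df)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    max_k = max(1, min(n - 1, Vt.shape[0]))
    cum = np.cumsum(evr[:max_k])
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, max_k)
    components = Vt[:k]
    T = Xc @ components.T  # PCA scores, n × k

    # Fisher LDA: generalized eigenproblem Sb w = λ Sw w in PCA space
    C = len(classes)
    means = np.vstack([T[y == cls].mean(axis=0) for cls in classes])
    counts = np.array([np.sum(y == cls) for cls in classes])
    grand = T.mean(axis=0)
    Sw = np.zeros((k, k))
    for ci, cls in enumerate(classes):
        D = T[y == cls] - means[ci]
        Sw += D.T @ D
    Sb = (counts[:, None] * (means - grand)).T @ (means - grand)

    ridge = 0.0
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        ridge = 1e-8 * max(np.trace(Sw) / k, 1.0)
        warnings.warn(
            "pooled within-class scatter is singular; adding a small ridge",
            stacklevel=2,
        )
        evals, evecs = scipy.linalg.eigh(Sb, Sw + ridge * np.eye(k))
    order = np.argsort(evals)[::-1]
    d = min(C - 1, k)
    W = evecs[:, order[:d]]
    # eigh returns Sw-orthonormal vectors (w' Sw w = 1); rescale so pooled
    # within-class variance per direction is 1
    W = W * np.sqrt(max(n - C, 1))
    # deterministic sign convention
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    W = W * signs

    Y = T @ W
    cmeans = np.vstack([Y[y == cls].mean(axis=0) for cls in classes])
    dispersions = np.empty(C)
    for ci, cls in enumerate(classes):
        dist2 = np.sum((Y[y == cls] - cmeans[ci]) ** 2, axis=1)
        disp = float(np.sqrt(dist2.mean()))
        # floor: keeps degenerate (duplicated-row) classes classifiable
        dispersions[ci] = max(disp, 1e-6 * (1.0 + np.linalg.norm(cmeans[ci])))

    return RecognitionModel(
        grid=library.grid,
        level=level,
        mean_=mean,
        components_=components,
        explained_variance_ratio_=evr,
        scalings_=W,
        class_labels=classes,
        centroids_=cmeans,
        dispersions_=dispersions,
        outlier_multiplier=outlier_multiplier,
    )


def _classify_matrix(
    model: RecognitionModel, X: np.ndarray, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus per-class distances for a stack of binned spectra."""
    if mode not in ("force", "outlier"):
        raise ValueError(f"mode must be 'force' or 'outlier', got {mode!r}")
    Y = model.project(X)
    diff = Y[:, None, :] - model.centroids_[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))  # n × C
    win = np.argmin(dist, axis=1)  # ties -> lowest index = lexicographically first
    labels = np.array([model.class_labels[w] for w in win], dtype=object)
    if mode == "outlier":
        thresh = model.outlier_multiplier * model.dispersions_[win]
        labels[dist[np.arange(len(win)), win] > thresh] = OUTLIER
    return labels, dist


def classify(
    model: RecognitionModel,
    vector: FeatureVector | np.ndarray,
    mode: str = "outlier",
) -> tuple[str, dict[str, float]]:
    """Classify one binned spectrum; returns (label, distance per class).

    In outlier mode the label is ``OUTLIER`` when the distance to the winning
    centroid exceeds ``multiplier × dispersion`` of that class; force mode
    always returns the nearest class.
    """
    if isinstance(vector, FeatureVector):
        if vector.grid != model.grid:
            raise ValueError("feature vector grid does not match model grid")
        x = vector.values
    else:
        x = np.asarray(vector, dtype=float)
    labels, dist = _classify_matrix(model, x[None, :], mode)
    return str(labels[0]), dict(zip(model.class_labels, dist[0]))


@dataclass
class CVReport:
    """Predictions and summary rates from cross-validation or holdout."""

    level: str
    fold_assignments: np.ndarray
    truth: np.ndarray
    predicted: np.ndarray
    confusion: pd.DataFrame = field(repr=False)
    rate_excluding_outliers: float = 0.0
    rate_including_outliers: float = 0.0

    @staticmethod
    def from_predictions(
        level: str, folds: np.ndarray, truth: np.ndarray, predicted: np.ndarray
    ) -> "CVReport":
        truth = np.asarray(truth, dtype=object)
        predicted = np.asarray(predicted, dtype=object)
        classes = sorted(set(truth))
        pred_labels = classes + [OUTLIER]
        conf = pd.DataFrame(0, index=classes, columns=pred_labels, dtype=int)
        for t, p in zip(truth, predicted):
            conf.loc[t, p] += 1
        correct = int(np.sum(truth == predicted))
        n = len(truth)
        n_out = int(np.sum(predicted == OUTLIER))
        excl = 100.0 * correct / (n - n_out) if n > n_out else float("nan")
        incl = 100.0 * correct / n if n else float("nan")
        return CVReport(
            level=level,
            fold_assignments=np.asarray(folds),
            truth=truth,
            predicted=predicted,
            confusion=conf,
            rate_excluding_outliers=excl,
            rate_including_outliers=incl,
        )

    def summary(self) -> str:
        n = len(self.truth)
        n_out = int(np.sum(self.predicted == OUTLIER))
        return (
            f"{self.level} model: {n} spectra, {n_out} flagged OUTLIER\n"
            f"  classification rate excluding outliers: "
            f"{self.rate_excluding_outliers:.2f}%\n"
            f"  classification rate including outliers: "
            f"{self.rate_including_outliers:.2f}%"
        )


def crossval(
    library: SpectralLibrary,
    level: str = "cell_line",
    k: int = 5,
    variance_kept: float = 0.95,
    outlier_multiplier: float = 3.0,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of the PCA/LDA model.

    Each fold holds out ~1/k of every class; the model is refit on the rest
    and the held-out spectra classified in outlier mode.
    """
    y = library.labels(level).astype(str)
    counts = pd.Series(y).value_counts()
    small = counts[counts < k]
    if len(small):
        raise ValueError(
            f"every class needs >= {k} rows for {k}-fold CV; too small: "
            f"{', '.join(small.index)}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    predicted = np.empty(len(y), dtype=object)
    for fold_no, (train_idx, test_idx) in enumerate(skf.split(library.X, y)):
        folds[test_idx] = fold_no
        model = fit_model(
            library.subset(train_idx),
            level=level,
            variance_kept=variance_kept,
            outlier_multiplier=outlier_multiplier,
        )
        labels, _ = _classify_matrix(model, library.X[test_idx], mode="outlier")
        predicted[test_idx] = labels
    return CVReport.from_predictions(level, folds, y, predicted)


def holdout_validate(
    library: SpectralLibrary,
    level: str = "cell_line",
    train_fraction: float = 2.0 / 3.0,
    variance_kept: float = 0.95,
    outlier_multiplier: float = 3.0,
    seed: int = 0,
) -> CVReport:
    """Per-class stratified train/validation split (default two-thirds train).

    Train size per class is ``round(train_fraction × class size)``, at least
    2 and at most size − 1; the validation spectra are classified in outlier
    mode.
    """
    y = library.labels(level).astype(str)
    counts = pd.Series(y).value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(
            f"every class needs >= 3 rows for a holdout split; too small: "
            f"{', '.join(small.index)}"
        )
    rng = np.random.default_rng(seed)
    train_mask = np.zeros(len(y), dtype=bool)
    for cls in sorted(set(y)):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 2), len(idx) - 1)
        train_mask[idx[:n_train]] = True
    model = fit_model(
        library.subset(np.where(train_mask)[0]),
        level=level,
        variance_kept=variance_kept,
        outlier_multiplier=outlier_multiplier,
    )
    val_idx = np.where(~train_mask)[0]
    labels, _ = _classify_matrix(model, library.X[val_idx], mode="outlier")
    folds = np.where(train_mask, -1, 0)
    return CVReport.from_predictions(level, folds[val_idx], y[val_idx], labels)
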