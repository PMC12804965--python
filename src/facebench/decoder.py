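"""Linear-readout model observer.

A "model observer" for the 2AFC categorization task is built by training
L2-regularized hinge-loss linear classifiers (linear SVMs) on per-image
feature vectors (e.g. penultimate-layer activations of a vision network,
2048 units per image).  Training images are resampled many times; test
accuracy is summarized over resamples, and the signed distance of each test
image to the learned hyperplane provides a per-image confidence that plays
the role of a behavioral per-image d' vector.

The module consumes plain feature matrices; it neither ships nor requires
any network weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC


@dataclass
class FeatureSet:
    """Per-image feature vectors with category labels.

    Attributes
    ----------
    image_ids : array of str, one per row of ``features``.
    labels : array of str, the category of each image.
    features : float matrix, shape (n_images, dim).
    metadata : free-form provenance (e.g. the Bayes-optimal accuracy of a
        synthetic cloud pair).
    """

    image_ids: np.ndarray
    labels: np.ndarray
    features: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image_ids = np.asarray(self.image_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if len(self.image_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"row mismatch: {n} feature rows, {len(self.image_ids)} ids, "
                f"{len(self.labels)} labels"
            )

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, mask: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            self.image_ids[mask], self.labels[mask], self.features[mask],
            dict(self.metadata),
        )


@dataclass
class DecoderResult:
    """Outcome of a resampled linear readout.

    ``per_image_margin`` holds, for every test image, the mean signed
    distance to the hyperplane across resamples, oriented so that positive
    means the classifier placed the image on its correct side.  ``margins``
    keeps the full (n_resamples, n_test) matrix so that per-resample
    accuracy can be recomputed exactly from margin signs.
    """

    n_train_per_class: int
    accuracy_mean: float
    accuracy_sd: float
    n_resamples: int
    per_image_margin: np.ndarray
    per_resample_accuracy: np.ndarray
    margins: np.ndarray
    image_ids: np.ndarray
    labels: np.ndarray
    classes: tuple
    C: float
    seed: int

    def summary(self) -> dict:
        return {
            "n_train_per_class": self.n_train_per_class,
            "accuracy_mean": float(self.accuracy_mean),
            "accuracy_sd": float(self.accuracy_sd),
            "n_resamples": self.n_resamples,
            "C": self.C,
            "seed": self.seed,
        }


@dataclass
class LearningCurve:
    results: list
    n_train_grid: list
    saturation_n: int
    saturation_tol: float

    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy_mean for r in self.results])


def _signed_labels(labels: np.ndarray, classes: tuple) -> np.ndarray:
    # decision_function > 0 predicts classes[1]; align +1 with each image's
    # own class so that positive margin == correct classification
    return np.where(np.asarray(labels, dtype=object) == classes[1], 1.0, -1.0)


def train_readout(
    train: FeatureSet,
    test: FeatureSet,
    n_train_per_class: int,
    n_resamples: int = 100,
    C: float = 1.0,
    seed: int = 0,
) -> DecoderResult:
    """Train resampled linear SVMs and score them on a held-out image set.

    Each resample draws ``n_train_per_class`` images per class without
    replacement from ``train``, standardizes features with training-fold
    statistics only, fits a hinge-loss, L2-regularized linear classifier,
    and records oriented test margins.  Accuracy is the fraction of test
    images with positive oriented margin, so the margin-sign fraction and
    the reported per-resample accuracy agree exactly by construction.
    """
    if train.dim != test.dim:
        raise ValueError(f"feature dim mismatch: train {train.dim}, test {test.dim}")
    overlap = set(train.image_ids) & set(test.image_ids)
    if overlap:
        raise ValueError(f"train/test image sets overlap: {sorted(overlap)[:5]} ...")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    classes = tuple(train.classes)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if not set(test.labels) <= set(classes):
        raise ValueError("test labels contain classes absent from training set")

    class_idx = {c: np.flatnonzero(train.labels == c) for c in classes}
    for c, idx in class_idx.items():
        if len(idx) < n_train_per_class:
            raise ValueError(
                f"class {c!r} has {len(idx)} training images, "
                f"need {n_train_per_class}"
            )

    y_signed = _signed_labels(test.labels, classes)
    y_train_all = np.where(train.labels == classes[1], 1, -1)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_test = len(test.labels)
    margins = np.empty((n_resamples, n_test))
    acc = np.empty(n_resamples)
    for r in range(n_resamples):
        sel = np.concatenate(
            [rng.choice(class_idx[c], n_train_per_class, replace=False) for c in classes]
        )
        X = train.features[sel]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        clf = LinearSVC(
            C=C, loss="hinge", penalty="l2", max_iter=20000, tol=1e-3,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            # near-optimal dual solutions are fine for accuracy/margins;
            # don't spam one warning per resample
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit((X - mu) / sd, y_train_all[sel])
        decision = clf.decision_function((test.features - mu) / sd)
        margins[r] = decision * y_signed
        acc[r] = float(np.mean(margins[r] > 0))

    return DecoderResult(
        n_train_per_class=n_train_per_class,
        accuracy_mean=float(acc.mean()),
        accuracy_sd=float(acc.std()),
        n_resamples=n_resamples,
        per_image_margin=margins.mean(axis=0),
        per_resample_accuracy=acc,
        margins=margins,
        image_ids=test.image_ids.copy(),
        labels=test.labels.copy(),
        classes=classes,
        C=C,
        seed=seed,
    )


def margin_i1(
    result: DecoderResult,
    labels: np.ndarray | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-image margin vector of a decoder, formatted like a behavioral i1.

    Values are mean oriented distances to the hyperplane (larger = more
    confidently correct).  They are *not* unit-calibrated: scaling all
    features scales the distances.  With ``normalize=True`` the per-category
    mean is subtracted, giving a model i1n directly comparable to a
    behavioral i1n.
    """
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        if len(labels) != len(result.labels) or not np.array_equal(labels, result.labels):
            raise ValueError("labels do not match the decoder's test labels")
    df = pd.DataFrame(
        {
            "image_id": result.image_ids,
            "category": result.labels,
            "margin": result.per_image_margin,
        }
    )
    if normalize:
        df["margin"] = df["margin"] - df.groupby("category")["margin"].transform("mean")
    return df


def learning_curve(
    train: FeatureSet,
    test: FeatureSet,
    n_train_grid: list[int],
    n_resamples: int = 50,
    C: float = 1.0,
    seed: int = 0,
    saturation_tol: float = 0.005,
) -> LearningCurve:
    """Readout accuracy as a function of training-set size.

    Returns one :class:`DecoderResult` per grid value plus the saturation
    point: the smallest n whose mean accuracy is within ``saturation_tol``
    of the maximum over the grid.
    """
    grid = [int(n) for n in n_train_grid]
    if not grid:
        raise ValueError("n_train_grid is empty")
    children = np.random.SeedSequence(seed).spawn(len(grid))
    results = [
        train_readout(
            train, test, n, n_resamples=n_resamples, C=C,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        for n, child in zip(grid, children)
    ]
    accs = np.array([r.accuracy_mean for r in results])
    best = accs.max()
    eligible = [n for n, a in zip(grid, accs) if a >= best - saturation_tol]
    return LearningCurve(
        results=results,
        n_train_grid=grid,
        saturation_n=min(eligible),
        saturation_tol=saturation_tol,
    )
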