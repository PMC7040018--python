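"""PCA -> two-axis LDA discriminator with a centroid distance-ratio rule.

The feature vectors (2444 angular log-power-spectrum values per sample)
are first reduced by PCA, keeping half of the available scores; a two-class
linear discriminant analysis is then solved in score space as the
generalised eigenproblem of between-class vs (ridge-regularised)
within-class scatter.  Samples are projected onto the two leading
discriminant directions (LD_S1, LD_S2) and classified by the ratio of
Euclidean distances to the two training-class centroids: ratio < 1 assigns
the first class, with ties going to the first class by convention.

For two classes the between-class scatter has rank one, so only one
canonical discriminant direction exists; the second axis used here is the
eigenvector with the second-largest eigenvalue of the same regularised
problem — the leading direction of residual within-class structure — with
a deterministic sign convention (largest-magnitude coordinate positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PCAModel",
    "DiscriminantModel",
    "ClassificationReport",
    "fit_pca",
    "fit_lda",
    "classify",
    "ld_function_map",
    "centroid_trajectory",
    "PCALDAClassifier",
]

#: relative ridge on the within-class scatter
LDA_RIDGE = 1e-6


@dataclass
class PCAModel:
    """Fitted PCA basis: mean, orthonormal loadings, kept-score count."""

    mean: np.ndarray  # (n_features,)
    components: np.ndarray  # (n_components, n_features), descending variance
    explained_variance: np.ndarray
    n_keep: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project onto the retained components."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.components[: self.n_keep].T


@dataclass
class DiscriminantModel:
    """Two LD directions in PC-score space plus training centroids."""

    directions: np.ndarray  # (2, n_keep), unit rows: LD_S1, LD_S2
    centroids: np.ndarray  # (2, 2): per class, in (LD_S1, LD_S2)
    classes: np.ndarray  # the two class labels, centroid order
    eigenvalues: np.ndarray
    training_projections: np.ndarray  # (n_train, 2)

    def project(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(scores, dtype=float)) @ self.directions.T


@dataclass
class ClassificationReport:
    """Per-sample distance-ratio decisions and the aggregate error rate."""

    predictions: np.ndarray
    distance_ratio: np.ndarray  # d(first class) / d(second class)
    projections: np.ndarray  # (n, 2) LD coordinates
    ties: np.ndarray  # boolean, ratio exactly 1 (assigned first class)
    error_rate: float | None = None  # percent, if truth supplied
    misclassified: np.ndarray | None = None  # indices, if truth supplied


def fit_pca(X: np.ndarray, n_keep: int | None = None) -> PCAModel:
    """PCA via SVD of the column-centred sample matrix.

    At most n_samples - 1 non-trivial components exist; by default half of
    them (floor((n_samples - 1)/2)) are retained for the discriminant step.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for PCA")
    if np.allclose(X, X[0]):
        raise ValueError("all samples identical: PCA undefined")
    n_comp = min(n - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(X)
    if n_keep is None:
        # half of the available scores, but never fewer than the 2 the
        # two-axis discriminant needs (relevant only for tiny training sets)
        n_keep = max(2, (n - 1) // 2)
    n_keep = min(n_keep, n_comp)
    return PCAModel(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        n_keep=int(n_keep),
    )


def _scatter_matrices(scores: np.ndarray, y: np.ndarray, classes: np.ndarray):
    overall = scores.mean(axis=0)
    d = scores.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = scores[y == c]
        mc = Xc.mean(axis=0)
        dev = Xc - mc
        Sw += dev.T @ dev
        dm = (mc - overall)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    return Sb, Sw


def fit_lda(
    scores: np.ndarray, labels: np.ndarray, ridge: float = LDA_RIDGE
) -> DiscriminantModel:
    """Two-axis LDA in PC-score space by a regularised generalised eigensolve.

    Solves Sb v = lambda (Sw + ridge*trace(Sw)/d * I) v; LD_S1 is the
    leading eigenvector, LD_S2 the next.  Rows are unit-normalised with the
    largest-magnitude coordinate made positive, so fits are deterministic.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    d = scores.shape[1]
    if d < 2:
        raise ValueError("need at least 2 retained PCA scores for a 2-axis LDA")
    Sb, Sw = _scatter_matrices(scores, labels, classes)
    lam = ridge * np.trace(Sw) / d
    if lam == 0:
        lam = ridge  # all-identical within classes: absolute fallback ridge
    Sw_reg = Sw + lam * np.eye(d)
    try:
        eigvals, eigvecs = linalg.eigh(Sb, Sw_reg)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("within-class scatter singular after regularisation") from exc
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    W = eigvecs[:, :2].T.copy()
    for i in range(2):
        W[i] /= np.linalg.norm(W[i])
        j = np.argmax(np.abs(W[i]))
        if W[i, j] < 0:
            W[i] = -W[i]
    proj = scores @ W.T
    centroids = np.stack([proj[labels == c].mean(axis=0) for c in classes])
    return DiscriminantModel(
        directions=W,
        centroids=centroids,
        classes=classes,
        eigenvalues=eigvals[:2],
        training_projections=proj,
    )


def classify(
    model: DiscriminantModel,
    scores: np.ndarray,
    truth: np.ndarray | None = None,
) -> ClassificationReport:
    """Distance-ratio decisions: predict the first class iff d1/d2 < 1.

    Ties (ratio exactly 1) are assigned to the first class by convention
    and flagged in the report.
    """
    proj = model.project(scores)
    d1 = np.linalg.norm(proj - model.centroids[0], axis=1)
    d2 = np.linalg.norm(proj - model.centroids[1], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d2 > 0, d1 / np.where(d2 > 0, d2, 1.0), np.inf)
    ratio = np.where((d1 == 0) & (d2 == 0), 1.0, ratio)
    pred = np.where(ratio <= 1.0, model.classes[0], model.classes[1])
    ties = ratio == 1.0
    report = ClassificationReport(
        predictions=pred, distance_ratio=ratio, projections=proj, ties=ties
    )
    if truth is not None:
        truth = np.asarray(truth)
        wrong = np.nonzero(pred != truth)[0]
        report.misclassified = wrong
        report.error_rate = 100.0 * wrong.size / truth.size
    return report


def ld_function_map(
    pca: PCAModel, model: DiscriminantModel, shape: tuple[int, int] = (47, 52)
) -> tuple[np.ndarray, np.ndarray]:
    """Back-project the LD directions into feature space as radius x frequency maps.

    Each map shows, per (radial bin, angular frequency in cycles per
    revolution), how strongly that cell contributes to the discriminant
    axis — the fingerprint used to read off where the discriminating
    texture lives within the droplet.
    """
    basis = pca.components[: pca.n_keep]
    if model.directions.shape[1] != basis.shape[0]:
        raise ValueError("LD directions and retained PCA basis disagree in size")
    flat = model.directions @ basis  # (2, n_features)
    if flat.shape[1] != shape[0] * shape[1]:
        raise ValueError(f"cannot reshape {flat.shape[1]} features to {shape}")
    return flat[0].reshape(shape), flat[1].reshape(shape)


def centroid_trajectory(
    projections: np.ndarray,
    conditions: np.ndarray,
    order: list | None = None,
) -> np.ndarray:
    """Per-condition centroids in (LD_S1, LD_S2), in the given condition order."""
    projections = np.atleast_2d(np.asarray(projections, dtype=float))
    conditions = np.asarray(conditions)
    if order is None:
        order = list(dict.fromkeys(conditions.tolist()))
    cents = []
    for c in order:
        sel = conditions == c
        if not sel.any():
            raise ValueError(f"condition {c!r} has no samples")
        cents.append(projections[sel].mean(axis=0))
    return np.stack(cents)


class PCALDAClassifier(BaseEstimator, ClassifierMixin):
    """Two-class PCA+LDA discriminator with the centroid distance-ratio rule.

    Parameters
    ----------
    n_keep : number of PCA scores kept for the LDA, or None for the default
        rule floor((n_samples - 1)/2) ("half of the largest scores").
    ridge : relative ridge added to the within-class scatter.

    Attributes
    ----------
    pca_ : fitted :class:`PCAModel`.
    lda_ : fitted :class:`DiscriminantModel`.
    classes_ : the two class labels (centroid order).
    """

    def __init__(self, n_keep: int | None = None, ridge: float = LDA_RIDGE) -> None:
        self.n_keep = n_keep
        self.ridge = ridge

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.pca_ = fit_pca(X, n_keep=self.n_keep)
        scores = self.pca_.transform(X)
        self.lda_ = fit_lda(scores, y, ridge=self.ridge)
        self.classes_ = self.lda_.classes
        return self

    def transform(self, X) -> np.ndarray:
        """Project samples into the 2-D (LD_S1, LD_S2) space."""
        check_is_fitted(self, "lda_")
        return self.lda_.project(self.pca_.transform(X))

    def report(self, X, y=None) -> ClassificationReport:
        check_is_fitted(self, "lda_")
        return classify(self.lda_, self.pca_.transform(X), truth=y)

    def predict(self, X):
        return self.report(X).predictions

    def decision_ratio(self, X) -> np.ndarray:
        """d(class 0) / d(class 1); < 1 means the first class."""
        return self.report(X).distance_ratio

    def error_rate(self, X, y) -> float:
        """Percentage of misclassified samples."""
        return float(self.report(X, np.asarray(y)).error_rate)

    def ld_maps(self, shape: tuple[int, int] = (47, 52)):
        check_is_fitted(self, "lda_")
        return ld_function_map(self.pca_, self.lda_, shape=shape)
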