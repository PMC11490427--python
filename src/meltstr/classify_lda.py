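"""Linear discriminant analysis on peak-feature vectors, from its defining equations.

LDA models every class as a Gaussian with its own mean and one shared
(pooled within-class) covariance.  For class c with mean mu_c, pooled
covariance S and prior pi_c, the discriminant is

    delta_c(x) = x' S^-1 mu_c - 1/2 mu_c' S^-1 mu_c + ln pi_c

and a sample is assigned to the class with the largest delta_c.  Because
the quadratic term -1/2 x' S^-1 x is common to all classes, posteriors
are exactly softmax(delta(x)).

The pooled covariance is the within-class scatter divided by n - C.  A
relative ridge ``lambda * diag(s)`` is added before inversion: constant
feature columns (the pad temperature, 64.95 °C, is the same for every
padded sample) make the scatter singular.  For columns whose scatter
diagonal is exactly zero the ridge scale falls back to the mean positive
diagonal, so the stabilization is effective precisely in the degenerate
case that motivates it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .melt_io import ContractError

__all__ = ["LDAModel", "fit_lda", "predict_lda", "predict_lda_batch"]


@dataclass
class LDAModel:
    """Trained LDA state: class means, pooled covariance, priors."""

    class_labels: list[str]
    class_means: np.ndarray  # (C, d)
    pooled_covariance: np.ndarray  # (d, d), ridge-stabilized
    priors: np.ndarray  # (C,)
    ridge: float
    feature_dim: int

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        self.pooled_covariance = np.asarray(self.pooled_covariance, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        C = len(self.class_labels)
        if self.class_means.shape != (C, self.feature_dim):
            raise ContractError("class_means shape inconsistent with labels/feature_dim")
        if not np.allclose(self.pooled_covariance, self.pooled_covariance.T, atol=1e-10):
            raise ContractError("pooled covariance must be symmetric")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ContractError("priors must sum to 1")

    # -- discriminants ---------------------------------------------------
    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """delta_c(x) for each row of X; shape (n, C)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_dim:
            raise ContractError(
                f"feature dimension {X.shape[1]} does not match model ({self.feature_dim})"
            )
        Sinv_mu = scipy.linalg.solve(self.pooled_covariance, self.class_means.T, assume_a="pos")
        lin = X @ Sinv_mu  # (n, C)
        const = -0.5 * np.sum(self.class_means.T * Sinv_mu, axis=0) + np.log(self.priors)
        return lin + const

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_labels": self.class_labels,
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
            "ridge": self.ridge,
            "feature_dim": self.feature_dim,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "LDAModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            class_labels=list(d["class_labels"]),
            class_means=np.array(d["class_means"], dtype=float),
            pooled_covariance=np.array(d["pooled_covariance"], dtype=float),
            priors=np.array(d["priors"], dtype=float),
            ridge=float(d["ridge"]),
            feature_dim=int(d["feature_dim"]),
        )


def _as_matrix(features) -> np.ndarray:
    """Accept FeatureVector sequences or plain arrays."""
    if hasattr(features, "ndim"):
        return np.atleast_2d(np.asarray(features, dtype=float))
    rows = [f.values if hasattr(f, "values") and not isinstance(f, np.ndarray) else f for f in features]
    return np.atleast_2d(np.asarray(rows, dtype=float))


def fit_lda(
    features,
    labels: Sequence[str],
    priors: str = "uniform",
    ridge: float = 1e-6,
) -> LDAModel:
    """Fit class means and pooled within-class covariance.

    ``features`` is a sequence of FeatureVectors or an (n, d) array;
    ``labels`` the known class labels.  ``priors`` is ``uniform``
    (matching a benchmark against the 1-in-C chance rate) or
    ``empirical`` (class frequencies).  ``ridge`` is the relative
    diagonal stabilizer; every class needs >= 2 samples and n > C.
    """
    X = _as_matrix(features)
    labels = [str(l) for l in labels]
    if len(labels) != X.shape[0]:
        raise ContractError("features and labels length mismatch")
    class_labels = sorted(set(labels))
    C = len(class_labels)
    n, d = X.shape
    if C < 2:
        raise ContractError("LDA needs at least 2 classes")
    if n <= C:
        raise ContractError(f"need more samples ({n}) than classes ({C})")
    if priors not in ("uniform", "empirical"):
        raise ContractError(f"priors must be 'uniform' or 'empirical', got {priors!r}")

    means = np.zeros((C, d))
    scatter = np.zeros((d, d))
    counts = np.zeros(C)
    idx = {c: i for i, c in enumerate(class_labels)}
    for c in class_labels:
        rows = X[[i for i, l in enumerate(labels) if l == c]]
        if rows.shape[0] < 2:
            raise ContractError(f"class {c!r} has fewer than 2 training samples")
        mu = rows.mean(axis=0)
        means[idx[c]] = mu
        centered = rows - mu
        scatter += centered.T @ centered
        counts[idx[c]] = rows.shape[0]
    Sw = scatter / (n - C)

    # effectively-constant columns (e.g. an all-pad temperature feature)
    # have zero scatter up to float dust; give them a ridge on the scale
    # of the informative columns instead of lambda * ~0
    diag = np.diag(Sw).copy()
    tol = 1e-12 * max(diag.max(), 1.0)
    informative = diag[diag > tol]
    fallback = informative.mean() if informative.size else 1.0
    scale = np.where(diag > tol, diag, fallback)
    S = Sw + ridge * np.diag(scale)

    # fail early, with advice, if still singular
    try:
        scipy.linalg.cholesky(S)
    except scipy.linalg.LinAlgError as exc:
        raise ContractError(
            "pooled covariance is singular; increase the ridge (lambda > 0) "
            "or remove constant/collinear feature columns"
        ) from exc

    pi = np.full(C, 1.0 / C) if priors == "uniform" else counts / n
    return LDAModel(
        class_labels=class_labels,
        class_means=means,
        pooled_covariance=S,
        priors=pi,
        ridge=ridge,
        feature_dim=d,
    )


def predict_lda(model: LDAModel, x) -> tuple[str, np.ndarray]:
    """Predict one sample: (label, posterior vector over model.class_labels).

    Posteriors are softmax of the discriminants; ties break toward the
    earlier class label.
    """
    X = _as_matrix([x]) if not hasattr(x, "ndim") else np.atleast_2d(np.asarray(x, dtype=float))
    delta = model.discriminants(X)[0]
    shifted = delta - delta.max()
    post = np.exp(shifted)
    post /= post.sum()
    return model.class_labels[int(np.argmax(delta))], post


def predict_lda_batch(model: LDAModel, features) -> tuple[list[str], np.ndarray]:
    """Vectorized prediction; returns (labels, (n, C) posterior matrix)."""
    X = _as_matrix(features)
    delta = model.discriminants(X)
    shifted = delta - delta.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    labels = [model.class_labels[i] for i in np.argmax(delta, axis=1)]
    return labels, post
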