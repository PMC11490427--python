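"""PCA-based melt-curve typing with per-class Gaussians in score space.

This is a fully specified, open implementation of the cluster-typing
workflow common in commercial HRM software: normalize each derivative
curve, project onto the leading principal components of the training
standards, model each genotype class as a Gaussian in score space, and
assign an unknown to the class with the highest posterior — or to
``UNCLASSIFIED`` when even the best class lies beyond an acceptable
Mahalanobis distance.

Unlike instrument-bound tools, the fitted model is serializable and can
type unknowns run at any later time, without re-running the standards.

Normalization operates on the *smoothed negative derivative* restricted
to the melt window, min-max scaled to [0, 1]: the derivative removes
additive baselines exactly, and the scaling removes per-sample
amplitude, leaving only melt-peak shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.stats import chi2

from .curve_features import DerivativeCurve
from .melt_io import ContractError

__all__ = [
    "UNCLASSIFIED",
    "PCAModel",
    "TypingResult",
    "normalize_curve",
    "fit_pca_typing",
    "type_unknown",
]

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class TypingResult:
    """Outcome of typing one unknown curve."""

    label: str  # class label or UNCLASSIFIED
    posteriors: np.ndarray  # over model.class_labels, sums to 1
    mahalanobis: float  # distance to the best class centroid
    scores: np.ndarray  # m-dimensional projection


@dataclass
class PCAModel:
    """Trained typing state: loadings plus per-class score Gaussians.

    ``grid`` is the midpoint temperature grid restricted to the melt
    window; ``loadings`` are m orthonormal rows; ``class_means`` the
    per-class score centroids; ``score_covariance`` the pooled
    within-class covariance of the standards' scores (an MLE, divided by
    n, so duplicated training sets fit identical models).
    """

    grid: np.ndarray
    mean_curve: np.ndarray
    loadings: np.ndarray  # (m, p)
    explained_variance: np.ndarray  # (m,)
    class_labels: list[str]
    class_means: np.ndarray  # (C, m)
    score_covariance: np.ndarray  # (m, m) pooled
    m: int
    typing_quantile: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean_curve = np.asarray(self.mean_curve, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        self.class_means = np.asarray(self.class_means, dtype=float)
        self.score_covariance = np.asarray(self.score_covariance, dtype=float)
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.m), atol=1e-10):
            raise ContractError("PCA loadings must be orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ContractError("explained variance must be non-increasing")

    def project(self, curve: np.ndarray) -> np.ndarray:
        curve = np.asarray(curve, dtype=float)
        if curve.shape != self.grid.shape:
            raise ContractError(
                f"curve length {curve.size} does not match model grid ({self.grid.size})"
            )
        return self.loadings @ (curve - self.mean_curve)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid": self.grid.tolist(),
            "mean_curve": self.mean_curve.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "class_labels": self.class_labels,
            "class_means": self.class_means.tolist(),
            "score_covariance": self.score_covariance.tolist(),
            "m": self.m,
            "typing_quantile": self.typing_quantile,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            grid=np.array(d["grid"]),
            mean_curve=np.array(d["mean_curve"]),
            loadings=np.array(d["loadings"]),
            explained_variance=np.array(d["explained_variance"]),
            class_labels=list(d["class_labels"]),
            class_means=np.array(d["class_means"]),
            score_covariance=np.array(d["score_covariance"]),
            m=int(d["m"]),
            typing_quantile=float(d["typing_quantile"]),
        )


def normalize_curve(
    dcurve: DerivativeCurve, melt_window: tuple[float, float] = (70.0, 90.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict -dF/dT to the melt window and min-max scale to [0, 1].

    Returns ``(grid, values)``.  A flat curve (max == min) carries no
    melt signal and is an error.
    """
    t = dcurve.midpoint_temperatures
    lo, hi = melt_window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ContractError(f"melt window [{lo}, {hi}] outside curve range [{t[0]}, {t[-1]}]")
    sel = (t >= lo) & (t <= hi)
    y = dcurve.neg_dfdt[sel]
    span = y.max() - y.min()
    if span <= 0:
        raise ContractError("no melt signal: derivative curve is flat in the melt window")
    return t[sel], (y - y.min()) / span


def fit_pca_typing(
    curves,
    labels: Sequence[str],
    grid: np.ndarray,
    m: int = 2,
    typing_quantile: float = 0.999,
) -> PCAModel:
    """Fit loadings on the standards and a Gaussian per class in score space.

    ``curves`` is an (n, p) array of normalized curves on ``grid``.
    Loadings are the top-m eigenvectors of the sample covariance
    (n-1 divisor), with each loading's largest-magnitude entry made
    positive for reproducibility.  Class Gaussians share a pooled
    covariance of the standards' scores.
    """
    X = np.atleast_2d(np.asarray(curves, dtype=float))
    labels = [str(l) for l in labels]
    n, p = X.shape
    if len(labels) != n:
        raise ContractError("curves and labels length mismatch")
    if m < 1 or m >= n:
        raise ContractError(f"component count m={m} must satisfy 1 <= m < n_standards ({n})")
    class_labels = sorted(set(labels))
    for c in class_labels:
        if labels.count(c) < 2:
            raise ContractError(f"class {c!r} has fewer than 2 standards")

    mean_curve = X.mean(axis=0)
    Xc = X - mean_curve
    # SVD of the centered matrix: eigenvectors of the sample covariance
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:m].copy()
    explained = (s[:m] ** 2) / (n - 1)
    for i in range(m):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]

    scores = Xc @ loadings.T  # (n, m)
    C = len(class_labels)
    class_means = np.zeros((C, m))
    pooled = np.zeros((m, m))
    for i, c in enumerate(class_labels):
        rows = scores[[k for k, l in enumerate(labels) if l == c]]
        mu = rows.mean(axis=0)
        class_means[i] = mu
        centered = rows - mu
        pooled += centered.T @ centered
    pooled /= n  # MLE divisor: invariant under duplication of the training set
    # guard against degenerate (e.g. perfectly collinear) score clouds
    tr = np.trace(pooled) / m
    pooled += 1e-12 * max(tr, 1.0) * np.eye(m)

    return PCAModel(
        grid=np.asarray(grid, dtype=float),
        mean_curve=mean_curve,
        loadings=loadings,
        explained_variance=explained,
        class_labels=class_labels,
        class_means=class_means,
        score_covariance=pooled,
        m=m,
        typing_quantile=typing_quantile,
    )


def type_unknown(model: PCAModel, curve: np.ndarray) -> TypingResult:
    """Type one normalized curve on the model grid.

    Posterior over classes is proportional to the Gaussian density of
    the curve's scores (uniform priors, shared covariance).  When the
    squared Mahalanobis distance to the best class exceeds the
    chi-square(m) quantile ``typing_quantile``, the sample is returned
    as ``UNCLASSIFIED``: it is too far from every cluster of standards.
    """
    scores = model.project(curve)
    Sinv = scipy.linalg.inv(model.score_covariance)
    diffs = scores - model.class_means  # (C, m)
    d2 = np.einsum("ci,ij,cj->c", diffs, Sinv, diffs)
    loglik = -0.5 * d2  # shared covariance: normalizing constants cancel
    shifted = loglik - loglik.max()
    post = np.exp(shifted)
    post /= post.sum()
    best = int(np.argmax(loglik))
    maha2 = float(d2[best])
    cutoff = chi2.ppf(model.typing_quantile, df=model.m)
    label = model.class_labels[best] if maha2 <= cutoff else UNCLASSIFIED
    return TypingResult(
        label=label, posteriors=post, mahalanobis=float(np.sqrt(maha2)), scores=scores
    )


def write_typing_report(results: Sequence[TypingResult], sample_ids: Sequence[str], model: PCAModel, path: str | Path) -> None:
    """TSV report: sample_id, assigned label, top-2 posteriors, Mahalanobis distance."""
    import pandas as pd

    rows = []
    for sid, r in zip(sample_ids, results):
        order = np.argsort(r.posteriors)[::-1]
        rows.append(
            {
                "sample_id": sid,
                "label": r.label,
                "top1_class": model.class_labels[order[0]],
                "top1_posterior": f"{r.posteriors[order[0]]:.6g}",
                "top2_class": model.class_labels[order[1]] if len(order) > 1 else "NA",
                "top2_posterior": f"{r.posteriors[order[1]]:.6g}" if len(order) > 1 else "NA",
                "mahalanobis": f"{r.mahalanobis:.6g}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
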