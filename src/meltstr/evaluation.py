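"""Confusion-matrix statistics and geno-group evaluation.

Every reported number in an HRM genotype-prediction experiment derives
from a known-by-predicted count table: overall accuracy, per-class
recall, homozygous/heterozygous splits (micro = pooled counts, macro =
mean of per-class recalls — both appear in practice, so both are
first-class here), the near-miss rate (misclassifications that get one
allele right and miss the other by a single repeat), and geno-group
accuracies.

Geno-groups trade genotype resolution for accuracy by merging easily
confused genotypes into one class.  Two evaluation protocols are
supported, because "compare the grouping the other way around" is
ambiguous: *collapse* sums the cells of an existing genotype-level
confusion matrix into group cells (no refit), while *retrain* relabels
the training standards with group labels and refits the classifier.
Collapsing can never lower accuracy; retraining can go either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .melt_io import ContractError, Genotype, read_confusion_tsv, write_confusion_tsv

__all__ = [
    "ConfusionMatrix",
    "GenoGroupScheme",
    "build_confusion",
    "accuracy",
    "subset_accuracy",
    "per_class_recall",
    "genotypes_near",
    "near_miss_rate",
    "collapse_confusion",
    "chance_rate",
    "evaluate_grouping_options",
    "load_schemes",
    "load_reference_confusion",
    "genotype_label_order",
]


@dataclass
class ConfusionMatrix:
    """Known-by-predicted count table; rows = known, columns = predicted."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.counts = np.asarray(self.counts)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ContractError(f"counts must be {n}x{n}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ContractError("confusion counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ContractError("confusion matrix grand total must be positive")
        self.counts = self.counts.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def misclassified(self) -> int:
        return self.total - self.trace

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_tsv(self, path) -> None:
        write_confusion_tsv(self.labels, self.counts, path)

    @classmethod
    def from_tsv(cls, path) -> "ConfusionMatrix":
        labels, counts = read_confusion_tsv(path)
        return cls(labels=labels, counts=counts)


def genotype_label_order(labels: Iterable[str]) -> list[str]:
    """Lexicographic by (allele_a, allele_b), the order used in reports."""
    return sorted(labels, key=lambda l: (Genotype.from_label(l).allele_a, Genotype.from_label(l).allele_b))


def build_confusion(
    known: Sequence[str], predicted: Sequence[str], label_order: Sequence[str]
) -> ConfusionMatrix:
    """Count table from paired label sequences, in the given label order."""
    if len(known) != len(predicted):
        raise ContractError("known and predicted sequences must have equal length")
    labels = [str(l) for l in label_order]
    idx = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for k, p in zip(known, predicted):
        if str(k) not in idx:
            raise ContractError(f"known label {k!r} not in label order")
        if str(p) not in idx:
            raise ContractError(f"predicted label {p!r} not in label order")
        counts[idx[str(k)], idx[str(p)]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall (micro) accuracy: trace over grand total."""
    return cm.trace / cm.total


def subset_accuracy(cm: ConfusionMatrix, row_subset: Sequence[str], mode: str = "micro") -> float:
    """Accuracy restricted to a subset of known-genotype rows.

    ``micro`` pools counts (sum of subset diagonals over sum of subset
    row totals); ``macro`` averages the per-row recalls.  Both appear in
    reported homozygous/heterozygous splits, so the mode is explicit.
    """
    if not row_subset:
        raise ContractError("row subset must be non-empty")
    if mode not in ("micro", "macro"):
        raise ContractError(f"mode must be 'micro' or 'macro', got {mode!r}")
    idx = []
    for l in row_subset:
        if str(l) not in cm.labels:
            raise ContractError(f"label {l!r} not in confusion matrix")
        idx.append(cm.labels.index(str(l)))
    diags = np.diag(cm.counts)[idx]
    totals = cm.row_totals()[idx]
    if (totals == 0).any():
        raise ContractError("subset contains a row with zero total")
    if mode == "micro":
        return float(diags.sum() / totals.sum())
    return float(np.mean(diags / totals))


def per_class_recall(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Diagonal over row total per label; ``None`` for empty rows (undefined)."""
    out: dict[str, float | None] = {}
    totals = cm.row_totals()
    diags = np.diag(cm.counts)
    for i, l in enumerate(cm.labels):
        out[l] = float(diags[i] / totals[i]) if totals[i] > 0 else None
    return out


def genotypes_near(g: Genotype, p: Genotype) -> bool:
    """True when the pair shares exactly one allele and differs by one repeat on the other.

    Both allele pairings are tried and the shared-allele matching is
    maximized, so e.g. (12,14) vs (12,15) is near (shared 12, 14->15)
    while (12,14) vs (13,16) is not (no shared allele).  The predicate
    is symmetric, and never true for identical genotypes.
    """
    pairings = (
        ((g.allele_a, p.allele_a), (g.allele_b, p.allele_b)),
        ((g.allele_a, p.allele_b), (g.allele_b, p.allele_a)),
    )
    for (x1, y1), (x2, y2) in pairings:
        n_equal = (x1 == y1) + (x2 == y2)
        if n_equal == 1:
            dx = abs(x1 - y1) if x1 != y1 else abs(x2 - y2)
            if dx == 1:
                return True
    return False


def near_miss_rate(cm: ConfusionMatrix) -> float | None:
    """Fraction of misclassified samples whose prediction is a near miss.

    Returns ``None`` (undefined) when the matrix has no
    misclassifications.  Labels must parse as genotypes.
    """
    genos = [Genotype.from_label(l) for l in cm.labels]
    off_total = cm.misclassified
    if off_total == 0:
        return None
    near = 0
    for i, gk in enumerate(genos):
        for j, gp in enumerate(genos):
            if i != j and genotypes_near(gk, gp):
                near += int(cm.counts[i, j])
    return near / off_total


@dataclass(frozen=True)
class GenoGroupScheme:
    """A genotype -> group mapping; groups are disjoint and cover the panel."""

    name: str
    mapping: Mapping[str, str]  # genotype label -> group label
    group_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        order = self.group_order or tuple(dict.fromkeys(self.mapping.values()))
        object.__setattr__(self, "group_order", order)
        missing = set(self.mapping.values()) - set(order)
        if missing:
            raise ContractError(f"groups {sorted(missing)} absent from group order")

    def group_of(self, genotype_label: str) -> str:
        if genotype_label not in self.mapping:
            raise ContractError(f"genotype {genotype_label!r} not mapped by scheme {self.name!r}")
        return self.mapping[genotype_label]

    @classmethod
    def identity(cls, labels: Sequence[str], name: str = "identity") -> "GenoGroupScheme":
        return cls(name=name, mapping={l: l for l in labels}, group_order=tuple(labels))


def collapse_confusion(cm: ConfusionMatrix, scheme: GenoGroupScheme) -> ConfusionMatrix:
    """Sum genotype cells into group cells; the grand total is conserved."""
    for l in cm.labels:
        if l not in scheme.mapping:
            raise ContractError(f"label {l!r} not mapped by scheme {scheme.name!r}")
    groups = [g for g in scheme.group_order if g in set(scheme.mapping[l] for l in cm.labels)]
    gidx = {g: i for i, g in enumerate(groups)}
    out = np.zeros((len(groups), len(groups)), dtype=int)
    for i, li in enumerate(cm.labels):
        for j, lj in enumerate(cm.labels):
            out[gidx[scheme.mapping[li]], gidx[scheme.mapping[lj]]] += int(cm.counts[i, j])
    return ConfusionMatrix(labels=groups, counts=out)


def chance_rate(n_classes: int) -> float:
    """Random-assignment baseline accuracy: 1/n."""
    if n_classes < 1:
        raise ContractError(f"n_classes must be >= 1, got {n_classes}")
    return 1.0 / n_classes


# ---------------------------------------------------------------------------
# grouping-option evaluation (retrain vs collapse protocols)


@dataclass
class GroupingResult:
    scheme: str
    protocol: str
    accuracy: float
    confusion: ConfusionMatrix


def evaluate_grouping_options(
    fit: Callable[[Sequence, Sequence[str]], object],
    predict: Callable[[object, Sequence], list[str]],
    train_X,
    train_labels: Sequence[str],
    test_X,
    test_labels: Sequence[str],
    schemes: Sequence[GenoGroupScheme],
    protocols: Sequence[str] = ("collapse", "retrain"),
) -> list[GroupingResult]:
    """Score every (scheme, protocol) combination with a generic classifier.

    ``fit(train_X, labels) -> model`` and ``predict(model, test_X) ->
    labels`` abstract over LDA (feature matrices) and PCA typing
    (normalized curves).  *collapse* fits once at genotype level and
    collapses the resulting confusion matrix per scheme; *retrain* maps
    the training labels to group labels and refits per scheme.
    """
    results: list[GroupingResult] = []
    base_order = list(dict.fromkeys(list(train_labels) + list(test_labels)))
    collapse_cm = None
    if "collapse" in protocols:
        model = fit(train_X, list(train_labels))
        preds = predict(model, test_X)
        order = base_order + sorted(set(preds) - set(base_order))  # e.g. UNCLASSIFIED
        collapse_cm = build_confusion(test_labels, preds, order)
    for scheme in schemes:
        for protocol in protocols:
            if protocol == "collapse":
                assert collapse_cm is not None
                extras = [l for l in collapse_cm.labels if l not in scheme.mapping]
                sch = scheme
                if extras:  # e.g. UNCLASSIFIED outcomes keep their own cell
                    sch = GenoGroupScheme(
                        name=scheme.name,
                        mapping={**dict(scheme.mapping), **{l: l for l in extras}},
                        group_order=tuple(scheme.group_order) + tuple(extras),
                    )
                cm = collapse_confusion(collapse_cm, sch)
            elif protocol == "retrain":
                g_train = [scheme.group_of(str(l)) for l in train_labels]
                g_test = [scheme.group_of(str(l)) for l in test_labels]
                model = fit(train_X, g_train)
                preds = predict(model, test_X)
                order = [g for g in scheme.group_order if g in set(g_train) | set(g_test)]
                order += sorted(set(preds) - set(order))
                cm = build_confusion(g_test, preds, order)
            else:
                raise ContractError(f"unknown protocol {protocol!r}")
            results.append(
                GroupingResult(scheme=scheme.name, protocol=protocol, accuracy=accuracy(cm), confusion=cm)
            )
    return results


def lda_fit_predict(priors: str = "uniform", ridge: float = 1e-6):
    """(fit, predict) pair running the package's LDA on feature matrices."""
    from .classify_lda import fit_lda, predict_lda_batch

    def fit(X, labels):
        return fit_lda(X, labels, priors=priors, ridge=ridge)

    def predict(model, X):
        return predict_lda_batch(model, X)[0]

    return fit, predict


def pca_fit_predict(grid, m: int = 2, typing_quantile: float = 0.999):
    """(fit, predict) pair running PCA score-space typing on normalized curves.

    Unclassified outcomes are returned as-is and will count as
    misclassifications unless the label order includes them.
    """
    import numpy as _np

    from .classify_pca import fit_pca_typing, type_unknown

    def fit(X, labels):
        return fit_pca_typing(_np.asarray(X), labels, grid, m=m, typing_quantile=typing_quantile)

    def predict(model, X):
        return [type_unknown(model, v).label for v in _np.asarray(X)]

    return fit, predict


# ---------------------------------------------------------------------------
# packaged fixtures


def load_schemes(locus: str) -> dict[str, GenoGroupScheme]:
    """Named geno-group schemes for a locus (options A, B, … as published)."""
    name = f"genogroups_{locus.lower()}.json"
    text = resources.files("meltstr.fixtures").joinpath(name).read_text(encoding="utf-8")
    payload = json.loads(text)
    out = {}
    for option, groups in payload["schemes"].items():
        mapping = {}
        for group_label, genotypes in groups.items():
            for g in genotypes:
                mapping[g] = group_label
        out[option] = GenoGroupScheme(
            name=f"{payload['locus']}-Option{option}",
            mapping=mapping,
            group_order=tuple(groups.keys()),
        )
    return out


def _homo_het_rows(labels: Sequence[str]) -> tuple[list[str], list[str]]:
    homo, het = [], []
    for l in labels:
        (homo if Genotype.from_label(l).homozygous else het).append(l)
    return homo, het


def compute_reference_report(fixtures_dir=None) -> list[dict]:
    """Recompute every reference statistic from the packaged count tables.

    Each entry of the returned list holds the statistic name, the value
    recomputed here (percentages on the 0–100 scale, counts as
    integers), the published reference value, and a ``passed`` flag
    (agreement at the printed 2-decimal precision).  ``fixtures_dir``
    overrides the packaged fixture location (mainly for testing
    sensitivity to corrupted tables); a missing file raises
    ``FileNotFoundError``.
    """
    from pathlib import Path

    spec_text = resources.files("meltstr.fixtures").joinpath("reference_statistics.json").read_text(
        encoding="utf-8"
    )
    entries = json.loads(spec_text)

    def get_cm(fixture: str) -> ConfusionMatrix:
        if fixtures_dir is not None:
            path = Path(fixtures_dir) / f"{fixture}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing fixture {path}")
            return ConfusionMatrix.from_tsv(path)
        return load_reference_confusion(fixture)

    report = []
    for name, entry in entries.items():
        stat = entry["statistic"]
        expected = entry["expected"]
        if stat.startswith("chance:"):
            value: float = round(100.0 * chance_rate(int(stat.split(":")[1])), 2)
        else:
            cm = get_cm(entry["fixture"])
            homo, het = _homo_het_rows(cm.labels)
            if stat == "accuracy":
                value = round(100.0 * accuracy(cm), 2)
            elif stat == "homozygous_micro":
                value = round(100.0 * subset_accuracy(cm, homo, "micro"), 2)
            elif stat == "heterozygous_micro":
                value = round(100.0 * subset_accuracy(cm, het, "micro"), 2)
            elif stat == "homozygous_macro":
                value = round(100.0 * subset_accuracy(cm, homo, "macro"), 2)
            elif stat == "heterozygous_macro":
                value = round(100.0 * subset_accuracy(cm, het, "macro"), 2)
            elif stat == "misclassified":
                value = cm.misclassified
            elif stat == "near_miss":
                rate = near_miss_rate(cm)
                value = round(100.0 * rate, 2) if rate is not None else float("nan")
            elif stat.startswith("recall:"):
                label = stat.split(":", 1)[1]
                rec = per_class_recall(cm)[label]
                value = round(100.0 * rec, 2) if rec is not None else float("nan")
            else:  # pragma: no cover - fixture schema guard
                raise ContractError(f"unknown statistic kind {stat!r}")
        n = 1 if entry["fixture"] is None else get_cm(entry["fixture"]).total
        report.append(
            {
                "name": name,
                "value": value,
                "reference": expected,
                "n": n,
                "passed": bool(abs(float(value) - float(expected)) < 0.005)
                if value == value
                else False,
            }
        )
    return report


_REFERENCE_FIXTURES = (
    "confusion_d5s818_pca",
    "confusion_d5s818_lda",
    "confusion_d18s51_pca",
    "confusion_d18s51_lda",
)


def load_reference_confusion(name: str) -> ConfusionMatrix:
    """Load a packaged reference confusion matrix.

    Names: ``confusion_<locus>_<method>`` with locus in {d5s818, d18s51}
    and method in {pca, lda} — the published genotype-prediction results
    these statistics reproduce.
    """
    if name not in _REFERENCE_FIXTURES:
        raise KeyError(f"unknown reference confusion {name!r}; available: {_REFERENCE_FIXTURES}")
    from .melt_io import load_fixture_confusion

    labels, counts = load_fixture_confusion(name)
    return ConfusionMatrix(labels=labels, counts=counts)
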