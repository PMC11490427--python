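"""Readers, writers and domain records for melt-curve data.

High-resolution melt (HRM) experiments record fluorescence of a
dye-saturated amplicon while the temperature ramps up; duplex
dissociation releases dye and fluorescence drops.  This module holds the
record types shared by the rest of the package — genotypes, locus
definitions, melt curves, sample metadata — and the plain-text formats
they travel in: wide CSV for curves (one temperature column, one
fluorescence column per sample), TSV for metadata, feature tables and
confusion matrices.

Instrument-specific export dialects are deliberately out of scope; the
wide CSV is the simplest loss-free interchange layout.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ContractError",
    "Genotype",
    "LocusSpec",
    "MeltCurve",
    "SampleRecord",
    "CANONICAL_START",
    "CANONICAL_STOP",
    "CANONICAL_STEP",
    "canonical_grid",
    "load_locus",
    "available_loci",
    "read_melt_table",
    "write_melt_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_confusion_tsv",
    "write_confusion_tsv",
    "read_feature_table",
    "write_feature_table",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented layout."""


class ContractError(ValueError):
    """Raised when a caller violates an operation's precondition."""


# The ramp used throughout: 60 -> 95 degC in 0.1 degC increments (351 points).
CANONICAL_START = 60.0
CANONICAL_STOP = 95.0
CANONICAL_STEP = 0.1


def canonical_grid() -> np.ndarray:
    """The canonical 60.0–95.0 °C temperature grid at 0.1 °C steps."""
    n = int(round((CANONICAL_STOP - CANONICAL_START) / CANONICAL_STEP)) + 1
    return np.round(CANONICAL_START + CANONICAL_STEP * np.arange(n), 2)


_GENOTYPE_RE = re.compile(r"^\((\d+),(\d+)\)$")


@dataclass(frozen=True, order=True)
class Genotype:
    """A pair of STR allele repeat counts, stored in canonical order.

    ``allele_a <= allele_b`` always; the constructor swaps if needed, so
    ``Genotype(13, 11) == Genotype(11, 13)``.  Rendered as ``(a,b)``.
    """

    allele_a: int
    allele_b: int

    def __post_init__(self) -> None:
        a, b = int(self.allele_a), int(self.allele_b)
        if a < 1 or b < 1:
            raise ContractError(f"allele repeat counts must be >= 1, got ({a},{b})")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def homozygous(self) -> bool:
        return self.allele_a == self.allele_b

    @property
    def label(self) -> str:
        return f"({self.allele_a},{self.allele_b})"

    def __str__(self) -> str:
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "Genotype":
        m = _GENOTYPE_RE.match(label.replace(" ", ""))
        if not m:
            raise FormatError(f"cannot parse genotype label {label!r}; expected '(a,b)'")
        return cls(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class LocusSpec:
    """Definition of one STR locus and its simulated amplicon.

    ``motif_length`` is base pairs per repeat unit (4 for the
    tetranucleotide loci shipped here); ``flank_length`` the non-repeat
    portion of the amplicon; ``gc_fraction`` its GC content used by the
    melting-temperature model.  Primer strings are the published assay
    primers.
    """

    name: str
    motif_length: int
    flank_length: int
    gc_fraction: float
    forward_primer: str
    reverse_primer: str
    allele_range: tuple[int, int]
    panel: tuple[Genotype, ...] = ()
    feature_count: int = 3

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ContractError("motif_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ContractError("gc_fraction must lie in [0, 1]")
        for p in (self.forward_primer, self.reverse_primer):
            if not p or not re.fullmatch(r"[ACGT]+", p):
                raise ContractError(f"primer must be non-empty uppercase ACGT, got {p!r}")
        lo, hi = self.allele_range
        if lo < 1 or hi < lo:
            raise ContractError(f"invalid allele_range {self.allele_range}")


@dataclass
class MeltCurve:
    """Raw temperature/fluorescence series for one sample at one locus."""

    sample_id: str
    locus: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ContractError(
                f"temperature/fluorescence length mismatch for {self.sample_id}: "
                f"{self.temperatures.size} vs {self.fluorescence.size}"
            )
        if self.temperatures.size < 10:
            raise ContractError(f"melt curve {self.sample_id} has fewer than 10 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ContractError(f"temperatures not strictly increasing for {self.sample_id}")

    def __len__(self) -> int:
        return int(self.temperatures.size)

    @property
    def on_canonical_grid(self) -> bool:
        g = canonical_grid()
        return len(self) == g.size and bool(np.allclose(self.temperatures, g, atol=1e-6))


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sample: identity, locus, role, known genotype.

    ``role`` is ``standard`` for training samples of known genotype, or
    ``unknown`` for samples submitted for prediction.  Standards must
    carry a genotype.
    """

    sample_id: str
    locus: str
    known_genotype: Genotype | None
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("standard", "unknown"):
            raise FormatError(f"unknown role {self.role!r} for {self.sample_id}")
        if self.role == "standard" and self.known_genotype is None:
            raise FormatError(f"standard {self.sample_id} has no known genotype")


# ---------------------------------------------------------------------------
# locus fixtures


def _fixture_text(name: str) -> str:
    return resources.files("meltstr.fixtures").joinpath(name).read_text(encoding="utf-8")


def available_loci() -> list[str]:
    return sorted(json.loads(_fixture_text("loci.json")))


def load_locus(name: str) -> LocusSpec:
    """Load a packaged locus definition (``D5S818`` or ``D18S51``)."""
    table = json.loads(_fixture_text("loci.json"))
    if name not in table:
        raise KeyError(f"no locus fixture named {name!r}; available: {sorted(table)}")
    d = table[name]
    return LocusSpec(
        name=d["name"],
        motif_length=d["motif_length"],
        flank_length=d["flank_length"],
        gc_fraction=d["gc_fraction"],
        forward_primer=d["forward_primer"],
        reverse_primer=d["reverse_primer"],
        allele_range=tuple(d["allele_range"]),
        panel=tuple(Genotype(a, b) for a, b in d["panel"]),
        feature_count=d["feature_count"],
    )


# ---------------------------------------------------------------------------
# melt-curve CSV


def read_melt_table(path: str | Path, locus: str = "") -> list[MeltCurve]:
    """Read a wide melt-curve CSV: ``Temperature,<id1>,<id2>,...``.

    Returns one :class:`MeltCurve` per sample column.  The temperature
    column must be strictly increasing; ragged or empty bodies are
    format errors.  Non-canonical grids are accepted with a warning
    (downstream stages only need strict monotonicity).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse melt table {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise FormatError(f"melt table {path} has an empty body")
    if df.shape[1] < 2:
        raise FormatError(f"melt table {path} needs a temperature column plus >=1 sample")
    if df.isna().any().any():
        raise FormatError(f"melt table {path} has ragged or non-numeric rows")
    temps = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(temps) > 0):
        raise FormatError(f"temperature column of {path} is not strictly increasing")
    curves = []
    for col in df.columns[1:]:
        curves.append(
            MeltCurve(
                sample_id=str(col),
                locus=locus,
                temperatures=temps.copy(),
                fluorescence=df[col].to_numpy(dtype=float),
            )
        )
    if not curves[0].on_canonical_grid:
        warnings.warn(
            f"melt table {path} is not on the canonical 60–95 °C / 0.1 °C grid",
            stacklevel=2,
        )
    return curves


def write_melt_table(curves: Sequence[MeltCurve], path: str | Path) -> None:
    """Write curves sharing one grid as a wide CSV.

    Temperatures are printed with 2 decimals, fluorescence with 6
    significant digits.
    """
    if not curves:
        raise ContractError("write_melt_table needs at least one curve")
    grid = curves[0].temperatures
    for c in curves[1:]:
        if len(c) != grid.size or not np.allclose(c.temperatures, grid, atol=1e-9):
            raise ContractError(
                f"curve {c.sample_id} is not on the same temperature grid as {curves[0].sample_id}"
            )
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("Temperature," + ",".join(c.sample_id for c in curves) + "\n")
        for i in range(grid.size):
            row = [f"{grid[i]:.2f}"] + [f"{c.fluorescence[i]:.6g}" for c in curves]
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# sample metadata TSV


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample sheet: TSV with sample_id, locus, allele_a, allele_b, role.

    Genotypes are canonicalized (allele_a <= allele_b).  For unknowns the
    allele columns may be ``NA``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "locus", "allele_a", "allele_b", "role"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample metadata {path} missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        a, b = row["allele_a"], row["allele_b"]
        has_gt = not (pd.isna(a) or pd.isna(b) or str(a).upper() == "NA" or str(b).upper() == "NA")
        gt = Genotype(int(a), int(b)) if has_gt else None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                locus=str(row["locus"]),
                known_genotype=gt,
                role=str(row["role"]),
            )
        )
    return records


def write_sample_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "locus": r.locus,
                "allele_a": r.known_genotype.allele_a if r.known_genotype else "NA",
                "allele_b": r.known_genotype.allele_b if r.known_genotype else "NA",
                "role": r.role,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# confusion-matrix TSV


def read_confusion_tsv(source: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a confusion matrix TSV (header = predicted labels, first column = known).

    Returns ``(labels, counts)``; the label sets of rows and columns must
    match in order.
    """
    df = pd.read_csv(source, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise FormatError(f"confusion matrix {source}: row and column labels differ")
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or (counts < 0).any():
        raise FormatError(f"confusion matrix {source}: counts must be non-negative numbers")
    return labels, counts.astype(int)


def write_confusion_tsv(labels: Sequence[str], counts: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(counts, dtype=int), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", index_label="known")


def load_fixture_confusion(name: str) -> tuple[list[str], np.ndarray]:
    """Load one of the packaged reference confusion matrices by fixture name."""
    import io

    return read_confusion_tsv(io.StringIO(_fixture_text(f"{name}.tsv")))


# ---------------------------------------------------------------------------
# feature table TSV (the flattened peak/shoulder encoding)


def write_feature_table(vectors, records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write feature vectors as TSV: id, locus, genotype, role, T_i/h_i, kinds.

    ``vectors`` is a sequence of :class:`meltstr.curve_features.FeatureVector`;
    ``records`` supplies genotype/role metadata keyed by sample_id.
    """
    meta = {r.sample_id: r for r in records}
    rows = []
    for v in vectors:
        k = len(v.observations)
        rec = meta.get(v.sample_id)
        row: dict[str, object] = {
            "sample_id": v.sample_id,
            "locus": v.locus,
            "genotype": rec.known_genotype.label if rec and rec.known_genotype else "NA",
            "role": rec.role if rec else "unknown",
        }
        for i, obs in enumerate(v.observations, start=1):
            row[f"T{i}"] = f"{obs.temperature:.6g}"
            row[f"h{i}"] = f"{obs.height:.6g}"
        for i, obs in enumerate(v.observations, start=1):
            row[f"kind{i}"] = obs.kind
        rows.append(row)
    if not rows:
        raise ContractError("write_feature_table needs at least one vector")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path):
    """Read a feature table written by :func:`write_feature_table`.

    Returns ``(vectors, records)``.
    """
    from .curve_features import FeatureVector, PeakObservation

    df = pd.read_csv(path, sep="\t", dtype=str)
    k = sum(1 for c in df.columns if re.fullmatch(r"T\d+", c))
    if k == 0:
        raise FormatError(f"feature table {path} has no T_i columns")
    vectors, records = [], []
    for _, row in df.iterrows():
        obs = [
            PeakObservation(
                temperature=float(row[f"T{i}"]),
                height=float(row[f"h{i}"]),
                kind=str(row[f"kind{i}"]),
            )
            for i in range(1, k + 1)
        ]
        vectors.append(FeatureVector(sample_id=str(row["sample_id"]), locus=str(row["locus"]), observations=obs))
        gt = None if str(row["genotype"]) == "NA" else Genotype.from_label(str(row["genotype"]))
        records.append(
            SampleRecord(sample_id=str(row["sample_id"]), locus=str(row["locus"]), known_genotype=gt, role=str(row["role"]))
        )
    return vectors, records
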