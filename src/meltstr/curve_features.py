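"""Melt-curve feature extraction: -dF/dT, peaks, shoulders, padding.

A melting transition appears as a peak in the negative derivative of
fluorescence with respect to temperature.  Heterozygous STR amplicons
produce two closely spaced transitions whose derivative lobes merge into
a primary peak with one or more *shoulders* — either resolved (a
separate local maximum) or unresolved (a terrace on the primary's
flank).  Each sample is summarized into a fixed-length vector of
(temperature, height) pairs: the primary peak first, then shoulders by
ascending temperature, padded at 64.95 °C when fewer observations than
the target count are found.  The fixed length is what lets samples with
different shoulder counts be compared by a classifier.

The derivative lives on interval *midpoints* of the temperature grid;
on the canonical 0.1 °C ramp from 60 °C the midpoints are 60.05, 60.15,
…, so 64.95 °C is a native grid point and padding needs no
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .melt_io import ContractError, MeltCurve

__all__ = [
    "PAD_TEMPERATURE",
    "PRIMARY",
    "SHOULDER_RESOLVED",
    "SHOULDER_UNRESOLVED",
    "PAD",
    "NoPeakError",
    "DerivativeCurve",
    "PeakObservation",
    "FeatureVector",
    "PeakConfig",
    "compute_derivative",
    "detect_peaks",
    "extract_features",
    "features_from_curve",
]

PAD_TEMPERATURE = 64.95

PRIMARY = "primary"
SHOULDER_RESOLVED = "shoulder_resolved"
SHOULDER_UNRESOLVED = "shoulder_unresolved"
PAD = "pad"
_KINDS = (PRIMARY, SHOULDER_RESOLVED, SHOULDER_UNRESOLVED, PAD)


class NoPeakError(ValueError):
    """No melt peak found inside the melt window; the sample is unusable."""


@dataclass
class DerivativeCurve:
    """Smoothed negative derivative -dF/dT on the midpoint grid."""

    midpoint_temperatures: np.ndarray
    neg_dfdt: np.ndarray
    smoothed: bool

    def __post_init__(self) -> None:
        self.midpoint_temperatures = np.asarray(self.midpoint_temperatures, dtype=float)
        self.neg_dfdt = np.asarray(self.neg_dfdt, dtype=float)
        if self.midpoint_temperatures.shape != self.neg_dfdt.shape:
            raise ContractError("derivative curve arrays must have equal length")

    def value_at(self, temperature: float) -> float:
        """Smoothed -dF/dT at a temperature (linear interpolation on the grid)."""
        t = self.midpoint_temperatures
        if temperature < t[0] - 1e-9 or temperature > t[-1] + 1e-9:
            raise ContractError(
                f"temperature {temperature} outside derivative grid [{t[0]}, {t[-1]}]"
            )
        return float(np.interp(temperature, t, self.neg_dfdt))


@dataclass(frozen=True)
class PeakObservation:
    """One detected melt feature: a (temperature, height) pair with a kind tag."""

    temperature: float
    height: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ContractError(f"unknown observation kind {self.kind!r}")
        # negative smoothed-derivative readings are instrument noise; clamp
        object.__setattr__(self, "height", max(float(self.height), 0.0))
        object.__setattr__(self, "temperature", float(self.temperature))


@dataclass
class FeatureVector:
    """Fixed-length peak/shoulder encoding for one sample.

    ``observations`` holds exactly k entries: primary first, then
    shoulders by ascending temperature, then pads (all at 64.95 °C).
    ``values`` flattens to (T1, h1, …, Tk, hk).
    """

    sample_id: str
    locus: str
    observations: list[PeakObservation]

    def __post_init__(self) -> None:
        kinds = [o.kind for o in self.observations]
        if kinds.count(PRIMARY) != 1 or kinds[0] != PRIMARY:
            raise ContractError("feature vector must start with exactly one primary peak")
        n_pad = kinds.count(PAD)
        if n_pad and kinds[-n_pad:] != [PAD] * n_pad:
            raise ContractError("pad observations must come last")

    @property
    def values(self) -> np.ndarray:
        return np.array(
            [x for o in self.observations for x in (o.temperature, o.height)], dtype=float
        )

    @property
    def kinds(self) -> list[str]:
        return [o.kind for o in self.observations]


@dataclass(frozen=True)
class PeakConfig:
    """Thresholds for peak and shoulder identification.

    ``melt_window``: temperature band searched for transitions (°C).
    ``prominence_frac``: a local maximum counts as a resolved peak when
    its topographic prominence is at least this fraction of the tallest
    in-window derivative value.
    ``terrace_frac``: an unresolved shoulder is a terrace on the
    primary's flank — a point where the slope of -dF/dT dips toward zero
    without crossing it, to within this fraction of the flank's maximum
    slope magnitude.
    """

    melt_window: tuple[float, float] = (70.0, 90.0)
    prominence_frac: float = 0.05
    terrace_frac: float = 0.15


def compute_derivative(curve: MeltCurve, window: int = 11, degree: int = 3) -> DerivativeCurve:
    """Finite-difference -dF/dT at interval midpoints, then local polynomial smoothing.

    ``window`` is an odd point count; ``window=1`` disables smoothing and
    returns the raw finite differences.  Negative output values are kept
    (they are signal noise, and clipping would bias the padding rule).
    """
    if window % 2 == 0:
        raise ContractError(f"smoothing window must be odd, got {window}")
    if window > 1 and window < degree + 2:
        raise ContractError(f"window {window} too small for polynomial degree {degree}")
    t = curve.temperatures
    f = curve.fluorescence
    if t.size <= window:
        raise ContractError(f"curve of length {t.size} too short for window {window}")
    raw = -np.diff(f) / np.diff(t)
    mid = 0.5 * (t[:-1] + t[1:])
    if window == 1:
        return DerivativeCurve(mid, raw, smoothed=False)
    sm = savgol_filter(raw, window_length=window, polyorder=degree)
    return DerivativeCurve(mid, sm, smoothed=True)


def _terrace_shoulders(
    y: np.ndarray,
    t: np.ndarray,
    p_idx: int,
    lo: int,
    hi: int,
    terrace_frac: float,
    height_floor: float,
) -> list[tuple[int, float]]:
    """Terrace test for unresolved shoulders around the primary at ``p_idx``.

    ``g = diff(y)`` is the slope of the smoothed derivative.  On the
    ascending flank an interior local minimum of g that stays positive
    but drops to <= terrace_frac of the flank's maximum slope marks a
    plateau — a melting transition riding on the primary's rise.  The
    descending flank is symmetric (local maximum of g, g < 0, small
    |g|).  A terrace must also sit at a derivative height above
    ``height_floor``: in the flat tails far from the transition the
    slope hovers near zero and would otherwise satisfy the test without
    being a melt feature.  Returns (index, temperature) pairs in
    y-coordinates.
    """
    g = np.diff(y[lo:hi])
    p = p_idx - lo
    out: list[tuple[int, float]] = []
    # ascending flank: g indices [0, p)
    asc = g[:p]
    if asc.size >= 3 and asc.max() > 0:
        gmax = asc.max()
        for i in range(1, asc.size - 1):
            if (
                asc[i] > 0
                and asc[i] < asc[i - 1]
                and asc[i] <= asc[i + 1]
                and asc[i] <= terrace_frac * gmax
                and y[lo + i] >= height_floor
            ):
                out.append((lo + i, t[lo + i]))
    # descending flank: g indices [p, len)
    desc = g[p:]
    if desc.size >= 3 and desc.min() < 0:
        gmin = abs(desc.min())
        for i in range(1, desc.size - 1):
            j = p + i
            if (
                desc[i] < 0
                and desc[i] > desc[i - 1]
                and desc[i] >= desc[i + 1]
                and abs(desc[i]) <= terrace_frac * gmin
                and y[lo + j] >= height_floor
            ):
                out.append((lo + j, t[lo + j]))
    # merge adjacent qualifying indices into one terrace
    merged: list[tuple[int, float]] = []
    for idx, temp in out:
        if merged and idx - merged[-1][0] <= 2:
            continue
        merged.append((idx, temp))
    return merged


def detect_peaks(dcurve: DerivativeCurve, cfg: PeakConfig | None = None) -> list[PeakObservation]:
    """Identify the primary melt peak and its shoulders.

    Procedure: (1) resolved candidates are local maxima of the smoothed
    -dF/dT inside the melt window with prominence >= prominence_frac of
    the tallest in-window value; (2) the tallest candidate is the
    primary (ties: lower temperature wins); the rest are resolved
    shoulders; (3) unresolved shoulders are terraces on the primary's
    flanks found by the slope test (see :func:`_terrace_shoulders`);
    (4) heights are read from the smoothed derivative at the detected
    temperatures; (5) returned primary-first, then shoulders by
    ascending temperature.

    Raises :class:`NoPeakError` when no candidate lies in the window.
    """
    cfg = cfg or PeakConfig()
    if not dcurve.smoothed:
        raise ContractError("detect_peaks requires a smoothed derivative curve")
    t = dcurve.midpoint_temperatures
    y = dcurve.neg_dfdt
    lo_t, hi_t = cfg.melt_window
    sel = np.nonzero((t >= lo_t) & (t <= hi_t))[0]
    if sel.size < 3:
        raise NoPeakError(f"melt window [{lo_t}, {hi_t}] contains too few grid points")
    lo, hi = int(sel[0]), int(sel[-1]) + 1
    ywin = y[lo:hi]
    peaks_rel, _ = find_peaks(ywin)
    if peaks_rel.size:
        prom = peak_prominences(ywin, peaks_rel)[0]
        keep = prom >= cfg.prominence_frac * ywin.max()
        peaks_rel = peaks_rel[keep]
    if peaks_rel.size == 0:
        raise NoPeakError(
            f"no melt peak with sufficient prominence inside [{lo_t}, {hi_t}] °C"
        )
    cand = peaks_rel + lo
    heights = y[cand]
    p_idx = int(cand[int(np.argmax(heights))])  # argmax takes first = lowest T on ties
    observations = [PeakObservation(t[p_idx], y[p_idx], PRIMARY)]
    shoulders: list[PeakObservation] = [
        PeakObservation(t[i], y[i], SHOULDER_RESOLVED) for i in cand if i != p_idx
    ]
    height_floor = cfg.prominence_frac * y[p_idx]
    for idx, temp in _terrace_shoulders(y, t, p_idx, lo, hi, cfg.terrace_frac, height_floor):
        shoulders.append(PeakObservation(temp, y[idx], SHOULDER_UNRESOLVED))
    shoulders.sort(key=lambda o: o.temperature)
    return observations + shoulders


def extract_features(
    peaks: Sequence[PeakObservation], dcurve: DerivativeCurve, k: int
) -> list[PeakObservation]:
    """Reduce detected observations to exactly ``k`` (temperature, height) pairs.

    More than k: keep the primary plus the k-1 tallest shoulders.  Fewer
    than k: append pad observations at 64.95 °C whose height is the
    smoothed -dF/dT there (a native point of the canonical midpoint
    grid).  Returns the ordered list: primary, shoulders by ascending
    temperature, pads.
    """
    if k not in (3, 4):
        raise ContractError(f"feature count k must be 3 or 4, got {k}")
    if not peaks:
        raise ContractError("extract_features needs at least one observation")
    primary = [o for o in peaks if o.kind == PRIMARY]
    if len(primary) != 1:
        raise ContractError("exactly one primary observation required")
    shoulders = [o for o in peaks if o.kind in (SHOULDER_RESOLVED, SHOULDER_UNRESOLVED)]
    if len(shoulders) > k - 1:
        shoulders = sorted(shoulders, key=lambda o: -o.height)[: k - 1]
    shoulders.sort(key=lambda o: o.temperature)
    obs = primary + shoulders
    while len(obs) < k:
        obs.append(PeakObservation(PAD_TEMPERATURE, dcurve.value_at(PAD_TEMPERATURE), PAD))
    return obs


def features_from_curve(
    curve: MeltCurve,
    k: int,
    window: int = 11,
    degree: int = 3,
    cfg: PeakConfig | None = None,
) -> FeatureVector:
    """Full pipeline for one curve: derivative -> peaks -> fixed-length vector."""
    dcurve = compute_derivative(curve, window=window, degree=degree)
    peaks = detect_peaks(dcurve, cfg)
    obs = extract_features(peaks, dcurve, k)
    return FeatureVector(sample_id=curve.sample_id, locus=curve.locus, observations=list(obs))
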