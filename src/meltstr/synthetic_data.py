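"""Synthetic qPCR melt curves with STR-genotype structure.

Each allele of a tetranucleotide STR contributes an amplicon species
whose melting temperature rises with amplicon length (longer repeats
melt later) and GC content.  A species melts as a logistic two-state
transition: fluorescence A*w*sigma((Tm - T)/s) that decays around Tm
with slope parameter s.  A heterozygote superimposes two such
transitions whose Tm's differ by only a fraction of a degree — the
central difficulty of melt-based STR genotyping — producing a primary
derivative peak with shoulders; a homozygote contributes one species at
double weight and a single clean peak.  On top of this sit a linear
baseline, an optional heteroduplex species melting below the matched
duplexes, per-sample Tm jitter (run-to-run thermal calibration error),
and iid Gaussian reading noise.

The melting-temperature model is Tm = c0 + c1*gc - c2/length, the
classic logarithm-free length/GC dependence; the default coefficients
put the simulated panels near 78–80 °C inside the 60–95 °C ramp, with
one repeat unit (4 bp) shifting Tm by roughly 0.1 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .melt_io import (
    CANONICAL_STEP,
    ContractError,
    Genotype,
    LocusSpec,
    MeltCurve,
    SampleRecord,
    canonical_grid,
)

__all__ = [
    "SimulationConfig",
    "SimulatedSample",
    "allele_amplicon_length",
    "allele_tm",
    "simulate_curve",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the melt-curve generator.

    tm_coeffs: (c0 offset °C, c1 GC coefficient °C, c2 length
    coefficient °C·bp) of Tm = c0 + c1*gc - c2/length.
    transition_slope: logistic width s in °C (~80% of a species' drop
    happens within ±1.4 s of its Tm).
    amplitude: total fluorescence released by one weight unit of
    product; each allele has weight 1, so a homozygote's single species
    carries weight 2.
    baseline: (intercept, slope per °C) linear background added to the
    signal; dF/dT of the baseline is constant, so it cancels in
    normalized derivatives but sets the pad height at 64.95 °C.
    heteroduplex: mismatched-strand duplexes in heterozygotes melt
    early; when enabled, a species of weight ``heteroduplex_weight`` is
    added ``heteroduplex_delta`` °C below the lower allele Tm.  Off by
    default.
    noise_sd: per-reading Gaussian noise (fluorescence units).
    tm_jitter_sd: per-sample Tm shift (°C), drawn once per sample.
    """

    tm_coeffs: tuple[float, float, float] = (67.0, 41.0, 675.0)
    transition_slope: float = 0.30
    amplitude: float = 1000.0
    baseline_intercept: float = 100.0
    baseline_slope: float = -0.5
    heteroduplex: bool = False
    heteroduplex_delta: float = 1.0
    heteroduplex_weight: float = 0.5
    noise_sd: float = 2.0
    tm_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_slope <= 0:
            raise ContractError("transition_slope must be positive")
        if self.noise_sd < 0 or self.tm_jitter_sd < 0:
            raise ContractError("noise standard deviations must be >= 0")
        if self.heteroduplex_delta < 0 or self.heteroduplex_weight <= 0:
            raise ContractError("heteroduplex parameters must be positive")


@dataclass
class SimulatedSample:
    """A simulated melt curve together with its ground truth."""

    curve: MeltCurve
    genotype: Genotype
    role: str  # standard | unknown

    @property
    def record(self) -> SampleRecord:
        return SampleRecord(
            sample_id=self.curve.sample_id,
            locus=self.curve.locus,
            known_genotype=self.genotype,
            role=self.role,
        )


def allele_amplicon_length(spec: LocusSpec, repeats: int) -> int:
    """Amplicon length in bp: flank plus motif_length x repeat count."""
    lo, hi = spec.allele_range
    if not lo <= repeats <= hi:
        raise ContractError(
            f"repeat count {repeats} outside {spec.name} allele range [{lo}, {hi}]"
        )
    return spec.flank_length + spec.motif_length * repeats


def allele_tm(
    spec: LocusSpec, repeats: int, coeffs: tuple[float, float, float] | None = None
) -> float:
    """Deterministic melting temperature of one allele's amplicon.

    Tm = c0 + c1*gc_fraction - c2/length; strictly increasing in repeat
    count whenever c2 > 0.
    """
    c0, c1, c2 = coeffs if coeffs is not None else SimulationConfig().tm_coeffs
    length = allele_amplicon_length(spec, repeats)
    return c0 + c1 * spec.gc_fraction - c2 / length


def _species(spec: LocusSpec, genotype: Genotype, cfg: SimulationConfig) -> list[tuple[float, float]]:
    """(Tm, weight) pairs for the duplex species a genotype produces."""
    if genotype.homozygous:
        return [(allele_tm(spec, genotype.allele_a, cfg.tm_coeffs), 2.0)]
    tma = allele_tm(spec, genotype.allele_a, cfg.tm_coeffs)
    tmb = allele_tm(spec, genotype.allele_b, cfg.tm_coeffs)
    out = [(tma, 1.0), (tmb, 1.0)]
    if cfg.heteroduplex:
        out.append((min(tma, tmb) - cfg.heteroduplex_delta, cfg.heteroduplex_weight))
    return out


def simulate_curve(
    spec: LocusSpec,
    genotype: Genotype,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
    role: str = "unknown",
) -> SimulatedSample:
    """One melt curve on the canonical 60–95 °C / 0.1 °C grid.

    F(T) = baseline(T) + A * sum_i w_i * sigma((Tm_i + J - T)/s) + eps(T)
    with J ~ N(0, tm_jitter_sd^2) drawn once per sample and eps iid
    N(0, noise_sd^2) per reading.
    """
    T = canonical_grid()
    F = cfg.baseline_intercept + cfg.baseline_slope * (T - T[0])
    jitter = rng.normal(0.0, cfg.tm_jitter_sd) if cfg.tm_jitter_sd > 0 else 0.0
    for tm, w in _species(spec, genotype, cfg):
        F = F + cfg.amplitude * w * expit((tm + jitter - T) / cfg.transition_slope)
    if cfg.noise_sd > 0:
        F = F + rng.normal(0.0, cfg.noise_sd, size=T.size)
    curve = MeltCurve(sample_id=sample_id, locus=spec.name, temperatures=T, fluorescence=F)
    return SimulatedSample(curve=curve, genotype=genotype, role=role)


def simulate_dataset(
    spec: LocusSpec,
    panel: Sequence[Genotype] | None = None,
    n_standards: int = 8,
    n_unknowns: int = 20,
    cfg: SimulationConfig | None = None,
) -> list[SimulatedSample]:
    """A full study design: standards and unknowns for every panel genotype.

    Defaults emulate the published designs: the locus's genotype panel
    with 7–10 (default 8) training standards per genotype.  Each sample
    draws from its own RNG substream keyed by (seed, sample index), so
    the dataset is reproducible and independent of generation order.
    """
    cfg = cfg or SimulationConfig()
    panel = list(panel) if panel is not None else list(spec.panel)
    if not panel:
        raise ContractError("genotype panel must be non-empty")
    samples: list[SimulatedSample] = []
    index = 0
    for genotype in panel:
        for j in range(n_standards):
            rng = np.random.default_rng([cfg.seed, index])
            samples.append(
                simulate_curve(
                    spec, genotype, cfg, rng,
                    sample_id=f"{spec.name}-std-{genotype.allele_a}-{genotype.allele_b}-{j}",
                    role="standard",
                )
            )
            index += 1
    for genotype in panel:
        for j in range(n_unknowns):
            rng = np.random.default_rng([cfg.seed, index])
            samples.append(
                simulate_curve(
                    spec, genotype, cfg, rng,
                    sample_id=f"{spec.name}-unk-{genotype.allele_a}-{genotype.allele_b}-{j}",
                    role="unknown",
                )
            )
            index += 1
    return samples
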