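# meltstr

STR genotype prediction from high-resolution melt (HRM) curves.

## The problem

Forensic DNA workflows reveal stochastic problems (allele drop-out,
mixtures) only at the final capillary-electrophoresis stage. qPCR
instruments, used much earlier for quantification, can record
high-resolution melt curves: fluorescence of a dye-saturated amplicon
falling as temperature ramps from 60 to 95 °C in 0.1 °C steps. For a
short tandem repeat (STR) locus, each allele's amplicon length — flank
plus 4 bp per repeat — shifts its melting temperature by a fraction of a
degree, so the shape of the melt curve carries (noisy, heavily
overlapping) genotype information. `meltstr` implements and evaluates
two ways of decoding it, for the D5S818 and D18S51 loci:

- **LDA on peak features.** The negative derivative −dF/dT peaks at
  each melting transition. Every sample is summarized as a fixed-length
  vector of (temperature, height) pairs — the primary peak, its
  shoulders (resolved or terrace-like), padded at 64.95 °C when fewer
  than k features are found (k = 3 for D5S818, 4 for D18S51). Linear
  discriminant analysis assigns the genotype c maximizing

      δ_c(x) = xᵀ Σ⁻¹ μ_c − ½ μ_cᵀ Σ⁻¹ μ_c + ln π_c

  with per-class means μ_c and a pooled within-class covariance Σ
  estimated from training "standards" of known genotype.

- **PCA score-space typing.** Normalized derivative curves are
  projected onto the leading principal components of the standards;
  each genotype forms a Gaussian cluster in score space, and an unknown
  receives the highest-posterior class — or `UNCLASSIFIED` beyond a
  χ²(m) Mahalanobis cutoff. This is an open, serializable counterpart
  to commercial cluster-typing software; the fitted model types later
  runs without re-running the standards.

Predictions are scored with confusion matrices and every statistic a
genotyping study reports: overall/micro/macro accuracy, homozygous vs
heterozygous splits, per-class recall, the near-miss rate
(misclassifications with one allele right and the other off by a single
repeat), and **geno-group** accuracies, where easily confused genotypes
are merged to trade resolution for accuracy (both by post-hoc matrix
collapsing and by retraining on group labels).

Because the original raw melt curves are not public, the package ships
a synthetic-data module that emulates the study design: per-allele
logistic melting transitions, Tm tracking amplicon length and GC
content, per-sample thermal jitter, reading noise, and an optional
heteroduplex species. The published confusion matrices themselves are
packaged as count-table fixtures, so every derivable statistic is
reproduced exactly from raw counts.

## Worked example

```python
from meltstr import (load_locus, simulate_dataset, features_from_curve,
                     fit_lda, predict_lda_batch, build_confusion, accuracy)
from meltstr.synthetic_data import SimulationConfig

spec = load_locus("D5S818")
cfg = SimulationConfig(tm_coeffs=(74.3, 41.0, 1850.0), seed=1)  # ~0.25 °C/repeat
samples = simulate_dataset(spec, n_standards=8, n_unknowns=20, cfg=cfg)
standards = [s for s in samples if s.role == "standard"]
unknowns  = [s for s in samples if s.role == "unknown"]

model = fit_lda([features_from_curve(s.curve, k=3) for s in standards],
                [s.genotype.label for s in standards])
pred, post = predict_lda_batch(model, [features_from_curve(s.curve, k=3) for s in unknowns])
cm = build_confusion([s.genotype.label for s in unknowns], pred, model.class_labels)
print(f"held-out accuracy: {accuracy(cm):.4f}")
```

prints `held-out accuracy: 0.9571` — 140 unknowns over the 7-genotype
panel, against a 1-in-7 chance rate of 0.1429. In this well-separated
regime one repeat unit moves Tm by ≥ 0.25 °C, so the peak features are
learnable; with the default coefficients (~0.1 °C per repeat, matching
the real assay's difficulty) the same pipeline lands near 59% — the
regime the published experiments lived in.

The `examples/` directory has one narrative script per capability
(simulation, feature extraction, LDA prediction, PCA typing, confusion
statistics and geno-groups). The same pipeline is scriptable from the
shell:

```bash
meltstr simulate --locus D5S818 --seed 7 --out-curves c.csv --out-metadata m.tsv
meltstr features --curves c.csv --metadata m.tsv --locus D5S818 --out f.tsv
meltstr train    --classifier lda --features f.tsv --model-out lda.json
meltstr predict  --classifier lda --model lda.json --features f.tsv --out p.tsv
meltstr evaluate --predictions p.tsv --locus D5S818 --grouping A
meltstr reproduce-tables
```

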