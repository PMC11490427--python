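"""Recompute every published statistic from the reference count tables.

The packaged fixtures hold the known-by-predicted confusion matrices of
the original D5S818/D18S51 HRM genotyping experiments (PCA- and
LDA-based predictions).  This script derives the reported accuracies,
homozygous/heterozygous splits, near-miss rate and per-class recall
from the raw counts, and shows what geno-group collapsing does to a
genotype-level matrix.
"""

from meltstr import (
    accuracy,
    chance_rate,
    collapse_confusion,
    load_reference_confusion,
    load_schemes,
    near_miss_rate,
    per_class_recall,
    subset_accuracy,
)

d5_lda = load_reference_confusion("confusion_d5s818_lda")
d5_pca = load_reference_confusion("confusion_d5s818_pca")
d18_pca = load_reference_confusion("confusion_d18s51_pca")
d18_lda = load_reference_confusion("confusion_d18s51_lda")

homo = [l for l in d5_lda.labels if l.split(",")[0][1:] == l.split(",")[1][:-1]]
het = [l for l in d5_lda.labels if l not in homo]

print("D5S818, LDA predictions:")
print(f"  overall accuracy      {100 * accuracy(d5_lda):6.2f}%  "
      f"({d5_lda.trace}/{d5_lda.total}; chance {100 * chance_rate(7):.2f}%)")
print(f"  homozygous (micro)    {100 * subset_accuracy(d5_lda, homo, 'micro'):6.2f}%")
print(f"  heterozygous (micro)  {100 * subset_accuracy(d5_lda, het, 'micro'):6.2f}%")

print("D5S818, PCA predictions:")
print(f"  homozygous (macro)    {100 * subset_accuracy(d5_pca, homo, 'macro'):6.2f}%")
print(f"  heterozygous (macro)  {100 * subset_accuracy(d5_pca, het, 'macro'):6.2f}%")

print("D18S51, PCA predictions:")
print(f"  overall accuracy      {100 * accuracy(d18_pca):6.2f}%  "
      f"({d18_pca.misclassified} misclassified)")
print(f"  near-miss rate        {100 * near_miss_rate(d18_pca):6.2f}%  "
      "(one allele right, the other off by one repeat)")
print(f"  recall of (12,16)     {100 * per_class_recall(d18_pca)['(12,16)']:6.2f}%  "
      "(largest allele-size gap, most distinct curve)")

print(f"D18S51, LDA predictions: overall accuracy {100 * accuracy(d18_lda):6.2f}%")

scheme = load_schemes("D5S818")["A"]
grouped = collapse_confusion(d5_lda, scheme)
print(f"\ngeno-group scheme {scheme.name}: "
      f"{len(d5_lda.labels)} genotypes -> {len(grouped.labels)} groups")
print(f"  collapsed accuracy    {100 * accuracy(grouped):6.2f}%  "
      f"({grouped.trace}/{grouped.total})")
print("  merging easily confused genotypes converts their mutual errors into")
print("  within-group hits - resolution traded for accuracy.")
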