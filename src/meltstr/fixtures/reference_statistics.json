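{
  "d5s818_lda_overall_accuracy_pct": {"fixture": "confusion_d5s818_lda", "statistic": "accuracy", "expected": 58.92},
  "d18s51_pca_overall_accuracy_pct": {"fixture": "confusion_d18s51_pca", "statistic": "accuracy", "expected": 40.38},
  "d18s51_lda_overall_accuracy_pct": {"fixture": "confusion_d18s51_lda", "statistic": "accuracy", "expected": 45.10},
  "d5s818_lda_homozygous_accuracy_pct": {"fixture": "confusion_d5s818_lda", "statistic": "homozygous_micro", "expected": 65.08},
  "d5s818_lda_heterozygous_accuracy_pct": {"fixture": "confusion_d5s818_lda", "statistic": "heterozygous_micro", "expected": 55.74},
  "d5s818_pca_homozygous_accuracy_pct": {"fixture": "confusion_d5s818_pca", "statistic": "homozygous_macro", "expected": 39.58},
  "d5s818_pca_heterozygous_accuracy_pct": {"fixture": "confusion_d5s818_pca", "statistic": "heterozygous_macro", "expected": 20.18},
  "d18s51_pca_misclassified_count": {"fixture": "confusion_d18s51_pca", "statistic": "misclassified", "expected": 62},
  "d18s51_pca_near_miss_pct": {"fixture": "confusion_d18s51_pca", "statistic": "near_miss", "expected": 40.32},
  "d18s51_pca_recall_12_16_pct": {"fixture": "confusion_d18s51_pca", "statistic": "recall:(12,16)", "expected": 57.14},
  "chance_rate_7_genotypes_pct": {"fixture": null, "statistic": "chance:7", "expected": 14.29}
}
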