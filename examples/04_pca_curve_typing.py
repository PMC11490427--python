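"""Type unknown melt curves by PCA scores and per-class Gaussians.

Normalized derivative curves are projected onto the leading principal
components of the training standards; each genotype forms a Gaussian
cluster in score space.  An unknown gets the highest-posterior class,
or UNCLASSIFIED when it is too far (in Mahalanobis distance) from
every cluster.  The fitted model is serializable, so standards do not
need to be re-run alongside later unknowns.
"""

import numpy as np

from meltstr import (
    UNCLASSIFIED,
    compute_derivative,
    fit_pca_typing,
    load_locus,
    normalize_curve,
    simulate_dataset,
    type_unknown,
)
from meltstr.synthetic_data import SimulationConfig

spec = load_locus("D5S818")
cfg = SimulationConfig(tm_coeffs=(74.3, 41.0, 1850.0), seed=5)
samples = simulate_dataset(spec, n_standards=8, n_unknowns=15, cfg=cfg)

grid = None
X_tr, y_tr, X_te, y_te = [], [], [], []
for s in samples:
    g, v = normalize_curve(compute_derivative(s.curve))
    grid = g
    if s.role == "standard":
        X_tr.append(v)
        y_tr.append(s.genotype.label)
    else:
        X_te.append(v)
        y_te.append(s.genotype.label)

model = fit_pca_typing(np.array(X_tr), y_tr, grid, m=2)
share = model.explained_variance / model.explained_variance.sum()
print(f"fitted {model.m} components on {len(y_tr)} standards; "
      f"variance split {np.round(share, 3)}")

results = [type_unknown(model, v) for v in X_te]
hits = sum(r.label == t for r, t in zip(results, y_te))
n_uncl = sum(r.label == UNCLASSIFIED for r in results)
print(f"typing accuracy: {hits}/{len(y_te)} = {hits / len(y_te):.4f} "
      f"({n_uncl} unclassified)")
for r, t in list(zip(results, y_te))[:5]:
    print(f"   true {t} -> {r.label:<12} top posterior {r.posteriors.max():.3f} "
          f"Mahalanobis {r.mahalanobis:.2f}")

model.to_json("d5s818_pca_model.json")
print("\nmodel saved to d5s818_pca_model.json; reload it later with")
print("PCAModel.from_json to type new unknowns without the standards.")
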