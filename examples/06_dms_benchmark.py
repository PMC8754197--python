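"""Benchmark classifier predictions against a DMS-style fitness screen.

Trains on 80% of a synthetic dataset, predicts pathogenicity probabilities
for the held-out 20%, simulates a deep-mutational-scanning experiment on
those variants (fitness falls with true pathogenicity, plus measurement
noise) and reports the absolute Spearman correlation, MSE and coverage.
"""

import numpy as np
import pandas as pd

from savpred import (
    FixtureSpec,
    TrainParams,
    benchmark_dms,
    impute,
    predict_proba,
    synth_dms,
    synth_feature_dataset,
    train,
)

spec = FixtureSpec(seed=5, n_pathogenic=2000, n_neutral=2000,
                   missingness=0.1)
matrix, labels, _ = synth_feature_dataset(spec)
y = labels.to_numpy().astype(int)

rng = np.random.default_rng(5)
order = rng.permutation(len(matrix))
test_idx, train_idx = order[:800], order[800:]
mask = np.zeros(len(matrix), dtype=bool)
mask[train_idx] = True
filled = impute(matrix, mask)

model = train(filled.df.iloc[train_idx], y[train_idx], TrainParams(seed=5))
probs = predict_proba(model, filled.df.iloc[test_idx])

idx = pd.Index(range(len(test_idx)))
dms = synth_dms(pd.Series(y[test_idx], index=idx, dtype=float),
                noise_sd=0.5, seed=5)
report = benchmark_dms(pd.Series(probs, index=idx), dms)

print(f"held-out variants: {report.n_shared} "
      f"(coverage {report.coverage:.0%})")
print(f"|Spearman rho| = {report.spearman_abs:.3f}: higher predicted "
      "pathogenicity tracks lower measured fitness")
print(f"MSE = {report.mse:.2f} (probabilities and fitness live on "
      "different scales, so rank correlation is the headline number)")
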