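#!/usr/bin/env python
"""Fit the seven-model family on the synthetic dataset and compare.

Reproduces the analysis machinery on synthetic data: the Bayes-only model MO,
the five computed-score models MOA_XB_X, and the judged-score model MOAB are
fitted by ML, compared by AIC and LR tests against MO, and the non-nested
pairs are compared by Vuong's and Clarke's tests.  Writes
results/model_comparison.csv, results/pairwise_tests.csv and
results/best_model_coefficients.csv.
"""

from pathlib import Path

import pandas as pd

from explanationism import (GeneratorConfig, compare_models, generate_dataset,
                            study_model_family)

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

table = generate_dataset(GeneratorConfig(seed=20260927))
report = compare_models(table, study_model_family(), baseline="MO")
report.to_csv(out_dir / "model_comparison.csv")

pairs = pd.DataFrame([{
    "test": r.test, "model_a": r.model_a, "model_b": r.model_b,
    "statistic": r.statistic, "p": r.p, "preferred": r.preferred,
} for r in report.pairwise])
pairs.to_csv(out_dir / "pairwise_tests.csv", index=False, float_format="%.6g")

best = report.fits[report.best]
best.coef.round(4).to_csv(out_dir / "best_model_coefficients.csv")

print(report.table.round(3).to_string(index=False))
print(f"\nBest model by AIC: {report.best} "
      f"(R2 = {best.r2:.3f}); the generating model was MOA_G3B_G3.")
mo, g3 = report.fits["MO"], report.fits["MOA_G3B_G3"]
print(f"AIC gap MO - MOA_G3B_G3: {mo.aic - g3.aic:.2f} "
      "(published analysis: 48.06 on the real data).")
print("\nBest-model coefficients:")
print(best.coef.round(4).to_string())
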