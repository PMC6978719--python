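"""The nonparametric statistics used by the cohort analyses, standalone.

Demonstrates the Friedman test for repeated measurements with its
Wilcoxon/Bonferroni post-hoc, Spearman and covariate-adjusted (partial)
rank correlation, the chi-square test of independence, and Cohen's kappa —
each computed from its defining formula.
"""

import numpy as np

from icas_hemoflow import (
    chi_square_independence,
    cohen_kappa,
    friedman_test,
    pairwise_posthoc,
    partial_spearman,
    spearman_rank,
)

rng = np.random.default_rng(0)

# Repeated measurements: 12 lesions x 3 locations, the third one elevated.
X = rng.normal(size=(12, 3))
X[:, 2] += 1.5
fr = friedman_test(X)
print(f"Friedman: Q = {fr.statistic:.3f}, df = {fr.df}, p = {fr.p_value:.4g}")
for res in pairwise_posthoc(X):
    print(f"  {res.name}: W+ = {res.statistic:.1f}, "
          f"p = {res.p_value:.4g}, Bonferroni p = {res.adjusted_p:.4g}")

# Correlation with and without covariate adjustment.
age = rng.uniform(50, 80, 40)
x = rng.normal(size=40) + 0.05 * age
y = rng.normal(size=40) + 0.05 * age
print(f"\nSpearman r_s          = {spearman_rank(x, y).r_s:+.3f} "
      "(confounded by age)")
print(f"partial Spearman r_s  = "
      f"{partial_spearman(x, y, age.reshape(-1, 1)).r_s:+.3f} "
      "(age adjusted)")

# Proportions and agreement.
chi = chi_square_independence([[12, 5], [6, 14]])
print(f"\nchi-square = {chi.statistic:.3f}, df = {chi.df}, "
      f"p = {chi.p_value:.4g}")
kap = cohen_kappa([[20, 5], [10, 15]])
print(f"Cohen's kappa = {kap.statistic:.3f} "
      f"(observed {kap.extra['p_observed']:.2f} vs "
      f"chance {kap.extra['p_expected']:.2f} agreement)")
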