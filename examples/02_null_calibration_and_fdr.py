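"""Why discrete nulls need their own calibration and FDR control.

Simulates 1000 null genes with heterogeneous carrier totals, samples
exact-null P values from each gene's support CDF, and compares the
empirical inflation factor (centered at 1) with the two uniform-assumption
estimators (biased).  Then plants a handful of true signals and compares
Benjamini-Hochberg with the resampling-based and discrete step-down
adjustments.
"""

import numpy as np

from raresum import (
    bh_adjust,
    discrete_stepdown_adjust,
    estimate_lambda_emp,
    estimate_lambda_trapd,
    expected_order_statistics,
    rbh_adjust,
    sample_null_pvalues,
    simulate_null_supports,
)

supports, observed, margins = simulate_null_supports(
    1000, n_cases=336, n_controls=8175, k_max=60, seed=7
)
npm = sample_null_pvalues(supports, 200, seed=8)
expected = expected_order_statistics(npm)

lam = estimate_lambda_emp(observed, expected)
lam_q = estimate_lambda_trapd(observed, "q05_095")
lam_2p = estimate_lambda_trapd(observed, "two_points")
print("pure-null cohort, exact-test P values:")
print(f"  lambda_emp       = {lam.value:.3f}   (exact-null expected ranks)")
print(f"  lambda_0.5-0.95  = {lam_q.value:.3f}   (uniform assumption)")
print(f"  lambda_2points   = {lam_2p.value:.3f}   (uniform assumption)")
print("  -> only the exact-null estimator is centered at 1\n")

# plant 10 strong signals: replace their observed P by their support minimum
rng = np.random.default_rng(9)
signal = rng.choice(len(observed), size=10, replace=False)
mixed = observed.copy()
for g in signal:
    mixed[g] = supports[g].pvalues[0]

for name, adj in (
    ("BH", bh_adjust(mixed)),
    ("RBH_UL", rbh_adjust(mixed, npm, variant="UL")),
    ("ADBH_SD", discrete_stepdown_adjust(mixed, supports)),
):
    rejected = set(np.flatnonzero(adj <= 0.05).tolist())
    true_hits = len(rejected & set(signal.tolist()))
    print(
        f"{name:>8}: {len(rejected):2d} rejections at FDR 0.05, "
        f"{true_hits}/10 planted signals recovered"
    )
print("\nThe discrete-aware methods reject at least as many true signals as BH.")
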