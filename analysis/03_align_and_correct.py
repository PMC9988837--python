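"""Symmetrize, Procrustes-align and covariate-correct the selected cohort.

Reports the alignment diagnostics (iterations, centroid-size distribution
by region) and verifies that the PLSR covariate correction decorrelates the
shapes from every covariate while preserving the grand mean.
"""

import numpy as np
import pandas as pd

import common
from morphancestry.covariate_model import STANDARD_COVARIATES

cohort, assignment, aligned, corrected = common.corrected_cohort()
labels = cohort.region_labels()
common.RESULTS.mkdir(parents=True, exist_ok=True)

size_rows = []
for region in cohort.region_names:
    sizes = aligned.centroid_sizes[labels == region]
    size_rows.append({"region": region, "n": len(sizes),
                      "centroid_size_mean": sizes.mean(),
                      "centroid_size_sd": sizes.std(ddof=1)})
sizes_df = pd.DataFrame(size_rows)
sizes_df.to_csv(common.RESULTS / "03_centroid_sizes.csv", index=False,
                float_format="%.4f")

X = cohort.covariates.design_matrix(STANDARD_COVARIATES)
resid = corrected.shapes.coords.reshape(corrected.shapes.n, -1)
max_r = max(
    float(np.abs(np.corrcoef(np.column_stack([X[:, [j]], resid]).T)[0, 1:]).max())
    for j in range(X.shape[1]))
mean_drift = float(np.abs(corrected.shapes.coords.mean(0)
                          - aligned.shapes.coords.mean(0)).max())

summary = pd.DataFrame([{
    "n": corrected.shapes.n,
    "L": corrected.shapes.n_landmarks,
    "gpa_iterations": aligned.iterations_used,
    "gpa_converged": aligned.converged,
    "max_abs_corr_resid_vs_covariates": max_r,
    "grand_mean_drift": mean_drift,
}])
summary.to_csv(common.RESULTS / "03_correction_summary.csv", index=False)

print(sizes_df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nGPA converged in {aligned.iterations_used} iterations; "
      f"covariate correction leaves max |r| = {max_r:.2e} against the "
      f"{X.shape[1]} covariates; grand-mean drift {mean_drift:.2e} "
      "(correction preserves the mean face).")
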