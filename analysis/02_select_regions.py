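"""Regional assignment: argmax labels, median thresholds, balanced draw.

Reproduces the cohort-composition table of the selection protocol: each
individual is labelled by its maximum admixture proportion, each region is
thresholded at the median of those maxima (inclusive), and 186 survivors
per region are drawn at random.
"""

import pandas as pd

import common
import morphancestry as ma

cohort = common.make_cohort()
assignment = ma.assign_max_region(cohort.q, list(cohort.region_names))
filtered = ma.median_threshold_filter(assignment)
final = ma.balanced_subsample(filtered, common.N_PER_REGION,
                              seed=common.STUDY_SEED)

common.RESULTS.mkdir(parents=True, exist_ok=True)
table = final.counts()
table["n_above_median"] = [
    int(filtered.table[(filtered.table.region == r)
                       & filtered.table.selected].shape[0])
    for r in final.region_names]
labels_true = pd.Series(cohort.true_region, index=cohort.q.ids)
table["argmax_matches_truth_pct"] = [
    100.0 * (final.table[final.table.region == r].index.map(labels_true) == r
             ).mean()
    for r in final.region_names]
table = table[["region", "n_members", "median_max_proportion",
               "n_above_median", "n_selected", "argmax_matches_truth_pct"]]
table.to_csv(common.RESULTS / "02_regional_selection.csv", index=False,
             float_format="%.4f")

print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\ntotal selected: {final.table.selected.sum()} "
      f"(target {common.N_PER_REGION} per region)")
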