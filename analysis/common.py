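"""Shared study conditions for the numbered analysis scripts.

The scripts run the full protocol on a synthetic cohort scaled for a
single-CPU desk run: 500 quasi-landmarks instead of 7160 and 1,000
permutations instead of 10,000; everything else (186 per region, 4 ancestry
PCs, 20 tested PCs, 96% shape-PCA variance) follows the study protocol.
Each script regenerates the cohort deterministically from STUDY_SEED, so
they can be run independently and in any order.
"""

from pathlib import Path

import morphancestry as ma
from morphancestry.covariate_model import STANDARD_COVARIATES

STUDY_SEED = 2023
N_PER_REGION = 186
N_LANDMARKS = 500
N_PERMUTATIONS = 1_000
K_ANCESTRY_PCS = 4
K_TESTED_PCS = 20

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def generator_config() -> ma.GeneratorConfig:
    # oversample so the median-threshold selection has individuals to drop
    return ma.GeneratorConfig(n_per_region=2 * N_PER_REGION,
                              n_landmarks=N_LANDMARKS, seed=STUDY_SEED)


def make_cohort() -> ma.SyntheticCohort:
    return ma.generate_cohort(generator_config())


def selected_cohort():
    """Regional selection applied to the oversampled cohort."""
    cohort = make_cohort()
    assignment = ma.select_cohort(cohort.q, N_PER_REGION, seed=STUDY_SEED,
                                  region_names=list(cohort.region_names))
    return cohort.subset(assignment.selected_mask()), assignment


def corrected_cohort():
    """Symmetrized, aligned, covariate-corrected selected cohort."""
    cohort, assignment = selected_cohort()
    sym = ma.symmetrize_cohort(cohort.shapes, cohort.template)
    aligned = ma.gpa(sym)
    cohort.covariates.table["centroid_size"] = aligned.centroid_sizes
    corrected = ma.correct(
        aligned.shapes, cohort.covariates.design_matrix(STANDARD_COVARIATES),
        predictor_names=list(STANDARD_COVARIATES))
    return cohort, assignment, aligned, corrected
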