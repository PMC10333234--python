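"""Phenotype prediction with Pearson-kernel ridge under nested grouped CV.

Generates a cohort whose phenotype is linear in 10 true-FC edges, predicts
it from the ground-truth FC features with confound-consistent nested CV, and
contrasts it with a pure-noise target.
"""

import numpy as np

import cofluct as cf

cohort = cf.generate_cohort(cf.CohortConfig(
    n_subjects=120, n_parcels=15, subject_snr=2.0, noise_sd=0.3,
    n_families=30, target_spec=[(10, 1.0, 0.3), (0, 0.0, 0.0)],
    target_noise_sd=0.3, seed=3))

features = cohort.true_fc_features()
groups = np.array([cohort.families[s] for s in cohort.subjects])
cv = cf.CVSpec(scheme="grouped_kfold", k_outer=10, k_inner=5, groups=groups,
               seed=0)
confounds = cohort.confounds.values  # age, sex, mean FD

for target in cohort.phenotypes.columns:
    y = cohort.phenotypes[target].values
    res = cf.run_prediction_cv(features, y, confounds, cv,
                               model="kernel_ridge",
                               metrics=["pearson_r", "r2"])
    print(f"{target}: mean fold r = {res.mean('pearson_r'):.3f}, "
          f"R2 = {res.mean('r2'):.3f}, "
          f"alphas chosen: {sorted(set(res.chosen_params))}")

print("target_0 carries real FC signal and is recovered; target_1 is pure "
      "noise and scores near 0 — the nested, grouped, confound-consistent "
      "CV does not manufacture spurious accuracy.")
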