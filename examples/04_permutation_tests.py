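"""Compare classifiers with permutation tests instead of t tests.

Fold accuracies violate the independence and normality assumptions of a
Student t test, so two permutation tests are used: a paired sign-permutation
test on per-dataset accuracy differences, and a randomized ANOVA comparing
whole accuracy-vs-q curves with q as a blocking factor.
"""

import numpy as np

from gsvc.classify import loso_cv, mean_accuracy, parcel_baselines, vector_baselines
from gsvc.stats import test1_paired_sign, test2_randomized_anova
from gsvc.synthetic import variability_grid

# paired sign-permutation test over 8 zero-overlap datasets
datasets = [ds for _, ds in variability_grid([0.0], [0.0], 8, seed=1, sigma_pix=0.5)]
gsvc = [mean_accuracy(loso_cv(ds, q_per_subject=3)) for ds in datasets]
linear = [vector_baselines(ds, "linear_svc")[0] for ds in datasets]
res = test1_paired_sign(gsvc, linear)
print(f"graph kernel mean {np.mean(gsvc):.3f}, linear SVC mean {np.mean(linear):.3f}")
print(f"paired sign test: mean difference {res.statistic:+.3f}, "
      f"p = {res.p_value:.4f} ({res.n_permutations} sign patterns)")

# randomized ANOVA over accuracy-vs-q curves on 4 datasets
q_list = (3, 6, 9)
curves = []  # (method, q, dataset)
for runner in (lambda ds, q: mean_accuracy(loso_cv(ds, q_per_subject=q)),
               lambda ds, q: parcel_baselines(ds, q, "linear_svc")[0]):
    curves.append([[runner(ds, q) for ds in datasets[:4]] for q in q_list])
res2 = test2_randomized_anova(np.asarray(curves), n_perm=2000, seed=0)
print(f"\naccuracy-vs-q curves over q = {q_list}:")
print(f"randomized ANOVA: F = {res2.statistic:.2f}, p = {res2.p_value:.4f}")
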