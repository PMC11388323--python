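"""Difference-of-influence Granger causality between the two networks.

Per subject, a bivariate VAR (order chosen by AIC) yields Geweke influences
F_{x->y} and F_{y->x} between the early-auditory and boundary-transition
time courses.  Haemodynamic blurring inflates both directions, so the
difference of influence DOI = F_{x->y} - F_{y->x} carries the direction;
a signed-rank test across subjects gives the group verdict.
"""

import numpy as np

from segflow import (
    SimulationConfig,
    default_ground_truth,
    fit_subject_granger,
    group_doi_test,
    simulate_timecourses,
)

cfg = SimulationConfig(n_subjects_per_group=18, n_scans=200, seed=3)
truth = default_ground_truth(cfg)  # coupling 0.4, early -> transition
tcs, ids, _ = simulate_timecourses(truth, cfg)

results = [
    fit_subject_granger(tcs[s, 0], tcs[s, 1], max_order=10, subject_id=ids[s])
    for s in range(len(ids))
]
orders = [r.order_aic for r in results]
dois = np.array([r.doi for r in results])
print(f"{len(results)} subjects; AIC orders: median {int(np.median(orders))}, "
      f"range {min(orders)}-{max(orders)}")
print(f"DOI: median {np.median(dois):.3f}, "
      f"{(dois > 0).sum()}/{len(dois)} positive")

g = group_doi_test(results, alpha=1e-4)
print(f"group signed-rank p = {g.p_raw:.2e} (FDR {g.p_fdr:.2e}) -> "
      f"direction: {g.direction}")
print("'x_causes_y' means the early network's past predicts the transition "
      "network beyond its own past — the planted unidirectional coupling.")
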