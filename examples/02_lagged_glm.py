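"""Lagged voxelwise GLM with Fisher pooling and lag-map clustering.

Each subject's data are residualised against the loudness confound, then
regressed on HRF-convolved copies of the boundary regressor shifted by
-1, 0 and +1 scans (2 s before, at, and after the boundary).  Subject
one-sided p-values are pooled with Fisher's combined-probability test, and
the mean lag maps are clustered to ask which lags engage similar voxels.
"""

import numpy as np

from segflow import (
    SimulationConfig,
    cluster_lag_maps,
    compare_lags,
    fisher_combine,
    fit_subject_glm,
    regress_out_confound,
    simulate_dataset,
)

cfg = SimulationConfig(n_subjects_per_group=6, n_scans=150,
                       grid_shape=(16, 16, 8), seed=7)
ds = simulate_dataset(cfg=cfg)
resid = [regress_out_confound(v, ds.rms) for v in ds.volumes]
glms = [fit_subject_glm(v, ds.scan_regressor) for v in resid]

print("Fisher-pooled activation (min pooled p per lag):")
for i, lag in enumerate(glms[0].lags):
    pooled = fisher_combine(np.stack([g.p_pos[i] for g in glms]), mask=ds.mask)
    print(f"  lag {lag:+d}: min p = {pooled.p.min():.2e}, "
          f"{(pooled.p < 1e-6).sum()} voxels below 1e-6")

maps = compare_lags(glms)
print("Lag-pair Wilcoxon rank-sum comparisons (min voxel p):")
for (a, b), m in maps.items():
    print(f"  lag {a:+d} vs {b:+d}: min p = {m.p.min():.3f}")

mean_maps = {
    f"lag{lag:+d}": np.stack([g.t_stats[i] for g in glms]).mean(axis=0)
    for i, lag in enumerate(glms[0].lags)
}
link = cluster_lag_maps(mean_maps)
print(f"First merge in hierarchical clustering: {link.first_merge()}")
print("Lags whose maps merge first engage the most similar voxels — the "
      "boundary (lag 0) and post-boundary (lag +1) maps pair up, apart "
      "from the pre-boundary (lag -1) map.")
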