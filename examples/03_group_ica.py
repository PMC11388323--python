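"""Group spatial ICA with GICA3 back-reconstruction and lag profiling.

Two-step PCA (per subject, then on the temporally concatenated group data)
feeds a spatial FastICA run over several model orders.  GICA3 back-projects
subject-specific maps and time courses; per component, the group-level lag
tuning of the time courses classifies it as an early (pre-boundary) or
transition (boundary/post-boundary) network.
"""

import numpy as np

from segflow import (
    SimulationConfig,
    match_components,
    profile_lag_significance,
    reduce_two_step,
    regress_out_confound,
    scan_model_orders,
    simulate_dataset,
)

cfg = SimulationConfig(n_subjects_per_group=8, n_scans=150,
                       grid_shape=(16, 16, 8), seed=21)
ds = simulate_dataset(cfg=cfg)
resid = [regress_out_confound(v, ds.rms) for v in ds.volumes]

red = reduce_two_step(resid, subject_dim=25, group_dim=16)
scan = scan_model_orders(red, orders=[2, 4, 6], seed=0)
dec = scan.decompositions[scan.reference_order]
print(f"model orders {scan.orders}, reference order {scan.reference_order}, "
      f"component stability across orders: {np.round(scan.stability, 3)}")

identity = np.abs(dec.subject_maps.mean(axis=0) - dec.group_maps).max()
print(f"GICA3 identity |mean(subject maps) - group map| = {identity:.2e}")

flat = ds.network_maps.reshape(2, -1)
planted = (flat - flat.mean(1, keepdims=True)) / flat.std(1, keepdims=True)
matches = match_components(planted, dec.group_maps, threshold=0.5)
print("planted-network matches (component, |spatial r|):", matches)

prof = profile_lag_significance(dec.subject_timecourses, ds.scan_regressor,
                                tr=cfg.tr, alpha=0.05)
for c, label in enumerate(prof.classification):
    ps = ", ".join(f"lag {l:+d}: p={prof.p[c, j]:.4f}"
                   for j, l in enumerate(prof.lags))
    print(f"  component {c}: {label:>10s}  ({ps})")
print("'early' peaks one scan before the boundary; 'transition' at and "
      "after it — the two planted networks are recovered with that tuning.")
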