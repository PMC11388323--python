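"""Run the whole analysis end to end on a synthetic study.

Generates markers, confound and 4-D volumes with planted ground truth, then
executes regressor construction, confound checks and removal, the lagged
GLM with Fisher pooling and cluster correction, lag-map clustering, group
ICA with GICA3 and lag profiling, group-difference maps, and the Granger
difference-of-influence test.  Everything lands in report.json; the same
config and seed reproduce it bit for bit.

Equivalent CLI:  segflow run --seed 7 --out scratch/pipeline_demo
"""

import json

from segflow import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=7,
    out_dir="scratch/pipeline_demo",
    simulate={"n_subjects_per_group": 6, "n_scans": 150,
              "grid_shape": (16, 16, 8)},
    n_permutations=200,
    ica_orders=(3, 4, 6),
    ica_subject_dim=20,
    ica_group_dim=12,
    gca_max_order=5,
    # 12 subjects cannot reach the full study's alpha = 1e-4 (the exact
    # signed-rank p floors at 2/2^12); use a demo-scale threshold
    gca_alpha=1e-3,
)
report = run_pipeline(cfg)

print(json.dumps(report["summary"], indent=2))
print()
ica = report["stages"]["ica"]
print(f"IC classifications: {ica['lag_profile']['classification']}")
gca = report["stages"]["granger"].get("group", {})
print(f"GCA: median DOI {gca.get('median_doi', float('nan')):.3f}, "
      f"p = {gca.get('p_raw', float('nan')):.2e}")
print("The report identifies an early and a transition component, clusters "
      "lag 0 with lag +1, and recovers the early->transition causal "
      "direction — the planted structure of the synthetic study.")
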