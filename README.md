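# segflow

Brain dynamics of event segmentation during naturalistic music listening —
a tested re-implementation of the full analysis chain, exercised end to end
on synthetic 4-D fMRI data with planted ground truth.

When people listen to music they parse the continuous stream into phrases.
Where many listeners agree a boundary occurred, the brain shows a
stereotyped sequence: one auditory network engages just *before* the
transition, another during and just *after* it, and the first
Granger-causes the second. `segflow` implements every stage needed to make
and test that claim:

- **Boundary regressor** — pool listeners' real-time boundary markers with
  Gaussian kernel density estimation into a continuous salience series
  `s(t) = Σ_j φ((t − t_j)/h)/h` (unnormalised, so it integrates to the
  marker count), resampled to the scan grid and convolved with a canonical
  double-gamma HRF.
- **Lagged GLM** — per subject, regress each voxel (after residualising the
  stimulus RMS confound) on the regressor shifted by −1, 0, +1 scans
  (TR = 2 s); pool one-sided p-values across subjects with Fisher's test,
  −2 Σ ln p ~ χ²(2k); compare lags and groups with Wilcoxon tests.
- **Group spatial ICA + GICA3** — two-step PCA reduction, spatial FastICA
  over a range of model orders, and GICA3 back-reconstruction whose subject
  maps average *exactly* to the group map; per-component lag profiling
  classifies early vs transition networks.
- **Granger difference of influence** — per subject, Geweke influences
  F_{x→y} = ln(RSS_restricted/RSS_full) from a bivariate VAR (AIC order);
  the difference of influence DOI = F_{x→y} − F_{y→x} is robust to the
  spurious bidirectionality that haemodynamic blurring induces; a
  signed-rank test across subjects gives the group direction.
- **Nonparametric inference** — exact Wilcoxon nulls (signed-rank n ≤ 25,
  rank-sum by DP/enumeration), permutation cluster-extent FWE correction,
  Benjamini–Hochberg FDR, and hierarchical clustering of lag maps.

The original fMRI recordings are access-restricted, so the package ships a
first-class synthetic-data module that emulates the study: two listener
groups marking boundaries with salience-dependent participation and jitter,
a weakly boundary-correlated loudness confound, two planted spatial
networks with the early/transition lag tuning, unidirectional causal
coupling between their time courses, and AR(1) voxel noise at a target SNR.
Everything downstream is validated against that planted truth.

## Worked example

`examples/` holds one short script per capability. The end-to-end run:

```bash
python examples/05_full_pipeline.py
```

prints (seed 7, 6+6 subjects, 16×16×8 grid, 150 scans):

```
{
  "confound_pearson_r": 0.06382717679643823,
  "lag_map_first_merge": ["lag+0", "lag+1"],
  "early_component": 1,
  "transition_component": 0,
  "gca_direction": "x_causes_y",
  "runtime_s": 1.45
}
IC classifications: ['transition', 'early', 'transition']
GCA: median DOI 0.408, p = 4.88e-04
```

Reading it: the boundary regressor is essentially uncorrelated with
loudness (r ≈ 0.06); hierarchical clustering joins the lag 0 and lag +1 GLM
maps first, apart from lag −1; ICA finds one component tuned to the scan
before the boundary ("early") and one tuned to the boundary and after
("transition"); and the group DOI test recovers the planted early →
transition causal direction (`x_causes_y`, median DOI 0.41).

The same pipeline is scriptable from the shell:

```bash
segflow run --seed 7 --out out/           # full pipeline -> report.json
segflow simulate --out data/ --seed 3     # just the synthetic study
segflow regressor --markers data/markers.tsv --tr 2 --n-scans 150 --out reg.tsv
segflow gca --timecourses tc.tsv --pair 0,1 --max-order 10
```

## Layout

```
src/segflow/       library (regressor, synthetic, glm, ica, granger,
                   inference, volumes, io, pipeline, cli)
examples/          one narrative script per capability
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical choices, limitations
```
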