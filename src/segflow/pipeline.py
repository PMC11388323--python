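"""End-to-end pipeline driver.

Runs the full analysis in the order of the study: boundary regressor (KDE of
markers) -> confound check and removal -> lagged voxelwise GLM with Fisher
pooling, lag and group contrasts -> group spatial ICA with GICA3
back-reconstruction and lag profiling -> Granger difference-of-influence
between the early and transition components -> agglomerative clustering of
the GLM lag maps.  Emits a machine-readable JSON report plus artifacts;
identical config + seed reproduces the report bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import glm as glm_mod
from . import ica as ica_mod
from . import io as io_mod
from .granger import fit_subject_granger, group_doi_test
from .inference import cluster_correct, cluster_lag_maps
from .regressor import (
    check_confound,
    estimate_salience,
    resample_to_scans,
)
from .synthetic import (
    SimulationConfig,
    default_ground_truth,
    simulate_dataset,
)

__all__ = ["PipelineConfig", "PipelineValidationError", "run_pipeline"]

log = logging.getLogger("segflow")


class PipelineValidationError(ValueError):
    """Raised before any computation when the configuration is invalid."""


@dataclass
class PipelineConfig:
    """Everything one run needs; every tunable lands in the emitted report."""

    seed: int = 0
    out_dir: str = "segflow_out"
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    truth: dict = field(default_factory=dict)  # GroundTruth overrides
    inputs: dict = field(default_factory=dict)  # markers/volumes/rms paths
    bandwidth: float = 2.0
    grid_step: float = 0.1
    hrf: str = "canonical"  # or "identity"
    lags: tuple[int, ...] = (-1, 0, 1)
    forming_threshold: float = 0.001
    n_permutations: int = 200
    ica_subject_dim: int = 20
    ica_group_dim: int = 12
    ica_orders: tuple[int, ...] = (4, 6, 8)
    ica_alpha: float = 0.05
    ica_group_forming_threshold: float = 0.05
    gca_max_order: int = 5
    gca_alpha: float = 1e-4

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lags", "ica_orders"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.inputs:
            for key in ("markers", "volumes", "rms"):
                p = self.inputs.get(key)
                if p is None:
                    raise PipelineValidationError(
                        f"inputs mode requires a '{key}' path"
                    )
                if not Path(p).exists():
                    raise PipelineValidationError(f"missing input file: {p}")
        if not 0 < self.forming_threshold < 1:
            raise PipelineValidationError("forming_threshold must lie in (0, 1)")
        if self.hrf not in ("canonical", "identity"):
            raise PipelineValidationError("hrf must be 'canonical' or 'identity'")

    def defaults_record(self) -> dict:
        d = dataclasses.asdict(self)
        d["lags"] = list(self.lags)
        d["ica_orders"] = list(self.ica_orders)
        return d


def _hrf_arg(cfg: PipelineConfig):
    return "identity" if cfg.hrf == "identity" else None


def _load_inputs(cfg: PipelineConfig):
    """Load pre-recorded markers, 4-D volumes and an RMS series from disk.

    ``inputs`` keys: ``markers`` (TSV), ``volumes`` (a directory of 4-D
    NIfTI files, one per subject, named ``<group>_<subject>.nii[.gz]``),
    ``rms`` (TSV), optional ``mask`` (NIfTI) and ``tr`` (seconds, overrides
    the header).
    """
    vol_dir = Path(cfg.inputs["volumes"])
    paths = sorted(
        list(vol_dir.glob("*.nii")) + list(vol_dir.glob("*.nii.gz"))
    )
    if not paths:
        raise PipelineValidationError(f"no NIfTI volumes found in {vol_dir}")
    mask = None
    if cfg.inputs.get("mask"):
        mask = io_mod.read_mask(cfg.inputs["mask"])
    volumes = []
    for p in paths:
        stem = p.name.split(".")[0]
        group, _, sid = stem.partition("_")
        volumes.append(
            io_mod.read_volume(
                p, mask=mask, tr=cfg.inputs.get("tr"),
                subject_id=sid or stem, group=group,
            )
        )
    mask = volumes[0].mask
    tr = volumes[0].tr
    duration = volumes[0].n_scans * tr
    markers = io_mod.read_markers(cfg.inputs["markers"], duration=duration)
    rms = io_mod.read_regressor_tsv(cfg.inputs["rms"])
    if rms.size != volumes[0].n_scans:
        raise PipelineValidationError(
            f"rms length {rms.size} != n_scans {volumes[0].n_scans}"
        )
    return volumes, markers, rms, tr, mask


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; write artifacts and report.json under out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": cfg.defaults_record(),
        "conventions": {
            "voxel_indices": "0-based",
            "times": "seconds",
            "scan_index": "0-based, value at frame onset",
        },
        "stages": {},
    }
    t0 = time.time()

    def stage(name: str):
        log.info("stage %s at %.1f s", name, time.time() - t0)
        report["stages"][name] = {"t_start_s": round(time.time() - t0, 3)}
        return report["stages"][name]

    # ---- data ----------------------------------------------------------
    st = stage("data")
    if cfg.inputs:
        volumes, markers, rms, tr, mask = _load_inputs(cfg)
        n_scans = volumes[0].n_scans
    else:
        sim_cfg = SimulationConfig(**{**cfg.simulate, "seed": cfg.seed})
        base_truth = default_ground_truth(sim_cfg)
        if cfg.truth:
            base_truth = dataclasses.replace(base_truth, **cfg.truth)
        ds = simulate_dataset(base_truth, sim_cfg, hrf=_hrf_arg(cfg))
        io_mod.ground_truth_to_json(ds.truth, out / "ground_truth.json")
        io_mod.write_markers(ds.markers, out / "markers.tsv")
        io_mod.write_regressor_tsv(ds.rms, out / "rms.tsv")
        volumes, markers, rms, mask = ds.volumes, ds.markers, ds.rms, ds.mask
        tr, n_scans = sim_cfg.tr, sim_cfg.n_scans
    st["n_subjects"] = len(volumes)
    st["n_scans"] = n_scans
    st["grid_shape"] = list(mask.shape)

    # ---- regressor -----------------------------------------------------
    st = stage("regressor")
    reg = estimate_salience(
        markers, bandwidth=cfg.bandwidth, grid_step=cfg.grid_step
    )
    reg = resample_to_scans(reg, tr=tr, n_scans=n_scans)
    io_mod.write_regressor_tsv(reg.scan_values, out / "boundary_regressor.tsv")
    conf = check_confound(reg.scan_values, rms)
    st["confound_check"] = {
        "pearson_r": conf.pearson_r,
        "pearson_p": conf.pearson_p,
        "spearman_rho": conf.spearman_rho,
        "spearman_p": conf.spearman_p,
    }

    # ---- GLM -----------------------------------------------------------
    st = stage("glm")
    resid_vols = [glm_mod.regress_out_confound(v, rms) for v in volumes]
    subject_glms = [
        glm_mod.fit_subject_glm(
            v, reg.scan_values, lags=cfg.lags, hrf=_hrf_arg(cfg), confound=rms
        )
        for v in resid_vols
    ]
    st["fisher"] = {}
    lag_stat_maps = {}
    for i, lag in enumerate(cfg.lags):
        for direction, attr in (("activation", "p_pos"), ("deactivation", "p_neg")):
            pmat = np.stack([getattr(g, attr)[i] for g in subject_glms])
            gm = glm_mod.fisher_combine(pmat, mask=mask, direction=direction)
            st["fisher"][f"lag{lag:+d}_{direction}"] = {
                "min_p": float(np.min(gm.p)),
                "n_voxels_p<0.001": int((gm.p < 0.001).sum()),
            }
        lag_stat_maps[f"lag{lag:+d}"] = np.stack(
            [g.t_stats[i] for g in subject_glms]
        ).mean(axis=0)
    # cluster-corrected group activation per lag (sign-flip on subject t maps)
    st["clusters"] = {}
    for i, lag in enumerate(cfg.lags):
        subj_t = np.zeros((len(subject_glms),) + mask.shape)
        subj_t[:, mask] = np.stack([g.t_stats[i] for g in subject_glms])
        table = cluster_correct(
            subj_t, mask,
            forming_threshold=cfg.forming_threshold,
            scheme="sign_flip",
            n_permutations=cfg.n_permutations,
            seed=cfg.seed + 100 + i,
        )
        table.table.to_csv(out / f"glm_clusters_lag{lag:+d}.tsv", sep="\t",
                           index=False)
        st["clusters"][f"lag{lag:+d}"] = {
            "n_clusters": int(len(table)),
            "n_significant": int(len(table.significant(0.05))),
        }
    lag_cmp = glm_mod.compare_lags(subject_glms)
    st["lag_comparison"] = {
        f"{a:+d}_vs_{b:+d}": {"min_p": float(np.min(m.p))}
        for (a, b), m in lag_cmp.items()
    }
    grp_cmp = {
        lag: glm_mod.compare_groups_glm(subject_glms, lag) for lag in cfg.lags
    }
    st["group_comparison"] = {
        f"lag{lag:+d}": {"min_p": float(np.min(m.p))}
        for lag, m in grp_cmp.items()
    }

    # ---- lag-map clustering -------------------------------------------
    st = stage("lag_map_clustering")
    link = cluster_lag_maps(lag_stat_maps)
    st["first_merge"] = list(link.first_merge())
    st["merge_heights"] = [float(h) for h in link.merges[:, 2]]
    (out / "lag_map_linkage.json").write_text(
        json.dumps({"items": link.item_names, "merges": link.merges.tolist()})
    )

    # ---- ICA -----------------------------------------------------------
    st = stage("ica")
    subject_dim = min(cfg.ica_subject_dim, n_scans - 1)
    group_dim = min(cfg.ica_group_dim, subject_dim * len(resid_vols))
    reduction = ica_mod.reduce_two_step(resid_vols, subject_dim, group_dim)
    orders = [k for k in cfg.ica_orders if k <= group_dim]
    scan = ica_mod.scan_model_orders(reduction, orders, seed=cfg.seed)
    decomp = scan.decompositions[scan.reference_order]
    profile = ica_mod.profile_lag_significance(
        decomp.subject_timecourses,
        reg.scan_values,
        lags=cfg.lags,
        tr=tr,
        hrf=_hrf_arg(cfg),
        alpha=cfg.ica_alpha,
    )
    io_mod.write_timecourses(
        decomp.subject_timecourses, decomp.subject_ids, out / "ic_timecourses.tsv"
    )
    st["model_orders"] = orders
    st["reference_order"] = scan.reference_order
    st["stability"] = [float(s) for s in scan.stability]
    st["lag_profile"] = {
        "classification": profile.classification,
        "p": profile.p.tolist(),
    }

    def _pick(label: str) -> int | None:
        idx = [i for i, c in enumerate(profile.classification) if c == label]
        if not idx:
            return None
        return int(min(idx, key=lambda i: float(np.min(profile.p[i]))))

    early_ic, trans_ic = _pick("early"), _pick("transition")
    st["early_component"] = early_ic
    st["transition_component"] = trans_ic

    st["group_difference"] = {}
    for label, ic in (("early", early_ic), ("transition", trans_ic)):
        if ic is None:
            continue
        gmap, table = ica_mod.compare_groups_ica(
            decomp.subject_maps[:, ic, :],
            decomp.subject_groups,
            mask,
            forming_threshold=cfg.ica_group_forming_threshold,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed + 200 + ic,
        )
        table.table.to_csv(out / f"ica_group_diff_{label}.tsv", sep="\t",
                           index=False)
        st["group_difference"][label] = {
            "n_significant_clusters": int(len(table.significant(0.05)))
        }

    # ---- Granger -------------------------------------------------------
    st = stage("granger")
    if early_ic is None or trans_ic is None:
        st["skipped"] = "early/transition components not both identified"
        gca_direction = "undetermined"
    else:
        results = [
            fit_subject_granger(
                decomp.subject_timecourses[s, early_ic],
                decomp.subject_timecourses[s, trans_ic],
                max_order=cfg.gca_max_order,
                subject_id=decomp.subject_ids[s],
            )
            for s in range(len(decomp.subject_ids))
        ]
        group = group_doi_test(results, alpha=cfg.gca_alpha)
        st["per_subject"] = [
            {
                "subject_id": r.subject_id,
                "order_aic": r.order_aic,
                "order_bic": r.order_bic,
                "f_xy": r.f_xy,
                "f_yx": r.f_yx,
                "doi": r.doi,
            }
            for r in results
        ]
        st["group"] = {
            "statistic": group.statistic,
            "p_raw": group.p_raw,
            "p_fdr": group.p_fdr,
            "median_doi": group.median_doi,
            "direction": group.direction,
        }
        gca_direction = group.direction

    report["summary"] = {
        "confound_pearson_r": conf.pearson_r,
        "lag_map_first_merge": list(link.first_merge()),
        "early_component": early_ic,
        "transition_component": trans_ic,
        "gca_direction": gca_direction,
        "runtime_s": round(time.time() - t0, 2),
    }
    # deterministic report: drop wall-clock timings from the serialized copy
    serializable = json.loads(json.dumps(report, default=float))
    for s in serializable["stages"].values():
        s.pop("t_start_s", None)
    serializable["summary"].pop("runtime_s", None)
    (out / "report.json").write_text(json.dumps(serializable, indent=2,
                                                sort_keys=True))
    return report
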