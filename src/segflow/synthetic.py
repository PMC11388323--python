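"""Synthetic music-listening fMRI data with planted ground truth.

Real boundary-perception fMRI data are access-restricted, so every analysis
stage in this package is exercised on simulated data whose generating truth
is known.  The generator emulates the study conditions:

* ~36 listeners in two groups (musicians / nonmusicians) marking segment
  boundaries in real time — a marked point process clustered around true
  boundary times, with salience-dependent participation and timing jitter,
  plus uniform false alarms;
* a loudness (RMS) confound that is temporally smooth and only weakly
  correlated with the boundary regressor;
* two planted spatial networks — an "early" network loading on the boundary
  regressor one scan before the boundary (lag -1) and a "transition" network
  loading at the boundary and one scan after (lags 0, +1) — with
  unidirectional causal coupling from the early network's time course into
  the transition network's;
* voxel data = network maps x time courses + a share of the RMS confound +
  AR(1) Gaussian noise scaled to a target SNR.

All randomness flows from ``SimulationConfig.seed`` through named
substreams, so identical configurations reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d

from .regressor import (
    BoundaryRegressor,
    MarkerSet,
    gaussian_kernel_density,
    hrf_convolve,
    lag_regressor,
)
from .volumes import VolumeSeries

__all__ = [
    "GroundTruth",
    "SimulationConfig",
    "SimulatedDataset",
    "default_ground_truth",
    "make_network_maps",
    "true_salience_regressor",
    "simulate_markers",
    "simulate_rms",
    "simulate_timecourses",
    "simulate_volumes",
    "simulate_dataset",
]

LAGS = (-1, 0, 1)
NETWORK_NAMES = ("early", "transition")

# fixed substream identifiers so each draw source is independently seeded
_STREAMS = {"markers": 1, "rms": 2, "timecourses": 3, "noise": 4}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], int(extra)])
    )


@dataclass
class GroundTruth:
    """Planted generating truth for a simulated dataset.

    ``lag_weights`` is (2 networks x 3 lags) over lags (-1, 0, +1); row 0 is
    the early network, row 1 the transition network.  ``coupling_coeff`` is
    the VAR cross-coefficient feeding the early network's past into the
    transition network's present (never the reverse).  ``group_gain``
    multiplies the lag weights per group.  ``snr`` is the ratio of network
    signal SD to voxel noise SD.
    """

    boundary_times: np.ndarray
    boundary_salience: np.ndarray
    lag_weights: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.8]])
    )
    coupling_coeff: float = 0.4
    group_gain: dict[str, float] = field(
        default_factory=lambda: {"musician": 1.5, "nonmusician": 1.0}
    )
    noise_ar1: float = 0.3
    snr: float = 1.0
    network_sigma_vox: float = 2.0
    confound_share: float = 0.5
    kde_bandwidth: float = 2.0

    def __post_init__(self) -> None:
        self.boundary_times = np.asarray(self.boundary_times, dtype=float)
        self.boundary_salience = np.asarray(self.boundary_salience, dtype=float)
        if np.any(np.diff(self.boundary_times) <= 0):
            raise ValueError("boundary times must be strictly increasing")
        if self.boundary_times.shape != self.boundary_salience.shape:
            raise ValueError("one salience weight per boundary is required")
        if np.any(self.boundary_salience < 0) or np.any(self.boundary_salience > 1):
            raise ValueError("salience must lie in [0, 1]")
        self.lag_weights = np.asarray(self.lag_weights, dtype=float)
        if self.lag_weights.shape != (2, 3):
            raise ValueError("lag_weights must be 2 networks x 3 lags")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults are desk scale (12+12 subjects, 20x20x10 grid, 150 scans at
    TR = 2 s); the full-scale study (18+18 subjects) is reached by raising
    ``n_subjects_per_group``.
    """

    n_subjects_per_group: int = 12
    n_scans: int = 150
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (20, 20, 10)
    marker_jitter_sd: float = 0.5
    false_alarm_rate: float = 0.5  # events per minute
    rms_boundary_corr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_jitter_sd < 0:
            raise ValueError("marker_jitter_sd must be non-negative")
        if self.false_alarm_rate < 0:
            raise ValueError("false_alarm_rate must be non-negative")
        if not -1 <= self.rms_boundary_corr <= 1:
            raise ValueError("rms_boundary_corr must lie in [-1, 1]")
        if self.n_scans < 3 or self.tr <= 0:
            raise ValueError("need n_scans >= 3 and tr > 0")

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr

    @property
    def groups(self) -> list[str]:
        return ["musician", "nonmusician"]

    def subject_ids(self) -> list[str]:
        return [
            f"{g[0]}{i + 1:02d}"
            for g in self.groups
            for i in range(self.n_subjects_per_group)
        ]

    def subject_groups(self) -> list[str]:
        return [g for g in self.groups for _ in range(self.n_subjects_per_group)]


def default_ground_truth(
    cfg: SimulationConfig, n_boundaries: int | None = None
) -> GroundTruth:
    """Boundary structure typical of phrase-level segmentation.

    Boundaries every ~20-30 s (phrase scale), placed deterministically from
    the config seed, with salience in (0.3, 1]; the stimulus keeps a 20 s
    tail after the last boundary so the haemodynamic response is observed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    usable = cfg.duration - 20.0
    if usable <= 30.0:
        raise ValueError("stimulus too short to place boundaries with a 20 s tail")
    if n_boundaries is None:
        n_boundaries = max(3, int(usable / 25.0))
    times = np.linspace(15.0, usable, n_boundaries)
    times = times + rng.uniform(-4.0, 4.0, size=n_boundaries)
    times = np.sort(np.clip(times, 5.0, usable))
    while np.any(np.diff(times) <= 1.0):  # keep boundaries separated
        times[1:][np.diff(times) <= 1.0] += 1.5
        times = np.sort(times)
    salience = rng.uniform(0.3, 1.0, size=n_boundaries)
    return GroundTruth(boundary_times=times, boundary_salience=salience)


def make_network_maps(
    grid_shape: tuple[int, int, int], sigma: float = 2.0
) -> np.ndarray:
    """Two disjoint non-negative Gaussian-blob networks on the grid.

    Blobs sit at the quarter points of the first axis, are thresholded at 1%
    of their peak, and must not overlap above half maximum.
    """
    nx, ny, nz = grid_shape
    centers = [
        (nx * 0.25, ny * 0.5, nz * 0.5),
        (nx * 0.75, ny * 0.5, nz * 0.5),
    ]
    xx, yy, zz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    maps = []
    for cx, cy, cz in centers:
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        blob = np.exp(-d2 / (2 * sigma**2))
        blob[blob < 0.01 * blob.max()] = 0.0
        maps.append(blob)
    maps = np.stack(maps)
    half = maps > 0.5 * maps.max(axis=(1, 2, 3), keepdims=True)
    if np.any(half[0] & half[1]):
        raise ValueError(
            f"grid {grid_shape} too small to place two disjoint networks "
            f"with sigma={sigma}"
        )
    return maps


def true_salience_regressor(
    truth: GroundTruth, cfg: SimulationConfig
) -> BoundaryRegressor:
    """Salience-weighted KDE of the *true* boundary times on the scan grid.

    This is the regressor an ideal, infinitely large panel of listeners
    would produce; recovery checks compare analysis output against it.
    """
    grid = np.arange(0.0, cfg.duration + 0.05, 0.1)
    density = gaussian_kernel_density(
        truth.boundary_times, grid, truth.kde_bandwidth, weights=truth.boundary_salience
    )
    scan_values = np.interp(np.arange(cfg.n_scans) * cfg.tr, grid, density)
    return BoundaryRegressor(
        fine_times=grid,
        fine_density=density,
        bandwidth=truth.kde_bandwidth,
        tr=cfg.tr,
        scan_values=scan_values,
    )


def simulate_markers(truth: GroundTruth, cfg: SimulationConfig) -> MarkerSet:
    """Simulate each listener's real-time boundary markers.

    A listener marks boundary k with probability equal to its salience, at
    the true time plus Gaussian jitter; uniform false alarms arrive at
    ``false_alarm_rate`` per minute.  Markers are clipped to the stimulus.
    """
    rng = _rng(cfg.seed, "markers")
    times: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for pid, group in zip(cfg.subject_ids(), cfg.subject_groups()):
        hits = rng.random(truth.boundary_times.size) < truth.boundary_salience
        marks = truth.boundary_times[hits]
        if cfg.marker_jitter_sd > 0 and marks.size:
            marks = marks + rng.normal(0.0, cfg.marker_jitter_sd, size=marks.size)
        n_fa = rng.poisson(cfg.false_alarm_rate * cfg.duration / 60.0)
        fas = rng.uniform(0.0, cfg.duration, size=n_fa)
        all_marks = np.clip(np.concatenate([marks, fas]), 0.0, cfg.duration)
        times[pid] = np.sort(all_marks)
        groups[pid] = group
    return MarkerSet(marker_times=times, groups=groups, duration=cfg.duration)


def simulate_rms(truth: GroundTruth, cfg: SimulationConfig) -> np.ndarray:
    """Smooth, strictly positive loudness series with a target correlation.

    Construction: mix the standardised true boundary regressor with a
    smoothed, orthogonalised noise series so the sample Pearson correlation
    with the boundary regressor equals ``rms_boundary_corr`` (up to the
    positivity floor), then shift/scale into a positive loudness range.
    """
    r = cfg.rms_boundary_corr
    b = true_salience_regressor(truth, cfg).scan_values.astype(float)
    if np.std(b) == 0:
        raise ValueError("degenerate boundary regressor: cannot target correlation")
    rng = _rng(cfg.seed, "rms")
    noise = gaussian_filter1d(rng.standard_normal(cfg.n_scans), sigma=2.0)
    bz = (b - b.mean()) / b.std()
    noise = noise - noise.mean()
    noise = noise - (noise @ bz) / (bz @ bz) * bz  # orthogonalise
    if np.std(noise) == 0:
        raise ValueError(f"n_scans={cfg.n_scans} too small to realise correlation {r}")
    nz = noise / noise.std()
    mix = r * bz + np.sqrt(1 - r**2) * nz
    out = 1.0 + 0.15 * mix
    if np.any(out <= 0):  # ~5+ sigma event; fold the offending tail up
        out = np.abs(out) + 1e-3
    return out


def _network_signals(
    truth: GroundTruth,
    cfg: SimulationConfig,
    scan_regressor: np.ndarray,
    gain: float,
    hrf: "np.ndarray | str | None",
) -> np.ndarray:
    """Deterministic (noise-free) network signals, (2, n_scans)."""
    sig = np.zeros((2, cfg.n_scans))
    for c in range(2):
        for j, lag in enumerate(LAGS):
            w = truth.lag_weights[c, j]
            if w == 0:
                continue
            lagged = lag_regressor(scan_regressor, lag)
            sig[c] += w * gain * hrf_convolve(lagged, tr=cfg.tr, hrf=hrf)
    return sig


def simulate_timecourses(
    truth: GroundTruth,
    cfg: SimulationConfig,
    scan_regressor: np.ndarray | None = None,
    hrf: "np.ndarray | str | None" = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-subject network time courses with planted causal coupling.

    Returns (tcs, subject_ids, groups) with ``tcs`` of shape
    (n_subjects, 2, n_scans).  Network 1 (early) evolves autonomously;
    network 2 (transition) receives ``coupling_coeff`` times network 1's
    previous sample — a unidirectional VAR(1) cross-term — plus innovation
    noise with SD = signal SD / snr.
    """
    if scan_regressor is None:
        scan_regressor = true_salience_regressor(truth, cfg).scan_values
    ids, groups = cfg.subject_ids(), cfg.subject_groups()
    tcs = np.zeros((len(ids), 2, cfg.n_scans))
    for s, (pid, group) in enumerate(zip(ids, groups)):
        rng = _rng(cfg.seed, "timecourses", extra=s)
        sig = _network_signals(truth, cfg, scan_regressor, truth.group_gain[group], hrf)
        sd_ref = np.std(sig[sig.std(axis=1) > 0]) if np.any(sig.std(axis=1) > 0) else 1.0
        innov_sd = sd_ref / truth.snr
        e = rng.normal(0.0, innov_sd, size=(2, cfg.n_scans))
        tc1 = sig[0] + e[0]
        tc2 = sig[1] + e[1]
        tc2[1:] += truth.coupling_coeff * tc1[:-1]
        tcs[s, 0] = tc1
        tcs[s, 1] = tc2
    return tcs, ids, groups


@dataclass
class SimulatedDataset:
    """Everything one simulated study produces, truth included."""

    truth: GroundTruth
    cfg: SimulationConfig
    markers: MarkerSet
    rms: np.ndarray
    scan_regressor: np.ndarray
    network_maps: np.ndarray  # (2, nx, ny, nz)
    mask: np.ndarray
    timecourses: np.ndarray  # (n_subjects, 2, n_scans)
    volumes: list[VolumeSeries]
    subject_ids: list[str]
    subject_groups: list[str]


def simulate_volumes(
    truth: GroundTruth,
    cfg: SimulationConfig,
    scan_regressor: np.ndarray | None = None,
    rms: np.ndarray | None = None,
    hrf: "np.ndarray | str | None" = None,
) -> tuple[list[VolumeSeries], np.ndarray, np.ndarray, np.ndarray]:
    """Subject 4-D volumes = network maps x time courses + confound + noise.

    Returns (volumes, timecourses, network_maps, mask).  Noise is AR(1) in
    time, independent across voxels, scaled so that the SD of the pooled
    network signal over in-network voxels divided by the noise SD equals
    ``truth.snr``.
    """
    if scan_regressor is None:
        scan_regressor = true_salience_regressor(truth, cfg).scan_values
    if rms is None:
        rms = simulate_rms(truth, cfg)
    maps = make_network_maps(cfg.grid_shape, sigma=truth.network_sigma_vox)
    mask = np.ones(cfg.grid_shape, dtype=bool)
    tcs, ids, groups = simulate_timecourses(truth, cfg, scan_regressor, hrf=hrf)

    in_net = maps.sum(axis=0) > 0
    flat_maps = maps.reshape(2, -1)
    vols: list[VolumeSeries] = []
    for s, (pid, group) in enumerate(zip(ids, groups)):
        signal_flat = flat_maps.T @ tcs[s]  # (n_voxels, n_scans)
        sig_sd = signal_flat[in_net.ravel()].std(axis=1).mean()
        noise_sd = (sig_sd if sig_sd > 0 else 1.0) / truth.snr
        rng = _rng(cfg.seed, "noise", extra=s)
        white = rng.standard_normal((signal_flat.shape[0], cfg.n_scans))
        if truth.noise_ar1 > 0:
            ar = sp_signal.lfilter([1.0], [1.0, -truth.noise_ar1], white, axis=1)
            ar *= np.sqrt(1 - truth.noise_ar1**2)  # unit marginal SD
        else:
            ar = white
        data_flat = (
            signal_flat + truth.confound_share * rms[None, :] + noise_sd * ar
        )
        data = data_flat.reshape(*cfg.grid_shape, cfg.n_scans)
        vols.append(
            VolumeSeries(
                data=data, mask=mask, tr=cfg.tr, subject_id=pid, group=group
            )
        )
    return vols, tcs, maps, mask


def simulate_dataset(
    truth: GroundTruth | None = None,
    cfg: SimulationConfig | None = None,
    hrf: "np.ndarray | str | None" = None,
) -> SimulatedDataset:
    """One full synthetic study: markers, RMS confound, volumes, truth."""
    cfg = cfg or SimulationConfig()
    truth = truth or default_ground_truth(cfg)
    markers = simulate_markers(truth, cfg)
    rms = simulate_rms(truth, cfg)
    reg = true_salience_regressor(truth, cfg)
    vols, tcs, maps, mask = simulate_volumes(
        truth, cfg, scan_regressor=reg.scan_values, rms=rms, hrf=hrf
    )
    return SimulatedDataset(
        truth=truth,
        cfg=cfg,
        markers=markers,
        rms=rms,
        scan_regressor=reg.scan_values,
        network_maps=maps,
        mask=mask,
        timecourses=tcs,
        volumes=vols,
        subject_ids=cfg.subject_ids(),
        subject_groups=cfg.subject_groups(),
    )
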