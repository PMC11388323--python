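"""Boundary-salience regressor construction.

Participants listen to music and press a key at "instants of significant
change".  Pooling those marker times across listeners through kernel density
estimation yields a continuous salience series: high where many listeners
agree a segment boundary occurred, low elsewhere.  This module builds that
regressor, resamples it to the scan grid, produces lagged and HRF-convolved
copies for the GLM design, and runs the loudness-confound association checks.

Conventions: times in seconds; scan index 0-based with the value taken at
frame onset (scan ``i`` covers ``[i*tr, (i+1)*tr)``); the density is
*unnormalised* (kernel-count scale), so it integrates to the total number of
markers and is comparable across stimuli with different marker counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .hrf import double_gamma_hrf, identity_hrf

__all__ = [
    "MarkerSet",
    "BoundaryRegressor",
    "ConfoundCheck",
    "gaussian_kernel_density",
    "estimate_salience",
    "resample_to_scans",
    "lag_regressor",
    "hrf_convolve",
    "compute_rms",
    "check_confound",
]


@dataclass
class MarkerSet:
    """Per-participant boundary marker times with group labels.

    ``marker_times`` maps participant id to a sorted array of event times in
    seconds; ``groups`` maps participant id to a group label (e.g.
    ``"musician"`` / ``"nonmusician"``).  ``duration`` is the stimulus length
    in seconds.
    """

    marker_times: dict[str, np.ndarray]
    groups: dict[str, str]
    duration: float

    def __post_init__(self) -> None:
        if set(self.marker_times) != set(self.groups):
            raise ValueError("marker_times and groups must list the same participants")
        for pid, t in self.marker_times.items():
            t = np.sort(np.asarray(t, dtype=float))
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(
                    f"participant {pid!r} has markers outside [0, {self.duration}]"
                )
            self.marker_times[pid] = t

    @property
    def participants(self) -> list[str]:
        return list(self.marker_times)

    def pooled_times(self, group: str | None = None) -> np.ndarray:
        """All marker times concatenated, optionally restricted to a group."""
        arrs = [
            t
            for pid, t in self.marker_times.items()
            if group is None or self.groups[pid] == group
        ]
        if not arrs:
            return np.empty(0)
        return np.sort(np.concatenate(arrs))

    def n_markers(self) -> int:
        return int(sum(t.size for t in self.marker_times.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (pid, self.groups[pid], t)
            for pid in self.participants
            for t in self.marker_times[pid]
        ]
        return pd.DataFrame(rows, columns=["participant_id", "group", "time_s"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, duration: float) -> "MarkerSet":
        required = {"participant_id", "group", "time_s"}
        if not required.issubset(df.columns):
            raise ValueError(f"marker table needs columns {sorted(required)}")
        times: dict[str, np.ndarray] = {}
        groups: dict[str, str] = {}
        for pid, sub in df.groupby("participant_id", sort=False):
            times[str(pid)] = np.sort(sub["time_s"].to_numpy(dtype=float))
            groups[str(pid)] = str(sub["group"].iloc[0])
        return cls(times, groups, duration)


@dataclass
class BoundaryRegressor:
    """Continuous boundary-salience series.

    ``fine_times``/``fine_density`` hold the KDE on a fine regular grid
    (participations per second, unnormalised); ``scan_values`` holds the
    series resampled to the scan grid once :func:`resample_to_scans` has run.
    """

    fine_times: np.ndarray
    fine_density: np.ndarray
    bandwidth: float
    tr: float | None = None
    scan_values: np.ndarray | None = None
    lags_available: tuple[int, ...] = field(default=(-1, 0, 1))

    @property
    def n_scans(self) -> int:
        if self.scan_values is None:
            raise ValueError("regressor has not been resampled to the scan grid")
        return len(self.scan_values)


@dataclass(frozen=True)
class ConfoundCheck:
    """Association between the boundary regressor and the loudness series."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def gaussian_kernel_density(
    times: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Unnormalised Gaussian kernel sum: sum_j w_j * N(t; times_j, bandwidth^2).

    Each kernel integrates to its weight (default 1), so the result
    integrates to the total weight — a count-scale density.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros_like(grid, dtype=float)
    w = np.ones(times.size) if weights is None else np.asarray(weights, dtype=float)
    z = (grid[:, None] - times[None, :]) / bandwidth
    return (np.exp(-0.5 * z**2) @ w) / (bandwidth * np.sqrt(2 * np.pi))


def estimate_salience(
    markers: MarkerSet,
    bandwidth: float = 2.0,
    grid_step: float = 0.1,
    group: str | None = None,
    normalized: bool = False,
) -> BoundaryRegressor:
    """Pool marker times across participants into a continuous salience series.

    The density at time t is the sum over all markers of a Gaussian kernel of
    width ``bandwidth`` seconds, evaluated on a regular grid of step
    ``grid_step`` covering ``[0, duration]``.  ``group`` restricts pooling to
    one participant group; the default pools across groups.  With
    ``normalized=True`` the density is divided by the marker count so it
    integrates to one (a probability density); the default count scale keeps
    peak height proportional to listener consensus.
    """
    if bandwidth <= 0 or grid_step <= 0:
        raise ValueError("bandwidth and grid_step must be positive")
    if not markers.participants:
        raise ValueError("MarkerSet has no participants")
    grid = np.arange(0.0, markers.duration + grid_step / 2, grid_step)
    times = markers.pooled_times(group=group)
    if times.size == 0:
        warnings.warn("no markers present; returning a zero regressor", stacklevel=2)
        density = np.zeros_like(grid)
    else:
        density = gaussian_kernel_density(times, grid, bandwidth)
        if normalized:
            density = density / times.size
    return BoundaryRegressor(fine_times=grid, fine_density=density, bandwidth=bandwidth)


def resample_to_scans(
    reg: BoundaryRegressor, tr: float, n_scans: int
) -> BoundaryRegressor:
    """Linearly interpolate the fine-grid density at scan onsets i*tr."""
    if tr <= 0 or n_scans < 1:
        raise ValueError("tr must be positive and n_scans >= 1")
    scan_times = np.arange(n_scans) * tr
    if scan_times[-1] > reg.fine_times[-1] + 1e-9:
        raise ValueError(
            f"scan grid extends to {scan_times[-1]:g} s but the fine grid ends "
            f"at {reg.fine_times[-1]:g} s"
        )
    values = np.interp(scan_times, reg.fine_times, reg.fine_density)
    return replace(reg, tr=tr, scan_values=values)


def _as_scan_series(reg: "BoundaryRegressor | np.ndarray") -> np.ndarray:
    if isinstance(reg, BoundaryRegressor):
        if reg.scan_values is None:
            raise ValueError("regressor has not been resampled to the scan grid")
        return reg.scan_values
    return np.asarray(reg, dtype=float)


def lag_regressor(reg: "BoundaryRegressor | np.ndarray", lag: int) -> np.ndarray:
    """Shift a scan-grid series by an integer number of scans.

    Positive lag shifts the series later (``out[i] = x[i - lag]``), modelling
    the post-boundary response; samples shifted past either edge are
    zero-filled.
    """
    x = _as_scan_series(reg)
    n = len(x)
    if abs(lag) >= n:
        raise ValueError(f"|lag| = {abs(lag)} must be < n_scans = {n}")
    out = np.zeros_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
    elif lag < 0:
        out[:lag] = x[-lag:]
    else:
        out[:] = x
    return out


def hrf_convolve(
    series: np.ndarray,
    tr: float = 2.0,
    hrf: "np.ndarray | str | None" = None,
) -> np.ndarray:
    """Convolve a scan-grid series with an HRF kernel, truncated to length.

    ``hrf`` may be an explicit kernel, ``"identity"`` (returns the input
    unchanged), or None for the canonical double-gamma sampled at TR.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if isinstance(hrf, str):
        if hrf != "identity":
            raise ValueError(f"unknown HRF name {hrf!r}")
        kernel = identity_hrf()
    elif hrf is None:
        kernel = double_gamma_hrf(tr)
    else:
        kernel = np.asarray(hrf, dtype=float)
    return np.convolve(x, kernel)[: len(x)]


def compute_rms(
    waveform: np.ndarray, rate: float, tr: float, n_scans: int
) -> np.ndarray:
    """Per-scan root-mean-square of an audio waveform.

    Value ``i`` is the RMS of the samples in the window
    ``[i*tr, (i+1)*tr)``; the waveform must cover all ``n_scans`` windows.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim == 2:  # multi-channel: use the first channel
        w = w[:, 0]
    if w.size == 0:
        raise ValueError("empty waveform")
    win = int(round(tr * rate))
    if win < 1:
        raise ValueError("window shorter than one sample; check tr and rate")
    if w.size < win * n_scans:
        raise ValueError(
            f"waveform has {w.size} samples but {win * n_scans} are needed "
            f"for {n_scans} scans of {tr} s at {rate} Hz"
        )
    frames = w[: win * n_scans].reshape(n_scans, win)
    return np.sqrt(np.mean(frames**2, axis=1))


def check_confound(reg: np.ndarray, rms: np.ndarray) -> ConfoundCheck:
    """Pearson and Spearman association between regressor and RMS series.

    A near-zero correlation licenses treating residualised data as free of
    loudness-driven structure.
    """
    x = _as_scan_series(reg)
    y = np.asarray(rms, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return ConfoundCheck(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )
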