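"""Nonparametric group inference on voxel maps.

Cluster-extent family-wise error (FWE) control by max-statistic permutation,
Benjamini-Hochberg FDR adjustment, the exact Wilcoxon signed-rank primitive,
and agglomerative clustering of statistic maps (used to ask whether the lag 0
and lag +1 GLM maps resemble each other more than either resembles lag -1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from ._ranktests import RankTestResult, signed_rank_test

__all__ = [
    "ClusterTable",
    "LinkageResult",
    "cluster_correct",
    "fdr_adjust",
    "wilcoxon_signed_rank",
    "cluster_lag_maps",
]


@dataclass
class ClusterTable:
    """Supra-threshold clusters with permutation-corrected extent p-values.

    ``table`` has one row per cluster: cluster_id, extent (voxels),
    peak_stat, peak_coord, sign, corrected_p.  ``null_max_extent`` is the
    permutation distribution of the maximum cluster extent.
    """

    table: pd.DataFrame
    forming_threshold: float
    n_permutations: int
    null_max_extent: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["corrected_p"] < alpha]


@dataclass
class LinkageResult:
    """Agglomerative merge sequence over statistic maps.

    ``merges`` is the scipy linkage matrix (n-1 rows of
    [idx_a, idx_b, height, size]); ``distance`` the condensed
    one-minus-Pearson distances; ``labels_`` the partition at the chosen cut.
    """

    merges: np.ndarray
    distance: np.ndarray
    item_names: list[str]
    labels_: np.ndarray

    def labels(self, n_clusters: int) -> np.ndarray:
        return fcluster(self.merges, t=n_clusters, criterion="maxclust")

    def first_merge(self) -> tuple[str, str]:
        """Names of the two items joined first."""
        i, j = int(self.merges[0, 0]), int(self.merges[0, 1])
        return self.item_names[i], self.item_names[j]


def _one_sample_t(data: np.ndarray) -> np.ndarray:
    """Vectorised one-sample t over axis 0 (subjects)."""
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def _two_sample_t(data: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance two-sample t over axis 0."""
    a, b = data[is_a], data[~is_a]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return np.where(sp2 > 0, t, 0.0)


def _label_clusters(
    exceed: np.ndarray, structure: np.ndarray
) -> tuple[np.ndarray, int]:
    return ndimage.label(exceed, structure=structure)


def _max_extent(exceed: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(exceed, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_correct(
    subject_maps: np.ndarray,
    mask: np.ndarray,
    forming_threshold: float = 0.001,
    scheme: str = "sign_flip",
    n_permutations: int = 1000,
    seed: int = 0,
    groups: np.ndarray | None = None,
    connectivity: int = 26,
) -> ClusterTable:
    """Cluster-extent FWE correction by max-statistic permutation.

    ``subject_maps`` is (n_subjects, nx, ny, nz).  The observed voxel
    statistic is a one-sample t against zero (``scheme="sign_flip"``) or a
    two-sample t between ``groups`` (``scheme="label_shuffle"``).  Voxels
    with two-sided parametric p below ``forming_threshold`` are labelled into
    connected components (positive and negative excursions separately); the
    null distribution of the maximum cluster extent is built by randomly
    sign-flipping subjects or shuffling group labels, and each observed
    cluster receives corrected_p = (1 + #{perm max >= extent}) / (n_perm + 1).
    """
    if not 0 < forming_threshold < 1:
        raise ValueError("forming_threshold must lie in (0, 1)")
    if scheme not in ("sign_flip", "label_shuffle"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is low; corrected p-values "
            "will be coarse",
            stacklevel=2,
        )
    data = np.asarray(subject_maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n_subj = data.shape[0]
    spatial = data.shape[1:]
    if mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} != map shape {spatial}")
    flat = data.reshape(n_subj, -1)[:, mask.ravel()]
    rng = np.random.default_rng(seed)
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])

    if scheme == "sign_flip":
        dof = n_subj - 1
        t_obs = _one_sample_t(flat)
    else:
        if groups is None:
            raise ValueError("label_shuffle requires group labels")
        labels = np.asarray(groups)
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise ValueError("label_shuffle requires exactly two groups")
        is_a = labels == uniq[0]
        if is_a.sum() < 2 or (~is_a).sum() < 2:
            raise ValueError("each group needs at least 2 subjects")
        dof = n_subj - 2
        t_obs = _two_sample_t(flat, is_a)

    t_crit = stats.t.isf(forming_threshold / 2, dof)

    def volume_exceed(tvals: np.ndarray, sign: int) -> np.ndarray:
        vol = np.zeros(spatial, dtype=bool)
        vol[mask] = sign * tvals > t_crit
        return vol

    # observed clusters, positive and negative excursions kept apart
    rows = []
    t_vol = np.full(spatial, 0.0)
    t_vol[mask] = t_obs
    for sign in (+1, -1):
        exceed = volume_exceed(t_obs, sign)
        labels_vol, n_clust = _label_clusters(exceed, structure)
        for cid in range(1, n_clust + 1):
            sel = labels_vol == cid
            extent = int(sel.sum())
            stat_vals = t_vol[sel]
            peak_idx = np.argmax(np.abs(stat_vals))
            peak_coord = tuple(int(c[peak_idx]) for c in np.nonzero(sel))
            rows.append(
                {
                    "sign": sign,
                    "extent": extent,
                    "peak_stat": float(stat_vals[peak_idx]),
                    "peak_coord": peak_coord,
                }
            )

    # permutation null of the maximum extent (both signs pooled: max |t|)
    null_max = np.zeros(n_permutations, dtype=int)
    if scheme == "sign_flip":
        flips = rng.choice([-1.0, 1.0], size=(n_permutations, n_subj))
        sumsq = (flat**2).sum(axis=0)
        for p in range(n_permutations):
            m = flips[p] @ flat / n_subj
            var = (sumsq / n_subj - m**2) * n_subj / (n_subj - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm = m / np.sqrt(var / n_subj)
            t_perm = np.where(var > 0, t_perm, 0.0)
            exceed = np.zeros(spatial, dtype=bool)
            exceed[mask] = np.abs(t_perm) > t_crit
            null_max[p] = _max_extent(exceed, structure)
    else:
        for p in range(n_permutations):
            perm = rng.permutation(n_subj)
            t_perm = _two_sample_t(flat[perm], is_a)
            exceed = np.zeros(spatial, dtype=bool)
            exceed[mask] = np.abs(t_perm) > t_crit
            null_max[p] = _max_extent(exceed, structure)

    for i, row in enumerate(sorted(rows, key=lambda r: -r["extent"])):
        row["cluster_id"] = i + 1
        row["corrected_p"] = (1 + int((null_max >= row["extent"]).sum())) / (
            n_permutations + 1
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "extent", "peak_stat", "peak_coord", "sign", "corrected_p"],
    )
    if len(table):
        table = table.sort_values("cluster_id").reset_index(drop=True)
    return ClusterTable(
        table=table,
        forming_threshold=forming_threshold,
        n_permutations=n_permutations,
        null_max_extent=null_max,
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (shape-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    adjusted = multipletests(flat, method="fdr_bh")[1]
    return adjusted.reshape(p.shape)


def wilcoxon_signed_rank(values: np.ndarray, mu0: float = 0.0) -> RankTestResult:
    """One-sample Wilcoxon signed-rank test (exact for n <= 25).

    Observations equal to ``mu0`` are dropped; if all are, p = 1.
    """
    return signed_rank_test(values, mu0=mu0)


def cluster_lag_maps(
    maps: "dict[str, np.ndarray] | list[np.ndarray]",
    mask: np.ndarray | None = None,
    method: str = "average",
) -> LinkageResult:
    """Agglomerative clustering of statistic maps under 1 - Pearson distance.

    ``maps`` is a dict name -> volume (or list of volumes); distances are
    computed over in-mask voxels.  Constant maps have undefined correlation
    and raise.
    """
    if method not in ("average", "complete"):
        raise ValueError("linkage method must be 'average' or 'complete'")
    if isinstance(maps, dict):
        names = list(maps)
        vols = [np.asarray(maps[k], dtype=float) for k in names]
    else:
        vols = [np.asarray(v, dtype=float) for v in maps]
        names = [f"map{i}" for i in range(len(vols))]
    if len(vols) < 3:
        raise ValueError("need at least 3 maps to cluster")
    if mask is None:
        flat = np.stack([v.ravel() for v in vols])
    else:
        mask = np.asarray(mask, dtype=bool)
        flat = np.stack([v[mask] for v in vols])
    if np.any(flat.std(axis=1) == 0):
        bad = [names[i] for i in np.nonzero(flat.std(axis=1) == 0)[0]]
        raise ValueError(f"constant map(s) {bad}: correlation distance undefined")
    corr = np.corrcoef(flat)
    dist = 1.0 - corr
    iu = np.triu_indices(len(vols), k=1)
    condensed = dist[iu]
    merges = linkage(condensed, method=method)
    labels_ = fcluster(merges, t=2, criterion="maxclust")
    return LinkageResult(
        merges=merges, distance=condensed, item_names=names, labels_=labels_
    )
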