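"""Group spatial ICA with GICA3 back-reconstruction.

The group decomposition follows the standard temporal-concatenation recipe:

1. per-subject PCA of the time dimension (subject-level reduction),
2. temporal concatenation of the reduced data across subjects,
3. group-level PCA,
4. spatial ICA (FastICA) on the group-reduced data, treating voxels as
   samples so the recovered sources are spatially independent maps.

Because a single "correct" model order is unknowable, the decomposition is
repeated over a range of orders and components are matched across orders by
absolute spatial correlation; components that persist are the stable ones.

Subject-specific maps and time courses are recovered with the GICA3
back-projection, whose defining property — the average of the subject maps
equals the group map — holds here by construction, exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from ._ranktests import signed_rank_test
from .glm import GroupMap, rank_sum_map
from .inference import ClusterTable, cluster_correct
from .regressor import hrf_convolve, lag_regressor
from .volumes import VolumeSeries

__all__ = [
    "Reduction",
    "ICADecomposition",
    "ModelOrderScan",
    "LagProfile",
    "reduce_two_step",
    "fit_spatial_ica",
    "scan_model_orders",
    "back_reconstruct_gica3",
    "profile_lag_significance",
    "compare_groups_ica",
    "match_components",
]

LAGS = (-1, 0, 1)


@dataclass
class Reduction:
    """Two-step PCA reduction with everything needed to back-project.

    ``reduced`` is (group_dim, n_voxels); ``subject_bases`` holds each
    subject's temporal principal directions F_i (n_scans, subject_dim);
    ``group_blocks`` holds the per-subject block G_i (subject_dim, group_dim)
    of the group projection; ``subject_reduced`` the per-subject reduced
    data X_i (subject_dim, n_voxels).
    """

    reduced: np.ndarray
    subject_bases: list[np.ndarray]
    group_blocks: list[np.ndarray]
    subject_reduced: list[np.ndarray]
    mask: np.ndarray
    subject_ids: list[str]
    subject_groups: list[str]
    tr: float
    subject_dim: int
    group_dim: int
    subject_eigvals: list[np.ndarray] = field(default_factory=list)
    group_eigvals: np.ndarray | None = None


@dataclass
class ICADecomposition:
    """A group spatial ICA fit plus GICA3 subject back-reconstruction.

    ``group_maps`` are z-scaled over voxels, one row per component, ordered
    by explained variance with the peak-magnitude voxel made positive.
    ``subject_maps`` are on the same scale, and their mean over subjects
    reproduces ``group_maps`` exactly (GICA3 consistency).
    """

    model_order: int
    group_maps: np.ndarray  # (order, n_voxels), z-scaled
    subject_maps: np.ndarray  # (n_subjects, order, n_voxels)
    subject_timecourses: np.ndarray  # (n_subjects, order, n_scans)
    mixing: np.ndarray  # (group_dim, order)
    unmixing: np.ndarray  # (order, group_dim)
    mask: np.ndarray
    subject_ids: list[str]
    subject_groups: list[str]
    seed: int
    scale_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale_sd: np.ndarray = field(default_factory=lambda: np.ones(0))

    def group_map_volume(self, component: int) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.group_maps[component]
        return vol


@dataclass
class ModelOrderScan:
    """Decompositions over a range of model orders with component matching."""

    orders: list[int]
    decompositions: dict[int, ICADecomposition]
    reference_order: int
    matches: dict[int, dict[int, tuple[int, float]]]
    stability: np.ndarray  # per reference component


@dataclass
class LagProfile:
    """Per-component, per-lag group significance of regressor tracking.

    ``stat``/``p`` are (n_components, n_lags) signed-rank results on the
    per-subject OLS betas of IC time course on lagged regressor;
    ``classification`` assigns each component early / transition / unrelated.
    """

    lags: tuple[int, ...]
    stat: np.ndarray
    p: np.ndarray
    betas: np.ndarray  # (n_subjects, n_components, n_lags)
    classification: list[str]
    alpha: float


def reduce_two_step(
    vols: list[VolumeSeries], subject_dim: int, group_dim: int
) -> Reduction:
    """Subject-level then group-level PCA of temporally concatenated data."""
    if not vols:
        raise ValueError("no volumes supplied")
    n_scans = vols[0].n_scans
    mask = vols[0].mask
    if subject_dim > n_scans:
        raise ValueError(f"subject_dim {subject_dim} exceeds n_scans {n_scans}")
    if group_dim > subject_dim * len(vols):
        raise ValueError(
            f"group_dim {group_dim} exceeds available rank "
            f"{subject_dim * len(vols)}"
        )
    bases, blocks_data, eigs = [], [], []
    for v in vols:
        if not np.array_equal(v.mask, mask):
            raise ValueError("all subjects must share one mask")
        Y = v.masked()  # (V, T)
        Yc = (Y - Y.mean(axis=1, keepdims=True)).T  # (T, V), voxel-demeaned
        U, S, _ = np.linalg.svd(Yc, full_matrices=False)
        rank = int((S > S[0] * 1e-10).sum()) if S.size else 0
        if subject_dim > rank:
            raise ValueError(
                f"subject {v.subject_id}: requested subject_dim {subject_dim} "
                f"but achievable rank is {rank}"
            )
        F = U[:, :subject_dim]  # (T, k1)
        bases.append(F)
        blocks_data.append(F.T @ Yc)  # X_i = (k1, V)
        eigs.append(S**2 / max(Yc.shape[0] - 1, 1))
    X = np.vstack(blocks_data)  # (M*k1, V)
    Ug, Sg, _ = np.linalg.svd(X, full_matrices=False)
    rank_g = int((Sg > Sg[0] * 1e-10).sum()) if Sg.size else 0
    if group_dim > rank_g:
        raise ValueError(
            f"requested group_dim {group_dim} but achievable rank is {rank_g}"
        )
    G = Ug[:, :group_dim]  # (M*k1, k2)
    reduced = G.T @ X  # (k2, V)
    k1 = subject_dim
    group_blocks = [G[i * k1 : (i + 1) * k1, :] for i in range(len(vols))]
    return Reduction(
        reduced=reduced,
        subject_bases=bases,
        group_blocks=group_blocks,
        subject_reduced=blocks_data,
        mask=mask,
        subject_ids=[v.subject_id for v in vols],
        subject_groups=[v.group for v in vols],
        tr=vols[0].tr,
        subject_dim=subject_dim,
        group_dim=group_dim,
        subject_eigvals=eigs,
        group_eigvals=Sg**2,
    )


def fit_spatial_ica(
    reduction: Reduction,
    model_order: int,
    seed: int = 0,
    fun: str = "logcosh",
    algorithm: str = "deflation",
    max_retries: int = 5,
) -> ICADecomposition:
    """Spatial FastICA on the group-reduced data + GICA3 back-reconstruction.

    Voxels are treated as samples and the reduced dimensions as features, so
    the estimated sources are spatially independent component maps.
    Deterministic given ``seed``; on non-convergence the fit retries with a
    shifted internal seed up to ``max_retries`` times, then raises.  The
    deflationary fixed-point scheme is the default: it extracts components
    one by one and, unlike the symmetric update, does not stall rotating
    within the near-Gaussian residual subspace that whitened fMRI data
    always contain.
    """
    if model_order > reduction.group_dim:
        raise ValueError(
            f"model_order {model_order} exceeds group_dim {reduction.group_dim}"
        )
    R = reduction.reduced  # (k2, V)
    last_err: Exception | None = None
    for attempt in range(max_retries):
        ica = FastICA(
            n_components=model_order,
            fun=fun,
            algorithm=algorithm,
            whiten="unit-variance",
            random_state=int(seed) + 1009 * attempt,
            max_iter=1000,
            tol=1e-4,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                sources = ica.fit_transform(R.T)  # (V, order)
            except Exception as err:  # singular whitening etc.
                last_err = err
                continue
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            last_err = RuntimeError("FastICA did not converge")
            continue
        break
    else:
        raise RuntimeError(
            f"spatial ICA failed to converge after {max_retries} attempts"
        ) from last_err

    S = sources.T  # (order, V)
    # unmixing consistent with sklearn's internal mean removal:
    # S = W @ (R - row_mean(R)) exactly
    mu = R.mean(axis=1, keepdims=True)
    Rc = R - mu
    W = S @ np.linalg.pinv(Rc)  # (order, k2)
    A = np.linalg.pinv(W)  # (k2, order) mixing

    # order components by explained variance (sources have unit variance,
    # so variance in the reduced space is the squared mixing-column norm)
    order_idx = np.argsort(-np.linalg.norm(A, axis=0))
    S, W, A = S[order_idx], W[order_idx], A[:, order_idx]
    # sign convention: peak-magnitude voxel of each map is positive
    signs = np.sign(S[np.arange(S.shape[0]), np.argmax(np.abs(S), axis=1)])
    signs[signs == 0] = 1.0
    S, W, A = S * signs[:, None], W * signs[:, None], A * signs[None, :]

    maps_s, tcs = back_reconstruct_gica3(S, W, A, mu, reduction)

    # z-scale group maps over voxels; subject maps get the same affine so
    # the GICA3 mean identity survives the rescaling
    m = S.mean(axis=1)
    sd = S.std(axis=1)
    sd[sd == 0] = 1.0
    S_z = (S - m[:, None]) / sd[:, None]
    maps_z = (maps_s - m[None, :, None]) / sd[None, :, None]

    return ICADecomposition(
        model_order=model_order,
        group_maps=S_z,
        subject_maps=maps_z,
        subject_timecourses=tcs,
        mixing=A,
        unmixing=W,
        mask=reduction.mask,
        subject_ids=reduction.subject_ids,
        subject_groups=reduction.subject_groups,
        seed=seed,
        scale_mean=m,
        scale_sd=sd,
    )


def back_reconstruct_gica3(
    sources: np.ndarray,
    unmixing: np.ndarray,
    mixing: np.ndarray,
    reduced_mean: np.ndarray,
    reduction: Reduction,
) -> tuple[np.ndarray, np.ndarray]:
    """GICA3 subject-specific maps and time courses.

    With X_i the subject-reduced data, G_i the subject block of the group
    projection and W the spatial unmixing, the subject map is
    ``S_i = W (M * G_i^T X_i - mu)`` (M = number of subjects), so that
    ``mean_i S_i = W (sum_i G_i^T X_i - mu) = W (R - mu) = S`` — the group
    map — identically.  Time courses are ``TC_i = F_i G_i A``.
    """
    M = len(reduction.subject_reduced)
    order = sources.shape[0]
    n_scans = reduction.subject_bases[0].shape[0]
    maps = np.empty((M, order, sources.shape[1]))
    tcs = np.empty((M, order, n_scans))
    for i in range(M):
        Gi = reduction.group_blocks[i]  # (k1, k2)
        Xi = reduction.subject_reduced[i]  # (k1, V)
        maps[i] = unmixing @ (M * (Gi.T @ Xi) - reduced_mean)
        tcs[i] = (reduction.subject_bases[i] @ (Gi @ mixing)).T
    return maps, tcs


def match_components(
    maps_a: np.ndarray, maps_b: np.ndarray, threshold: float = 0.7
) -> dict[int, tuple[int, float]]:
    """Greedy matching of component maps by absolute spatial correlation.

    Returns {index_in_a: (index_in_b, |corr|)} for pairs above threshold.
    """
    ca = maps_a - maps_a.mean(axis=1, keepdims=True)
    cb = maps_b - maps_b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ca, axis=1)
    nb = np.linalg.norm(cb, axis=1)
    corr = np.abs(ca @ cb.T / np.outer(na, nb))
    out: dict[int, tuple[int, float]] = {}
    used_b: set[int] = set()
    flat = np.argsort(-corr, axis=None)
    for idx in flat:
        i, j = np.unravel_index(idx, corr.shape)
        if i in out or j in used_b:
            continue
        if corr[i, j] < threshold:
            break
        out[int(i)] = (int(j), float(corr[i, j]))
        used_b.add(int(j))
    return out


def scan_model_orders(
    reduction: Reduction,
    orders: list[int],
    seed: int = 0,
    match_threshold: float = 0.7,
) -> ModelOrderScan:
    """Fit spatial ICA at each model order and match components across them.

    The smallest order serves as the reference; each reference component's
    stability score is its mean match correlation across the other orders
    where a match above threshold exists.
    """
    if not orders:
        raise ValueError("orders must be non-empty")
    decomps = {k: fit_spatial_ica(reduction, k, seed=seed) for k in orders}
    ref = min(orders)
    ref_maps = decomps[ref].group_maps
    matches: dict[int, dict[int, tuple[int, float]]] = {}
    scores = [[] for _ in range(ref)]
    for k in orders:
        if k == ref:
            continue
        m = match_components(ref_maps, decomps[k].group_maps, match_threshold)
        matches[k] = m
        for i, (_, c) in m.items():
            scores[i].append(c)
    stability = np.array([float(np.mean(s)) if s else 0.0 for s in scores])
    if len(orders) == 1:
        stability = np.ones(ref)
    return ModelOrderScan(
        orders=list(orders),
        decompositions=decomps,
        reference_order=ref,
        matches=matches,
        stability=stability,
    )


def profile_lag_significance(
    subject_timecourses: np.ndarray,
    scan_regressor: np.ndarray,
    lags: tuple[int, ...] = LAGS,
    tr: float = 2.0,
    hrf: "np.ndarray | str | None" = None,
    alpha: float = 0.05,
) -> LagProfile:
    """Group-level lag tuning of each component's time course.

    Per component and lag, each subject's OLS beta of its IC time course on
    the (HRF-convolved) lagged regressor is computed; a one-sample Wilcoxon
    signed-rank test across subjects against zero gives the group statistic.
    A component is classified "early" if its minimum-p lag is -1,
    "transition" if 0 or +1, and "unrelated" if no lag reaches ``alpha``.
    The exact signed-rank p floors at 2/2^n once every subject's beta has
    the same sign, so several lags can tie at the minimum; ties are broken
    by the largest absolute median beta (effect size), and only then toward
    lag 0.
    """
    tcs = np.asarray(subject_timecourses, dtype=float)
    if tcs.ndim != 3:
        raise ValueError("subject_timecourses must be (subjects, components, scans)")
    n_subj, n_comp, n_scans = tcs.shape
    if n_subj < 6:
        raise ValueError("need at least 6 subjects for group lag profiling")
    regs = np.stack(
        [
            hrf_convolve(lag_regressor(scan_regressor, lag), tr=tr, hrf=hrf)
            for lag in lags
        ]
    )  # (L, T)
    regs_c = regs - regs.mean(axis=1, keepdims=True)
    denom = (regs_c**2).sum(axis=1)
    betas = np.full((n_subj, n_comp, len(lags)), np.nan)
    for s in range(n_subj):
        for c in range(n_comp):
            tc = tcs[s, c]
            if tc.std() == 0:
                warnings.warn(
                    f"subject {s} component {c}: constant time course, "
                    "beta excluded",
                    stacklevel=2,
                )
                continue
            tc_c = tc - tc.mean()
            betas[s, c] = (regs_c @ tc_c) / denom
    stat = np.zeros((n_comp, len(lags)))
    p = np.ones((n_comp, len(lags)))
    for c in range(n_comp):
        for j in range(len(lags)):
            vals = betas[:, c, j]
            vals = vals[np.isfinite(vals)]
            res = signed_rank_test(vals)
            stat[c, j], p[c, j] = res.z, res.p_two
    classification = []
    med = np.nanmedian(betas, axis=0)  # (n_comp, n_lags)
    for c in range(n_comp):
        if np.min(p[c]) >= alpha:
            classification.append("unrelated")
            continue
        pmin = np.min(p[c])
        tied = [j for j in range(len(lags)) if p[c, j] == pmin]
        # ties: largest |median beta| wins, then the lag nearest 0
        best = min(tied, key=lambda j: (-abs(med[c, j]), abs(lags[j]), -lags[j]))
        classification.append("early" if lags[best] == -1 else "transition")
    return LagProfile(
        lags=tuple(lags), stat=stat, p=p, betas=betas,
        classification=classification, alpha=alpha,
    )


def compare_groups_ica(
    subject_maps: np.ndarray,
    groups: list[str],
    mask: np.ndarray,
    forming_threshold: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[GroupMap, ClusterTable]:
    """Group comparison of one component's subject-specific maps.

    ``subject_maps`` is (n_subjects, n_voxels) for a single component.
    Voxelwise two-sample rank-sum statistics are cluster-corrected with
    label-shuffle permutations at the component's forming threshold.
    """
    maps2d = np.asarray(subject_maps, dtype=float)
    labels = np.asarray(groups)
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    is_a = labels == uniq[0]
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    z, p = rank_sum_map(maps2d[is_a], maps2d[~is_a])
    gmap = GroupMap(stat=z, p=p, direction="two-sided",
                    method="wilcoxon_rank_sum", mask=mask)
    vols = np.zeros((maps2d.shape[0],) + mask.shape)
    vols[:, mask] = maps2d
    table = cluster_correct(
        vols, mask,
        forming_threshold=forming_threshold,
        scheme="label_shuffle",
        n_permutations=n_permutations,
        seed=seed,
        groups=labels,
    )
    return gmap, table
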