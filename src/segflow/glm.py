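"""Voxelwise general linear model on lagged boundary regressors.

Per subject: the loudness (RMS) confound is regressed out of every in-mask
voxel; the residual data are fitted against time-shifted copies of the
boundary-salience regressor (lags -1, 0, +1 scans); subject-level one-sided
p-values are pooled across participants with Fisher's combined-probability
test, separately for activations and deactivations.  Lag and group contrasts
use Wilcoxon rank tests; Spearman rank correlation is available as an
assumption-free alternative association measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._ranktests import rank_sum_null_pmf, rank_sum_test, signed_rank_test
from .regressor import hrf_convolve, lag_regressor
from .volumes import VolumeSeries

__all__ = [
    "SubjectGLM",
    "GroupMap",
    "build_lagged_design",
    "regress_out_confound",
    "fit_subject_glm",
    "fisher_combine",
    "compare_lags",
    "compare_groups_glm",
    "spearman_association",
    "rank_sum_map",
]

LAGS = (-1, 0, 1)


@dataclass
class SubjectGLM:
    """Per-voxel OLS results for one subject's lagged design.

    Arrays are (n_lags, n_voxels) over in-mask voxels; ``p_pos`` is the
    one-sided probability of a positive effect, ``p_neg`` of a negative one
    (p_pos + p_neg = 1).
    """

    subject_id: str
    group: str
    lags: tuple[int, ...]
    betas: np.ndarray
    t_stats: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    dof: int
    mask: np.ndarray


@dataclass
class GroupMap:
    """A group-level per-voxel statistic map with probabilities."""

    stat: np.ndarray  # per in-mask voxel
    p: np.ndarray
    direction: str  # {"activation", "deactivation", "two-sided"}
    method: str
    mask: np.ndarray

    def volume(self, which: str = "stat", fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, fill)
        vol[self.mask] = getattr(self, which)
        return vol


def regress_out_confound(vol: VolumeSeries, confound: np.ndarray) -> VolumeSeries:
    """Residualise every in-mask voxel on (intercept, confound) by OLS.

    The residuals are exactly orthogonal to the confound (and zero-mean), so
    downstream statistics cannot be driven by it.
    """
    c = np.asarray(confound, dtype=float)
    if c.size != vol.n_scans:
        raise ValueError(f"confound length {c.size} != n_scans {vol.n_scans}")
    if np.std(c) == 0:
        raise ValueError("constant confound: nothing to regress out")
    X = np.column_stack([np.ones_like(c), c])
    Y = vol.masked().T  # (n_scans, n_voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return vol.with_masked(resid.T)


def build_lagged_design(
    scan_regressor: np.ndarray,
    lags: tuple[int, ...] = LAGS,
    tr: float = 2.0,
    hrf: "np.ndarray | str | None" = None,
) -> np.ndarray:
    """Design matrix: intercept + one HRF-convolved lagged regressor per lag.

    Columns are ordered (intercept, *lags).  Pass ``hrf="identity"`` to skip
    haemodynamic convolution.
    """
    x = np.asarray(scan_regressor, dtype=float)
    cols = [np.ones_like(x)]
    for lag in lags:
        cols.append(hrf_convolve(lag_regressor(x, lag), tr=tr, hrf=hrf))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via near-zero R diagonal of a QR
        names = ["intercept"] + [f"lag{lag:+d}" for lag in lags]
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [names[i] for i in np.nonzero(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X


def fit_subject_glm(
    vol: VolumeSeries,
    scan_regressor: np.ndarray,
    lags: tuple[int, ...] = LAGS,
    hrf: "np.ndarray | str | None" = None,
    joint: bool = True,
    confound: np.ndarray | None = None,
) -> SubjectGLM:
    """Per-voxel OLS of the (residualised) data on the lagged design.

    ``joint=True`` fits all lag columns in one design (shared variance is
    split by least squares); ``joint=False`` fits each lag separately.

    When the data have been residualised against a confound, pass the same
    series as ``confound``: it enters the design as a nuisance column, which
    by Frisch-Waugh is equivalent to residualising both sides.  Projecting
    the confound out of the data alone leaves the design columns' own
    confound share in place and biases the lag betas wherever the smooth
    confound correlates with the HRF-convolved regressors.
    """
    Y = vol.masked().T  # (n_scans, n_voxels)
    n = Y.shape[0]
    nuis = None
    if confound is not None:
        nuis = np.asarray(confound, dtype=float)
        if nuis.size != n:
            raise ValueError(f"confound length {nuis.size} != n_scans {n}")

    def _with_nuisance(X: np.ndarray) -> np.ndarray:
        return X if nuis is None else np.column_stack([X, nuis])

    def _fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        p = X.shape[1]
        dof = n - p
        if dof <= 0:
            raise ValueError(f"not enough scans ({n}) for {p} regressors")
        pinv = np.linalg.pinv(X)
        beta = pinv @ Y
        resid = Y - X @ beta
        mse = (resid**2).sum(axis=0) / dof
        xtx_inv_diag = np.sum(pinv**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.outer(xtx_inv_diag, mse))
            t = np.where(se > 0, beta / se, 0.0)
        return beta, t, dof

    if joint:
        X = build_lagged_design(scan_regressor, lags=lags, tr=vol.tr, hrf=hrf)
        beta, t, dof = _fit(_with_nuisance(X))
        betas, ts = beta[1 : 1 + len(lags)], t[1 : 1 + len(lags)]
    else:
        rows_b, rows_t = [], []
        dof = n - 2
        for lag in lags:
            X = build_lagged_design(scan_regressor, lags=(lag,), tr=vol.tr, hrf=hrf)
            b, t, dof = _fit(_with_nuisance(X))
            rows_b.append(b[1])
            rows_t.append(t[1])
        betas, ts = np.array(rows_b), np.array(rows_t)

    p_pos = stats.t.sf(ts, dof)
    p_neg = stats.t.cdf(ts, dof)
    return SubjectGLM(
        subject_id=vol.subject_id,
        group=vol.group,
        lags=tuple(lags),
        betas=betas,
        t_stats=ts,
        p_pos=p_pos,
        p_neg=p_neg,
        dof=dof,
        mask=vol.mask,
    )


def fisher_combine(
    p_values: np.ndarray, mask: np.ndarray | None = None, direction: str = "activation"
) -> GroupMap:
    """Fisher's combined probability test across subjects, per voxel.

    ``p_values`` is (k_subjects, n_voxels) of one-sided probabilities; the
    pooled statistic is -2 * sum(ln p), referred to a chi-square with 2k
    degrees of freedom.  Zero p-values are clipped to the smallest positive
    float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-values clipped to the smallest positive float",
                      stacklevel=2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    k = p.shape[0]
    stat = -2.0 * np.log(p).sum(axis=0)
    pooled = stats.chi2.sf(stat, df=2 * k)
    if mask is None:
        mask = np.ones(stat.shape, dtype=bool)
    return GroupMap(stat=stat, p=pooled, direction=direction, method="fisher",
                    mask=mask)


def rank_sum_map(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised voxelwise two-sample Wilcoxon rank-sum test.

    ``a``/``b`` are (n_a, n_voxels) and (n_b, n_voxels).  Tie-free voxels
    share one exact null distribution (computed once); voxels with ties fall
    back to the per-voxel routine.  Returns (z, p_two).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[0], b.shape[0]
    n = n1 + n2
    pooled = np.vstack([a, b])
    ranks = stats.rankdata(pooled, axis=0, method="average")
    w = ranks[:n1].sum(axis=0)
    mean = n1 * (n + 1) / 2.0
    var0 = n1 * n2 * (n + 1) / 12.0
    z = (w - mean) / np.sqrt(var0)

    tied = (np.diff(np.sort(pooled, axis=0), axis=0) == 0).any(axis=0)
    p = np.empty(pooled.shape[1])
    if max(n1, n2) <= 25:
        pmf = rank_sum_null_pmf(n1, n2)
        cdf = np.cumsum(pmf)
        sf_incl = 1.0 - np.concatenate([[0.0], cdf[:-1]])  # P(W >= w)
        wi = np.rint(w).astype(int)
        p_greater = sf_incl[np.clip(wi, 0, len(pmf) - 1)]
        p_less = cdf[np.clip(wi, 0, len(pmf) - 1)]
        p[:] = np.minimum(1.0, 2 * np.minimum(p_greater, p_less))
    else:
        sd = np.sqrt(var0)
        zc = (np.abs(w - mean) - 0.5) / sd
        p[:] = np.minimum(1.0, 2 * stats.norm.sf(zc))
    for v in np.nonzero(tied)[0]:
        res = rank_sum_test(a[:, v], b[:, v])
        p[v] = res.p_two
        z[v] = res.z
    return z, p


def compare_lags(
    subject_glms: list[SubjectGLM],
    paired: bool = False,
    statistic: str = "t_stats",
) -> dict[tuple[int, int], GroupMap]:
    """Voxelwise Wilcoxon comparison of subject-level maps between lag pairs.

    Default follows the two-sample rank-sum form; ``paired=True`` uses the
    within-subject signed-rank variant instead (lags are measured in the
    same subjects, so pairing is arguably the better match — both are kept).
    """
    if len(subject_glms) < 2:
        raise ValueError("need at least 2 subjects")
    lags = subject_glms[0].lags
    mask = subject_glms[0].mask
    stacked = {
        lag: np.stack([getattr(g, statistic)[i] for g in subject_glms])
        for i, lag in enumerate(lags)
    }
    out: dict[tuple[int, int], GroupMap] = {}
    for i, la in enumerate(lags):
        for lb in lags[i + 1 :]:
            A, B = stacked[la], stacked[lb]
            if paired:
                d = A - B
                z = np.empty(d.shape[1])
                p = np.empty(d.shape[1])
                for v in range(d.shape[1]):
                    res = signed_rank_test(d[:, v])
                    z[v], p[v] = res.z, res.p_two
                method = "wilcoxon_signed_rank"
            else:
                z, p = rank_sum_map(A, B)
                method = "wilcoxon_rank_sum"
            out[(la, lb)] = GroupMap(
                stat=z, p=p, direction="two-sided", method=method, mask=mask
            )
    return out


def compare_groups_glm(
    subject_glms: list[SubjectGLM],
    lag: int,
    statistic: str = "t_stats",
) -> GroupMap:
    """Voxelwise two-sample rank-sum comparison between the two groups."""
    groups = sorted({g.group for g in subject_glms})
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    li = subject_glms[0].lags.index(lag)
    a = np.stack([getattr(g, statistic)[li] for g in subject_glms
                  if g.group == groups[0]])
    b = np.stack([getattr(g, statistic)[li] for g in subject_glms
                  if g.group == groups[1]])
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    z, p = rank_sum_map(a, b)
    return GroupMap(stat=z, p=p, direction="two-sided",
                    method="wilcoxon_rank_sum", mask=subject_glms[0].mask)


def spearman_association(
    vol: VolumeSeries, scan_regressor: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rank correlation of every in-mask voxel with the regressor.

    Returns (rho, p) per in-mask voxel; constant voxels get rho = nan and
    p = nan (flagged, not raised).
    """
    x = np.asarray(scan_regressor, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 scans")
    Y = vol.masked()
    rx = stats.rankdata(x)
    ry = stats.rankdata(Y, axis=1, method="average")
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((ry_c**2).sum(axis=1) * (rx_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ry_c @ rx_c) / denom
    rho = np.where(denom > 0, rho, np.nan)
    # two-sided p via the t approximation, as standard for Spearman's rho
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, np.where(np.isnan(rho), np.nan, 0.0))
    return rho, p
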