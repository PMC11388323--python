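"""Difference-of-influence Granger causality between network time courses.

For the two back-reconstructed component time courses X (early auditory
network) and Y (boundary transition network), the Geweke-style influence of
X on Y is

    F_{x->y} = ln( var(resid of Y on its own lags)
                 / var(resid of Y on its own lags + X's lags) )

and symmetrically for F_{y->x}.  At fMRI temporal resolution haemodynamic
blurring can turn a truly unidirectional influence into an apparent
bidirectional one; the difference of influence DOI = F_{x->y} - F_{y->x} is
robust to that inflation, and its sign across subjects carries the
direction.  Model order is chosen per subject by AIC (BIC recorded
alongside) from a bivariate VAR fitted on the common sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._ranktests import signed_rank_test

__all__ = [
    "GrangerResult",
    "GroupGrangerTest",
    "select_var_order",
    "granger_influence",
    "doi",
    "fit_subject_granger",
    "group_doi_test",
]


@dataclass(frozen=True)
class GrangerResult:
    """Per-subject bidirectional influence measures."""

    subject_id: str
    order_aic: int
    order_bic: int
    f_xy: float
    f_yx: float

    @property
    def doi(self) -> float:
        return self.f_xy - self.f_yx


@dataclass(frozen=True)
class GroupGrangerTest:
    """Group-level signed-rank test on subject difference-of-influence."""

    statistic: float
    p_raw: float
    p_fdr: float
    direction: str  # {"x_causes_y", "y_causes_x", "undetermined"}
    median_doi: float
    n_subjects: int


def _standardize(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    sd = a.std()
    if sd == 0:
        raise ValueError("constant series: Granger analysis undefined")
    return (a - a.mean()) / sd


def _lag_matrix(series: np.ndarray, order: int, start: int) -> np.ndarray:
    """Columns series[t-1], ..., series[t-order] for t = start..n-1."""
    n = series.size
    return np.column_stack([series[start - k : n - k] for k in range(1, order + 1)])


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def select_var_order(
    x: np.ndarray, y: np.ndarray, max_order: int = 10
) -> tuple[int, int]:
    """AIC- and BIC-optimal order of the bivariate VAR, on a common sample.

    All candidate orders 1..max_order are fitted by OLS on the sample
    t = max_order..n-1 so the criteria are comparable.  Near-singular fits
    are skipped with a warning.
    """
    x = _standardize(x)
    y = _standardize(y)
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    n = x.size
    if n <= 3 * max_order:
        raise ValueError(
            f"series length {n} must exceed 3 * max_order = {3 * max_order}"
        )
    nobs = n - max_order
    aics, bics = {}, {}
    for p in range(1, max_order + 1):
        Z = np.column_stack(
            [np.ones(nobs), _lag_matrix(x, p, max_order), _lag_matrix(y, p, max_order)]
        )
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            warnings.warn(f"VAR order {p}: singular design, skipped", stacklevel=2)
            continue
        resid = np.column_stack(
            [
                y[max_order:] - Z @ np.linalg.lstsq(Z, y[max_order:], rcond=None)[0],
                x[max_order:] - Z @ np.linalg.lstsq(Z, x[max_order:], rcond=None)[0],
            ]
        )
        sigma = resid.T @ resid / nobs
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            warnings.warn(f"VAR order {p}: degenerate residual covariance, skipped",
                          stacklevel=2)
            continue
        k = 2 * (1 + 2 * p)  # free parameters across both equations
        aics[p] = logdet + 2.0 * k / nobs
        bics[p] = logdet + np.log(nobs) * k / nobs
    if not aics:
        raise ValueError("no VAR order could be fitted")
    return min(aics, key=aics.get), min(bics, key=bics.get)


def granger_influence(
    x: np.ndarray, y: np.ndarray, order: int
) -> tuple[float, float]:
    """Geweke log-variance-ratio influences (F_{x->y}, F_{y->x}).

    Both directions are computed on the same sample window
    t = order..n-1.  Series are variance-normalised first (the measure is
    scale-invariant; normalisation only stabilises the OLS).
    """
    x = _standardize(x)
    y = _standardize(y)
    n = x.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= 3 * order:
        raise ValueError(f"series length {n} must exceed 3 * order = {3 * order}")
    nobs = n - order
    ones = np.ones(nobs)
    Lx = _lag_matrix(x, order, order)
    Ly = _lag_matrix(y, order, order)

    def influence(target: np.ndarray, own: np.ndarray, other: np.ndarray) -> float:
        rss_r = _ols_rss(np.column_stack([ones, own]), target)
        rss_f = _ols_rss(np.column_stack([ones, own, other]), target)
        if rss_f <= 0:
            raise ValueError("zero residual variance: series is deterministic")
        return float(np.log(rss_r / rss_f))

    f_xy = influence(y[order:], Ly, Lx)
    f_yx = influence(x[order:], Lx, Ly)
    return f_xy, f_yx


def doi(x: np.ndarray, y: np.ndarray, order: int) -> float:
    """Difference of influence F_{x->y} - F_{y->x} (antisymmetric in x, y)."""
    f_xy, f_yx = granger_influence(x, y, order)
    return f_xy - f_yx


def fit_subject_granger(
    x: np.ndarray,
    y: np.ndarray,
    max_order: int = 10,
    subject_id: str = "sub-00",
) -> GrangerResult:
    """Order selection (AIC used, BIC recorded) + influence for one subject."""
    order_aic, order_bic = select_var_order(x, y, max_order=max_order)
    f_xy, f_yx = granger_influence(x, y, order_aic)
    return GrangerResult(
        subject_id=subject_id,
        order_aic=order_aic,
        order_bic=order_bic,
        f_xy=f_xy,
        f_yx=f_yx,
    )


def group_doi_test(
    results: list[GrangerResult],
    alpha: float = 1e-4,
    n_tests: int = 1,
) -> GroupGrangerTest:
    """One-sample signed-rank test of subject DOIs against zero.

    ``n_tests`` is the number of network pairs examined in the family; when
    testing a single pair out of a family, the step-up adjustment for the
    smallest p reduces to ``p * n_tests`` (identity when 1).  With several
    observed pairs, adjust the collected ``p_raw`` values with
    :func:`segflow.inference.fdr_adjust` instead.  Direction is the sign of
    the median DOI when significant, else undetermined.
    """
    dois = np.array([r.doi for r in results], dtype=float)
    n = dois.size
    if n < 6:
        warnings.warn(
            f"only {n} subjects: group test underpowered, direction "
            "undetermined",
            stacklevel=2,
        )
        return GroupGrangerTest(0.0, 1.0, 1.0, "undetermined",
                                float(np.median(dois)) if n else 0.0, n)
    res = signed_rank_test(dois)
    p_raw = res.p_two
    p_fdr = float(min(1.0, p_raw * max(1, n_tests)))
    med = float(np.median(dois))
    if p_fdr < alpha and med != 0:
        direction = "x_causes_y" if med > 0 else "y_causes_x"
    else:
        direction = "undetermined"
    return GroupGrangerTest(
        statistic=res.statistic,
        p_raw=p_raw,
        p_fdr=p_fdr,
        direction=direction,
        median_doi=med,
        n_subjects=n,
    )
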