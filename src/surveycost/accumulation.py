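"""Species accumulation with effort: resampled collector's curves and the
Polce-Kunin multi-scale accumulation model.

Effort is applied at two scales, sites (``k``) and samples within a site
(``n``).  Collector's curves are built by repeatedly (default 1,000 times)
drawing a random ordering of the sites — optionally first drawing which
sample represents each site — and recording cumulative richness at each
effort level.  The summarized curve starts at the average richness of a
single unit of effort and levels off at total cumulative richness.

The curve is made usable for scenario modeling by fitting the Polce-Kunin
model

    S = (a + k**z * n**c) / (b + n**c),

where ``S`` is expected richness, ``z`` increases with beta diversity among
sites (compositional turnover), ``c`` shapes the within-site collector's
curve, and ``a``, ``b`` are constants.  The fit is nonlinear least squares
of log(model) against log(median cumulative richness), with every starting
value at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CollectorCurve",
    "AccumulationFit",
    "PolceKuninModel",
    "collector_curve",
    "fit_polce_kunin",
    "predict_richness",
    "polce_kunin",
]


def polce_kunin(n, k, a, b, c, z):
    """Expected richness (a + k^z n^c)/(b + n^c) on the natural scale."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    nc = n**c
    return (a + k**z * nc) / (b + nc)


@dataclass(frozen=True)
class CollectorCurve:
    """Summarized resampled collector's curve over a (n, k) effort grid.

    ``table`` has one row per (n, k) with columns ``n, k, median_S, mean_S,
    q05, q95``.
    """

    table: pd.DataFrame
    iterations: int
    seed: int | None = None
    one_per_site: bool = False

    @property
    def total_richness(self) -> int:
        return int(round(self.table["median_S"].max()))


@dataclass
class AccumulationFit:
    """Fitted Polce-Kunin parameters with uncertainties and diagnostics."""

    a: float
    b: float
    c: float
    z: float
    se: dict = field(default_factory=dict)
    converged: bool = False
    rss: float = float("nan")
    message: str = ""
    model: "PolceKuninModel | None" = None

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.z)


def _incidence(matrix: pd.DataFrame, site_col: str) -> tuple[np.ndarray, list, np.ndarray]:
    """Boolean sample x species array, site labels, per-sample site index."""
    if site_col not in matrix.columns:
        raise ValueError(f"incidence matrix needs a {site_col!r} column")
    drop = [site_col] + (["sample_id"] if "sample_id" in matrix.columns else [])
    species = [c for c in matrix.columns if c not in drop]
    if len(matrix) == 0 or not species:
        raise ValueError("incidence matrix is empty")
    # read counts reduce to incidence at >= 1 read
    cells = matrix[species].to_numpy(dtype=float) > 0
    sites = list(dict.fromkeys(matrix[site_col]))
    site_idx = np.array([sites.index(s) for s in matrix[site_col]])
    return cells, sites, site_idx


def collector_curve(
    matrix: pd.DataFrame,
    iterations: int = 1000,
    seed: int | None = None,
    one_per_site: bool = False,
    n_values: Sequence[int] | None = None,
    site_col: str = "site_id",
) -> CollectorCurve:
    """Resampled collector's curve from a sample x species incidence matrix.

    ``matrix`` has one row per sample, a ``site_id`` column, and one column
    per species (counts or 0/1; any positive entry is a detection).  For
    each iteration, ``n`` samples are drawn without replacement at each site
    (``one_per_site=True`` forces n=1, the single-sample strategy: one
    sample is chosen at random to represent a site at each iteration), the
    sites are randomly ordered, and cumulative richness is recorded after
    each site.  Medians, means and 5%/95% resampling quantiles are taken
    across iterations.  Only sites holding at least ``n`` samples enter the
    grid row for that ``n``.  A fixed ``seed`` makes the curve
    bit-reproducible.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    cells, sites, site_idx = _incidence(matrix, site_col)
    samples_by_site = [np.flatnonzero(site_idx == i) for i in range(len(sites))]

    if one_per_site:
        n_grid = [1]
    elif n_values is not None:
        n_grid = sorted(set(int(n) for n in n_values))
    else:
        n_grid = list(range(1, max(len(ix) for ix in samples_by_site) + 1))

    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        usable = [ix for ix in samples_by_site if len(ix) >= n]
        if not usable:
            continue
        k_max = len(usable)
        richness = np.empty((iterations, k_max), dtype=np.int64)
        for it in range(iterations):
            site_union = np.empty((k_max, cells.shape[1]), dtype=bool)
            for j, ix in enumerate(usable):
                chosen = ix if len(ix) == n else rng.choice(ix, size=n, replace=False)
                site_union[j] = cells[chosen].any(axis=0)
            order = rng.permutation(k_max)
            cum = np.logical_or.accumulate(site_union[order], axis=0)
            richness[it] = cum.sum(axis=1)
        for j in range(k_max):
            col = richness[:, j]
            rows.append(
                dict(
                    n=n,
                    k=j + 1,
                    median_S=float(np.median(col)),
                    mean_S=float(col.mean()),
                    q05=float(np.quantile(col, 0.05)),
                    q95=float(np.quantile(col, 0.95)),
                )
            )
    table = pd.DataFrame(rows)
    return CollectorCurve(table=table, iterations=iterations, seed=seed, one_per_site=one_per_site)


class PolceKuninModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of the Polce-Kunin accumulation model.

    scikit-learn-style estimator.  ``X`` is an array of shape (m, 2) with
    columns ``[n, k]`` (samples per site, sites); ``y`` is the median
    cumulative richness at each effort point.  The default objective matches
    log(model) to log(y); set ``log_fit=False`` for a natural-scale fit.

    Fitted attributes: ``a_, b_, c_, z_`` (parameters), ``se_`` (asymptotic
    standard errors), ``converged_``, ``rss_`` (residual sum of squares on
    the fitting scale), ``cov_`` and ``message_``.  Non-convergence and
    unidentifiable (degenerate) inputs set ``converged_ = False`` with a
    diagnostic message; no exception is raised.
    """

    _COND_LIMIT = 1e8  # Jacobian condition number beyond which the fit is flagged

    def __init__(self, start: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
                 log_fit: bool = True, max_nfev: int = 20000):
        self.start = start
        self.log_fit = log_fit
        self.max_nfev = max_nfev

    def _residuals(self, theta, n, k, y):
        pred = polce_kunin(n, k, *theta)
        bad = ~np.isfinite(pred) | (pred <= 0)
        if self.log_fit:
            out = np.where(bad, 0.0, np.log(np.where(bad, 1.0, pred))) - np.log(y)
        else:
            out = np.where(bad, 0.0, pred) - y
        # guard against numerical excursions outside the model's domain
        return np.where(bad, 1e3 * (1.0 + np.abs(np.nan_to_num(pred))), out)

    def fit(self, X, y) -> "PolceKuninModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: [n, k]")
        keep = np.isfinite(y) & (y > 0)
        n, k, y = X[keep, 0], X[keep, 1], y[keep]
        if len(np.unique(np.column_stack([n, k]), axis=0)) < 4:
            raise ValueError("need >= 4 distinct (n, k) points with positive richness")

        # a, b >= 0 keeps numerator and denominator positive for n, k >= 1,
        # the region where the accumulation model is meaningful
        result = least_squares(
            self._residuals, np.asarray(self.start, dtype=float),
            args=(n, k, y), method="trf",
            bounds=([0.0, 0.0, -np.inf, -np.inf], [np.inf] * 4),
            max_nfev=self.max_nfev,
        )
        self.result_ = result
        self.a_, self.b_, self.c_, self.z_ = (float(v) for v in result.x)
        self.params_ = result.x.copy()
        self.rss_ = float(2.0 * result.cost)
        dof = max(len(y) - 4, 1)
        jtj = result.jac.T @ result.jac
        cond = np.linalg.cond(jtj)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.cov_ = (self.rss_ / dof) * np.linalg.pinv(jtj)
        se = np.sqrt(np.abs(np.diag(self.cov_)))
        self.se_ = dict(zip("abcz", (float(v) for v in se)))
        identifiable = np.isfinite(cond) and cond < self._COND_LIMIT
        self.converged_ = bool(result.success and identifiable)
        if not result.success:
            self.message_ = f"optimizer did not converge: {result.message}"
        elif not identifiable:
            self.message_ = (
                f"parameters poorly identified (Jacobian condition {cond:.2e}); "
                "the curve may be degenerate (e.g. flat or single-site)"
            )
        else:
            self.message_ = "converged"
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return polce_kunin(X[:, 0], X[:, 1], self.a_, self.b_, self.c_, self.z_)

    def predict_ci(self, X, alpha: float = 0.05) -> pd.DataFrame:
        """Delta-method CI for predicted richness on the natural scale."""
        from scipy.stats import norm

        X = np.asarray(X, dtype=float)
        pred = self.predict(X)
        grads = np.empty((len(X), 4))
        eps = 1e-6
        for j in range(4):
            theta_hi = self.params_.copy()
            theta_lo = self.params_.copy()
            step = eps * max(1.0, abs(self.params_[j]))
            theta_hi[j] += step
            theta_lo[j] -= step
            hi = polce_kunin(X[:, 0], X[:, 1], *theta_hi)
            lo = polce_kunin(X[:, 0], X[:, 1], *theta_lo)
            grads[:, j] = (hi - lo) / (2 * step)
        var = np.einsum("ij,jk,ik->i", grads, self.cov_, grads)
        halfwidth = norm.ppf(1 - alpha / 2) * np.sqrt(np.maximum(var, 0.0))
        return pd.DataFrame(
            {"fit": pred, "ci_low": pred - halfwidth, "ci_high": pred + halfwidth}
        )


def _curve_xy(curve, response: str = "median_S"):
    table = curve.table if isinstance(curve, CollectorCurve) else pd.DataFrame(curve)
    X = table[["n", "k"]].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    return X, y


def fit_polce_kunin(
    curve,
    start: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
    response: str = "median_S",
    log_fit: bool = True,
) -> AccumulationFit:
    """Fit the Polce-Kunin model to a summarized collector's curve.

    ``curve`` is a :class:`CollectorCurve` or a DataFrame with columns
    ``n, k`` and a richness column (default the median, as used for the
    headline fit; pass ``response="mean_S"`` for the mean).
    """
    model = PolceKuninModel(start=start, log_fit=log_fit)
    X, y = _curve_xy(curve, response)
    model.fit(X, y)
    return AccumulationFit(
        a=model.a_, b=model.b_, c=model.c_, z=model.z_,
        se=model.se_, converged=model.converged_, rss=model.rss_,
        message=model.message_, model=model,
    )


def predict_richness(fit, n, k):
    """Expected species count at effort (n, k) from a fitted model."""
    if isinstance(fit, PolceKuninModel):
        return polce_kunin(n, k, fit.a_, fit.b_, fit.c_, fit.z_)
    return polce_kunin(n, k, fit.a, fit.b, fit.c, fit.z)
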