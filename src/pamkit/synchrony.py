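"""Intraspecific spatial synchrony in day-to-day vocalization rates.

Synchrony is measured as the Pearson correlation, across shared dates, of a
species' daily (sqrt-transformed) vocalization rates at two locations, and
summarized either at two discrete scales (paired stands ~150 m apart vs.
watersheds ~16 km apart) or continuously as a distance-indexed correlogram: a
cubic regression spline of pair correlations against pair distance, with a
cluster (site-level) bootstrap confidence envelope.  Sites are the bootstrap
unit because the 45 pairs formed from 10 sites are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline


def corr_se(r: float, n: int) -> float:
    """Standard error of a Pearson correlation: sqrt((1 - r^2) / (n - 2))."""
    if n < 3:
        raise ValueError("corr_se requires n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return float(np.sqrt((1 - r**2) / (n - 2)))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class TwoScaleResult:
    """Correlations at the paired-stand (~150 m) and between-watershed (~16 km) scales."""

    within: dict[str, tuple[float, float]]  # watershed -> (r, se)
    between: tuple[float, float]
    n_dates: int


def two_scale_correlation(stand_rates: pd.DataFrame) -> TwoScaleResult:
    """Two-scale synchrony from a dates x stands rate matrix.

    Columns must be named ``watershed/forest_age``.  Within each watershed the
    two stand-age series are correlated across dates; the between-watershed
    correlation uses the within-watershed stand means.  Standard errors come
    from :func:`corr_se`.
    """
    cols = list(stand_rates.columns)
    watersheds = sorted({c.split("/")[0] for c in cols})
    if len(watersheds) != 2:
        raise ValueError("two_scale_correlation expects exactly 2 watersheds")
    rates = stand_rates.dropna()
    n = len(rates)
    if n < 3:
        raise ValueError("need >= 3 shared dates")
    within = {}
    ws_means = {}
    for ws in watersheds:
        stands = [c for c in cols if c.split("/")[0] == ws]
        if len(stands) != 2:
            raise ValueError(f"watershed {ws} must have exactly 2 stands")
        r = _pearson(rates[stands[0]].to_numpy(), rates[stands[1]].to_numpy())
        within[ws] = (r, corr_se(r, n))
        ws_means[ws] = rates[stands].mean(axis=1)
    rb = _pearson(ws_means[watersheds[0]].to_numpy(), ws_means[watersheds[1]].to_numpy())
    return TwoScaleResult(within=within, between=(rb, corr_se(rb, n)), n_dates=n)


# ---------------------------------------------------------------------------
# spline correlogram


@dataclass
class Correlogram:
    """Distance-indexed synchrony estimate with a bootstrap envelope."""

    grid: np.ndarray            # distances (m)
    estimate: np.ndarray        # spline estimate of correlation at grid
    lower: np.ndarray           # 2.5% bootstrap envelope (NaN when n_boot == 0)
    upper: np.ndarray
    pairs: pd.DataFrame         # site_a, site_b, distance_m, r, n
    n_boot: int

    def x_intercept(self) -> float | None:
        """First distance where the estimate crosses zero, if it does in range."""
        sign = np.sign(self.estimate)
        crossings = np.nonzero(np.diff(sign) != 0)[0]
        if crossings.size == 0:
            return None
        i = crossings[0]
        x0, x1 = self.grid[i], self.grid[i + 1]
        y0, y1 = self.estimate[i], self.estimate[i + 1]
        return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def pair_correlations(series: pd.DataFrame, distances: pd.DataFrame) -> pd.DataFrame:
    """Pearson r across dates for every unordered site pair, with distances."""
    sites = list(series.columns)
    rows = []
    for a, b in combinations(sites, 2):
        r = _pearson(series[a].to_numpy(float), series[b].to_numpy(float))
        n = int((series[a].notna() & series[b].notna()).sum())
        rows.append({"site_a": a, "site_b": b,
                     "distance_m": float(distances.loc[a, b]), "r": r, "n": n})
    return pd.DataFrame(rows)


def _fit_spline(dist: np.ndarray, r: np.ndarray, df: int,
                grid: np.ndarray) -> np.ndarray:
    """Least-squares cubic regression B-spline with ``df`` basis functions.

    Interior knots (df - 4 of them) sit at distance quantiles; the fitted
    spline is evaluated on ``grid`` with extrapolation allowed (the grid stays
    inside the observed range in normal use).
    """
    k = 3
    lo, hi = dist.min(), dist.max()
    n_interior = df - (k + 1)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(dist, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    design = BSpline.design_matrix(np.clip(dist, lo, hi), t, k).toarray()
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    return BSpline(t, coef, k, extrapolate=True)(grid)


def spline_correlogram(series: pd.DataFrame, distances: pd.DataFrame,
                       n_boot: int = 1000, df: int = 4, seed: int | None = None,
                       n_grid: int = 100, alpha: float = 0.05,
                       drop_incomplete_dates: bool = True) -> Correlogram:
    """Nonparametric spline correlogram of daily rates against site separation.

    ``series`` is a dates x sites matrix of a species' transformed daily
    rates; ``distances`` the symmetric inter-site distance matrix in meters.
    All unordered site pairs contribute a Pearson r; a cubic regression spline
    (``df`` basis functions) of r on distance is the estimate, and the
    envelope holds the alpha/2 and 1-alpha/2 percentiles over ``n_boot``
    bootstrap resamples of *sites* (pairs recomputed and the spline refitted
    per resample).  The envelope is widened where needed to bracket the point
    estimate.  Self-pairs (distance 0 between copies of one site) are
    excluded.  Set ``n_boot=0`` to skip the envelope.
    """
    if series.shape[1] < 4:
        raise ValueError("need >= 4 sites")
    if drop_incomplete_dates:
        series = series.dropna()
    if len(series) < 5:
        raise ValueError("need >= 5 shared dates")
    pairs = pair_correlations(series, distances)
    ok = pairs.dropna(subset=["r"])
    if len(ok) < df:
        raise ValueError(f"fewer pairs ({len(ok)}) than spline df ({df})")
    dist = ok["distance_m"].to_numpy()
    rvals = ok["r"].to_numpy()
    grid = np.linspace(dist.min(), dist.max(), n_grid)
    estimate = _fit_spline(dist, rvals, df, grid)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sites = list(series.columns)
        data = series.to_numpy(float)
        curves = np.full((n_boot, n_grid), np.nan)
        for b in range(n_boot):
            take = rng.integers(0, len(sites), size=len(sites))
            bd, br = [], []
            for i, j in combinations(range(len(sites)), 2):
                si, sj = take[i], take[j]
                if si == sj:
                    continue  # self-pair of a duplicated site
                r = _pearson(data[:, si], data[:, sj])
                if np.isnan(r):
                    continue
                bd.append(float(distances.iloc[si, sj]))
                br.append(r)
            if len(bd) < df or len(set(bd)) < 2:
                continue
            curves[b] = _fit_spline(np.array(bd), np.array(br), df, grid)
        valid = curves[~np.isnan(curves).all(axis=1)]
        lower = np.nanpercentile(valid, 100 * alpha / 2, axis=0)
        upper = np.nanpercentile(valid, 100 * (1 - alpha / 2), axis=0)
        lower = np.minimum(lower, estimate)
        upper = np.maximum(upper, estimate)
    else:
        lower = np.full(n_grid, np.nan)
        upper = np.full(n_grid, np.nan)

    return Correlogram(grid=grid, estimate=estimate, lower=lower, upper=upper,
                       pairs=pairs, n_boot=n_boot)
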