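"""Interspecific covariation in daily vocalization activity.

Pairs of species whose daily rates rise and fall together are detected with a
date-randomization null: shuffling the date order of both series destroys any
shared temporal structure while preserving each species' marginal
distribution, so the permuted correlations form the null for the observed
Pearson r.  Activity guilds — clusters of species with covarying rates — are
found by PCA of the standardized dates x species rate table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .activity import critical_r


@dataclass
class PairTestResult:
    species_a: str
    species_b: str
    r: float
    n: int
    n_perm: int
    p: float

    @property
    def stars(self) -> str:
        return "**" if self.p < 0.01 else "*" if self.p < 0.05 else ""


def select_common_species(rates: pd.DataFrame, min_presence: float = 0.5) -> list[str]:
    """Species detected (rate > 0) on at least ``min_presence`` of the dates."""
    frac = (rates > 0).mean(axis=0)
    return list(frac.index[frac >= min_presence])


def species_corr_matrix(rates: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pearson correlation matrix among species' daily rates.

    ``rates`` is a dates x species matrix of mean transformed rates.  Returns
    the symmetric matrix (NaN for zero-variance species) plus a tally of
    positive / negative off-diagonal pairs.
    """
    if rates.shape[0] < 3 or rates.shape[1] < 2:
        raise ValueError("need >= 3 dates and >= 2 species")
    constant = rates.columns[rates.std(ddof=0) == 0]
    if len(constant):
        warnings.warn(f"zero-variance species reported as NaN: {list(constant)}",
                      stacklevel=2)
    r = rates.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    iu = np.triu_indices(len(r), k=1)
    off = r.to_numpy()[iu]
    tally = {
        "n_pairs": int(off.size),
        "n_positive": int(np.nansum(off > 0)),
        "n_negative": int(np.nansum(off < 0)),
    }
    return r, tally


def _perm_null_r(a: np.ndarray, b: np.ndarray, n_perm: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Null correlations from jointly permuting the date order of both series."""
    n = a.size
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    # permuting both series independently; equivalent to permuting one, but we
    # follow the stated procedure
    pa = rng.permuted(np.broadcast_to(az, (n_perm, n)), axis=1)
    pb = rng.permuted(np.broadcast_to(bz, (n_perm, n)), axis=1)
    return (pa * pb).sum(axis=1) / n


def randomization_test(series_a: pd.Series | np.ndarray,
                       series_b: pd.Series | np.ndarray,
                       n_perm: int = 1000, seed: int | None = None,
                       name_a: str = "a", name_b: str = "b") -> PairTestResult:
    """Two-sided date-randomization test of the correlation between two series.

    p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1): the add-one convention
    counts the observed ordering as one permutation, so p is never zero.
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 5:
        raise ValueError("need >= 5 dates")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant series")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    null = _perm_null_r(a, b, n_perm, rng)
    p = (1 + int(np.sum(np.abs(null) >= abs(r_obs) - 1e-12))) / (n_perm + 1)
    return PairTestResult(name_a, name_b, r_obs, int(a.size), n_perm, float(p))


def exact_randomization_p(series_a, series_b) -> float:
    """Exact permutation p by full enumeration (oracle; feasible for n <= ~8)."""
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    n = a.size
    if factorial(n) > 50_000:
        raise ValueError("enumeration infeasible for this n")
    from itertools import permutations

    r_obs = abs(np.corrcoef(a, b)[0, 1])
    count = 0
    total = 0
    for order in permutations(range(n)):
        r = abs(np.corrcoef(a[list(order)], b)[0, 1])
        if r >= r_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def all_pair_tests(rates: pd.DataFrame, n_perm: int = 1000,
                   seed: int | None = None) -> pd.DataFrame:
    """Randomization test for every species pair; seeds split per pair."""
    species = list(rates.columns)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(species) * (len(species) - 1) // 2)
    rows = []
    for k, (a, b) in enumerate(combinations(species, 2)):
        res = randomization_test(rates[a], rates[b], n_perm=n_perm,
                                 seed=int(seeds[k]), name_a=a, name_b=b)
        rows.append({"species_a": a, "species_b": b, "r": res.r, "n": res.n,
                     "p": res.p, "stars": res.stars})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# guild structure


@dataclass
class GuildPCA:
    """PCA of the species correlation matrix: loadings, variance, date scores."""

    loadings: pd.DataFrame        # species x components, orthonormal columns
    percent_variance: np.ndarray  # nonincreasing, sums to 100
    scores: pd.DataFrame          # dates x components


def pca_activity(rates: pd.DataFrame, n_components: int | None = None) -> GuildPCA:
    """Correlation-matrix PCA of the dates x species rate table.

    Columns are standardized (so the decomposition is of the correlation
    matrix); zero-variance species are dropped with a warning.  Sign
    convention: each component's largest-magnitude loading is positive.
    """
    if rates.shape[0] < 3 or rates.shape[1] < 2:
        raise ValueError("need >= 3 dates and >= 2 species")
    sd = rates.std(ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance species: {dropped}", stacklevel=2)
        rates = rates.drop(columns=dropped)
    z = (rates - rates.mean()) / rates.std(ddof=1)
    k = n_components or min(z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    raw_scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T  # species x components, orthonormal
    # sign convention
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            raw_scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    pct = 100 * pca.explained_variance_ratio_
    return GuildPCA(
        loadings=pd.DataFrame(loadings, index=rates.columns, columns=names),
        percent_variance=pct,
        scores=pd.DataFrame(raw_scores, index=rates.index, columns=names),
    )


def pc_env_correlation(guilds: GuildPCA, env: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r of each principal-component score series with each environmental
    variable across shared dates, with the |r| significance threshold."""
    shared = guilds.scores.index.intersection(env.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared dates")
    rows = []
    for pc in guilds.scores.columns:
        for var in env.columns:
            x = guilds.scores.loc[shared, pc].to_numpy(float)
            y = env.loc[shared, var].to_numpy(float)
            mask = ~(np.isnan(x) | np.isnan(y))
            n = int(mask.sum())
            r = (float(np.corrcoef(x[mask], y[mask])[0, 1])
                 if n >= 3 and x[mask].std() > 0 and y[mask].std() > 0 else np.nan)
            rows.append({
                "component": pc, "variable": var, "r": r, "n": n,
                "critical_r": critical_r(n, alpha) if n >= 4 else np.nan,
            })
    return pd.DataFrame(rows)
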