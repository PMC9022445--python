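"""Incidence-based diversity: sample-based rarefaction, Chao2 richness, and
resampling-based optimization of the (locations x occasions) sampling design.

The working object is a binary incidence matrix: rows are (location, occasion)
samples, columns species, with Q_i the number of samples containing species i.
Sample-based rarefaction gives the expected richness in t pooled samples drawn
without replacement:

    E[S_t] = S_obs - sum_i C(T - Q_i, t) / C(T, t)

computed with log-binomials for numerical stability.  The design surface asks
how expected richness trades off between adding recording locations and adding
sampling occasions, by resampling an occasion-extended dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .ingest import CountMatrix, Recording


@dataclass
class IncidenceMatrix:
    """Binary (location, occasion) x species detection matrix."""

    data: pd.DataFrame  # MultiIndex (location, occasion) rows, species columns

    def __post_init__(self):
        arr = self.data.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("incidence cells must be 0/1")
        self.data = self.data.astype(np.int8)

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def Q(self) -> pd.Series:
        """Per-species incidence frequency: number of samples containing it."""
        return self.data.sum(axis=0)

    @property
    def s_obs(self) -> int:
        return int((self.Q > 0).sum())

    @property
    def locations(self) -> list:
        return list(self.data.index.get_level_values("location").unique())

    def for_location(self, location) -> "IncidenceMatrix":
        return IncidenceMatrix(self.data.xs(location, level="location", drop_level=False))


def incidence_from_counts(cm: CountMatrix, recordings: list[Recording],
                          exclude_taxa: tuple[str, ...] = ("mammal",)
                          ) -> IncidenceMatrix:
    """Binarize the count matrix into (location, occasion) incidence.

    Location = site, occasion = date.  Mammals are excluded by default: bird
    richness is the usual reporting unit; pass ``exclude_taxa=()`` to keep all.
    Excluded recordings are dropped.
    """
    keep = [s for s in cm.counts.columns if cm.taxon_of(s) not in exclude_taxa]
    meta = {r.recording_id: (r.site_id, r.date) for r in recordings if not r.excluded}
    rows = cm.counts.index.intersection(list(meta))
    inc = (cm.counts.loc[rows, keep] > 0).astype(np.int8)
    idx = pd.MultiIndex.from_tuples([meta[r] for r in rows],
                                    names=["location", "occasion"])
    inc.index = idx
    return IncidenceMatrix(inc.sort_index())


def rarefaction_expected(inc: IncidenceMatrix, t: int) -> float:
    """Expected species richness in ``t`` pooled samples (sample-based rarefaction)."""
    T = inc.T
    if not 1 <= t <= T:
        raise ValueError(f"t must be in [1, {T}]")
    Q = inc.Q.to_numpy()
    Q = Q[Q > 0]

    def log_binom(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    miss = np.zeros(Q.size)
    feasible = (T - Q) >= t  # species can be absent from a t-subset
    tq = (T - Q)[feasible]
    miss[feasible] = np.exp(log_binom(tq, t) - log_binom(T, t))
    return float(Q.size - miss.sum())


def rarefaction_curve(inc: IncidenceMatrix) -> pd.Series:
    """E[S_t] for t = 1..T."""
    return pd.Series(
        {t: rarefaction_expected(inc, t) for t in range(1, inc.T + 1)},
        name="expected_richness",
    )


@dataclass
class Chao2Estimate:
    estimate: float
    se: float
    s_obs: int
    q1: int
    q2: int


def chao2(inc: IncidenceMatrix) -> Chao2Estimate:
    """Chao2 incidence-based richness estimate with SE.

    Classic form when duplicates exist (Q2 > 0):

        S_chao2 = S_obs + ((T-1)/T) * Q1^2 / (2 Q2)

    bias-corrected when Q2 = 0.  The variance uses the standard asymptotic
    formulas for each case.
    """
    T = inc.T
    if T < 2:
        raise ValueError("chao2 requires T >= 2")
    Q = inc.Q
    q1 = int((Q == 1).sum())
    q2 = int((Q == 2).sum())
    s_obs = inc.s_obs
    A = (T - 1) / T
    if q2 > 0:
        est = s_obs + A * q1**2 / (2 * q2)
        ratio = q1 / q2
        var = q2 * (0.5 * A * ratio**2 + A**2 * ratio**3 + 0.25 * A**2 * ratio**4)
    else:
        est = s_obs + A * q1 * (q1 - 1) / 2
        var = (A * q1 * (q1 - 1) / 2
               + A**2 * q1 * (2 * q1 - 1) ** 2 / 4
               - A**2 * q1**4 / (4 * max(est, 1.0)))
        var = max(var, 0.0)
    return Chao2Estimate(float(est), float(np.sqrt(var)), s_obs, q1, q2)


def accumulation_curves(inc: IncidenceMatrix) -> pd.DataFrame:
    """Single-location average and pooled species accumulation curves.

    The single-location curve at t is the mean, over locations with >= t
    occasions, of that location's rarefaction curve (alpha/beta-diversity); the
    pooled curve treats all samples as one pool (gamma-diversity).
    """
    pooled = rarefaction_curve(inc)
    per_loc = {loc: rarefaction_curve(inc.for_location(loc)) for loc in inc.locations}
    single = pd.DataFrame(per_loc).mean(axis=1)
    out = pd.DataFrame({"pooled": pooled, "single_location_mean": single})
    out.index.name = "t"
    return out


def extend_occasions(inc: IncidenceMatrix, target_occasions: int = 190,
                     seed: int | None = None) -> IncidenceMatrix:
    """Extend each location to ``target_occasions`` by resampling its observed
    occasion rows with replacement (preserving within-occasion co-occurrence).

    A species never seen at a location cannot appear in that location's
    extension.  Observed rows are kept and the remainder drawn at random.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for loc in inc.locations:
        sub = inc.data.xs(loc, level="location")
        n_obs = len(sub)
        if n_obs < 1:
            raise ValueError(f"location {loc} has no observed occasions")
        if target_occasions < n_obs:
            raise ValueError("target_occasions below observed count; truncation unsupported")
        extra = rng.integers(0, n_obs, size=target_occasions - n_obs)
        rows = np.concatenate([np.arange(n_obs), extra])
        block = sub.iloc[rows].copy()
        block.index = pd.MultiIndex.from_product(
            [[loc], range(target_occasions)], names=["location", "occasion"]
        )
        blocks.append(block)
    return IncidenceMatrix(pd.concat(blocks))


@dataclass
class DesignSurface:
    """Mean species richness over a grid of (n_locations, n_occasions) designs."""

    surface: pd.DataFrame  # columns: n_locations, n_occasions, mean_richness, se
    n_rep: int
    seed: int | None

    def frontier(self, budget: int) -> pd.DataFrame:
        """Designs whose total effort n_locations * n_occasions equals ``budget``."""
        s = self.surface
        return s[s["n_locations"] * s["n_occasions"] == budget].reset_index(drop=True)


def design_surface(ext: IncidenceMatrix, n_rep: int = 1000,
                   seed: int | None = None,
                   locations_grid: list[int] | None = None,
                   occasions_grid: list[int] | None = None) -> DesignSurface:
    """Expected richness for every (n_locations, n_occasions) sampling design.

    Each replicate draws ``n_locations`` locations without replacement, then
    ``n_occasions`` occasions without replacement independently within each
    chosen location, and counts the distinct species detected.  The cell value
    is the mean over ``n_rep`` replicates (with its Monte-Carlo SE).
    """
    locs = ext.locations
    n_loc_avail = len(locs)
    occ_per_loc = min(len(ext.data.xs(loc, level="location")) for loc in locs)
    lgrid = locations_grid or list(range(1, n_loc_avail + 1))
    ogrid = occasions_grid or list(range(1, occ_per_loc + 1))
    if max(lgrid) > n_loc_avail or max(ogrid) > occ_per_loc:
        raise ValueError("grid cell exceeds available locations/occasions")

    rng = np.random.default_rng(seed)
    # dense bool array per location: occasions x species
    arr = {loc: ext.data.xs(loc, level="location").to_numpy(bool) for loc in locs}
    rows = []
    for nl in lgrid:
        for no in ogrid:
            richness = np.empty(n_rep)
            for rep in range(n_rep):
                chosen = rng.choice(n_loc_avail, size=nl, replace=False)
                seen = None
                for li in chosen:
                    a = arr[locs[li]]
                    occ = rng.choice(a.shape[0], size=no, replace=False)
                    det = a[occ].any(axis=0)
                    seen = det if seen is None else (seen | det)
                richness[rep] = seen.sum()
            rows.append({
                "n_locations": nl, "n_occasions": no,
                "mean_richness": float(richness.mean()),
                "se": float(richness.std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0,
            })
    return DesignSurface(pd.DataFrame(rows), n_rep=n_rep, seed=seed)
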