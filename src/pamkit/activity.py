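"""Vocalization-activity analysis: transforms, daily rate series, environmental
correlations, habitat ANOVA, and phenology.

Species-specific vocalization counts per 10-min recording are right-skewed
(approximately gamma), and a square-root transform normalizes them well; all
rate series here are means of sqrt-transformed counts.  Rate series are plain
pandas objects: long DataFrames with columns ``date``, ``unit``, ``species``,
``rate`` (one row per date x aggregation unit), or date-indexed wide frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .ingest import CountMatrix, Recording, Site, ValidationError

DEFAULT_ALPHAS = (0.05, 0.01, 0.001)


def transform_counts(cm: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Element-wise square root of the count matrix."""
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    if (counts.to_numpy() < 0).any():
        raise ValidationError("counts must be nonnegative")
    return np.sqrt(counts.astype(float))


def _unit_map(recordings: list[Recording], level: str,
              sites: list[Site] | None) -> dict[str, str]:
    if level == "recorder":
        return {r.recording_id: r.site_id for r in recordings}
    if level == "all":
        return {r.recording_id: "all" for r in recordings}
    if sites is None:
        raise ValidationError(f"level {level!r} requires site metadata")
    site_info = {s.site_id: s for s in sites}
    if level == "stand":
        return {
            r.recording_id: f"{site_info[r.site_id].watershed}/{site_info[r.site_id].forest_age}"
            for r in recordings
        }
    if level == "watershed":
        return {r.recording_id: site_info[r.site_id].watershed for r in recordings}
    raise ValidationError(f"unknown aggregation level {level!r}")


def daily_means(tcm: pd.DataFrame, recordings: list[Recording],
                level: str = "recorder", sites: list[Site] | None = None,
                hierarchical: bool = False) -> pd.DataFrame:
    """Mean transformed rate per (date, unit, species).

    ``level`` is one of ``recorder``/``stand``/``watershed``/``all``.  With
    ``hierarchical=True`` the watershed level averages recorders within stands
    first and then stands within watersheds (the two agree when stands are
    balanced).  Excluded recordings are dropped.
    """
    active = [r for r in recordings if not r.excluded and r.recording_id in tcm.index]
    if not active:
        raise ValidationError("no retained recordings in matrix")
    if hierarchical and level == "watershed":
        stand = daily_means(tcm, recordings, "stand", sites)
        site_ws = {s.site_id: s.watershed for s in sites}
        stand["unit"] = stand["unit"].str.split("/").str[0]
        return (
            stand.groupby(["date", "unit", "species"], as_index=False)["rate"].mean()
        )
    umap = _unit_map(active, level, sites)
    dates = {r.recording_id: r.date for r in active}
    long = tcm.loc[[r.recording_id for r in active]].rename_axis("recording_id").reset_index()
    long = long.melt(id_vars="recording_id", var_name="species", value_name="rate")
    long["date"] = long["recording_id"].map(dates)
    long["unit"] = long["recording_id"].map(umap)
    return long.groupby(["date", "unit", "species"], as_index=False)["rate"].mean()


def rate_matrix(long: pd.DataFrame, species: str) -> pd.DataFrame:
    """Pivot one species' long rate series to dates x units."""
    sub = long[long["species"] == species]
    return sub.pivot(index="date", columns="unit", values="rate").sort_index()


def species_by_date(tcm: pd.DataFrame, recordings: list[Recording]) -> pd.DataFrame:
    """Dates x species matrix of mean transformed rates across all recorders."""
    long = daily_means(tcm, recordings, level="all")
    return long.pivot(index="date", columns="species", values="rate").sort_index()


def total_rate(cm: CountMatrix, recordings: list[Recording],
               exclude_taxa: tuple[str, ...] = ()) -> pd.Series:
    """Per-date mean of sqrt(total vocalizations per recording)."""
    counts = cm.counts
    keep = [s for s in counts.columns if cm.taxon_of(s) not in exclude_taxa]
    per_rec = np.sqrt(counts[keep].sum(axis=1).astype(float))
    dates = {r.recording_id: r.date for r in recordings if not r.excluded}
    per_rec = per_rec[per_rec.index.isin(dates)]
    return per_rec.groupby(per_rec.index.map(dates)).mean().rename("all")


# ---------------------------------------------------------------------------
# correlations with environment


def critical_r(n: int, alpha: float = 0.05) -> float:
    """|r| threshold for a two-sided test of zero correlation, df = n - 2."""
    if n < 4:
        raise ValidationError("critical_r requires n >= 4")
    t_star = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t_star / np.sqrt(t_star**2 + n - 2))


@dataclass
class EnvCorrelation:
    """Pairwise Pearson correlations among environment and rate variables.

    ``r``: symmetric correlation matrix (unit diagonal, NaN where a variable
    has no variance); ``n``: pairwise-complete sample sizes; ``critical``:
    per-pair |r| thresholds at the requested alpha levels (keyed by alpha).
    No multiple-testing correction is applied.
    """

    r: pd.DataFrame
    n: pd.DataFrame
    critical: dict[float, pd.DataFrame]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.r.abs() > self.critical[alpha]


def correlate_env(rates: pd.DataFrame | pd.Series, weather: pd.DataFrame,
                  ambient: pd.Series | None = None,
                  alphas: tuple[float, ...] = DEFAULT_ALPHAS) -> EnvCorrelation:
    """Full correlation matrix over rate series, weather covariates, and ambient sound.

    All inputs must be indexed by date.  Observations are pairwise-complete;
    ``n`` reports the per-pair date count (>= 3 required somewhere).
    """
    parts = [weather.copy()]
    rates = rates.to_frame() if isinstance(rates, pd.Series) else rates
    parts.append(rates)
    if ambient is not None:
        parts.append(ambient.rename("ambient_sound").to_frame())
    combined = pd.concat(parts, axis=1)
    notna = combined.notna().astype(int)
    n = pd.DataFrame(notna.T.to_numpy() @ notna.to_numpy(),
                     index=combined.columns, columns=combined.columns)
    if int(n.to_numpy().max()) < 3:
        raise ValidationError("fewer than 3 shared dates")
    r = combined.corr(method="pearson", min_periods=3)
    np.fill_diagonal(r.values, 1.0)
    crit = {}
    for alpha in alphas:
        nv = n.to_numpy().astype(float)
        with np.errstate(invalid="ignore"):
            thr = np.where(nv >= 4,
                           np.vectorize(lambda m: critical_r(int(m), alpha) if m >= 4 else np.nan)(nv),
                           np.nan)
        crit[alpha] = pd.DataFrame(thr, index=n.index, columns=n.columns)
    return EnvCorrelation(r=r, n=n, critical=crit)


# ---------------------------------------------------------------------------
# habitat comparison


def habitat_anova(data: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects ANOVA of daily stand-level rates on habitat structure.

    ``data`` needs columns ``rate``, ``forest_age``, ``watershed``, ``date``
    (one row per date x forest_age x watershed cell mean).  Effects: forest
    age, watershed, their interaction, and date (categorical), fitted by least
    squares with sequential (type-I) sums of squares, which coincide with the
    classical decomposition in the balanced case.
    """
    for col in ("rate", "forest_age", "watershed", "date"):
        if col not in data.columns:
            raise ValidationError(f"habitat_anova: missing column {col!r}")
    for col in ("forest_age", "watershed"):
        if data[col].nunique() < 2:
            raise ValidationError(f"factor {col!r} needs >= 2 levels")
    cells = data.groupby(["forest_age", "watershed"]).size()
    if len(cells) < data["forest_age"].nunique() * data["watershed"].nunique():
        raise ValidationError("empty forest_age x watershed cells: interaction inestimable")
    model = smf.ols(
        "rate ~ C(forest_age) + C(watershed) + C(forest_age):C(watershed) + C(date)",
        data=data,
    ).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table.index = [
        {
            "C(forest_age)": "forest_age",
            "C(watershed)": "watershed",
            "C(forest_age):C(watershed)": "forest_age:watershed",
            "C(date)": "date",
            "Residual": "residual",
        }.get(ix, ix)
        for ix in table.index
    ]
    return table


def phenology_series(tcm: pd.DataFrame, recordings: list[Recording],
                     species: list[str]) -> pd.DataFrame:
    """Date-ordered mean +/- SE of transformed rates across recorders, per species.

    Dates with no detection of a species report 0 (the recorders were running;
    absence of vocalization is data, not missingness).
    """
    active = [r for r in recordings if not r.excluded and r.recording_id in tcm.index]
    dates = {r.recording_id: r.date for r in active}
    if len(set(dates.values())) < 2:
        raise ValidationError("phenology requires >= 2 dates")
    sub = tcm.loc[list(dates)].copy()
    for sp in species:
        if sp not in sub.columns:
            sub[sp] = 0.0
    sub = sub[species]
    sub["date"] = sub.index.map(dates)
    grouped = sub.groupby("date")
    rows = []
    for sp in species:
        g = grouped[sp]
        agg = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
        agg["se"] = agg["sd"] / np.sqrt(agg["n"])
        for date, row in agg.iterrows():
            rows.append({"species": sp, "date": date, "mean": row["mean"],
                         "se": 0.0 if np.isnan(row["se"]) else row["se"],
                         "n": int(row["n"])})
    return pd.DataFrame(rows).sort_values(["species", "date"]).reset_index(drop=True)
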