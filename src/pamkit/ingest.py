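"""Reading, validation, and summary of annotation data.

The central in-memory object is the :class:`CountMatrix`: recordings x species
vocalization counts, built from a long-format ("tidy") annotation table with one
row per (recording, species) pair.  Long format is canonical on disk; the wide
matrix exists only in memory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

ANNOTATION_COLUMNS = ("recording_id", "site_id", "date", "species", "count")

RAVEN_BEGIN = "Begin Time (s)"
RAVEN_END = "End Time (s)"
RAVEN_LOW = "Low Freq (Hz)"
RAVEN_HIGH = "High Freq (Hz)"


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass(frozen=True)
class Recording:
    """One timed recording bout at a site.

    ``rain_rank`` follows the five-tier audible-rain scale (0 = absent ...
    4 = very hard rain); ``wind_rank`` the three-tier wind scale (0-2).
    """

    recording_id: str
    site_id: str
    date: str
    start_clock: str = "06:20"
    duration_s: float = 600.0
    year: int | None = None
    rain_rank: int = 0
    wind_rank: int = 0
    excluded: bool = False

    def __post_init__(self):
        if self.rain_rank not in (0, 1, 2, 3, 4):
            raise ValidationError(f"rain_rank must be 0-4, got {self.rain_rank!r}")
        if self.wind_rank not in (0, 1, 2):
            raise ValidationError(f"wind_rank must be 0-2, got {self.wind_rank!r}")
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be > 0")


@dataclass(frozen=True)
class Site:
    site_id: str
    latitude: float
    longitude: float
    watershed: str = ""
    forest_age: str = ""
    elevation_m: float = float("nan")

    def __post_init__(self):
        if not (math.isnan(self.latitude) or abs(self.latitude) <= 90):
            raise ValidationError(f"site {self.site_id}: |latitude| > 90")
        if not (math.isnan(self.longitude) or abs(self.longitude) <= 180):
            raise ValidationError(f"site {self.site_id}: |longitude| > 180")


@dataclass
class CountMatrix:
    """Recordings x species nonnegative integer vocalization counts.

    ``counts`` is a wide DataFrame (index: recording ids, columns: species
    codes).  ``taxon_class`` maps each species code to ``"bird"`` or
    ``"mammal"``; unknown codes default to ``"bird"``.
    """

    counts: pd.DataFrame
    taxon_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate recording ids")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate species codes")
        arr = c.to_numpy()
        if arr.size and ((arr < 0).any() or not np.allclose(arr, np.round(arr))):
            raise ValidationError("counts must be nonnegative integers")
        self.counts = c.astype(np.int64)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def recording_ids(self) -> list[str]:
        return list(self.counts.index)

    def taxon_of(self, code: str) -> str:
        return self.taxon_class.get(code, "bird")

    def to_long(self, drop_zeros: bool = True) -> pd.DataFrame:
        long = (
            self.counts.rename_axis("recording_id")
            .reset_index()
            .melt(id_vars="recording_id", var_name="species", value_name="count")
        )
        if drop_zeros:
            long = long[long["count"] > 0]
        return long.reset_index(drop=True)


@dataclass
class SelectionTable:
    """Raven-convention selection table: time-frequency boxes of annotated sounds."""

    selections: pd.DataFrame  # columns: selection, begin_s, end_s, low_hz, high_hz, species
    recording_id: str = ""

    def __post_init__(self):
        sel = self.selections
        bad = sel[sel["end_s"] <= sel["begin_s"]]
        if len(bad):
            raise ValidationError(
                f"selection {bad['selection'].iloc[0]}: end time must exceed begin time"
            )
        bad = sel[sel["high_hz"] < sel["low_hz"]]
        if len(bad):
            raise ValidationError(
                f"selection {bad['selection'].iloc[0]}: low frequency exceeds high"
            )
        self.selections = sel.sort_values("begin_s", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.selections)

    def intervals(self) -> np.ndarray:
        """(n, 2) array of (begin_s, end_s)."""
        return self.selections[["begin_s", "end_s"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers


def read_annotations(path) -> tuple[CountMatrix, list[Recording]]:
    """Read a long-format annotation CSV into a count matrix plus recordings.

    Required columns: recording_id, site_id, date, species, count.  Optional:
    taxon_class, year, start_clock, duration_s, rain_rank, wind_rank.  Missing
    (recording, species) pairs become zeros; unknown species codes are kept
    verbatim.
    """
    df = pd.read_csv(path, dtype={"recording_id": str, "site_id": str, "species": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation file missing columns: {missing}")

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0) | (counts != np.round(counts))]
    if len(bad):
        i = bad[0]
        raise ValidationError(
            f"row {i}: count {df.loc[i, 'count']!r} for "
            f"({df.loc[i, 'recording_id']}, {df.loc[i, 'species']}) "
            "is not a nonnegative integer"
        )
    df["count"] = counts.astype(np.int64)

    dup = df.duplicated(subset=["recording_id", "species"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate (recording, species) pair: ({r['recording_id']}, {r['species']})"
        )

    wide = (
        df.pivot(index="recording_id", columns="species", values="count")
        .fillna(0)
        .astype(np.int64)
    )
    taxa = {}
    if "taxon_class" in df.columns:
        taxa = (
            df.dropna(subset=["taxon_class"])
            .drop_duplicates("species")
            .set_index("species")["taxon_class"]
            .to_dict()
        )

    meta_cols = {
        "year": None, "start_clock": "06:20", "duration_s": 600.0,
        "rain_rank": 0, "wind_rank": 0,
    }
    recs = []
    for rid, grp in df.groupby("recording_id", sort=True):
        row = grp.iloc[0]
        kwargs = {}
        for col, default in meta_cols.items():
            if col in df.columns and not pd.isna(row[col]):
                val = row[col]
                if col in ("year", "rain_rank", "wind_rank"):
                    val = int(val)
                elif col == "duration_s":
                    val = float(val)
                kwargs[col] = val
            elif default is not None:
                kwargs[col] = default
        date = str(row["date"])
        if "year" not in kwargs:
            kwargs["year"] = int(date[:4]) if date[:4].isdigit() else None
        recs.append(Recording(recording_id=str(rid), site_id=str(row["site_id"]),
                              date=date, **kwargs))
    return CountMatrix(wide, taxa), recs


def write_annotations(cm: CountMatrix, recordings: list[Recording], path) -> None:
    """Write the long-format annotation CSV (inverse of :func:`read_annotations`)."""
    meta = pd.DataFrame(
        [
            {
                "recording_id": r.recording_id, "site_id": r.site_id, "date": r.date,
                "year": r.year, "start_clock": r.start_clock,
                "duration_s": r.duration_s, "rain_rank": r.rain_rank,
                "wind_rank": r.wind_rank,
            }
            for r in recordings
        ]
    )
    long = cm.to_long(drop_zeros=True)
    # recordings with no detections keep one explicit zero row so the
    # round trip preserves the matrix shape
    silent = set(cm.recording_ids) - set(long["recording_id"])
    if silent and cm.species:
        zero_rows = pd.DataFrame(
            {"recording_id": sorted(silent), "species": cm.species[0], "count": 0}
        )
        long = pd.concat([long, zero_rows], ignore_index=True)
    long["taxon_class"] = long["species"].map(cm.taxon_of)
    out = long.merge(meta, on="recording_id", how="left")
    cols = ["recording_id", "site_id", "date", "species", "count", "taxon_class",
            "year", "start_clock", "duration_s", "rain_rank", "wind_rank"]
    out[cols].to_csv(path, index=False)


def read_selection_table(path, species_column: str = "Species",
                         recording_id: str = "") -> SelectionTable:
    """Read a Raven-style tab-separated selection table.

    ``species_column`` names the annotation column carrying the species code
    (Raven allows arbitrary annotation column names).
    """
    df = pd.read_csv(path, sep="\t")
    for col in (RAVEN_BEGIN, RAVEN_END):
        if col not in df.columns:
            raise ValidationError(f"selection table missing column {col!r}")
    sel = pd.DataFrame(
        {
            "selection": df.get("Selection", pd.Series(range(1, len(df) + 1))),
            "begin_s": df[RAVEN_BEGIN].astype(float),
            "end_s": df[RAVEN_END].astype(float),
            "low_hz": df.get(RAVEN_LOW, pd.Series(0.0, index=df.index)).astype(float),
            "high_hz": df.get(RAVEN_HIGH, pd.Series(np.inf, index=df.index)).astype(float),
            "species": df.get(species_column, pd.Series("", index=df.index)).astype(str),
        }
    )
    return SelectionTable(sel, recording_id=recording_id)


def write_selection_table(table: SelectionTable, path,
                          species_column: str = "Species") -> None:
    sel = table.selections
    out = pd.DataFrame(
        {
            "Selection": sel["selection"],
            "View": "Spectrogram 1",
            "Channel": 1,
            RAVEN_BEGIN: sel["begin_s"].round(2),
            RAVEN_END: sel["end_s"].round(2),
            RAVEN_LOW: sel["low_hz"],
            RAVEN_HIGH: sel["high_hz"],
            species_column: sel["species"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_sites(path) -> list[Site]:
    df = pd.read_csv(path, dtype={"site_id": str})
    sites = []
    for _, row in df.iterrows():
        sites.append(
            Site(
                site_id=str(row["site_id"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                watershed=str(row.get("watershed", "")),
                forest_age=str(row.get("forest_age", "")),
                elevation_m=float(row.get("elevation_m", float("nan"))),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# summaries


def summarize_species(cm: CountMatrix, recordings: list[Recording] | None = None,
                      group_by: str | None = None) -> pd.DataFrame:
    """Per-species vocalization totals, optionally split by a grouping unit.

    Returns a DataFrame indexed by species code, sorted descending by grand
    total, with a ``total`` column plus one column per group level when
    ``group_by`` is one of ``year``/``site``/``watershed`` (watershed requires
    recordings whose site ids encode it, or use daily_means upstream).
    """
    if cm.counts.size == 0:
        raise ValidationError("empty count matrix")
    out = pd.DataFrame({"total": cm.counts.sum(axis=0)})
    if group_by is not None:
        if recordings is None:
            raise ValidationError("group_by requires recordings metadata")
        key = {
            "year": {r.recording_id: r.year for r in recordings},
            "site": {r.recording_id: r.site_id for r in recordings},
            "date": {r.recording_id: r.date for r in recordings},
        }.get(group_by)
        if key is None:
            raise ValidationError(f"unsupported group_by {group_by!r}")
        groups = cm.counts.groupby(cm.counts.index.map(key)).sum().T
        groups.columns = [f"{group_by}={g}" for g in groups.columns]
        out = out.join(groups)
    out["taxon_class"] = [cm.taxon_of(s) for s in out.index]
    return out.sort_values("total", ascending=False)


def recording_summary(cm: CountMatrix) -> pd.DataFrame:
    """Per-recording total vocalizations and number of species detected."""
    return pd.DataFrame(
        {
            "total_vocalizations": cm.counts.sum(axis=1),
            "species_detected": (cm.counts > 0).sum(axis=1),
        }
    )


def dominance_share(cm: CountMatrix, recordings: list[Recording] | None = None,
                    year: int | None = None, top_k: int | None = None,
                    species: str | None = None,
                    exclude_taxa: tuple[str, ...] = ()) -> float:
    """Percentage of vocalizations from the top-k species or one named species.

    Species are ranked by within-year totals; the denominator is the year total
    after removing species whose taxon class is in ``exclude_taxa``.  Returned
    to one decimal place (the conventional reporting precision).
    """
    if (top_k is None) == (species is None):
        raise ValidationError("specify exactly one of top_k or species")
    counts = cm.counts
    if year is not None:
        if recordings is None:
            raise ValidationError("year filtering requires recordings metadata")
        ids = [r.recording_id for r in recordings if r.year == year]
        if not ids:
            raise ValidationError(f"no recordings in year {year}")
        counts = counts.loc[counts.index.intersection(ids)]
    totals = counts.sum(axis=0)
    kept = totals[[s for s in totals.index if cm.taxon_of(s) not in exclude_taxa]]
    denom = kept.sum()
    if denom == 0:
        raise ValidationError("no vocalizations in denominator")
    if top_k is not None:
        if top_k > (kept > 0).size:
            raise ValidationError(f"top_k={top_k} exceeds species count")
        numer = kept.sort_values(ascending=False).iloc[:top_k].sum()
    else:
        if species not in kept.index:
            raise ValidationError(f"species {species!r} not in matrix")
        numer = kept[species]
    return round(100.0 * numer / denom, 1)


def pairwise_distances(sites: list[Site]) -> pd.DataFrame:
    """Great-circle (haversine) distances between sites, in meters."""
    if len(sites) < 2:
        raise ValidationError("need at least 2 sites")
    for s in sites:
        if math.isnan(s.latitude) or math.isnan(s.longitude):
            raise ValidationError(f"site {s.site_id}: missing coordinates")
    lat = np.radians([s.latitude for s in sites])
    lon = np.radians([s.longitude for s in sites])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    ids = [s.site_id for s in sites]
    return pd.DataFrame(d, index=ids, columns=ids)


def apply_exclusions(recordings: list[Recording], max_rain_rank: int = 2,
                     explicit_dates: set[str] | frozenset[str] = frozenset()
                     ) -> list[Recording]:
    """Flag recordings made in heavy rain or on explicitly excluded dates.

    Returns a new list with ``excluded`` set; recordings already excluded stay
    excluded.  The number of newly excluded recordings is logged.
    """
    out = []
    n_new = 0
    for r in recordings:
        flag = r.rain_rank > max_rain_rank or r.date in explicit_dates
        if flag and not r.excluded:
            n_new += 1
        out.append(replace(r, excluded=r.excluded or flag))
    logger.info("apply_exclusions: %d recordings newly excluded", n_new)
    return out


def retained(recordings: list[Recording]) -> list[Recording]:
    return [r for r in recordings if not r.excluded]


def repeatability(first: CountMatrix, second: CountMatrix
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """Annotation repeatability between two blind passes over the same recordings.

    Returns per-species squared Pearson correlation of counts across the shared
    recordings (NaN where a species has zero variance in either pass), plus a
    per-recording boolean: are the detected species sets identical?
    """
    shared = first.counts.index.intersection(second.counts.index)
    if len(shared) == 0:
        raise ValidationError("no shared recording ids between passes")
    species = first.counts.columns.union(second.counts.columns)
    a = first.counts.reindex(index=shared, columns=species, fill_value=0)
    b = second.counts.reindex(index=shared, columns=species, fill_value=0)
    rows = []
    for sp in species:
        x, y = a[sp].to_numpy(float), b[sp].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"species": sp, "r2": r2, "n": len(shared)})
    same_sets = pd.Series(
        [(a.loc[rid] > 0).equals(b.loc[rid] > 0) for rid in shared],
        index=shared, name="species_set_identical",
    )
    return pd.DataFrame(rows).set_index("species"), same_sets
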