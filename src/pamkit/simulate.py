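"""Synthetic data with the statistical structure the analyses assume.

Three generators provide ground truth for every pipeline stage:

* :func:`simulate_counts` — per (site, date, species) vocalization counts.
  Counts are generated on the square-root scale, where a normal model holds
  (field count distributions are gamma-like and sqrt-normalize well), then
  squared and rounded.  The sqrt-scale mean combines a species baseline
  (drawn per site from a gamma rate distribution), a seasonal linear trend, a
  guild-shared day factor, a spatially correlated local day effect with
  exponential distance decay, and suppression proportional to the day's
  ambient-noise covariate.  Because generation happens on the sqrt scale, the
  analysis-side square-root transform is exactly the right normalization.
* :func:`simulate_weather` — multivariate-normal daily covariates with a
  configurable cross-correlation target (default: a positively intercorrelated
  wind / dripping / ambient-sound block), zero-inflated precipitation.
* :func:`simulate_audio` — soundscape audio: Gaussian background of known
  sigma, band-limited chirp "songs" with Hann envelopes, and short broadband
  "drip" transients, plus the ground-truth selection table of song events.

All generators are fully seeded; the same seed reproduces outputs exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ambient import Waveform
from .ingest import CountMatrix, Recording, SelectionTable, Site

# ---------------------------------------------------------------------------
# site layouts and dates


def default_site_layout(n_sites: int = 10, origin: tuple[float, float] = (43.94, -71.75)
                        ) -> list[Site]:
    """A study-like layout: ``n_sites`` recorders with pairwise separations
    spanning roughly 176-1729 m, placed on fixed offsets from ``origin``."""
    offsets_m = [
        (0, 0), (175, 25), (330, -130), (450, 280), (690, 40),
        (840, -250), (1010, 330), (1220, -70), (1450, 190), (1700, -310),
    ]
    if n_sites > len(offsets_m):
        raise ValueError(f"layout supports up to {len(offsets_m)} sites")
    lat0, lon0 = origin
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(lat0))
    sites = []
    for i, (dx, dy) in enumerate(offsets_m[:n_sites]):
        sites.append(Site(
            site_id=f"S{i + 1:02d}",
            latitude=lat0 + dy / m_per_deg_lat,
            longitude=lon0 + dx / m_per_deg_lon,
            watershed="HB", forest_age="mature", elevation_m=600.0,
        ))
    return sites


def default_dates(n_dates: int = 19, year: int = 2018) -> list[str]:
    """Evenly spaced breeding-season sampling dates (mid-May onward)."""
    start = pd.Timestamp(year=year, month=5, day=13)
    return [(start + pd.Timedelta(days=3 * i)).strftime("%Y-%m-%d")
            for i in range(n_dates)]


# ---------------------------------------------------------------------------
# community count model


@dataclass
class SpeciesSpec:
    """Generative parameters for one species.

    ``baseline_shape``/``baseline_scale``: gamma distribution of the species'
    per-site baseline call rate (counts per recording); ``seasonal_slope``:
    linear date trend on the sqrt scale over the season (sqrt-counts per unit
    of the standardized date); ``guild``: which latent day factor the species
    loads on (0 = none); ``guild_loading``: its loading; ``noise_coeff``:
    sqrt-scale suppression per SD of the ambient covariate; ``occupancy``:
    probability the species is present at a given site at all.
    """

    code: str
    baseline_shape: float = 8.0
    baseline_scale: float = 4.0
    fixed_baseline: float | None = None  # overrides the gamma draw when set
    seasonal_slope: float = 0.0
    guild: int = 0
    guild_loading: float = 1.0
    noise_coeff: float = 0.0
    occupancy: float = 1.0
    taxon_class: str = "bird"


@dataclass
class CommunitySpec:
    """Study conditions for the count generator.

    Defaults mirror the emulated field design: 10 sites with separations of
    ~180-1700 m, 19 breeding-season dates, sqrt-scale day effects with
    exponential spatial decay.  ``day_effect_sd`` is the SD of the local
    (site-level) day effect; ``spatial_range_m`` its exponential decay range;
    ``regional_sd`` a day effect shared by all sites; ``guild_sd`` the SD of
    each latent guild day factor; ``residual_sd`` the independent sqrt-scale
    noise per (site, date, species).
    """

    species: list[SpeciesSpec] = field(default_factory=lambda: [
        SpeciesSpec("SPA", baseline_shape=10, baseline_scale=10,
                    seasonal_slope=-0.8, guild=1),
        SpeciesSpec("SPB", baseline_shape=8, baseline_scale=6,
                    seasonal_slope=-0.5, guild=1),
        SpeciesSpec("SPC", baseline_shape=8, baseline_scale=5, guild=1),
        SpeciesSpec("SPD", baseline_shape=8, baseline_scale=5,
                    noise_coeff=0.8, guild=2),
        SpeciesSpec("SPE", baseline_shape=6, baseline_scale=5,
                    noise_coeff=0.6, guild=2),
        SpeciesSpec("SPF", baseline_shape=6, baseline_scale=4,
                    noise_coeff=0.5, guild=2),
        SpeciesSpec("SPG", baseline_shape=4, baseline_scale=3, occupancy=0.8),
        SpeciesSpec("SPH", baseline_shape=3, baseline_scale=3, occupancy=0.6),
        SpeciesSpec("SPI", baseline_shape=2, baseline_scale=2, occupancy=0.5),
        SpeciesSpec("SPJ", baseline_shape=1.5, baseline_scale=2, occupancy=0.4),
    ])
    sites: list[Site] = field(default_factory=default_site_layout)
    dates: list[str] = field(default_factory=default_dates)
    day_effect_sd: float = 0.7
    spatial_range_m: float = 500.0
    regional_sd: float = 0.4
    guild_sd: float = 0.6
    residual_sd: float = 0.5
    ambient_mean: float = -2.0
    ambient_sd: float = 0.4


@dataclass
class SimulatedCounts:
    """Generator output plus the latent truth used to create it."""

    count_matrix: CountMatrix
    recordings: list[Recording]
    sites: list[Site]
    truth: dict

    def write(self, out_dir) -> None:
        from pathlib import Path

        from .ingest import write_annotations

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_annotations(self.count_matrix, self.recordings, out / "annotations.csv")
        pd.DataFrame(
            [
                {"site_id": s.site_id, "watershed": s.watershed,
                 "forest_age": s.forest_age, "latitude": s.latitude,
                 "longitude": s.longitude, "elevation_m": s.elevation_m}
                for s in self.sites
            ]
        ).to_csv(out / "sites.csv", index=False)


def _exponential_day_effects(dist_m: np.ndarray, n_dates: int, sd: float,
                             range_m: float, rng: np.random.Generator) -> np.ndarray:
    """(n_dates, n_sites) draws with Cov = sd^2 * exp(-d/range)."""
    if sd == 0:
        return np.zeros((n_dates, dist_m.shape[0]))
    cov = sd**2 * np.exp(-dist_m / range_m)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    z = rng.standard_normal((n_dates, len(cov)))
    return z @ chol.T


def simulate_counts(spec: CommunitySpec, seed: int | None = None,
                    ambient: pd.Series | None = None) -> SimulatedCounts:
    """Draw a full annotation dataset from the community model.

    ``ambient`` optionally supplies the per-date ambient-noise covariate
    (log10 scale, e.g. from :func:`simulate_weather`); otherwise it is drawn
    as N(ambient_mean, ambient_sd).  The returned ``truth`` record carries all
    latent effects: site baselines, day effects, guild factors, the ambient
    series, and the noiseless sqrt-scale means.
    """
    from .ingest import pairwise_distances

    rng = np.random.default_rng(seed)
    n_sites, n_dates, n_species = len(spec.sites), len(spec.dates), len(spec.species)
    if n_sites < 1 or n_dates < 1 or n_species < 1:
        raise ValueError("spec dimensions must be positive")
    dist = (pairwise_distances(spec.sites).to_numpy()
            if n_sites > 1 else np.zeros((1, 1)))

    if ambient is None:
        amb = rng.normal(spec.ambient_mean, spec.ambient_sd, size=n_dates)
        ambient = pd.Series(amb, index=spec.dates, name="ambient_sound")
    amb_std = ((ambient.to_numpy() - ambient.mean())
               / (ambient.std() if ambient.std() > 0 else 1.0))

    date_x = np.linspace(-1, 1, n_dates)  # standardized season axis
    n_guilds = max((s.guild for s in spec.species), default=0)
    guild_factors = rng.normal(0, spec.guild_sd, size=(n_dates, n_guilds + 1))
    guild_factors[:, 0] = 0.0  # guild 0 = no shared factor
    regional = rng.normal(0, spec.regional_sd, size=n_dates)
    local = _exponential_day_effects(dist, n_dates, spec.day_effect_sd,
                                     spec.spatial_range_m, rng)

    occupied = np.array([
        rng.random(n_sites) < sp.occupancy for sp in spec.species
    ])  # species x sites
    baselines = np.array([
        np.full(n_sites, sp.fixed_baseline) if sp.fixed_baseline is not None
        else rng.gamma(sp.baseline_shape, sp.baseline_scale, size=n_sites)
        for sp in spec.species
    ])  # species x sites, count scale

    counts = np.zeros((n_sites, n_dates, n_species), dtype=np.int64)
    mu_store = np.zeros_like(counts, dtype=float)
    for k, sp in enumerate(spec.species):
        mu = np.sqrt(baselines[k])[:, None]  # sites x 1, sqrt scale
        mu = (mu
              + sp.seasonal_slope * date_x[None, :]
              + sp.guild_loading * guild_factors[:, sp.guild][None, :]
              + regional[None, :]
              + local.T
              - sp.noise_coeff * amb_std[None, :])
        y = mu + rng.normal(0, spec.residual_sd, size=mu.shape)
        c = np.where(y > 0, np.round(y**2), 0).astype(np.int64)
        c[~occupied[k], :] = 0
        counts[:, :, k] = c
        mu_store[:, :, k] = mu

    rec_ids, rows, recs = [], [], []
    for i, site in enumerate(spec.sites):
        for d, date in enumerate(spec.dates):
            rid = f"{site.site_id}_{date}"
            rec_ids.append(rid)
            rows.append(counts[i, d, :])
            recs.append(Recording(recording_id=rid, site_id=site.site_id,
                                  date=date, year=int(date[:4])))
    cm = CountMatrix(
        pd.DataFrame(rows, index=rec_ids, columns=[s.code for s in spec.species]),
        {s.code: s.taxon_class for s in spec.species},
    )
    truth = {
        "ambient": ambient,
        "baselines": baselines,
        "occupied": occupied,
        "guild_factors": guild_factors,
        "regional": regional,
        "local_day_effects": local,
        "sqrt_scale_means": mu_store,
        "spec": spec,
    }
    return SimulatedCounts(cm, recs, spec.sites, truth)


# ---------------------------------------------------------------------------
# weather


DEFAULT_WEATHER_VARS = (
    "temperature", "precipitation", "wind_speed", "solar_radiation",
    "relative_humidity", "dewpoint", "barometric_pressure", "delta_pressure",
    "dripping_sound", "ambient_sound",
)

_WEATHER_MEANS = {
    "temperature": 15.0, "precipitation": 0.0, "wind_speed": 1.2,
    "solar_radiation": 250.0, "relative_humidity": 80.0, "dewpoint": 11.0,
    "barometric_pressure": 1013.0, "delta_pressure": 0.0,
    "dripping_sound": 1.0, "ambient_sound": -2.0,
}
_WEATHER_SDS = {
    "temperature": 4.0, "precipitation": 1.0, "wind_speed": 0.9,
    "solar_radiation": 90.0, "relative_humidity": 12.0, "dewpoint": 4.0,
    "barometric_pressure": 5.0, "delta_pressure": 3.0,
    "dripping_sound": 0.8, "ambient_sound": 0.4,
}


def default_weather_correlation() -> pd.DataFrame:
    """Identity plus the positively intercorrelated wind / dripping / ambient
    block and a temperature-dewpoint link."""
    v = list(DEFAULT_WEATHER_VARS)
    c = pd.DataFrame(np.eye(len(v)), index=v, columns=v)
    block = [("wind_speed", "dripping_sound", 0.7),
             ("wind_speed", "ambient_sound", 0.7),
             ("dripping_sound", "ambient_sound", 0.85),
             ("precipitation", "dripping_sound", 0.4),
             ("precipitation", "ambient_sound", 0.35),
             ("temperature", "dewpoint", 0.7),
             ("relative_humidity", "dewpoint", 0.5)]
    for a, b, r in block:
        c.loc[a, b] = c.loc[b, a] = r
    return c


def simulate_weather(dates: list[str], seed: int | None = None,
                     correlation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Daily weather covariates as correlated multivariate-normal draws.

    ``correlation`` is the target correlation matrix (must be positive
    definite); precipitation is zero-inflated by truncating its latent draw at
    zero after shifting (most mornings are dry), and relative humidity is
    clipped to [0, 100].
    """
    if len(dates) < 1:
        raise ValueError("need at least one date")
    corr = correlation if correlation is not None else default_weather_correlation()
    vals = np.linalg.eigvalsh(corr.to_numpy())
    if vals.min() <= 1e-10:
        raise ValueError("correlation target is not positive definite")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr.to_numpy())
    z = rng.standard_normal((len(dates), len(corr))) @ chol.T
    out = pd.DataFrame(index=pd.Index(dates, name="date"))
    for j, var in enumerate(corr.columns):
        x = _WEATHER_MEANS[var] + _WEATHER_SDS[var] * z[:, j]
        if var == "precipitation":
            x = np.maximum(0.0, x - 1.0)  # zero-inflation: dry unless latent is high
        if var == "relative_humidity":
            x = np.clip(x, 0.0, 100.0)
        if var == "dripping_sound":
            x = np.clip(np.round(x), 0, 4)
        out[var] = x
    return out


# ---------------------------------------------------------------------------
# soundscape audio


@dataclass
class SongEvent:
    onset_s: float
    duration_s: float
    center_hz: float
    bandwidth_hz: float = 400.0
    amplitude: float = 0.1
    species: str = "SPX"


@dataclass
class SoundscapeSpec:
    """Parameters for one synthetic recording.

    ``background_sigma`` is the linear-scale SD of the Gaussian noise floor.
    ``drip_rate_per_min`` places short (~20 ms) broadband transients at
    Poisson times.  Song events must keep the >1 s inter-event pause that
    defines distinct vocalization events in the annotation convention (checked
    per species).
    """

    duration_s: float = 600.0
    rate: int = 44100
    background_sigma: float = 0.02
    songs: list[SongEvent] = field(default_factory=list)
    drip_rate_per_min: float = 0.0
    drip_amplitude: float = 0.3

    def __post_init__(self):
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be positive")
        by_species: dict[str, list[SongEvent]] = {}
        for ev in self.songs:
            if ev.onset_s < 0 or ev.onset_s + ev.duration_s > self.duration_s:
                raise ValueError(f"song event at {ev.onset_s}s outside recording")
            by_species.setdefault(ev.species, []).append(ev)
        for evs in by_species.values():
            evs = sorted(evs, key=lambda e: e.onset_s)
            for prev, nxt in zip(evs, evs[1:]):
                if nxt.onset_s - (prev.onset_s + prev.duration_s) <= 1.0:
                    raise ValueError(
                        "song events of one species must be separated by > 1 s"
                    )


def random_song_events(duration_s: float, events_per_min: float, seed: int,
                       species: str = "SPX", center_hz: float = 4000.0,
                       bandwidth_hz: float = 500.0, song_duration_s: float = 1.5,
                       amplitude: float = 0.15) -> list[SongEvent]:
    """Poisson-like song times thinned to respect the > 1 s pause convention."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(events_per_min * duration_s / 60)
    onsets = np.sort(rng.uniform(0, duration_s - song_duration_s, size=n))
    events: list[SongEvent] = []
    last_end = -np.inf
    for t in onsets:
        if t - last_end > 1.0 + 1e-6:
            events.append(SongEvent(float(t), song_duration_s, center_hz,
                                    bandwidth_hz, amplitude, species))
            last_end = t + song_duration_s
    return events


def simulate_audio(spec: SoundscapeSpec, seed: int | None = None
                   ) -> tuple[Waveform, SelectionTable]:
    """Render the soundscape and its ground-truth selection table.

    Songs are linear chirps sweeping the event's frequency band under a Hann
    amplitude envelope; drips are 20-ms white-noise bursts with an exponential
    decay.  Samples exceeding full scale are clipped with a warning (clipped
    vocalizations are tolerated, matching field annotation practice).
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.rate))
    x = rng.normal(0.0, spec.background_sigma, size=n)

    for ev in spec.songs:
        i0 = int(round(ev.onset_s * spec.rate))
        m = int(round(ev.duration_s * spec.rate))
        t = np.arange(m) / spec.rate
        f0 = ev.center_hz - ev.bandwidth_hz / 2
        f1 = ev.center_hz + ev.bandwidth_hz / 2
        phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) / ev.duration_s * t**2)
        envelope = np.hanning(m)
        x[i0:i0 + m] += ev.amplitude * envelope * np.sin(phase)

    if spec.drip_rate_per_min > 0:
        n_drips = rng.poisson(spec.drip_rate_per_min * spec.duration_s / 60)
        drip_len = int(0.02 * spec.rate)
        decay = np.exp(-np.arange(drip_len) / (0.004 * spec.rate))
        for t0 in rng.uniform(0, spec.duration_s - 0.05, size=n_drips):
            i0 = int(t0 * spec.rate)
            x[i0:i0 + drip_len] += (spec.drip_amplitude * decay
                                    * rng.standard_normal(drip_len))

    if np.abs(x).max() > 1.0:
        warnings.warn("amplitude exceeds full scale; samples clipped", stacklevel=2)
        x = np.clip(x, -1.0, 1.0)

    sel = pd.DataFrame(
        {
            "selection": range(1, len(spec.songs) + 1),
            "begin_s": [ev.onset_s for ev in spec.songs],
            "end_s": [ev.onset_s + ev.duration_s for ev in spec.songs],
            "low_hz": [ev.center_hz - ev.bandwidth_hz / 2 for ev in spec.songs],
            "high_hz": [ev.center_hz + ev.bandwidth_hz / 2 for ev in spec.songs],
            "species": [ev.species for ev in spec.songs],
        }
    )
    return Waveform(x, spec.rate), SelectionTable(sel)
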