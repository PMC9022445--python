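"""Ambient sound-pressure estimation from uncalibrated field audio.

Recorders in terrestrial PAM are rarely amplitude-calibrated, so all levels
here are *relative*: the log10 of the RMS amplitude of the raw samples, where
RMS is computed as the standard deviation of the samples within a 1-s window
(mean removal absorbs any DC offset).  Two estimators of the ambient noise
floor are provided:

* ``a_manual`` — emulates manual review: a seeded random second within each
  minute, advanced forward until a 1-s interval free of annotated
  vocalizations is found.
* ``a_automated`` — a sliding 1-s window stepped by 0.1 s within each minute;
  a low percentile (default 10th) of the windowed log10(RMS) values is the
  minute's "quiet second", and the recording value is the mean over minutes.

The low percentile makes the automated estimator robust to sparse loud events
(songs, drips) occupying a small fraction of each minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .ingest import SelectionTable


class DegenerateAudioError(ValueError):
    """A window or dataset carries no variance to analyze."""


@dataclass
class Waveform:
    """Mono audio samples at a fixed rate, amplitudes in arbitrary linear units."""

    samples: np.ndarray
    rate: int = 44100

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 2:  # stereo: average to mono
            self.samples = self.samples.mean(axis=1)
        if self.samples.size == 0:
            raise ValueError("empty waveform")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def segment(self, begin_s: float, end_s: float) -> "Waveform":
        i0 = int(round(begin_s * self.rate))
        i1 = int(round(end_s * self.rate))
        if i0 < 0 or i1 > self.samples.size or i1 <= i0:
            raise ValueError(f"segment [{begin_s}, {end_s}] outside waveform")
        return Waveform(self.samples[i0:i1], self.rate)


def read_wav(path) -> Waveform:
    """Read a PCM WAV file; integer PCM is normalized to [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(2 ** (8 * data.dtype.itemsize - 1))
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        data = (data.astype(np.float64) - 128.0) / 128.0
    return Waveform(data.astype(np.float64), int(rate))


def write_wav(wave: Waveform, path) -> None:
    """Write 16-bit PCM; samples outside [-1, 1] are clipped."""
    clipped = np.clip(wave.samples, -1.0, 1.0)
    wavfile.write(path, wave.rate, np.round(clipped * 32767).astype(np.int16))


@dataclass
class AmbientEstimate:
    recording_id: str
    per_minute_quiet: list[float]
    method: str  # {"manual", "automated"}
    snip_times: list[float] = field(default_factory=list)

    @property
    def a_value(self) -> float:
        return float(np.mean(self.per_minute_quiet))


@dataclass
class VarianceComponents:
    """Proportions of random variance among days, locations, and minutes."""

    occasion: float
    location: float
    minute: float
    raw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = self.occasion + self.location + self.minute
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("proportions must sum to 1")
        if min(self.occasion, self.location, self.minute) < 0:
            raise ValueError("proportions must be nonnegative")


# ---------------------------------------------------------------------------


def rms_log10(samples: np.ndarray | Waveform, on_constant: str = "raise") -> float:
    """log10 RMS of a snip, with RMS = population SD of the raw samples.

    ``on_constant`` controls zero-variance snips: ``"raise"`` (default) or
    ``"neginf"`` to return the -infinity sentinel.
    """
    x = samples.samples if isinstance(samples, Waveform) else np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("empty snip")
    sd = float(x.std())  # divisor n, mean removed
    if sd == 0.0:
        if on_constant == "neginf":
            return float("-inf")
        raise DegenerateAudioError("constant (zero-variance) snip")
    return float(np.log10(sd))


def _windowed_log10_rms(x: np.ndarray, win: int, step: int) -> np.ndarray:
    """log10(std) for every length-``win`` window starting at multiples of ``step``
    fully inside ``x``.  Computed from cumulative sums; O(n)."""
    n = x.size
    if n < win:
        return np.empty(0)
    starts = np.arange(0, n - win + 1, step)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[starts + win] - c1[starts]
    s2 = c2[starts + win] - c2[starts]
    var = s2 / win - (s1 / win) ** 2
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore"):
        return 0.5 * np.log10(var)


def a_automated(wave: Waveform, window_s: float = 1.0, step_s: float = 0.1,
                percentile: float = 10.0, recording_id: str = "") -> AmbientEstimate:
    """Automated quiet-second ambient estimate.

    Each whole minute is analyzed independently: every ``window_s`` window that
    fits fully inside the minute, advanced by ``step_s``, yields a log10(RMS);
    the minute's quiet metric is the given percentile of those values (linear
    interpolation between order statistics).  The recording-level estimate is
    the mean over minutes; a trailing partial minute is ignored.
    """
    if window_s > 60:
        raise ValueError("window_s must be <= 60")
    rate = wave.rate
    minute = 60 * rate
    n_minutes = wave.samples.size // minute
    if n_minutes < 1:
        raise ValueError("waveform shorter than one minute")
    win = int(round(window_s * rate))
    step = max(1, int(round(step_s * rate)))
    per_minute = []
    for m in range(n_minutes):
        seg = wave.samples[m * minute:(m + 1) * minute]
        vals = _windowed_log10_rms(seg, win, step)
        per_minute.append(float(np.percentile(vals, percentile, method="linear")))
    return AmbientEstimate(recording_id, per_minute, "automated")


def _overlaps(begin: float, end: float, intervals: np.ndarray) -> bool:
    if intervals.size == 0:
        return False
    return bool(np.any((intervals[:, 0] < end) & (intervals[:, 1] > begin)))


def a_manual(wave: Waveform, selections: SelectionTable, seed: int,
             window_s: float = 1.0, scan_step_s: float = 0.1,
             recording_id: str = "") -> AmbientEstimate:
    """Manual-style ambient estimate from vocalization-free seconds.

    For each whole minute a random starting second is drawn (seeded); the 1-s
    window is advanced by ``scan_step_s`` until it overlaps no annotated
    selection, rolling into subsequent minutes when the current one is fully
    occupied.  Each minute contributes at most one snip; a minute whose scan
    reaches the end of the recording contributes none.
    """
    rate = wave.rate
    n_minutes = int(wave.duration_s // 60)
    if n_minutes < 1:
        raise ValueError("waveform shorter than one minute")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, 60, size=n_minutes)
    intervals = selections.intervals()
    end_t = wave.samples.size / rate
    found_times: list[float] = []
    for m in range(n_minutes):
        t = m * 60 + float(offsets[m])
        while t + window_s <= end_t:
            if not _overlaps(t, t + window_s, intervals):
                if t not in found_times:
                    found_times.append(t)
                break
            t += scan_step_s
    if not found_times:
        raise ValueError("no vocalization-free second found in recording")
    quiets = [rms_log10(wave.segment(t, t + window_s)) for t in found_times]
    return AmbientEstimate(recording_id, quiets, "manual", snip_times=found_times)


# ---------------------------------------------------------------------------
# variance decomposition


def variance_components(minute_table: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments variance components for per-minute quiet metrics.

    ``minute_table`` needs columns ``year``, ``location``, ``occasion``,
    ``minute``, ``value``.  Within each year (fixed), occasion (day) and
    location are crossed random factors; the residual is among-minute
    variation.  Estimates use balanced two-way ANOVA expected mean squares:

        E[MS_occ] = sigma_e^2 + M*L*sigma_occ^2
        E[MS_loc] = sigma_e^2 + M*O*sigma_loc^2

    Negative component estimates are truncated at zero before normalizing to
    proportions.  Per-year estimates are pooled weighting by observations.
    """
    req = {"year", "location", "occasion", "minute", "value"}
    if not req <= set(minute_table.columns):
        raise ValueError(f"minute_table needs columns {sorted(req)}")
    comps = np.zeros(3)  # occasion, location, residual
    weight = 0.0
    for _, grp in minute_table.groupby("year"):
        L = grp["location"].nunique()
        O = grp["occasion"].nunique()
        if L < 2 or O < 2:
            raise ValueError("need >= 2 locations and >= 2 occasions per year")
        y = grp["value"].to_numpy(float)
        n = y.size
        M = n / (L * O)  # minutes per (location, occasion) cell
        grand = y.mean()
        ss_tot = float(((y - grand) ** 2).sum())
        occ_means = grp.groupby("occasion")["value"].mean().to_numpy()
        loc_means = grp.groupby("location")["value"].mean().to_numpy()
        ss_occ = M * L * float(((occ_means - grand) ** 2).sum())
        ss_loc = M * O * float(((loc_means - grand) ** 2).sum())
        ms_occ = ss_occ / (O - 1)
        ms_loc = ss_loc / (L - 1)
        df_res = n - 1 - (O - 1) - (L - 1)
        ms_res = (ss_tot - ss_occ - ss_loc) / df_res
        v_occ = (ms_occ - ms_res) / (M * L)
        v_loc = (ms_loc - ms_res) / (M * O)
        comps += n * np.array([v_occ, v_loc, ms_res])
        weight += n
    comps /= weight
    comps = np.maximum(comps, 0.0)
    total = comps.sum()
    if total == 0:
        raise DegenerateAudioError("no variance in quiet metrics; proportions undefined")
    p = comps / total
    return VarianceComponents(
        occasion=float(p[0]), location=float(p[1]), minute=float(p[2]),
        raw={"occasion": float(comps[0]), "location": float(comps[1]),
             "minute": float(comps[2])},
    )


def fold_range(per_day_values: dict[str, float] | pd.Series) -> pd.DataFrame:
    """Fold-change of each day's linear-scale ambient level over the quietest day."""
    s = pd.Series(per_day_values, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 days")
    if (s <= 0).any():
        raise ValueError("ambient values must be positive on the linear scale")
    out = pd.DataFrame({"value": s, "fold_over_min": s / s.min()})
    out["rank"] = out["value"].rank(ascending=False).astype(int)
    return out.sort_values("fold_over_min", ascending=False)
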