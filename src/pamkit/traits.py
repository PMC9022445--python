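"""Vocal-trait measurement: snip extraction, duration, dominant frequency.

Duration comes from the annotated selection bounds, never from the audio.
Dominant ("peak") frequency is measured only on *clean* snips — vocalizations
whose time span overlaps no other annotated selection — as the frequency bin
with maximum time-averaged power in a Hann-windowed magnitude spectrogram
(DFT 512, 50% overlap by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .ambient import Waveform
from .ingest import SelectionTable

logger = logging.getLogger(__name__)


@dataclass
class Snip:
    """A short audio segment delimiting one annotated vocalization."""

    waveform: Waveform
    recording_id: str
    begin_s: float
    end_s: float
    species: str
    clean: bool

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


def _is_clean(row_idx: int, sel: pd.DataFrame) -> bool:
    me = sel.iloc[row_idx]
    others = sel.drop(sel.index[row_idx])
    return not bool(
        ((others["begin_s"] < me["end_s"]) & (others["end_s"] > me["begin_s"])).any()
    )


def extract_snips(wave: Waveform, selections: SelectionTable, quota: int = 2,
                  seed: int = 0) -> tuple[list[Snip], dict[str, int]]:
    """Seeded stratified random sample of up to ``quota`` snips per species.

    Sampling is without replacement within species.  Each snip's ``clean``
    flag records whether it overlaps any other selection in the table.
    Returns the snips plus a shortfall report: species -> number of snips
    short of quota (only species with a shortfall appear).
    """
    sel = selections.selections
    if len(sel) == 0:
        return [], {}
    if (sel["end_s"] > wave.duration_s + 1e-9).any() or (sel["begin_s"] < 0).any():
        bad = sel[(sel["end_s"] > wave.duration_s + 1e-9) | (sel["begin_s"] < 0)]
        raise ValueError(
            f"selection {bad['selection'].iloc[0]} outside waveform bounds"
        )
    rng = np.random.default_rng(seed)
    snips: list[Snip] = []
    shortfall: dict[str, int] = {}
    for species in sorted(sel["species"].unique()):
        idx = np.flatnonzero((sel["species"] == species).to_numpy())
        take = min(quota, idx.size)
        if take < quota:
            shortfall[species] = quota - take
            logger.warning("species %s: only %d of %d requested snips available",
                           species, take, quota)
        chosen = rng.choice(idx, size=take, replace=False)
        for i in sorted(chosen):
            row = sel.iloc[i]
            snips.append(
                Snip(
                    waveform=wave.segment(row["begin_s"], row["end_s"]),
                    recording_id=selections.recording_id,
                    begin_s=float(row["begin_s"]),
                    end_s=float(row["end_s"]),
                    species=species,
                    clean=_is_clean(i, sel),
                )
            )
    return snips, shortfall


def peak_frequency(snip: Snip | Waveform, dft_size: int = 512,
                   overlap: float = 0.5, require_clean: bool = False) -> float:
    """Dominant frequency of a snip, in kHz.

    The magnitude spectrogram (Hann window, ``dft_size`` samples, fractional
    ``overlap``) is averaged over frames and the argmax bin returned.  The
    resolution is one bin width, rate/dft_size (~86 Hz at 44.1 kHz / 512).
    """
    if isinstance(snip, Snip):
        if not snip.clean:
            msg = "peak_frequency on a non-clean snip"
            if require_clean:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        wave = snip.waveform
    else:
        wave = snip
    if wave.samples.size < dft_size:
        raise ValueError("snip shorter than one DFT frame")
    freqs, _, sxx = signal.spectrogram(
        wave.samples, fs=wave.rate, window="hann", nperseg=dft_size,
        noverlap=int(dft_size * overlap), mode="magnitude",
    )
    mean_power = (sxx ** 2).mean(axis=1)
    return float(freqs[int(np.argmax(mean_power))] / 1000.0)


def trait_summary(snips: list[Snip], dft_size: int = 512,
                  overlap: float = 0.5) -> pd.DataFrame:
    """Per-species duration and peak-frequency summaries.

    Duration statistics use every snip; frequency statistics use clean snips
    long enough for one DFT frame (species with none get duration stats only).
    SDs are sample SDs (divisor n-1); a single observation reports SD as NaN.
    """
    if not snips:
        raise ValueError("no snips to summarize")
    rows = []
    by_species: dict[str, list[Snip]] = {}
    for s in snips:
        by_species.setdefault(s.species, []).append(s)
    for species in sorted(by_species):
        group = by_species[species]
        durations = np.array([s.duration_s for s in group])
        freqs = [
            peak_frequency(s, dft_size=dft_size, overlap=overlap)
            for s in group
            if s.clean and s.waveform.samples.size >= dft_size
        ]
        rows.append(
            {
                "species": species,
                "n_duration": durations.size,
                "n_frequency": len(freqs),
                "duration_mean_s": float(durations.mean()),
                "duration_sd_s": float(durations.std(ddof=1)) if durations.size > 1 else np.nan,
                "peak_freq_mean_khz": float(np.mean(freqs)) if freqs else np.nan,
                "peak_freq_sd_khz": float(np.std(freqs, ddof=1)) if len(freqs) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("species")
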