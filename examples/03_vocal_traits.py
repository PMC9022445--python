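"""Vocal-trait measurement: duration and dominant frequency per species.

Renders a soundscape with two synthetic species singing at 3.2 kHz and
5.0 kHz, extracts a stratified random sample of snips from the ground-truth
selection table, and summarizes duration and peak frequency per species.
Peak frequency comes only from clean (non-overlapping) vocalizations.
"""

import pamkit as pk
from pamkit.simulate import SongEvent, SoundscapeSpec

songs = (
    [SongEvent(5 + 10 * k, 0.8, 3200, 300, 0.3, "LOWF") for k in range(10)]
    + [SongEvent(10 + 10 * k, 1.6, 5000, 400, 0.3, "HIGF") for k in range(10)]
)
spec = SoundscapeSpec(duration_s=120, background_sigma=0.01, songs=songs)
wave, selections = pk.simulate_audio(spec, seed=6)

snips, shortfall = pk.extract_snips(wave, selections, quota=5, seed=7)
print(f"sampled {len(snips)} snips; quota shortfalls: {shortfall or 'none'}")

summary = pk.trait_summary(snips)
print(summary.round(3).to_string())
print("\nDuration comes from the selection bounds; peak frequency is the "
      "argmax bin of the time-averaged spectrogram (resolution ~86 Hz), "
      "so the 3.2 and 5.0 kHz species should be cleanly separated.")
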