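"""Estimate a tone audiogram from descending level series.

For each tested frequency a level series descends in 10 dB steps; the
automated observer scores response presence against the trace's own noise
floor and the threshold is the midpoint between the last present and first
absent levels. True thresholds are the male reference means, so the
recovered audiogram should bottom out near 25 dB SPL at 8 kHz.
"""

from voleabr import draw_animal, male_click_config
from voleabr.conditions import TONE_FREQS_KHZ
from voleabr.pipeline import audiogram_session

config = draw_animal(
    male_click_config(n_epochs=400, noise_sd_uv=0.5), seed=11
)
audiogram = audiogram_session(config, TONE_FREQS_KHZ)

print("frequency_khz  threshold_db_spl  (true threshold)")
for f in audiogram.frequencies():
    r = audiogram.thresholds[f]
    shown = r.threshold_db_spl if r.censored == "none" else r.censored
    print(f"{f:13.0f}  {shown!s:>16}   ({config.threshold_db[f]:.1f})")
print("best frequency:", audiogram.best_frequency_khz(), "kHz")
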