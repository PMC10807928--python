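"""Stimulus conditions and the measurement grids used throughout the package.

The experimental design is built on three fixed grids: tone frequencies for
the audiogram, the ITD grid for binaural click stimulation, and the 10-degree
azimuth grid of the free-field speaker array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

#: Tone-burst frequencies (kHz) tested for the audiogram.
TONE_FREQS_KHZ: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 32.0, 46.0)

#: Interaural time differences (ms) for binaural click stimulation.
ITD_GRID_MS: tuple[float, ...] = tuple(np.round(np.arange(-2.0, 2.01, 0.5), 3))

#: Horizontal-plane speaker azimuths (deg); negative = left, positive = right.
AZIMUTH_GRID_DEG: tuple[int, ...] = tuple(range(-90, 91, 10))

WAVES: tuple[str, ...] = ("I", "II", "III", "IV")


def speaker_grid_positions(horizontal: bool = True, vertical: bool = True):
    """All (azimuth, elevation) positions of the two-axis speaker array.

    Each axis spans 180 degrees in 10-degree steps (19 positions); the full
    array therefore offers 19 x 19 = 361 potential measurement positions.
    """
    az = AZIMUTH_GRID_DEG if horizontal else (0,)
    el = AZIMUTH_GRID_DEG if vertical else (0,)
    return [(a, e) for a in az for e in el]


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulation condition: which ear(s), what sound, how loud.

    Parameters
    ----------
    ear : {"left", "right", "binaural"}
    kind : {"click", "tone"}
    level_db_spl : stimulus level in dB SPL.
    frequency_khz : tone frequency (kHz); required for tones, must be one of
        :data:`TONE_FREQS_KHZ`.
    itd_ms : interaural time difference (ms); binaural conditions only, must
        lie on :data:`ITD_GRID_MS`.
    """

    ear: str
    kind: str = "click"
    level_db_spl: float = 90.0
    frequency_khz: Optional[float] = None
    itd_ms: Optional[float] = None

    def __post_init__(self):
        if self.ear not in ("left", "right", "binaural"):
            raise ValueError(f"unknown ear {self.ear!r}")
        if self.kind not in ("click", "tone"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "tone":
            if self.frequency_khz is None:
                raise ValueError("tone condition requires frequency_khz")
            if self.frequency_khz not in TONE_FREQS_KHZ:
                raise ValueError(
                    f"tone frequency {self.frequency_khz} kHz not in the "
                    f"tested set {TONE_FREQS_KHZ}"
                )
        if self.ear == "binaural":
            if self.itd_ms is None:
                raise ValueError("binaural condition requires itd_ms")
            if not any(np.isclose(self.itd_ms, g) for g in ITD_GRID_MS):
                raise ValueError(f"itd {self.itd_ms} ms is off the ITD grid")
        elif self.itd_ms is not None:
            raise ValueError("itd_ms only applies to binaural conditions")

    @property
    def is_monaural(self) -> bool:
        return self.ear in ("left", "right")
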