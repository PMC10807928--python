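"""Published group-level reference values for prairie-vole hearing.

These tables hold the reported click-ABR wave amplitudes/latencies, BIC (DN1)
amplitude/latency across ITDs, tone thresholds and head/pinna morphometry for
male and female prairie voles, as mean, standard error and group size. They
parameterize the synthetic-session generator (between-animal spread is
reconstructed as sqrt(N) * SE) and serve as the ground truth for
parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RefValue:
    """A reported group statistic: mean +/- standard error over n animals."""

    mean: float
    se: float
    n: int

    @property
    def sd(self) -> float:
        """Between-animal standard deviation implied by the SE: SE * sqrt(n)."""
        return self.se * self.n**0.5


# Click-ABR wave peak-to-trough amplitudes (uV) at 90 dB SPL.
WAVE_AMPLITUDE_UV = {
    "male": {
        "I": RefValue(3.2, 0.10, 10),
        "II": RefValue(3.1, 0.14, 10),
        "III": RefValue(2.5, 0.13, 10),
        "IV": RefValue(3.4, 0.13, 10),
    },
    "female": {
        "I": RefValue(4.9, 0.22, 9),
        "II": RefValue(4.2, 0.20, 9),
        "III": RefValue(1.8, 0.054, 9),
        "IV": RefValue(3.2, 0.085, 9),
    },
}

# Click-ABR wave latencies (ms) at 90 dB SPL.
WAVE_LATENCY_MS = {
    "male": {
        "I": RefValue(1.96, 0.03, 10),
        "II": RefValue(2.76, 0.05, 10),
        "III": RefValue(3.43, 0.06, 10),
        "IV": RefValue(4.43, 0.07, 10),
    },
    "female": {
        "I": RefValue(2.02, 0.05, 9),
        "II": RefValue(2.98, 0.06, 9),
        "III": RefValue(3.71, 0.09, 9),
        "IV": RefValue(4.83, 0.12, 9),
    },
}

# Click threshold (dB SPL).
CLICK_THRESHOLD_DB = {
    "male": RefValue(65.4, 1.99, 12),
    "female": RefValue(63.2, 1.21, 11),
}

# Tone thresholds (dB SPL) per frequency (kHz); the audiogram.
TONE_THRESHOLD_DB = {
    "male": {
        1.0: RefValue(46.2, 7.2, 7),
        2.0: RefValue(37.5, 6.4, 7),
        4.0: RefValue(40.0, 2.7, 7),
        8.0: RefValue(25.0, 2.7, 7),
        16.0: RefValue(28.8, 3.2, 7),
        24.0: RefValue(35.0, 3.8, 7),
        32.0: RefValue(28.8, 4.6, 7),
        46.0: RefValue(38.8, 4.2, 7),
    },
    "female": {
        1.0: RefValue(50.6, 2.9, 9),
        2.0: RefValue(38.3, 3.7, 9),
        4.0: RefValue(40.6, 2.9, 9),
        8.0: RefValue(26.1, 2.0, 9),
        16.0: RefValue(31.7, 3.3, 9),
        24.0: RefValue(37.3, 2.8, 9),
        32.0: RefValue(31.7, 2.4, 9),
        46.0: RefValue(45.0, 2.4, 9),
    },
}

# DN1 (BIC) magnitude (uV) per ITD (ms).
BIC_AMPLITUDE_UV = {
    "male": {
        -2.0: RefValue(2.7, 0.53, 9),
        -1.5: RefValue(2.6, 0.44, 9),
        -1.0: RefValue(3.4, 0.70, 9),
        -0.5: RefValue(3.4, 0.55, 9),
        0.0: RefValue(3.0, 0.55, 9),
        0.5: RefValue(3.4, 0.53, 9),
        1.0: RefValue(2.9, 0.39, 9),
        1.5: RefValue(2.6, 0.49, 9),
        2.0: RefValue(2.8, 0.40, 9),
    },
    "female": {
        -2.0: RefValue(1.8, 0.35, 9),
        -1.5: RefValue(2.1, 0.43, 9),
        -1.0: RefValue(3.1, 0.70, 9),
        -0.5: RefValue(2.6, 0.49, 9),
        0.0: RefValue(3.1, 0.56, 9),
        0.5: RefValue(2.6, 0.50, 9),
        1.0: RefValue(2.9, 0.57, 9),
        1.5: RefValue(2.4, 0.44, 9),
        2.0: RefValue(2.0, 0.43, 9),
    },
}

# DN1 (BIC) latency (ms) per ITD (ms).
BIC_LATENCY_MS = {
    "male": {
        -2.0: RefValue(6.3, 0.17, 9),
        -1.5: RefValue(5.9, 0.08, 9),
        -1.0: RefValue(5.3, 0.11, 9),
        -0.5: RefValue(4.9, 0.09, 9),
        0.0: RefValue(4.5, 0.09, 9),
        0.5: RefValue(5.0, 0.10, 9),
        1.0: RefValue(5.4, 0.11, 9),
        1.5: RefValue(5.8, 0.14, 9),
        2.0: RefValue(6.3, 0.16, 9),
    },
    "female": {
        -2.0: RefValue(6.6, 0.12, 9),
        -1.5: RefValue(6.0, 0.08, 9),
        -1.0: RefValue(5.6, 0.11, 9),
        -0.5: RefValue(5.0, 0.09, 9),
        0.0: RefValue(4.6, 0.09, 9),
        0.5: RefValue(5.2, 0.14, 9),
        1.0: RefValue(5.7, 0.10, 9),
        1.5: RefValue(5.9, 0.22, 9),
        2.0: RefValue(6.3, 0.18, 9),
    },
}

# Head and pinna morphometry (mm except weight in g).
MORPHOMETRY = {
    "male": {
        "nose_to_pinna_mm": RefValue(27.7, 0.7, 14),
        "inter_pinna_mm": RefValue(15.3, 0.3, 14),
        "pinna_width_mm": RefValue(10.7, 0.3, 14),
        "pinna_length_mm": RefValue(13.2, 0.3, 14),
        "effective_diameter_mm": RefValue(11.8, 0.2, 14),
        "weight_g": RefValue(39.2, 1.9, 14),
    },
    "female": {
        "nose_to_pinna_mm": RefValue(27.4, 0.4, 12),
        "inter_pinna_mm": RefValue(15.4, 0.7, 11),
        "pinna_width_mm": RefValue(10.2, 0.3, 13),
        "pinna_length_mm": RefValue(13.0, 0.3, 13),
        "effective_diameter_mm": RefValue(11.5, 0.3, 13),
        "weight_g": RefValue(31.5, 1.5, 13),
    },
}
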