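"""Response-presence scoring, descending-step threshold rule, audiograms.

Hearing threshold is estimated from a level series descending in 10 dB steps:
a response-presence decision is made per level, and the threshold is the
midpoint between the last level with a response and the first level without
one (present at 60 dB SPL, absent at 50 -> threshold 55 dB SPL). Series that
never lose the response are censored below the lowest tested level; series
with no response anywhere are censored above the highest. An automated
observer stands in for the trained human raters: the peak-to-peak voltage in
the response window is compared against a noise-floor estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .abr import AveragedTrace
from .conditions import TONE_FREQS_KHZ

__all__ = [
    "LevelSeries",
    "ThresholdResult",
    "Audiogram",
    "response_present",
    "estimate_threshold",
    "build_audiogram",
    "RESPONSE_WINDOW_MS",
    "NOISE_WINDOW_MS",
]

#: Window (ms) holding the evoked response (brackets the wave I-IV latencies).
RESPONSE_WINDOW_MS: Tuple[float, float] = (1.0, 8.0)
#: Post-response window (ms) used as the noise-floor reference.
NOISE_WINDOW_MS: Tuple[float, float] = (10.0, 12.0)
#: Assumed noise bandwidth (Hz): the upper edge of the standard band-pass.
NOISE_BANDWIDTH_HZ = 3000.0


def _p2p_window_correction(t_resp_s: float, t_noise_s: float) -> float:
    """Scale a noise peak-to-peak measured over ``t_noise_s`` to the value
    expected over ``t_resp_s``.

    The extreme range of n effectively independent Gaussian samples grows as
    sqrt(2 ln n); with n ~ 2 * bandwidth * T this gives the
    sqrt(ln n_resp / ln n_noise) correction. Without it a response window
    longer than the noise window inflates the score of pure noise (expected
    ratio ~1.5 for 7 ms vs 2 ms) and the presence criterion loses its
    "twice the noise floor" meaning.
    """
    n_resp = max(2.0, 2.0 * NOISE_BANDWIDTH_HZ * t_resp_s)
    n_noise = max(2.0, 2.0 * NOISE_BANDWIDTH_HZ * t_noise_s)
    return float(np.sqrt(np.log(n_resp) / np.log(n_noise)))


@dataclass
class LevelSeries:
    """Averaged traces per level, descending in exact 10 dB steps.

    ``tag`` identifies the stimulus: ``"click"`` or a tone frequency in kHz.
    """

    traces: Dict[float, AveragedTrace]
    tag: Union[str, float] = "click"

    def __post_init__(self):
        if len(self.traces) < 2:
            raise ValueError("a level series needs at least two levels")
        levels = self.levels_descending()
        if any(np.diff(levels) != -10):
            raise ValueError("levels must be spaced by exactly 10 dB")

    def levels_descending(self):
        return sorted(self.traces, reverse=True)


@dataclass
class ThresholdResult:
    """Estimated threshold (dB SPL) or a censoring flag, plus the decisions."""

    threshold_db_spl: Optional[float]
    censored: str = "none"  # "none" | "below_min" | "above_max"
    decisions: Dict[float, bool] = field(default_factory=dict)
    scores: Dict[float, float] = field(default_factory=dict)


@dataclass
class Audiogram:
    """Threshold per tone frequency (kHz)."""

    thresholds: Dict[float, ThresholdResult] = field(default_factory=dict)
    animal_id: Optional[str] = None

    def frequencies(self):
        return sorted(self.thresholds)

    def best_frequency_khz(self) -> Optional[float]:
        """Frequency with the lowest uncensored threshold."""
        best, best_thr = None, np.inf
        for f in self.frequencies():
            r = self.thresholds[f]
            if r.censored == "none" and r.threshold_db_spl < best_thr:
                best, best_thr = f, r.threshold_db_spl
        return best


def response_present(
    trace: AveragedTrace,
    noise_ref: Union[AveragedTrace, Tuple[float, float]] = NOISE_WINDOW_MS,
    criterion: float = 2.0,
    response_window_ms: Tuple[float, float] = RESPONSE_WINDOW_MS,
) -> Tuple[bool, float]:
    """Automated response decision for one averaged trace.

    The score is the peak-to-peak voltage inside the response window divided
    by a noise peak-to-peak estimate for that window. The estimate comes
    from the noise reference (a separate trace or a window of this trace,
    default the final 2 ms) scaled to the response-window length by the
    extreme-value correction of :func:`_p2p_window_correction`. The response
    is declared present when the score reaches ``criterion``. The score is
    scale invariant: multiplying trace and reference by one constant leaves
    it unchanged.
    """
    t = trace.time_ms()
    a, b = response_window_ms
    resp = trace.values[(t >= a) & (t <= b)]
    if isinstance(noise_ref, AveragedTrace):
        noise = noise_ref.values
        t_noise = noise.size / noise_ref.fs
    else:
        na, nb = noise_ref
        noise = trace.values[(t >= na) & (t <= nb)]
        t_noise = (nb - na) / 1000.0
    noise_p2p = float(np.ptp(noise))
    if noise_p2p == 0.0:
        raise ValueError("degenerate (all-equal) noise reference")
    noise_p2p *= _p2p_window_correction((b - a) / 1000.0, t_noise)
    score = float(np.ptp(resp)) / noise_p2p
    return score >= criterion, score


def estimate_threshold(series: LevelSeries, criterion: float = 2.0) -> ThresholdResult:
    """Descending-step midpoint rule on a level series.

    Scanning from the highest level down, the threshold is the midpoint of
    the last present and first absent levels; with levels on multiples of
    10 dB the estimate therefore always ends in 5. A response at every level
    censors the result below the minimum tested level; no response anywhere
    censors it above the maximum. A response re-appearing below an absent
    level is non-monotone: it triggers a warning and the first absence is
    used.
    """
    levels = series.levels_descending()
    decisions, scores = {}, {}
    for lv in levels:
        present, score = response_present(series.traces[lv], criterion=criterion)
        decisions[lv], scores[lv] = present, score

    first_absent = next((i for i, lv in enumerate(levels) if not decisions[lv]), None)
    if first_absent is not None and any(decisions[lv] for lv in levels[first_absent:]):
        warnings.warn(
            "non-monotone level series: response present below an absent level; "
            "using the first absence from the top",
            stacklevel=2,
        )
    if first_absent is None:
        return ThresholdResult(None, censored="below_min",
                               decisions=decisions, scores=scores)
    if first_absent == 0:
        return ThresholdResult(None, censored="above_max",
                               decisions=decisions, scores=scores)
    thr = 0.5 * (levels[first_absent - 1] + levels[first_absent])
    return ThresholdResult(float(thr), decisions=decisions, scores=scores)


def build_audiogram(
    results: Dict[float, ThresholdResult], animal_id: Optional[str] = None
) -> Audiogram:
    """Assemble per-frequency threshold results into an audiogram.

    Keys must come from the tested tone-frequency set; censored entries are
    carried through unaltered.
    """
    if not results:
        raise ValueError("no threshold results supplied")
    for f in results:
        if f not in TONE_FREQS_KHZ:
            raise ValueError(f"frequency {f} kHz not in the tested set")
    return Audiogram(thresholds=dict(results), animal_id=animal_id)
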