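"""Epoch containers, filtering/averaging, and ABR wave I-IV quantification.

An evoked-potential session yields, per stimulus condition, a stack of
stimulus-locked epochs. The analysis path is: band-pass filter the epochs
(50-3000 Hz, zero-phase by default so wave latencies are not biased), average
them into a single trace, subtract the whole-trace mean (baseline
normalization), then quantify each of the four ABR waves as peak-to-trough
amplitude (uV) and time-to-peak latency (ms). Automatically detected peaks can
be corrected with an annotation set (keep / move / deselect), and left/right
ear measurements are averaged per animal.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal

from .conditions import WAVES, StimulusCondition

__all__ = [
    "EpochSet",
    "AveragedTrace",
    "WaveMeasure",
    "PeakSet",
    "AnnotationSet",
    "bandpass_filter",
    "average_epochs",
    "detect_peaks",
    "apply_annotations",
    "average_ears",
    "DEFAULT_WAVE_WINDOWS_MS",
]

# Search windows (ms) per wave, centered between the reported male and female
# mean latencies, +-0.6 ms. Adjacent windows overlap; peak assignment enforces
# strictly increasing latencies instead.
DEFAULT_WAVE_WINDOWS_MS: Dict[str, Tuple[float, float]] = {
    "I": (1.4, 2.6),
    "II": (2.3, 3.5),
    "III": (3.0, 4.2),
    "IV": (4.0, 5.4),
}


@dataclass
class EpochSet:
    """A stack of stimulus-locked voltage epochs for one condition.

    samples : (n_epochs, n_samples) array, uV.
    fs : sampling rate, Hz.
    """

    samples: np.ndarray
    fs: float
    condition: Optional[StimulusCondition] = None
    animal_id: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_epochs(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def epoch_dur_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs * 1000.0


@dataclass
class AveragedTrace:
    """Across-epoch mean trace, baseline-normalized to zero mean."""

    values: np.ndarray
    fs: float
    condition: Optional[StimulusCondition] = None
    animal_id: Optional[str] = None
    baseline_offset: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.values.size

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs * 1000.0

    def sample_at_ms(self, t_ms: float) -> int:
        return int(round(t_ms / 1000.0 * self.fs))


@dataclass
class WaveMeasure:
    """One wave's quantification: present flag, latency, peak-to-trough."""

    present: bool = False
    latency_ms: float = float("nan")
    peak_value_uv: float = float("nan")
    trough_value_uv: float = float("nan")
    n_ears: int = 1

    @property
    def amplitude_uv(self) -> float:
        if not self.present:
            return float("nan")
        return self.peak_value_uv - self.trough_value_uv


@dataclass
class PeakSet:
    """Wave I-IV measurements for one averaged trace (or one animal)."""

    waves: Dict[str, WaveMeasure] = field(
        default_factory=lambda: {w: WaveMeasure() for w in WAVES}
    )
    animal_id: Optional[str] = None
    ear: Optional[str] = None

    def __getitem__(self, wave: str) -> WaveMeasure:
        return self.waves[wave]

    def present_waves(self):
        return [w for w in WAVES if self.waves[w].present]

    def validate(self):
        lats = [self.waves[w].latency_ms for w in self.present_waves()]
        if any(np.diff(lats) <= 0):
            raise ValueError("wave latencies must be strictly increasing")
        for w in self.present_waves():
            if self.waves[w].amplitude_uv < 0:
                raise ValueError("amplitude must be non-negative")


@dataclass
class AnnotationSet:
    """Manual corrections: per-wave keep (default), move, or deselect.

    actions maps wave name to ``("keep",)``, ``("move", sample_index)`` or
    ``("deselect",)``.
    """

    actions: Dict[str, tuple] = field(default_factory=dict)

    def action_for(self, wave: str) -> tuple:
        return self.actions.get(wave, ("keep",))


def bandpass_filter(
    epochs: EpochSet,
    lo_hz: float = 50.0,
    hi_hz: float = 3000.0,
    order: int = 2,
    zero_phase: bool = True,
) -> EpochSet:
    """Band-pass each epoch with a Butterworth filter (default 50-3000 Hz).

    Zero-phase (forward-backward) application is the default: it doubles the
    effective order but introduces no group delay, so wave latencies are not
    biased. ``zero_phase=False`` gives the causal single-pass filter.
    """
    if not (0 < lo_hz < hi_hz):
        raise ValueError("need 0 < lo_hz < hi_hz")
    if hi_hz >= epochs.fs / 2:
        raise ValueError(f"hi_hz={hi_hz} must be below Nyquist ({epochs.fs / 2})")
    sos = signal.butter(
        order, [lo_hz, hi_hz], btype="bandpass", fs=epochs.fs, output="sos"
    )
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, epochs.samples, axis=-1)
    else:
        filtered = signal.sosfilt(sos, epochs.samples, axis=-1)
    return EpochSet(
        samples=filtered,
        fs=epochs.fs,
        condition=epochs.condition,
        animal_id=epochs.animal_id,
        seed=epochs.seed,
    )


def average_epochs(epochs: EpochSet) -> AveragedTrace:
    """Pointwise mean across epochs, then whole-trace mean subtracted.

    The subtracted mean is recorded as ``baseline_offset`` so the raw average
    can be reconstructed.
    """
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    mean = epochs.samples.mean(axis=0)
    offset = float(mean.mean())
    return AveragedTrace(
        values=mean - offset,
        fs=epochs.fs,
        condition=epochs.condition,
        animal_id=epochs.animal_id,
        baseline_offset=offset,
    )


def _default_prominence(trace: AveragedTrace, tail_ms: float = 2.0) -> float:
    """2x the RMS of the trace's final ``tail_ms`` (assumed post-response)."""
    n_tail = max(2, int(round(tail_ms / 1000.0 * trace.fs)))
    tail = trace.values[-n_tail:]
    return 2.0 * float(np.sqrt(np.mean(tail**2)))


def detect_peaks(
    trace: AveragedTrace,
    windows_ms: Optional[Dict[str, Tuple[float, float]]] = None,
    min_prominence_uv: Optional[float] = None,
) -> PeakSet:
    """Find and quantify waves I-IV on an averaged trace.

    For each wave, the largest local maximum inside its search window (with
    prominence at least ``min_prominence_uv``, default 2x the RMS of the final
    2 ms) is taken as the peak; ties between equal maxima break toward earlier
    latency, and assignment runs in wave order so latencies are strictly
    increasing. The trough is the minimum between the wave's peak and the next
    detected wave's peak (trace end for the last wave). Waves with no
    acceptable local maximum are flagged absent, not errors.
    """
    windows_ms = dict(windows_ms) if windows_ms is not None else dict(DEFAULT_WAVE_WINDOWS_MS)
    starts = [windows_ms[w][0] for w in WAVES if w in windows_ms]
    ends = [windows_ms[w][1] for w in WAVES if w in windows_ms]
    if any(np.diff(starts) <= 0) or any(np.diff(ends) <= 0):
        raise ValueError("wave windows must be ordered by wave")
    for w, (a, b) in windows_ms.items():
        if not a < b:
            raise ValueError(f"empty window for wave {w}")
    if min_prominence_uv is None:
        min_prominence_uv = _default_prominence(trace)

    y = trace.values
    t = trace.time_ms()
    peak_idx, props = signal.find_peaks(y, prominence=min_prominence_uv)

    out = PeakSet(animal_id=trace.animal_id)
    if trace.condition is not None:
        out.ear = trace.condition.ear
    assigned: Dict[str, int] = {}
    prev_i = -1
    for w in WAVES:
        if w not in windows_ms:
            continue
        a, b = windows_ms[w]
        cand = peak_idx[(t[peak_idx] >= a) & (t[peak_idx] <= b) & (peak_idx > prev_i)]
        if cand.size == 0:
            continue
        best = cand[np.argmax(y[cand])]  # argmax returns first (earliest) tie
        assigned[w] = int(best)
        prev_i = int(best)

    present = [w for w in WAVES if w in assigned]
    for k, w in enumerate(present):
        i = assigned[w]
        j = assigned[present[k + 1]] if k + 1 < len(present) else y.size
        trough = float(np.min(y[i:j]))
        out.waves[w] = WaveMeasure(
            present=True,
            latency_ms=float(t[i]),
            peak_value_uv=float(y[i]),
            trough_value_uv=trough,
        )
    return out


def apply_annotations(
    peaks: PeakSet, annotations: AnnotationSet, trace: AveragedTrace
) -> PeakSet:
    """Apply manual keep/move/deselect corrections and re-quantify.

    Moving a wave re-reads the peak value at the new sample and recomputes
    the trough against the (possibly updated) next present wave.
    """
    out = copy.deepcopy(peaks)
    y = trace.values
    t = trace.time_ms()
    for w in WAVES:
        action = annotations.action_for(w)
        if action[0] == "keep":
            continue
        if action[0] == "deselect":
            out.waves[w] = WaveMeasure(present=False)
        elif action[0] == "move":
            idx = int(action[1])
            if not 0 <= idx < y.size:
                raise ValueError(f"move target {idx} outside trace")
            out.waves[w] = WaveMeasure(
                present=True,
                latency_ms=float(t[idx]),
                peak_value_uv=float(y[idx]),
                trough_value_uv=float("nan"),
            )
        else:
            raise ValueError(f"unknown annotation action {action[0]!r}")
    # re-derive troughs from the final peak positions
    present = out.present_waves()
    idxs = [trace.sample_at_ms(out.waves[w].latency_ms) for w in present]
    for k, w in enumerate(present):
        i = idxs[k]
        j = idxs[k + 1] if k + 1 < len(present) else y.size
        out.waves[w] = replace(out.waves[w], trough_value_uv=float(np.min(y[i:j])))
    out.validate()
    return out


def average_ears(left: PeakSet, right: PeakSet) -> PeakSet:
    """Per-wave mean of amplitude and latency across the two ears.

    Waves present in only one ear are carried through with ``n_ears=1``;
    waves absent in both stay absent. The averaged measure stores the mean
    amplitude via peak/trough values (peak = amplitude, trough = 0).
    """
    out = PeakSet(animal_id=left.animal_id or right.animal_id, ear="both")
    for w in WAVES:
        lm, rm = left.waves[w], right.waves[w]
        both = [m for m in (lm, rm) if m.present]
        if not both:
            continue
        amp = float(np.mean([m.amplitude_uv for m in both]))
        lat = float(np.mean([m.latency_ms for m in both]))
        out.waves[w] = WaveMeasure(
            present=True,
            latency_ms=lat,
            peak_value_uv=amp,
            trough_value_uv=0.0,
            n_ears=len(both),
        )
    return out
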