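"""Binaural interaction component (BIC) and DN1 quantification across ITDs.

The BIC is the residual of binaural over summed monaural responses,
BIC(t) = binaural(t) - [left(t) + right(t)], computed on baseline-normalized
averaged traces with no time-shifting of the monaural responses. Its first
deflection, DN1, is negative under this sign convention; its magnitude
relative to the zero baseline and its latency are the binaural read-outs,
tracked across the +-2 ms ITD grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal

from .abr import AveragedTrace
from .conditions import ITD_GRID_MS

__all__ = [
    "BICTrace",
    "BICMeasure",
    "BICCurve",
    "compute_bic",
    "measure_dn1",
    "bic_curve",
    "DEFAULT_DN1_WINDOW_MS",
]

#: DN1 search window (ms): brackets wave IV and the reported DN1 latencies.
DEFAULT_DN1_WINDOW_MS: Tuple[float, float] = (3.5, 8.0)


@dataclass
class BICTrace:
    """Derived binaural-interaction trace at one ITD."""

    values: np.ndarray
    fs: float
    itd_ms: float
    animal_id: Optional[str] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    def time_ms(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs * 1000.0


@dataclass
class BICMeasure:
    """DN1 magnitude (uV, relative to the zero baseline) and latency (ms)."""

    itd_ms: float
    present: bool = False
    dn1_amplitude_uv: float = float("nan")
    dn1_latency_ms: float = float("nan")


@dataclass
class BICCurve:
    """Ordered DN1 measures over the ITD grid."""

    measures: Dict[float, BICMeasure] = field(default_factory=dict)
    animal_id: Optional[str] = None

    def itds(self):
        return sorted(self.measures)

    def amplitude(self, itd_ms: float) -> float:
        return self.measures[itd_ms].dn1_amplitude_uv

    def latency(self, itd_ms: float) -> float:
        return self.measures[itd_ms].dn1_latency_ms


def compute_bic(
    left: AveragedTrace,
    right: AveragedTrace,
    binaural: AveragedTrace,
    itd_ms: float = 0.0,
) -> BICTrace:
    """BIC(t) = binaural(t) - [left(t) + right(t)].

    The monaural traces are summed as recorded (no ITD re-alignment). All
    three traces must share length and sampling rate and should already be
    baseline-normalized (as produced by :func:`voleabr.abr.average_epochs`).
    """
    for tr in (left, right, binaural):
        if tr.n_samples != left.n_samples or tr.fs != left.fs:
            raise ValueError("traces must share length and sampling rate")
    values = binaural.values - (left.values + right.values)
    return BICTrace(
        values=values, fs=left.fs, itd_ms=itd_ms,
        animal_id=binaural.animal_id or left.animal_id,
    )


def measure_dn1(
    bic: BICTrace,
    window_ms: Tuple[float, float] = DEFAULT_DN1_WINDOW_MS,
    noise_criterion: Optional[float] = None,
) -> BICMeasure:
    """Locate DN1: the most negative local extremum inside the window.

    The amplitude is the magnitude of that extremum relative to the zero
    baseline of the (normalized) trace. DN1 is reported absent when no local
    minimum exists in the window or when its magnitude falls below the noise
    criterion (default: 2x the RMS of the BIC trace outside the window).
    """
    a, b = window_ms
    t = bic.time_ms()
    if not (a < b) or a < t[0] or b > t[-1] + 1e-9:
        raise ValueError("DN1 window must be non-empty and inside the trace")
    inside = (t >= a) & (t <= b)
    if noise_criterion is None:
        outside = bic.values[~inside]
        noise_criterion = 2.0 * float(np.sqrt(np.mean(outside**2)))

    minima, _ = signal.find_peaks(-bic.values)
    minima = minima[inside[minima]]
    if minima.size == 0:
        return BICMeasure(itd_ms=bic.itd_ms, present=False)
    best = minima[np.argmin(bic.values[minima])]
    value = float(bic.values[best])
    if abs(value) < noise_criterion:
        return BICMeasure(itd_ms=bic.itd_ms, present=False)
    return BICMeasure(
        itd_ms=bic.itd_ms,
        present=True,
        dn1_amplitude_uv=abs(value),
        dn1_latency_ms=float(t[best]),
    )


def bic_curve(
    sessions: Dict[float, Tuple[AveragedTrace, AveragedTrace, AveragedTrace]],
    window_ms: Tuple[float, float] = DEFAULT_DN1_WINDOW_MS,
    animal_id: Optional[str] = None,
) -> BICCurve:
    """Compute and measure the BIC at every ITD of a session.

    ``sessions`` maps ITD (ms) to (left, right, binaural) averaged traces;
    ITDs must lie on the +-2 ms grid. Missing-ear entries (None anywhere in
    the triple) yield an absent measure at that ITD.
    """
    curve = BICCurve(animal_id=animal_id)
    for itd in sorted(sessions):
        if not any(np.isclose(itd, g) for g in ITD_GRID_MS):
            raise ValueError(f"itd {itd} ms off the ITD grid")
        triple = sessions[itd]
        if any(tr is None for tr in triple):
            curve.measures[itd] = BICMeasure(itd_ms=itd, present=False)
            continue
        left, right, binaural = triple
        bic = compute_bic(left, right, binaural, itd_ms=itd)
        curve.measures[itd] = measure_dn1(bic, window_ms)
    return curve
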