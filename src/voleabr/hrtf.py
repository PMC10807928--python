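"""HRTF processing: sweep deconvolution, gains, DTFs, ILD spectra, ITDs.

Free-field two-ear sweep recordings on the horizontal 10-degree grid are
turned into acoustic localization cues. The swept-sine recordings are
deconvolved into impulse responses; 512-point FFT magnitude spectra windowed
from the impulse peak give per-ear gains relative to the no-head calibration
(the HRTF); removing the across-position mean gain per frequency gives the
directional transfer function (DTF); the right-minus-left gain is the ILD
spectrum; and the interaural cross-correlation lag (relative to the
autocorrelation peak, with parabolic sub-sample interpolation) is the ITD.
A rigid-head prediction ties the maximal ITD to head morphometry: acoustic
path (pinna width + inter-pinna distance) divided by the speed of sound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy import signal as sp_signal
from scipy.fft import next_fast_len

from .synth import HRTFRecordingSet, SweepSpec, Waveform, sweep_signal

__all__ = [
    "ImpulseResponse",
    "GainSpectrum",
    "CueSet",
    "MorphometrySet",
    "deconvolve_sweep",
    "average_repeats",
    "ir_to_spectrum",
    "compute_gain",
    "octave_smooth",
    "compute_dtf",
    "compute_ild",
    "estimate_itd",
    "predict_max_itd",
    "path_length_for_itd",
    "effective_diameter",
    "analyze_scene",
]


@dataclass
class ImpulseResponse:
    """A deconvolved impulse response; ``lag0`` is the index of zero lag."""

    samples: np.ndarray
    fs: float
    lag0: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    def peak_index(self) -> int:
        return int(np.argmax(np.abs(self.samples)))

    def peak_lag(self) -> int:
        return self.peak_index() - self.lag0


@dataclass
class GainSpectrum:
    """Magnitude response in dB on a fixed frequency grid."""

    freqs_hz: np.ndarray
    gain_db: np.ndarray
    smoothing: str = "raw"  # "raw" or e.g. "1/48 octave"
    nfft: int = 512

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float).ravel()
        self.gain_db = np.asarray(self.gain_db, dtype=float).ravel()
        if self.freqs_hz.shape != self.gain_db.shape:
            raise ValueError("frequency grid and gains must align")

    def band(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        return (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)


@dataclass
class CueSet:
    """Per-azimuth localization cues extracted from one recording set."""

    freqs_hz: np.ndarray
    gain_left: Dict[int, GainSpectrum] = field(default_factory=dict)
    gain_right: Dict[int, GainSpectrum] = field(default_factory=dict)
    dtf_left: Dict[int, GainSpectrum] = field(default_factory=dict)
    dtf_right: Dict[int, GainSpectrum] = field(default_factory=dict)
    ild: Dict[int, GainSpectrum] = field(default_factory=dict)
    itd_ms: Dict[int, float] = field(default_factory=dict)

    @property
    def azimuths(self):
        return sorted(self.gain_left)


@dataclass(frozen=True)
class MorphometrySet:
    """Head/pinna calipers (mm) and weight (g) for one animal."""

    pinna_width_mm: float
    pinna_length_mm: float
    inter_pinna_mm: float
    nose_to_pinna_mm: Optional[float] = None
    weight_g: Optional[float] = None
    sex: Optional[str] = None
    animal_id: Optional[str] = None

    def __post_init__(self):
        if min(self.pinna_width_mm, self.pinna_length_mm, self.inter_pinna_mm) <= 0:
            raise ValueError("lengths must be positive")

    @property
    def effective_diameter_mm(self) -> float:
        return effective_diameter(self.pinna_length_mm, self.pinna_width_mm)


# --------------------------------------------------------------------------
# deconvolution
# --------------------------------------------------------------------------

def deconvolve_sweep(
    recording: Union[Waveform, np.ndarray],
    spec: SweepSpec,
    out_len: int = 4096,
    pre: int = 512,
    reg: float = 1e-6,
) -> ImpulseResponse:
    """Recover the impulse response from a swept-sine recording.

    The recording is convolved with the sweep's inverse filter — the
    amplitude-compensated time-reversed sweep, realized in the frequency
    domain as conj(S) / (|S|^2 + eps) — which concentrates the system's
    energy at its delay. The returned segment places zero lag at index
    ``pre``; ``out_len`` samples are kept.
    """
    if isinstance(recording, Waveform):
        if recording.fs != spec.fs:
            raise ValueError("recording and sweep sampling rates differ")
        rec = recording.samples
    else:
        rec = np.asarray(recording, dtype=float).ravel()
    sweep = sweep_signal(spec).samples
    nfft = next_fast_len(rec.size + sweep.size)
    S = np.fft.rfft(sweep, nfft)
    R = np.fft.rfft(rec, nfft)
    denom = (np.abs(S) ** 2) + reg * float(np.max(np.abs(S) ** 2))
    ir = np.fft.irfft(R * np.conj(S) / denom, nfft)
    # circular result: index 0 holds zero lag; roll so negative lags precede it
    rolled = np.roll(ir, pre)
    return ImpulseResponse(samples=rolled[:out_len], fs=spec.fs, lag0=pre)


def average_repeats(recordings: np.ndarray) -> np.ndarray:
    """Time-domain mean over stacked sweep repeats (repeats are played from
    one clock, so they are already aligned)."""
    rec = np.atleast_2d(np.asarray(recordings, dtype=float))
    return rec.mean(axis=0)


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

def ir_to_spectrum(
    ir: ImpulseResponse, nfft: int = 512, pre_peak_ms: float = 1.0
) -> GainSpectrum:
    """512-point FFT magnitude of the IR, windowed from its peak.

    A rectangular window of ``nfft`` samples starting ``pre_peak_ms`` before
    the impulse peak is transformed; at 44.1 kHz that spans ~11.6 ms, enough
    for the direct sound and pinna reflections.
    """
    start = max(0, ir.peak_index() - int(round(pre_peak_ms / 1000.0 * ir.fs)))
    seg = ir.samples[start : start + nfft]
    if seg.size < nfft:
        seg = np.pad(seg, (0, nfft - seg.size))
    mag = np.abs(np.fft.rfft(seg, nfft))
    gain_db = 20.0 * np.log10(np.maximum(mag, 1e-12))
    return GainSpectrum(
        freqs_hz=np.fft.rfftfreq(nfft, 1.0 / ir.fs), gain_db=gain_db, nfft=nfft
    )


def _check_grids(a: GainSpectrum, b: GainSpectrum):
    if a.freqs_hz.shape != b.freqs_hz.shape or not np.allclose(a.freqs_hz, b.freqs_hz):
        raise ValueError("frequency grids differ")


def compute_gain(animal: GainSpectrum, calibration: GainSpectrum) -> GainSpectrum:
    """HRTF gain: animal spectrum minus calibration spectrum (dB)."""
    _check_grids(animal, calibration)
    return GainSpectrum(
        freqs_hz=animal.freqs_hz,
        gain_db=animal.gain_db - calibration.gain_db,
        smoothing=animal.smoothing,
        nfft=animal.nfft,
    )


def octave_smooth(spectrum: GainSpectrum, fraction: float = 1 / 48) -> GainSpectrum:
    """Fractional-octave smoothing with a Gaussian kernel in log2 frequency.

    Powers (not dB) are averaged with weights exp(-0.5 (dl / sigma)^2) where
    dl is the log2 frequency distance and sigma = fraction / 2; weights are
    normalized per output bin, so flat spectra pass through unchanged. The
    zero-frequency bin is left untouched.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    f = spectrum.freqs_hz
    pos = f > 0
    logf = np.log2(f[pos])
    power = 10.0 ** (spectrum.gain_db[pos] / 10.0)
    sigma = fraction / 2.0
    d = logf[:, None] - logf[None, :]
    w = np.exp(-0.5 * (d / sigma) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    smoothed = w @ power
    out = spectrum.gain_db.copy()
    out[pos] = 10.0 * np.log10(np.maximum(smoothed, 1e-30))
    return GainSpectrum(
        freqs_hz=spectrum.freqs_hz,
        gain_db=out,
        smoothing=f"1/{round(1 / fraction)} octave",
        nfft=spectrum.nfft,
    )


def compute_dtf(gains: Dict[int, GainSpectrum]) -> Dict[int, GainSpectrum]:
    """Directional transfer functions: per-frequency mean across positions
    subtracted from each position's gain, so DTFs average to 0 dB."""
    if len(gains) < 2:
        raise ValueError("DTF needs gains from at least two positions")
    azimuths = sorted(gains)
    ref = gains[azimuths[0]]
    for az in azimuths[1:]:
        _check_grids(ref, gains[az])
    mean = np.mean([gains[az].gain_db for az in azimuths], axis=0)
    return {
        az: GainSpectrum(
            freqs_hz=ref.freqs_hz,
            gain_db=gains[az].gain_db - mean,
            smoothing=gains[az].smoothing,
            nfft=gains[az].nfft,
        )
        for az in azimuths
    }


def compute_ild(right: GainSpectrum, left: GainSpectrum) -> GainSpectrum:
    """ILD spectrum: right-ear gain minus left-ear gain (dB)."""
    _check_grids(right, left)
    return GainSpectrum(
        freqs_hz=right.freqs_hz,
        gain_db=right.gain_db - left.gain_db,
        smoothing=right.smoothing,
        nfft=right.nfft,
    )


# --------------------------------------------------------------------------
# ITD
# --------------------------------------------------------------------------

def _parabolic_refine(c: np.ndarray, i: int) -> float:
    """Sub-sample offset of the extremum of a 3-point parabola around i."""
    if i <= 0 or i >= c.size - 1:
        return 0.0
    denom = c[i - 1] - 2.0 * c[i] + c[i + 1]
    if denom == 0:
        return 0.0
    return 0.5 * (c[i - 1] - c[i + 1]) / denom


def estimate_itd(
    left: ImpulseResponse, right: ImpulseResponse, interpolate: bool = True
) -> float:
    """ITD (ms) from the interaural cross-correlation of impulse responses.

    The lag maximizing the left/right cross-correlation, minus the lag
    maximizing the (left) autocorrelation, converted to milliseconds.
    Positive ITD means the right ear leads (source on the right). Parabolic
    interpolation refines the peak below one sample unless ``interpolate``
    is False.
    """
    if left.fs != right.fs:
        raise ValueError("sampling rates differ")
    l, r = left.samples, right.samples
    if not (np.any(l) and np.any(r)):
        raise ValueError("all-zero impulse response")
    xc = sp_signal.correlate(r, l, mode="full")
    i = int(np.argmax(xc))
    lag = i - (l.size - 1) + (_parabolic_refine(xc, i) if interpolate else 0.0)
    # reference: the autocorrelation peak lag (zero for any signal)
    ac = sp_signal.correlate(l, l, mode="full")
    j = int(np.argmax(ac))
    lag0 = j - (l.size - 1) + (_parabolic_refine(ac, j) if interpolate else 0.0)
    delta = (lag - lag0) + (right.lag0 - left.lag0)  # right minus left delay
    return float(-delta / left.fs * 1000.0)


# --------------------------------------------------------------------------
# morphometry-based prediction
# --------------------------------------------------------------------------

def predict_max_itd(m: MorphometrySet, c_m_s: float = 343.0) -> float:
    """Maximal ITD (us) for a rigid head: (pinna width + inter-pinna) / c."""
    if c_m_s <= 0:
        raise ValueError("speed of sound must be positive")
    path_m = (m.pinna_width_mm + m.inter_pinna_mm) / 1000.0
    return path_m / c_m_s * 1e6


def path_length_for_itd(itd_us: float, c_m_s: float = 343.0) -> float:
    """Inverse of :func:`predict_max_itd`: acoustic path length (mm)."""
    if c_m_s <= 0:
        raise ValueError("speed of sound must be positive")
    return itd_us * 1e-6 * c_m_s * 1000.0


def effective_diameter(length_mm: float, width_mm: float) -> float:
    """Equal-area circle diameter of an elliptical pinna: sqrt(l * w)."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("dimensions must be positive")
    return math.sqrt(length_mm * width_mm)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

def analyze_scene(
    recordings: HRTFRecordingSet,
    smooth_fraction: Optional[float] = 1 / 48,
    nfft: int = 512,
) -> CueSet:
    """Run the full cue-extraction pipeline on a recording set.

    Repeats are averaged in the time domain, each ear's recording and the
    calibration are deconvolved, 512-point gains are computed relative to
    the calibration and optionally 1/48-octave smoothed, DTFs are formed by
    removing the across-azimuth mean, and ILD/ITD are extracted per azimuth.
    """
    spec = recordings.sweep
    cal_ir = deconvolve_sweep(recordings.calibration, spec)
    cal_spec = ir_to_spectrum(cal_ir, nfft=nfft)

    gains_l, gains_r, itds, irs = {}, {}, {}, {}
    for az in recordings.azimuths:
        ir_l = deconvolve_sweep(average_repeats(recordings.left[az]), spec)
        ir_r = deconvolve_sweep(average_repeats(recordings.right[az]), spec)
        irs[az] = (ir_l, ir_r)
        gl = compute_gain(ir_to_spectrum(ir_l, nfft=nfft), cal_spec)
        gr = compute_gain(ir_to_spectrum(ir_r, nfft=nfft), cal_spec)
        if smooth_fraction:
            gl = octave_smooth(gl, smooth_fraction)
            gr = octave_smooth(gr, smooth_fraction)
        gains_l[az], gains_r[az] = gl, gr
        itds[az] = estimate_itd(ir_l, ir_r)

    dtf_l = compute_dtf(gains_l) if len(gains_l) >= 2 else {}
    dtf_r = compute_dtf(gains_r) if len(gains_r) >= 2 else {}
    ild = {az: compute_ild(gains_r[az], gains_l[az]) for az in gains_l}
    return CueSet(
        freqs_hz=cal_spec.freqs_hz,
        gain_left=gains_l,
        gain_right=gains_r,
        dtf_left=dtf_l,
        dtf_right=dtf_r,
        ild=ild,
        itd_ms=itds,
    )
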