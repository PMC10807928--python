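"""Synthetic ABR sessions and binaural acoustic scenes.

Everything downstream of data acquisition is testable against this module:
it fabricates click/tone-evoked epoch stacks with four Gaussian ABR waves,
level-dependent growth above a true threshold, binaural epochs carrying an
injected DN1 deflection whose amplitude/latency follow a per-ITD table, and
two-ear free-field sweep recordings shaped by a rigid-head delay-and-shadow
model. Group parameters default to the published prairie-vole reference
values; between-animal spread is drawn as Normal(mean, sqrt(N) * SE).

Conventions: voltages in uV, times in ms inside epochs, azimuth in degrees
(positive = right), ITD positive when the right ear leads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from . import reference
from .abr import EpochSet
from .conditions import AZIMUTH_GRID_DEG, ITD_GRID_MS, StimulusCondition

__all__ = [
    "WaveParams",
    "BICParams",
    "ABRSimConfig",
    "HeadModel",
    "SweepSpec",
    "Waveform",
    "HRTFRecordingSet",
    "linear_db_growth",
    "female_click_config",
    "male_click_config",
    "table_bic_params",
    "symmetric_bic_params",
    "draw_animal",
    "generate_abr_epochs",
    "generate_binaural_session",
    "generate_level_series",
    "sweep_signal",
    "generate_hrtf_scene",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveParams:
    """One ABR wave's template: Gaussian bump of height ``amplitude_uv`` (uV)
    centered at ``latency_ms`` with standard deviation ``width_ms``.

    ``amplitude_sd`` / ``latency_sd`` are between-animal SDs used by
    :func:`draw_animal`. All waves are positive-going; the troughs between
    waves emerge from the superposition and the band-pass filter.
    """

    amplitude_uv: float
    latency_ms: float
    amplitude_sd: float = 0.0
    latency_sd: float = 0.0
    width_ms: float = 0.15
    sign: int = 1


@dataclass(frozen=True)
class BICParams:
    """DN1 amplitude (uV) and latency (ms) versus ITD (ms), with SDs.

    ``amplitude[itd]`` is the magnitude of the injected negative deflection.
    """

    amplitude: Dict[float, float]
    latency: Dict[float, float]
    amplitude_sd: Dict[float, float] = field(default_factory=dict)
    latency_sd: Dict[float, float] = field(default_factory=dict)
    width_ms: float = 0.25

    def __call__(self, itd_ms: float) -> Tuple[float, float]:
        key = _grid_key(itd_ms)
        return self.amplitude[key], self.latency[key]


def linear_db_growth(level_db: float, threshold_db: float, saturation_db: float = 90.0) -> float:
    """Amplitude scale in [0, 1]: linear in dB above threshold, saturating.

    Zero at and below the true threshold, 1 at ``saturation_db`` and above.
    A threshold at or above the saturation level degenerates to a step.
    """
    if threshold_db >= saturation_db:
        return 1.0 if level_db >= threshold_db else 0.0
    return float(np.clip((level_db - threshold_db) / (saturation_db - threshold_db), 0.0, 1.0))


@dataclass
class ABRSimConfig:
    """Full parameterization of one simulated animal/session.

    wave_params : per-wave template parameters (means are used directly; call
        :func:`draw_animal` to realize a new animal from the SDs).
    noise_sd_uv : per-epoch additive white Gaussian noise SD.
    growth : callable ``(level_db, threshold_db) -> scale in [0, 1]``.
    threshold_db : true threshold(s); a scalar, or a dict keyed by ``"click"``
        and tone frequency in kHz.
    bic_params : DN1 table for binaural sessions.
    """

    wave_params: Dict[str, WaveParams]
    noise_sd_uv: float = 5.0
    n_epochs: int = 500
    epoch_dur_ms: float = 12.0
    fs: float = 97656.25
    growth: Callable[[float, float], float] = linear_db_growth
    threshold_db: object = 0.0
    bic_params: Optional[BICParams] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.fs <= 0 or self.epoch_dur_ms <= 0:
            raise ValueError("fs and epoch_dur_ms must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        lats = [self.wave_params[w].latency_ms for w in sorted(self.wave_params)]
        order = [self.wave_params[w].latency_ms for w in ("I", "II", "III", "IV") if w in self.wave_params]
        if any(np.diff(order) <= 0):
            raise ValueError("wave latencies must increase strictly I<II<III<IV")
        for w, p in self.wave_params.items():
            if p.amplitude_uv < 0:
                raise ValueError(f"wave {w} amplitude must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_dur_ms * self.fs / 1000.0))

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs * 1000.0

    def resolve_threshold(self, condition: StimulusCondition) -> float:
        if isinstance(self.threshold_db, dict):
            key = "click" if condition.kind == "click" else condition.frequency_khz
            return float(self.threshold_db[key])
        return float(self.threshold_db)


# --------------------------------------------------------------------------
# reference-parameterized factories
# --------------------------------------------------------------------------

def _wave_params_for(sex: str) -> Dict[str, WaveParams]:
    amps = reference.WAVE_AMPLITUDE_UV[sex]
    lats = reference.WAVE_LATENCY_MS[sex]
    return {
        w: WaveParams(
            amplitude_uv=amps[w].mean,
            latency_ms=lats[w].mean,
            amplitude_sd=amps[w].sd,
            latency_sd=lats[w].sd,
        )
        for w in amps
    }


def _click_config(sex: str, **kwargs) -> ABRSimConfig:
    thresholds = {"click": reference.CLICK_THRESHOLD_DB[sex].mean}
    thresholds.update({f: rv.mean for f, rv in reference.TONE_THRESHOLD_DB[sex].items()})
    defaults = dict(
        wave_params=_wave_params_for(sex),
        threshold_db=thresholds,
        bic_params=table_bic_params("male" if sex == "male" else "female"),
    )
    defaults.update(kwargs)
    return ABRSimConfig(**defaults)


def female_click_config(**kwargs) -> ABRSimConfig:
    """Session config with the published female group means."""
    return _click_config("female", **kwargs)


def male_click_config(**kwargs) -> ABRSimConfig:
    """Session config with the published male group means."""
    return _click_config("male", **kwargs)


def table_bic_params(sex: str) -> BICParams:
    """DN1 table exactly as reported for ``sex`` across the ITD grid."""
    amp = reference.BIC_AMPLITUDE_UV[sex]
    lat = reference.BIC_LATENCY_MS[sex]
    return BICParams(
        amplitude={i: amp[i].mean for i in amp},
        latency={i: lat[i].mean for i in lat},
        amplitude_sd={i: amp[i].sd for i in amp},
        latency_sd={i: lat[i].sd for i in lat},
    )


def symmetric_bic_params(sex: str = "male") -> BICParams:
    """Canonical smooth DN1 curve: linear in |ITD|, fit to the table.

    The reported per-ITD rows carry sampling noise (the male amplitude row
    peaks at |itd| = 0.5-1.0 ms within its SEs). For qualitative-shape work
    the canonical curve regresses the ITD-symmetrized table on |itd|:
    amplitude declines and latency grows linearly away from zero ITD, giving
    a generator whose DN1 amplitude is strictly maximal and latency strictly
    minimal at 0 ITD — the shape reported across species. SDs are the
    pooled table SDs.
    """
    raw = table_bic_params(sex)
    itds = sorted(raw.amplitude)
    x = np.abs(itds)
    amp_fit = np.polynomial.Polynomial.fit(x, [raw.amplitude[i] for i in itds], 1)
    lat_fit = np.polynomial.Polynomial.fit(x, [raw.latency[i] for i in itds], 1)
    asd = float(np.mean([raw.amplitude_sd[i] for i in itds]))
    lsd = float(np.mean([raw.latency_sd[i] for i in itds]))
    return BICParams(
        amplitude={i: max(0.0, float(amp_fit(abs(i)))) for i in itds},
        latency={i: float(lat_fit(abs(i))) for i in itds},
        amplitude_sd={i: asd for i in itds},
        latency_sd={i: lsd for i in itds},
    )


def draw_animal(config: ABRSimConfig, seed: int) -> ABRSimConfig:
    """Realize one animal from the population config.

    One shared standard-normal deviate per parameter family (wave amplitudes,
    wave latencies, BIC amplitudes, BIC latencies) is scaled by each entry's
    between-animal SD. Marginally each parameter is Normal(mean, SD); the
    shared deviate preserves the latency ordering I<II<III<IV and couples the
    BIC curve across ITDs the way real animals are coupled. Drawn amplitudes
    are clipped at zero.
    """
    rng = np.random.default_rng(seed)
    z_amp, z_lat, z_bamp, z_blat = rng.standard_normal(4)
    waves = {
        w: replace(
            p,
            amplitude_uv=max(0.0, p.amplitude_uv + z_amp * p.amplitude_sd),
            latency_ms=p.latency_ms + z_lat * p.latency_sd,
        )
        for w, p in config.wave_params.items()
    }
    bic = config.bic_params
    if bic is not None:
        bic = BICParams(
            amplitude={
                i: max(0.0, bic.amplitude[i] + z_bamp * bic.amplitude_sd.get(i, 0.0))
                for i in bic.amplitude
            },
            latency={
                i: bic.latency[i] + z_blat * bic.latency_sd.get(i, 0.0)
                for i in bic.latency
            },
            amplitude_sd=dict(bic.amplitude_sd),
            latency_sd=dict(bic.latency_sd),
            width_ms=bic.width_ms,
        )
    return replace(config, wave_params=waves, bic_params=bic, seed=seed)


# --------------------------------------------------------------------------
# epoch generation
# --------------------------------------------------------------------------

def _grid_key(itd_ms: float) -> float:
    for g in ITD_GRID_MS:
        if math.isclose(itd_ms, g, abs_tol=1e-9):
            return g
    raise ValueError(f"itd {itd_ms} ms is off the +-2 ms / 0.5 ms grid")


def _condition_rng(config: ABRSimConfig, condition: StimulusCondition, salt: int = 0):
    """Deterministic substream per (config seed, condition)."""
    key = [
        int(config.seed),
        {"left": 1, "right": 2, "binaural": 3}[condition.ear],
        {"click": 1, "tone": 2}[condition.kind],
        int(round(condition.level_db_spl * 10)) + 10_000,
        int(round((condition.frequency_khz or 0) * 10)),
        int(round((condition.itd_ms or 0) * 10)) + 100,
        int(salt),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def _template(config: ABRSimConfig, scale: float) -> np.ndarray:
    t = config.time_ms()
    out = np.zeros(config.n_samples)
    for p in config.wave_params.values():
        out += (
            p.sign
            * p.amplitude_uv
            * scale
            * np.exp(-0.5 * ((t - p.latency_ms) / p.width_ms) ** 2)
        )
    return out


def generate_abr_epochs(config: ABRSimConfig, condition: StimulusCondition) -> EpochSet:
    """Simulate ``config.n_epochs`` stimulus-locked epochs for one monaural
    condition: the wave template scaled by the level-growth function plus
    white Gaussian noise. Deterministic given ``config.seed``.
    """
    if not condition.is_monaural:
        raise ValueError("generate_abr_epochs handles monaural conditions; "
                         "use generate_binaural_session for binaural ones")
    scale = config.growth(condition.level_db_spl, config.resolve_threshold(condition))
    template = _template(config, scale)
    rng = _condition_rng(config, condition)
    noise = rng.standard_normal((config.n_epochs, config.n_samples)) * config.noise_sd_uv
    return EpochSet(
        samples=template[None, :] + noise,
        fs=config.fs,
        condition=condition,
        seed=config.seed,
    )


def generate_binaural_session(
    config: ABRSimConfig,
    itds_ms: Sequence[float],
    level_db_spl: float = 90.0,
) -> Dict[float, Tuple[EpochSet, EpochSet, EpochSet]]:
    """Simulate a binaural-click session across ITDs.

    Per ITD the session holds left-only and right-only epoch stacks plus a
    binaural stack whose epochs are the sum of the two noiseless monaural
    templates with an injected negative DN1 deflection (amplitude/latency
    from ``config.bic_params``) and fresh noise. The binaural response is
    therefore exactly additive whenever the DN1 amplitude is zero.
    """
    if config.bic_params is None:
        raise ValueError("config.bic_params is required for binaural sessions")
    itds = [_grid_key(i) for i in itds_ms]
    t = config.time_ms()
    out: Dict[float, Tuple[EpochSet, EpochSet, EpochSet]] = {}
    for itd in itds:
        left = generate_abr_epochs(
            config, StimulusCondition("left", "click", level_db_spl)
        )
        right = generate_abr_epochs(
            config, StimulusCondition("right", "click", level_db_spl)
        )
        # monaural mean responses = the noiseless template at this level
        scale = config.growth(level_db_spl, config.resolve_threshold(
            StimulusCondition("left", "click", level_db_spl)))
        mono_sum = 2.0 * _template(config, scale)
        amp, lat = config.bic_params(itd)
        if amp < 0:
            raise ValueError("DN1 amplitude must be a magnitude (>= 0)")
        dn1 = -amp * np.exp(-0.5 * ((t - lat) / config.bic_params.width_ms) ** 2)
        cond = StimulusCondition("binaural", "click", level_db_spl, itd_ms=itd)
        rng = _condition_rng(config, cond)
        noise = rng.standard_normal((config.n_epochs, config.n_samples)) * config.noise_sd_uv
        out[itd] = (
            left,
            right,
            EpochSet(samples=mono_sum + dn1 + noise, fs=config.fs,
                     condition=cond, seed=config.seed),
        )
    return out


def generate_level_series(
    config: ABRSimConfig,
    levels_db_spl: Sequence[float],
    condition: StimulusCondition,
) -> Dict[float, EpochSet]:
    """Simulate a descending level series (10 dB steps) for one condition.

    Below the config's true threshold the template scale is zero, so those
    epoch stacks contain noise only.
    """
    levels = list(levels_db_spl)
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(np.diff(levels) != -10):
        raise ValueError("levels must descend in exact 10 dB steps")
    out = {}
    for level in levels:
        cond = StimulusCondition(
            condition.ear, condition.kind, float(level), condition.frequency_khz
        )
        out[float(level)] = generate_abr_epochs(config, cond)
    return out


# --------------------------------------------------------------------------
# acoustic scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepSpec:
    """Exponential (logarithmic) sine sweep used for HRTF measurement.

    ``n_points`` fixes the sample count (128k at 44.1 kHz, just under 3 s);
    when omitted it is derived from ``duration_s``. The instantaneous
    frequency runs from ``f_start_hz`` to ``f_end_hz`` over the sweep.
    """

    f_start_hz: float = 250.0
    f_end_hz: float = 20000.0
    duration_s: float = 3.0
    fs: float = 44100.0
    level_dbfs: float = -15.0
    n_points: Optional[int] = 131072

    def __post_init__(self):
        if not (0 < self.f_start_hz < self.f_end_hz):
            raise ValueError("need 0 < f_start < f_end")
        if self.f_end_hz >= self.fs / 2:
            raise ValueError("f_end must be below Nyquist")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_points if self.n_points else int(round(self.duration_s * self.fs))

    @property
    def sweep_duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Waveform:
    """A sampled acoustic signal (full-scale units, |x| <= 1 nominally)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()


@dataclass
class HRTFRecordingSet:
    """Two-ear sweep recordings per azimuth plus a no-head calibration.

    ``left``/``right`` map azimuth (deg) to (n_repeats, n) sample arrays.
    """

    left: Dict[int, np.ndarray]
    right: Dict[int, np.ndarray]
    calibration: np.ndarray
    sweep: SweepSpec
    fs: float
    n_repeats: int = 5
    head: Optional["HeadModel"] = None

    @property
    def azimuths(self) -> list:
        return sorted(self.left)


@dataclass(frozen=True)
class HeadModel:
    """Rigid-head acoustics: interaural delay and high-frequency shadow.

    The maximal interaural delay is the acoustic path (pinna width plus
    inter-pinna distance) divided by the speed of sound; delay scales with
    sin(azimuth). The level shadow is a first-order high shelf reaching
    ``max_ild_db`` (right minus left) at +90 degrees well above
    ``shadow_corner_hz``.
    """

    pinna_width_mm: float = 10.45
    pinna_length_mm: float = 13.1
    inter_pinna_mm: float = 15.35
    max_ild_db: float = 18.0
    shadow_corner_hz: float = 4000.0
    c_m_s: float = 343.0

    def __post_init__(self):
        if min(self.pinna_width_mm, self.pinna_length_mm, self.inter_pinna_mm) <= 0:
            raise ValueError("head dimensions must be positive")
        if self.c_m_s <= 0:
            raise ValueError("speed of sound must be positive")

    @property
    def max_itd_s(self) -> float:
        return (self.pinna_width_mm + self.inter_pinna_mm) / 1000.0 / self.c_m_s


def sweep_signal(spec: SweepSpec) -> Waveform:
    """Generate the exponential sweep at ``level_dbfs`` re full scale."""
    n = spec.n_samples
    T = spec.sweep_duration_s
    t = np.arange(n) / spec.fs
    r = spec.f_end_hz / spec.f_start_hz
    k = math.log(r)
    phase = 2 * math.pi * spec.f_start_hz * T / k * (np.exp(t * k / T) - 1.0)
    amp = 10.0 ** (spec.level_dbfs / 20.0)
    return Waveform(samples=amp * np.sin(phase), fs=spec.fs)


def _head_response(
    head: Optional[HeadModel], az_deg: float, freqs: np.ndarray, bulk_delay_s: float
) -> Tuple[np.ndarray, np.ndarray]:
    """(left, right) complex frequency responses; ``head=None`` = calibration."""
    if head is None:
        h = np.exp(-2j * np.pi * freqs * bulk_delay_s)
        return h, h
    s = math.sin(math.radians(az_deg))
    itd = head.max_itd_s * s          # >0: right leads
    tau_l = bulk_delay_s + itd / 2.0
    tau_r = bulk_delay_s - itd / 2.0
    shelf = freqs**2 / (freqs**2 + head.shadow_corner_hz**2)
    ild_db = head.max_ild_db * s * shelf      # right - left, dB
    g_r = 10.0 ** (+ild_db / 40.0)
    g_l = 10.0 ** (-ild_db / 40.0)
    left = g_l * np.exp(-2j * np.pi * freqs * tau_l)
    right = g_r * np.exp(-2j * np.pi * freqs * tau_r)
    return left, right


def generate_hrtf_scene(
    head: HeadModel,
    azimuths_deg: Iterable[int] = AZIMUTH_GRID_DEG,
    spec: SweepSpec = SweepSpec(),
    n_repeats: int = 5,
    mic_noise_sd: float = 0.0,
    seed: int = 0,
    bulk_delay_s: float = 1e-3,
) -> HRTFRecordingSet:
    """Render two-ear sweep recordings through the rigid-head model.

    Per azimuth the sweep is convolved (frequency-domain, exact fractional
    delays) with the head response of each ear; the calibration recording
    sees only the common bulk propagation delay, so it is head-independent.
    """
    azimuths = []
    for az in azimuths_deg:
        if int(az) not in AZIMUTH_GRID_DEG:
            raise ValueError(f"azimuth {az} off the 10-degree grid")
        azimuths.append(int(az))
    x = sweep_signal(spec).samples
    n_out = x.size + int(round(bulk_delay_s * spec.fs)) + 1024
    nfft = int(2 ** math.ceil(math.log2(n_out)))
    X = np.fft.rfft(x, nfft)
    freqs = np.fft.rfftfreq(nfft, 1.0 / spec.fs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_771]))

    def render(h: np.ndarray) -> np.ndarray:
        y = np.fft.irfft(X * h, nfft)[:n_out]
        reps = np.tile(y, (n_repeats, 1))
        if mic_noise_sd > 0:
            reps = reps + rng.standard_normal(reps.shape) * mic_noise_sd
        return reps

    left, right = {}, {}
    for az in azimuths:
        hl, hr = _head_response(head, az, freqs, bulk_delay_s)
        left[az] = render(hl)
        right[az] = render(hr)
    hcal, _ = _head_response(None, 0.0, freqs, bulk_delay_s)
    calibration = np.fft.irfft(X * hcal, nfft)[:n_out]
    return HRTFRecordingSet(
        left=left, right=right, calibration=calibration,
        sweep=spec, fs=spec.fs, n_repeats=n_repeats, head=head,
    )
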