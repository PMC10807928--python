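"""On-disk formats: epoch containers, peak/BIC/audiogram tables, WAV scenes.

Epoch sets travel as a samples CSV plus a JSON sidecar holding sampling
rate, condition, and provenance. Measurement tables are tidy CSVs (one row
per animal x wave / ITD / frequency). Acoustic recordings are float32 PCM
WAV. Text tables round to six significant digits; the epoch container
stores full float64 precision (17 significant digits round-trips exactly).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .abr import AnnotationSet, EpochSet, PeakSet, WaveMeasure
from .audiogram import Audiogram
from .binaural import BICCurve, BICMeasure
from .conditions import WAVES, StimulusCondition

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_wav",
    "read_wav",
    "peaks_to_frame",
    "write_peaks_csv",
    "read_peaks_csv",
    "bic_curve_to_frame",
    "write_bic_csv",
    "audiogram_to_frame",
    "write_audiogram_csv",
    "write_annotations",
    "read_annotations",
]

PathLike = Union[str, Path]


# --------------------------------------------------------------------------
# epoch containers
# --------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, basepath: PathLike) -> None:
    """Write ``<base>.csv`` (full-precision samples) + ``<base>.json`` sidecar."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(base.with_suffix(".csv"), epochs.samples, delimiter=",", fmt="%.17g")
    meta = {
        "fs": epochs.fs,
        "n_epochs": epochs.n_epochs,
        "n_samples": epochs.n_samples,
        "animal_id": epochs.animal_id,
        "seed": epochs.seed,
        "condition": dataclasses.asdict(epochs.condition) if epochs.condition else None,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_epochs(basepath: PathLike) -> EpochSet:
    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    try:
        samples = np.loadtxt(base.with_suffix(".csv"), delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"corrupt epoch samples file {base.with_suffix('.csv')}: {exc}") from exc
    if samples.shape != (meta["n_epochs"], meta["n_samples"]):
        raise ValueError(
            f"epoch file {base}: shape {samples.shape} does not match sidecar "
            f"({meta['n_epochs']}, {meta['n_samples']})"
        )
    cond = StimulusCondition(**meta["condition"]) if meta.get("condition") else None
    return EpochSet(
        samples=samples,
        fs=meta["fs"],
        condition=cond,
        animal_id=meta.get("animal_id"),
        seed=meta.get("seed"),
    )


# --------------------------------------------------------------------------
# WAV
# --------------------------------------------------------------------------

def write_wav(path: PathLike, samples: np.ndarray, fs: float) -> None:
    """Float32 PCM WAV (mono or multichannel, channels in columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, int(round(fs)), np.asarray(samples, dtype=np.float32))


def read_wav(path: PathLike):
    fs, data = wavfile.read(path)
    return np.asarray(data, dtype=float), float(fs)


# --------------------------------------------------------------------------
# tidy tables
# --------------------------------------------------------------------------

def peaks_to_frame(peaksets: Dict[str, PeakSet]) -> pd.DataFrame:
    """Tidy wave table: (animal, ear, wave, amplitude_uV, latency_ms, present)."""
    rows = []
    for key, ps in peaksets.items():
        for w in WAVES:
            m = ps.waves[w]
            rows.append(
                {
                    "animal_id": ps.animal_id or key,
                    "ear": ps.ear,
                    "wave": w,
                    "present": m.present,
                    "amplitude_uV": m.amplitude_uv if m.present else np.nan,
                    "latency_ms": m.latency_ms if m.present else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_peaks_csv(peaksets: Dict[str, PeakSet], path: PathLike) -> None:
    frame = peaks_to_frame(peaksets)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.6g")


def read_peaks_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "wave", "present", "amplitude_uV", "latency_ms"}
    if not required <= set(df.columns):
        raise ValueError(f"peak table {path} missing columns {required - set(df.columns)}")
    return df


def bic_curve_to_frame(curves: Dict[str, BICCurve]) -> pd.DataFrame:
    rows = []
    for key, curve in curves.items():
        for itd in curve.itds():
            m: BICMeasure = curve.measures[itd]
            rows.append(
                {
                    "animal_id": curve.animal_id or key,
                    "itd_ms": itd,
                    "present": m.present,
                    "dn1_amplitude_uV": m.dn1_amplitude_uv if m.present else np.nan,
                    "dn1_latency_ms": m.dn1_latency_ms if m.present else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_bic_csv(curves: Dict[str, BICCurve], path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bic_curve_to_frame(curves).to_csv(path, index=False, float_format="%.6g")


def audiogram_to_frame(audiograms: Dict[str, Audiogram]) -> pd.DataFrame:
    rows = []
    for key, ag in audiograms.items():
        for f in ag.frequencies():
            r = ag.thresholds[f]
            rows.append(
                {
                    "animal_id": ag.animal_id or key,
                    "frequency_khz": f,
                    "threshold_db_spl": r.threshold_db_spl,
                    "censored": r.censored,
                }
            )
    return pd.DataFrame(rows)


def write_audiogram_csv(audiograms: Dict[str, Audiogram], path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    audiogram_to_frame(audiograms).to_csv(path, index=False, float_format="%.6g")


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

def write_annotations(ann: AnnotationSet, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps({w: list(a) for w, a in ann.actions.items()}, indent=1))


def read_annotations(path: PathLike) -> AnnotationSet:
    raw = json.loads(Path(path).read_text())
    return AnnotationSet(actions={w: tuple(a) for w, a in raw.items()})
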