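"""Signal conditioning and feature extraction for sEMG recordings.

Pipeline per recording: 4th-order Butterworth band-pass (20-400 Hz, zero
phase by default) -> whole-recording RMS per channel -> paraspinal muscle
symmetry index (PMSI = RMS_convex / RMS_concave) per bilateral pair ->
model input tensors (anti-alias resampled, length-normalised, optionally
z-scored) plus a static feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .cohort import (
    CHANNEL_NAMES,
    MUSCLE_PAIRS,
    N_CHANNELS,
    PAIR_REGION,
    MEASUREMENT_WEEKS,
    EMGRecording,
    MuscleChannel,
    PatientStatic,
)

PAIR_NAMES = list(MUSCLE_PAIRS)  # fixed order: ES, MF, RA, EO


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design used throughout the pipeline."""

    order: int = 4
    low_hz: float = 20.0
    high_hz: float = 400.0
    mode: str = "zero_phase"  # or "causal"

    def validate(self, sample_rate_hz: float) -> None:
        nyq = sample_rate_hz / 2.0
        if not (0 < self.low_hz < self.high_hz < nyq):
            raise ValueError(
                f"infeasible band [{self.low_hz}, {self.high_hz}] Hz for "
                f"sample rate {sample_rate_hz} Hz (Nyquist {nyq})"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    def sos(self, sample_rate_hz: float) -> np.ndarray:
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass",
            fs=sample_rate_hz, output="sos",
        )


def bandpass_filter(x: np.ndarray, sample_rate_hz: float,
                    spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Band-pass filter along the last axis.

    Zero-phase mode applies the filter forward and backward (no phase
    shift; magnitude response squared).  Output has the input's length.
    """
    spec.validate(sample_rate_hz)
    x = np.asarray(x)
    if x.shape[-1] < 3 * spec.order:
        raise ValueError(f"sequence too short to filter: {x.shape[-1]} samples")
    sos = spec.sos(sample_rate_hz)
    dtype = x.dtype if x.dtype in (np.float32, np.float64) else np.float64
    if spec.mode == "zero_phase":
        y = sps.sosfiltfilt(sos, x.astype(np.float64), axis=-1)
    else:
        y = sps.sosfilt(sos, x.astype(np.float64), axis=-1)
    return y.astype(dtype)


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude sqrt(mean(x^2)) of a 1-D signal."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("rms of empty sequence is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def pmsi(rms_convex: float, rms_concave: float) -> float:
    """Paraspinal muscle symmetry index: RMS_convex / RMS_concave.

    1 means symmetric activation; > 1 convex-dominant, < 1 concave-dominant.
    """
    if rms_convex < 0 or rms_concave < 0:
        raise ValueError("RMS values must be nonnegative")
    if rms_concave == 0:
        raise ZeroDivisionError("PMSI undefined: concave RMS is zero")
    return rms_convex / rms_concave


@dataclass
class FeatureSet:
    """Per-recording features: filtered per-channel RMS and per-pair PMSI."""

    patient_id: str
    week: int
    exercise: str
    rms_per_channel: np.ndarray  # [8], uV, order = MuscleChannel enum
    pmsi_per_pair: dict[str, float]  # pair name -> ratio
    sex: str
    bmi: float


def extract_features(recording: EMGRecording, static: PatientStatic,
                     spec: FilterSpec = FilterSpec()) -> FeatureSet:
    """Filter, compute per-channel RMS and per-pair PMSI.

    The convex side of each pair is read from the patient's regional
    convex-side map (paraspinal pairs via the lumbar placement level,
    abdominal pairs via the thoracic curve).
    """
    filt = bandpass_filter(recording.signals, recording.sample_rate_hz, spec)
    rms_vals = np.array([rms(filt[i]) for i in range(N_CHANNELS)])
    pmsis: dict[str, float] = {}
    for pair, (chL, chR) in MUSCLE_PAIRS.items():
        convex = static.convex_side[PAIR_REGION[pair]]
        cvx, ccv = (chL, chR) if convex == "L" else (chR, chL)
        pmsis[pair] = pmsi(rms_vals[cvx.value], rms_vals[ccv.value])
    return FeatureSet(
        patient_id=recording.patient_id,
        week=recording.week,
        exercise=recording.exercise.name,
        rms_per_channel=rms_vals,
        pmsi_per_pair=pmsis,
        sex=static.sex,
        bmi=static.bmi,
    )


@dataclass(frozen=True)
class TensorSpec:
    """Shape contract for the network's time-series input."""

    target_rate_hz: float = 100.0
    target_len: int = 2000
    normalization: str = "per_channel_zscore"  # or "none"

    def validate(self, sample_rate_hz: float) -> None:
        if self.target_len < 1:
            raise ValueError("target_len must be >= 1")
        if self.target_rate_hz > sample_rate_hz:
            raise ValueError("cannot resample above the original rate")
        if self.normalization not in ("per_channel_zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _resample(x: np.ndarray, sample_rate_hz: float, target_rate_hz: float) -> np.ndarray:
    if target_rate_hz == sample_rate_hz:
        return x
    frac = Fraction(target_rate_hz / sample_rate_hz).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def _fit_length(x: np.ndarray, target_len: int) -> np.ndarray:
    """Centre-crop or centre-pad (zeros) the last axis to target_len."""
    n = x.shape[-1]
    if n == target_len:
        return x
    if n > target_len:
        start = (n - target_len) // 2
        return x[..., start : start + target_len]
    pad = target_len - n
    left = pad // 2
    widths = [(0, 0)] * (x.ndim - 1) + [(left, pad - left)]
    return np.pad(x, widths)


# Static vector layout: [sex female, sex male, BMI / 20, week one-hot (4)]
# followed by 4 pairs x 4 weeks of (PMSI - 1), zero-filled for weeks after
# the recording's week (no future leakage).  Units are chosen so every
# feature is O(1) around a natural origin: symmetric activation maps to 0.
_PMSI_OFFSET = 7  # index of the first PMSI slot
STATIC_DIM = _PMSI_OFFSET + len(PAIR_NAMES) * len(MEASUREMENT_WEEKS)


def static_vector(static: PatientStatic, week: int,
                  pmsi_history: dict[int, dict[str, float]] | None) -> np.ndarray:
    """Fixed-size static feature vector for one sample.

    ``pmsi_history`` maps week -> {pair -> PMSI}; only entries at weeks
    <= ``week`` are used (no future leakage).
    """
    v = np.zeros(STATIC_DIM, dtype=np.float64)
    v[0] = 1.0 if static.sex == "female" else 0.0
    v[1] = 1.0 if static.sex == "male" else 0.0
    v[2] = static.bmi / 20.0
    v[3 + MEASUREMENT_WEEKS.index(week)] = 1.0
    if pmsi_history:
        for wi, w in enumerate(MEASUREMENT_WEEKS):
            if w > week or w not in pmsi_history:
                continue
            for pi, pair in enumerate(PAIR_NAMES):
                slot = _PMSI_OFFSET + wi * len(PAIR_NAMES) + pi
                v[slot] = pmsi_history[w].get(pair, 1.0) - 1.0
    return v


def build_model_inputs(
    recording: EMGRecording,
    static: PatientStatic,
    tensor_spec: TensorSpec = TensorSpec(),
    filter_spec: FilterSpec = FilterSpec(),
    pmsi_history: dict[int, dict[str, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (time-series tensor, static vector) pair for one sample.

    The tensor is [8 x target_len]: filtered, polyphase-resampled to
    ``target_rate_hz``, centre-cropped/zero-padded, and per-channel
    z-scored unless normalization is "none".  When ``pmsi_history`` is
    omitted, only the recording's own week is available for the PMSI
    slots of the static vector.
    """
    tensor_spec.validate(recording.sample_rate_hz)
    filt = bandpass_filter(recording.signals, recording.sample_rate_hz, filter_spec)
    ts = _resample(filt.astype(np.float64), recording.sample_rate_hz, tensor_spec.target_rate_hz)
    ts = _fit_length(ts, tensor_spec.target_len)
    if tensor_spec.normalization == "per_channel_zscore":
        mu = ts.mean(axis=-1, keepdims=True)
        sd = ts.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        ts = (ts - mu) / sd
    if pmsi_history is None:
        fs = extract_features(recording, static, filter_spec)
        pmsi_history = {recording.week: fs.pmsi_per_pair}
    sv = static_vector(static, recording.week, pmsi_history)
    return ts.astype(np.float32), sv.astype(np.float32)
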