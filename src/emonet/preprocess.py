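"""Continuous EEG conditioning and epoching.

The conditioning chain is fixed: band-pass filter, common-average
re-reference, anti-aliased downsampling, and segmentation of the last
``tail_s`` seconds of each song into non-overlapping 1-s epochs. Filtering
uses zero-phase windowed-sinc FIR kernels (Hamming window) so that epoch
timing is preserved; downsampling is polyphase with an exact integer ratio
whenever the rates allow it.

Artifact removal (ICA-based in sensor-space EEG practice) is exposed as a
pluggable hook that defaults to pass-through: the synthetic generator plants
no ocular or muscle artifacts, and real-data users can supply their own
cleaner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .errors import (
    InsufficientDataError,
    InvalidBandError,
    InvalidMontageError,
    ShapeError,
)

#: The 59-electrode 10-20 montage used by the study's wireless EEG system
#: (CPz reference, AFz ground; neither is a data channel).
DEFAULT_MONTAGE_59: tuple[str, ...] = (
    "Fp1", "Fp2", "FPz",
    "AF3", "AF4", "AF7", "AF8",
    "Fz", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8",
    "FCz", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6",
    "FT7", "FT8",
    "Cz", "C1", "C2", "C3", "C4", "C5", "C6",
    "T7", "T8",
    "TP7", "TP8",
    "CP1", "CP2", "CP3", "CP4", "CP5", "CP6",
    "Pz", "P3", "P4", "P5", "P6", "P7", "P8",
    "POz", "PO3", "PO4", "PO5", "PO6", "PO7", "PO8",
    "Oz", "O1", "O2",
)


@dataclass
class Recording:
    """Continuous multichannel EEG: ``data`` is channels x samples in µV."""

    data: np.ndarray
    rate: float
    channel_names: Sequence[str] | None = None
    reference: str = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError(
                f"recording data must be 2-D (channels x samples), got {self.data.shape}"
            )
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise InvalidMontageError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class EpochLabel:
    """Bookkeeping attached to one epoch: who, which scenario, which song."""

    subject: int
    scenario: str
    emotion: str
    song: int


@dataclass
class EpochSet:
    """Epoch-segmented data: ``data`` is epochs x channels x samples."""

    data: np.ndarray
    rate: float
    labels: list[EpochLabel]
    window_s: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError(
                f"epoch data must be 3-D (epochs x channels x samples), got {self.data.shape}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ShapeError(
                f"{len(self.labels)} labels for {self.data.shape[0]} epochs"
            )
        expected = int(round(self.window_s * self.rate))
        if self.data.shape[2] != expected:
            raise ShapeError(
                f"epoch length {self.data.shape[2]} != round(window_s*rate) = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def y(self) -> np.ndarray:
        return np.array([lab.emotion for lab in self.labels])

    @classmethod
    def concat(cls, epoch_sets: Sequence["EpochSet"]) -> "EpochSet":
        if not epoch_sets:
            raise ValueError("cannot concatenate an empty list of EpochSets")
        rates = {es.rate for es in epoch_sets}
        if len(rates) != 1:
            raise ShapeError(f"mixed sampling rates {sorted(rates)}")
        data = np.concatenate([es.data for es in epoch_sets], axis=0)
        labels = [lab for es in epoch_sets for lab in es.labels]
        return cls(data, epoch_sets[0].rate, labels, epoch_sets[0].window_s)


def design_bandpass_fir(low_hz: float, high_hz: float, rate: float,
                        max_taps: int | None = None) -> np.ndarray:
    """Linear-phase band-pass kernel (windowed sinc, Hamming window).

    The transition bandwidth is ``min(low_hz, 0.25*low_hz + 2)`` Hz, which
    keeps the kernel short enough for 1-Hz edges while tightening for wider
    bands; Hamming needs ~3.3 cycles of the transition width.
    """
    if not (0 < low_hz < high_hz < rate / 2):
        raise InvalidBandError(
            f"band ({low_hz}, {high_hz}) Hz invalid for rate {rate} Hz "
            f"(need 0 < low < high < Nyquist = {rate / 2} Hz)"
        )
    trans_bw = min(low_hz, 0.25 * low_hz + 2.0)
    numtaps = int(np.ceil(3.3 * rate / trans_bw)) | 1  # force odd
    if max_taps is not None:
        numtaps = min(numtaps, max_taps | 1)
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                         window="hamming", fs=rate)


def _filter_zero_phase(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR kernel with zero phase via reflect padding.

    A linear-phase kernel applied once in 'same' mode is already zero-phase;
    reflect padding by one kernel length suppresses edge transients.
    """
    pad = min(len(kernel), data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    shape = (1,) * (data.ndim - 1) + (len(kernel),)
    out = signal.fftconvolve(padded, kernel.reshape(shape), mode="same", axes=-1)
    return out[..., pad:pad + data.shape[-1]]


def bandpass(rec: Recording, low_hz: float = 1.0, high_hz: float = 45.0) -> Recording:
    """Zero-phase FIR band-pass; length-preserving."""
    kernel = design_bandpass_fir(low_hz, high_hz, rec.rate)
    out = _filter_zero_phase(rec.data, kernel)
    meta = dict(rec.meta)
    meta.setdefault("steps", []).append(f"bandpass({low_hz},{high_hz})")
    return replace(rec, data=out, meta=meta)


def rereference_average(rec: Recording) -> Recording:
    """Common-average reference: subtract the instantaneous cross-channel mean."""
    if rec.n_channels < 2:
        raise InvalidMontageError(
            "average reference requires at least 2 channels, got "
            f"{rec.n_channels}"
        )
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    meta = dict(rec.meta)
    meta.setdefault("steps", []).append("rereference_average")
    return replace(rec, data=out, reference="average", meta=meta)


def resample(rec: Recording, target_hz: float) -> Recording:
    """Polyphase anti-aliased downsampling to ``target_hz``."""
    if target_hz > rec.rate:
        raise InvalidBandError(
            f"upsampling not supported: target {target_hz} Hz > rate {rec.rate} Hz"
        )
    if target_hz == rec.rate:
        return rec
    frac = Fraction(target_hz / rec.rate).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    n_expected = int(round(rec.n_samples * target_hz / rec.rate))
    out = out[..., :n_expected]
    if out.shape[-1] < n_expected:  # resample_poly may round down by one
        out = np.pad(out, [(0, 0), (0, n_expected - out.shape[-1])], mode="edge")
    meta = dict(rec.meta)
    meta.setdefault("steps", []).append(f"resample({target_hz})")
    return replace(rec, data=out, rate=float(target_hz), meta=meta)


def clean_artifacts(rec: Recording,
                    hook: Callable[[Recording], Recording] | None = None) -> Recording:
    """Artifact-removal slot; defaults to pass-through (see module docstring)."""
    return rec if hook is None else hook(rec)


def epoch_tail(rec: Recording, label: EpochLabel, tail_s: float = 150.0,
               window_s: float = 1.0) -> EpochSet:
    """Segment the last ``tail_s`` seconds into contiguous ``window_s`` epochs.

    Epochs are non-overlapping and end exactly at the recording's last
    sample; every epoch carries the song's label. A recording shorter than
    ``tail_s`` is an error, never a silent truncation.
    """
    if tail_s <= 0 or window_s <= 0:
        raise ValueError("tail_s and window_s must be positive")
    n_windows = tail_s / window_s
    if abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError(f"tail_s={tail_s} not divisible by window_s={window_s}")
    n_windows = int(round(n_windows))
    n_per = int(round(window_s * rec.rate))
    n_tail = n_windows * n_per
    if rec.n_samples < n_tail:
        raise InsufficientDataError(
            f"recording has {rec.n_samples / rec.rate:.1f} s but tail_s={tail_s} "
            f"requires {n_tail / rec.rate:.1f} s"
        )
    tail = rec.data[:, rec.n_samples - n_tail:]
    data = tail.reshape(rec.n_channels, n_windows, n_per).transpose(1, 0, 2)
    return EpochSet(data.copy(), rec.rate, [label] * n_windows, window_s,
                    meta={"steps": list(rec.meta.get("steps", []))})


def validate_channels(names: Sequence[str],
                      montage: Sequence[str] = DEFAULT_MONTAGE_59) -> None:
    """Raise if any channel name is outside the configured montage."""
    unknown = [n for n in names if n not in set(montage)]
    if unknown:
        raise InvalidMontageError(f"channels not in montage: {unknown}")


def preprocess_recording(rec: Recording, label: EpochLabel, *,
                         low_hz: float = 1.0, high_hz: float = 45.0,
                         target_hz: float = 250.0, tail_s: float = 150.0,
                         window_s: float = 1.0,
                         artifact_hook: Callable[[Recording], Recording] | None = None,
                         ) -> EpochSet:
    """Full conditioning chain in the fixed order: filter, re-reference,
    artifact hook, resample, epoch."""
    rec = bandpass(rec, low_hz, high_hz)
    rec = rereference_average(rec)
    rec = clean_artifacts(rec, artifact_hook)
    rec = resample(rec, target_hz)
    return epoch_tail(rec, label, tail_s, window_s)
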