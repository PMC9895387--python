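"""Deterministic signal conditioning: band-pass, notch, reference, epoching.

All filters are zero-phase (forward-backward application), so stage order
does not introduce phase distortion and filtering commutes with the average
reference.  Artifact handling is a simple amplitude threshold on epochs:
synthetic recordings carry no ocular/muscular artifacts, and a threshold is
a reproducible stand-in for manual component selection.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EEGRecording, EpochSet


def _fir_bandpass_taps(low_hz: float, high_hz: float, fs_hz: float) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass taps.

    Transition bandwidth is 25% of the lower edge, floored at 0.5 Hz; the
    Hamming window needs ~3.3/N of normalized width for that transition.
    """
    trans = max(0.25 * low_hz, 0.5)
    numtaps = int(np.ceil(3.3 * fs_hz / trans))
    numtaps += (numtaps + 1) % 2  # odd length -> symmetric, linear phase
    return signal.firwin(
        numtaps, [low_hz, high_hz], pass_zero=False, fs=fs_hz, window="hamming"
    )


def bandpass_filter(rec: EEGRecording, low_hz: float, high_hz: float) -> EEGRecording:
    """Zero-phase FIR band-pass between ``low_hz`` and ``high_hz``.

    The symmetric (linear-phase) kernel is applied once by FFT convolution
    with the group delay compensated, which is phase-free for odd-length
    symmetric taps; edges are odd-extended to suppress transients.
    """
    if not (0 < low_hz < high_hz < rec.fs_hz / 2):
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for fs={rec.fs_hz} Hz: "
            "need 0 < low < high < fs/2"
        )
    taps = _fir_bandpass_taps(low_hz, high_hz, rec.fs_hz)
    half = len(taps) // 2
    x = rec.data
    pad = min(half, x.shape[1] - 1)
    left = 2 * x[:, :1] - x[:, pad:0:-1]
    right = 2 * x[:, -1:] - x[:, -2 : -pad - 2 : -1]
    ext = np.concatenate([left, x, right], axis=1)
    out = signal.fftconvolve(ext, taps[None, :], mode="same", axes=1)
    out = out[:, pad : pad + x.shape[1]]
    return rec.with_data(out)


def notch_filter(rec: EEGRecording, freq_hz: float = 50.0, q: float = 35.0) -> EEGRecording:
    """Zero-phase IIR notch at ``freq_hz`` (mains suppression)."""
    if not (0 < freq_hz < rec.fs_hz / 2):
        raise ValueError(f"invalid notch frequency {freq_hz} Hz for fs={rec.fs_hz} Hz")
    b, a = signal.iirnotch(freq_hz, q, fs=rec.fs_hz)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return rec.with_data(out)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-montage to the common average reference (idempotent)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(out, reference="average")


def epoch_fixed_length(rec: EEGRecording, length_s: float = 2.0) -> EpochSet:
    """Cut consecutive non-overlapping epochs; the trailing remainder is
    discarded."""
    n_per = int(round(rec.fs_hz * length_s))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s shorter than one {length_s} s epoch"
        )
    trimmed = rec.data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(epochs=epochs.copy(), fs_hz=rec.fs_hz, epoch_length_s=length_s)


def reject_artifacts_amplitude(ep: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Mark epochs containing any |sample| above ``threshold_uv`` as rejected.

    The boundary is inclusive: samples exactly at the threshold are kept.
    Data is never modified, only ``kept_mask``.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(ep.epochs).max(axis=(1, 2))
    mask = ep.kept_mask & (peak <= threshold_uv)
    return EpochSet(
        epochs=ep.epochs, fs_hz=ep.fs_hz, epoch_length_s=ep.epoch_length_s, kept_mask=mask
    )


def crop(rec: EEGRecording, start_s: float = 0.0, stop_s: float | None = None) -> EEGRecording:
    """Select a time window (e.g. the first 3 min of a resting run)."""
    i0 = int(round(start_s * rec.fs_hz))
    i1 = rec.n_samples if stop_s is None else min(rec.n_samples, int(round(stop_s * rec.fs_hz)))
    if i1 <= i0:
        raise ValueError("empty crop window")
    return rec.with_data(rec.data[:, i0:i1].copy())
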