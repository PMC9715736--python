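"""Reference, resampling and normalization — the in-scope preprocessing.

Microstate analysis assumes common-average-referenced data (the GFP and
all spatial correlations are computed on zero-mean topographies), so
:func:`common_average_reference` is the mandatory first step.  Recordings
acquired at a higher rate are decimated with an anti-alias FIR low-pass,
and :func:`normalize_global` rescales a whole record by its mean GFP so
amplitudes are comparable across subjects while within-record GFP
structure (and hence the mean-GFP feature) is preserved.

Artifact removal (ICA, bad-channel repair) belongs to external tooling and
is deliberately not implemented here; an optional band-pass is provided as
plumbing for real recordings.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EEGRecording
from .segmentation import compute_gfp


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across electrodes from every sample.

    Idempotent; requires at least two channels.
    """
    if rec.n_channels < 2:
        raise ValueError("common average reference is undefined for < 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def decimate(rec: EEGRecording, factor: int) -> EEGRecording:
    """Reduce the sampling rate by an integer ``factor``.

    Applies a zero-phase FIR anti-alias low-pass before down-selection
    (``scipy.signal.decimate`` with ``ftype="fir"``).  ``factor == 1``
    returns an unmodified copy.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"decimation factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return rec.copy_with(data=rec.data.copy())
    data = signal.decimate(rec.data, factor, axis=1, ftype="fir", zero_phase=True)
    return rec.copy_with(data=data, fs=rec.fs / factor)


def normalize_global(rec: EEGRecording) -> EEGRecording:
    """Divide the whole record by its mean GFP (output mean GFP = 1).

    A single global divisor keeps relative GFP across time intact, so the
    per-class mean-GFP feature remains meaningful; idempotent and invariant
    to positive rescaling of the input.
    """
    mean_gfp = float(np.mean(compute_gfp(rec).values))
    if mean_gfp <= 0:
        raise ValueError("cannot normalize an all-zero (or single-valued) record")
    return rec.copy_with(data=rec.data / mean_gfp)


def bandpass(rec: EEGRecording, low_hz: float = 1.0, high_hz: float = 45.0,
             numtaps: int | None = None) -> EEGRecording:
    """Optional zero-phase FIR band-pass (default 1-45 Hz)."""
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError("require 0 < low < high < Nyquist")
    if numtaps is None:
        numtaps = int(3 * rec.fs / low_hz) | 1   # ~3 cycles of the low edge, odd
    taps = signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=rec.fs)
    data = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    return rec.copy_with(data=data)
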