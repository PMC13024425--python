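"""Signal conditioning for continuous EEG recordings.

The chain mirrors standard resting-state EEG practice: zero-phase FIR
band-pass (0.5–70 Hz), 50 Hz FIR notch, full-scalp average reference,
polyphase resampling to 150 Hz, channel-count standardization to 128, and
amplitude-based epoch rejection at ±100 µV.  Filtering happens at the native
sampling rate so the 70 Hz upper edge stays below the pre-resample Nyquist;
70 Hz also remains valid after resampling to 150 Hz (Nyquist 75 Hz).

ICA-based artifact removal is deliberately not part of the chain (it is a
manual, visual-inspection-driven step); :func:`run_pipeline` accepts an
optional ``cleaning_hook`` so an external cleaning function can be plugged
in at that point of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import TYPE_CHECKING, Callable

import numpy as np
from mne.filter import filter_data, notch_filter
from scipy.signal import resample_poly

from .synth import RawRecording

if TYPE_CHECKING:  # pragma: no cover
    from .tensorize import EpochSet

__all__ = [
    "FilterSpec",
    "bandpass_fir",
    "notch",
    "average_reference",
    "resample",
    "standardize_channels",
    "reject_epochs_by_amplitude",
    "run_pipeline",
]


@dataclass(frozen=True)
class FilterSpec:
    l_freq: float
    h_freq: float
    kind: str = "bandpass"  # or "notch"
    notch_freq: float = 50.0


def bandpass_fir(rec: RawRecording, l_freq: float, h_freq: float) -> RawRecording:
    """Zero-phase windowed-sinc FIR band-pass, per channel.

    Transition bandwidths follow the usual EEG heuristic
    ``min(max(0.25 * edge, 2 Hz), edge)``.
    """
    nyq = rec.sfreq / 2.0
    if not (0 < l_freq < h_freq):
        raise ValueError(f"need 0 < l_freq < h_freq, got {l_freq}, {h_freq}")
    if h_freq >= nyq:
        raise ValueError(f"h_freq {h_freq} Hz must lie below Nyquist ({nyq} Hz)")
    out = filter_data(
        rec.data.astype(np.float64), rec.sfreq, l_freq, h_freq,
        method="fir", fir_design="firwin", phase="zero", verbose="error",
    )
    return rec.replace_data(out)


def notch(rec: RawRecording, freq: float = 50.0) -> RawRecording:
    """Narrow FIR band-stop (width 1 Hz) around ``freq`` to remove line noise."""
    if freq >= rec.sfreq / 2.0:
        raise ValueError(f"notch frequency {freq} Hz must lie below Nyquist")
    out = notch_filter(
        rec.data.astype(np.float64), rec.sfreq, freqs=freq,
        method="fir", fir_design="firwin", notch_widths=1.0,
        trans_bandwidth=1.0, phase="zero", verbose="error",
    )
    return rec.replace_data(out)


def average_reference(rec: RawRecording) -> RawRecording:
    """Re-reference so the cross-channel mean is zero at every sample."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.replace_data(out)


def resample(rec: RawRecording, target_sfreq: float = 150.0) -> RawRecording:
    """Polyphase rational resampling (e.g. 250 -> 150 Hz is ratio 3/5).

    Upsampling is rejected: the pipeline only ever standardizes downwards.
    """
    if target_sfreq > rec.sfreq:
        raise ValueError(
            f"upsampling not supported ({rec.sfreq} -> {target_sfreq} Hz)")
    if target_sfreq == rec.sfreq:
        return rec
    frac = Fraction(target_sfreq / rec.sfreq).limit_denominator(1000)
    out = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.replace_data(out, sfreq=target_sfreq)


def standardize_channels(rec: RawRecording, c_target: int = 128) -> RawRecording:
    """Truncate to the first ``c_target`` channels or zero-pad up to it."""
    c = rec.n_channels
    if c == c_target:
        return rec
    if c > c_target:
        return rec.replace_data(
            rec.data[:c_target], channel_names=rec.channel_names[:c_target])
    pad = np.zeros((c_target - c, rec.n_samples))
    names = rec.channel_names + [f"PAD{i + 1}" for i in range(c_target - c)]
    return rec.replace_data(np.vstack([rec.data, pad]), channel_names=names)


def reject_epochs_by_amplitude(epochs: "EpochSet", threshold_uv: float = 100.0) -> np.ndarray:
    """Keep-mask over epochs: False iff any sample exceeds ±threshold (µV).

    Must run on physical-unit epochs, before normalization; normalized input
    is rejected because the threshold is meaningless on z-scored data.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if getattr(epochs, "units", "uV") != "uV":
        raise ValueError(
            "ordering violation: amplitude rejection must run on µV epochs "
            "before normalization, got units="
            f"{epochs.units!r}")
    data = epochs.data
    return ~np.any(np.abs(data) > threshold_uv, axis=(1, 2))


def run_pipeline(
    rec: RawRecording,
    l_freq: float = 0.5,
    h_freq: float = 70.0,
    notch_freq: float | None = 50.0,
    target_sfreq: float = 150.0,
    c_target: int = 128,
    cleaning_hook: Callable[[RawRecording], RawRecording] | None = None,
) -> RawRecording:
    """Full conditioning chain on one continuous recording.

    Order: band-pass -> notch -> (optional external cleaning hook, the slot
    where ICA-style artifact removal would sit) -> average reference ->
    resample -> channel standardization.  Epoching and amplitude-based epoch
    rejection happen downstream (see :mod:`eegroute.tensorize`).
    """
    out = bandpass_fir(rec, l_freq, h_freq)
    if notch_freq is not None:
        out = notch(out, notch_freq)
    if cleaning_hook is not None:
        out = cleaning_hook(out)
    out = average_reference(out)
    out = resample(out, target_sfreq)
    out = standardize_channels(out, c_target)
    return out
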