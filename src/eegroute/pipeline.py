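"""Cohort-level orchestration: recordings -> model-ready epoch tensors.

Chain per recording (at the native sampling rate first, so the 70 Hz upper
band edge stays below Nyquist): band-pass -> notch -> average reference ->
resample to 150 Hz -> standardize to 128 channels -> 2-s epochs.

Amplitude-based epoch rejection (±100 µV) is always decided on the
full-band (0.5–70 Hz) version of the recording and the resulting keep-mask
is applied to every band representation, which keeps per-band epoch sets
aligned for the ``allbands`` concatenation.
"""

from __future__ import annotations

import numpy as np

from .bands import BAND_ORDER, CANONICAL_BANDS, FULLBAND_HI, FULLBAND_LO
from .preprocess import (average_reference, bandpass_fir, notch,
                         reject_epochs_by_amplitude, resample,
                         standardize_channels)
from .synth import RawRecording
from .tensorize import EpochSet, build_input, concat_epoch_sets, epoch

__all__ = ["prepare_recording", "prepare_cohort"]


def _condition(rec: RawRecording, l_freq: float, h_freq: float,
               notch_freq: float | None, target_sfreq: float,
               c_target: int) -> RawRecording:
    out = bandpass_fir(rec, l_freq, h_freq)
    if notch_freq is not None:
        out = notch(out, notch_freq)
    out = average_reference(out)
    out = resample(out, target_sfreq)
    return standardize_channels(out, c_target)


def prepare_recording(rec: RawRecording, mode: str = "fullband",
                      window_s: float = 2.0, reject_uv: float | None = 100.0,
                      notch_freq: float | None = 50.0,
                      target_sfreq: float = 150.0,
                      c_target: int = 128) -> EpochSet:
    """Condition, epoch and (optionally) reject one recording for a band mode."""
    full = _condition(rec, FULLBAND_LO, FULLBAND_HI, notch_freq,
                      target_sfreq, c_target)
    full_epochs = epoch(full, window_s)
    keep = (reject_epochs_by_amplitude(full_epochs, reject_uv)
            if reject_uv is not None
            else np.ones(full_epochs.n_epochs, dtype=bool))
    if mode == "fullband":
        return full_epochs.select(keep)
    band_names = BAND_ORDER if mode == "allbands" else (mode,)
    per_band = {}
    for name in band_names:
        b = CANONICAL_BANDS[name]
        proc = _condition(rec, b.lo, b.hi, notch_freq, target_sfreq, c_target)
        es = epoch(proc, window_s).select(keep)
        per_band[name] = EpochSet(data=es.data, subject_ids=es.subject_ids,
                                  labels=es.labels, sfreq=es.sfreq,
                                  band_mode=name, units=es.units)
    return build_input(per_band, mode)


def prepare_cohort(recs: list[RawRecording], mode: str = "fullband",
                   window_s: float = 2.0, reject_uv: float | None = 100.0,
                   notch_freq: float | None = 50.0,
                   target_sfreq: float = 150.0,
                   c_target: int = 128) -> EpochSet:
    """Prepare every recording and stack the epochs into one EpochSet."""
    return concat_epoch_sets([
        prepare_recording(r, mode=mode, window_s=window_s, reject_uv=reject_uv,
                          notch_freq=notch_freq, target_sfreq=target_sfreq,
                          c_target=c_target)
        for r in recs
    ])
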