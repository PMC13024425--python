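"""Epoch tensors and leak-free fold-wise normalization.

Continuous recordings are cut into non-overlapping 2-s windows (the
classification unit), optionally decomposed into the five canonical bands,
and assembled into the model-facing tensor: ``(N, 1, C, T)`` with C = 128
for ``fullband`` or a single band, and C = 5*128 = 640 for ``allbands``
(channel-wise concatenation in the fixed order delta, theta, alpha, beta,
gamma).

Z-score normalization is per-(channel, time) location across the epoch
dimension, with statistics estimated from training-fold epochs only and a
sigma floor of 1e-6; the same (mu, sigma) are then applied to validation
and test epochs of that fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .bands import BAND_ORDER, CANONICAL_BANDS, FULLBAND_HI, FULLBAND_LO, BandSpec
from .preprocess import bandpass_fir
from .synth import RawRecording

__all__ = [
    "EpochSet",
    "NormStats",
    "SIGMA_FLOOR",
    "epoch",
    "epoch_cohort",
    "band_decompose",
    "build_input",
    "fit_normalizer",
    "apply_normalizer",
]

SIGMA_FLOOR = 1e-6
BAND_MODES = ("fullband",) + BAND_ORDER + ("allbands",)


@dataclass(frozen=True)
class EpochSet:
    """Stacked fixed-length epochs with per-epoch subject ids and labels."""

    data: np.ndarray  # (N, C, T)
    subject_ids: np.ndarray  # (N,) str
    labels: np.ndarray  # (N,) in {0, 1}
    sfreq: float
    band_mode: str = "fullband"
    units: str = "uV"  # or "normalized"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (N, C, T)")
        n = self.data.shape[0]
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids/labels must have length N")
        if self.band_mode not in BAND_MODES:
            raise ValueError(f"unknown band_mode {self.band_mode!r}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def as_model_input(self) -> np.ndarray:
        """The 4-D (N, 1, C, T) view consumed by the network."""
        n, c, t = self.data.shape
        return self.data.reshape(n, 1, c, t)

    def select(self, mask: np.ndarray) -> "EpochSet":
        return replace(self, data=self.data[mask],
                       subject_ids=self.subject_ids[mask],
                       labels=self.labels[mask])


@dataclass(frozen=True)
class NormStats:
    """Per-(channel, time) mean/std from one training fold, sigma-floored."""

    mu: np.ndarray  # (C, T)
    sigma: np.ndarray  # (C, T), >= sigma_floor
    sigma_floor: float = SIGMA_FLOOR
    fold_id: int = -1


def epoch(rec: RawRecording, window_s: float = 2.0) -> EpochSet:
    """Cut a recording into non-overlapping windows; the tail is discarded.

    Epoch i covers samples ``[i*wT, (i+1)*wT)`` (0-based, half-open), so the
    epochs tile the first ``N*wT`` samples exactly.
    """
    w = int(round(window_s * rec.sfreq))
    n = rec.n_samples // w
    if n == 0:
        warnings.warn(
            f"recording {rec.subject_id} shorter than one {window_s}-s window;"
            " returning empty EpochSet", stacklevel=2)
    data = rec.data[:, : n * w].reshape(rec.n_channels, n, w).transpose(1, 0, 2)
    return EpochSet(
        data=np.ascontiguousarray(data),
        subject_ids=np.array([rec.subject_id] * n),
        labels=np.array([rec.label] * n, dtype=int),
        sfreq=rec.sfreq,
    )


def concat_epoch_sets(sets: list[EpochSet]) -> EpochSet:
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    first = sets[0]
    if any(s.sfreq != first.sfreq or s.band_mode != first.band_mode
           or s.units != first.units for s in sets):
        raise ValueError("epoch sets disagree on sfreq/band_mode/units")
    return EpochSet(
        data=np.concatenate([s.data for s in sets]),
        subject_ids=np.concatenate([s.subject_ids for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        sfreq=first.sfreq, band_mode=first.band_mode, units=first.units)


def epoch_cohort(recs: list[RawRecording], window_s: float = 2.0) -> EpochSet:
    """Epoch every recording and stack into one EpochSet."""
    return concat_epoch_sets([epoch(r, window_s) for r in recs])


def band_decompose(rec: RawRecording,
                   bands: list[BandSpec] | None = None) -> dict[str, RawRecording]:
    """Band-pass the continuous recording into each canonical band.

    Decomposition happens before epoching to avoid per-epoch filter edge
    artifacts.
    """
    if bands is None:
        bands = [CANONICAL_BANDS[b] for b in BAND_ORDER]
    nyq = rec.sfreq / 2.0
    for b in bands:
        if b.hi >= nyq:
            raise ValueError(
                f"band {b.name} upper edge {b.hi} Hz is not below Nyquist {nyq} Hz")
    return {b.name: bandpass_fir(rec, b.lo, b.hi) for b in bands}


def build_input(per_band: dict[str, EpochSet], mode: str) -> EpochSet:
    """Assemble the model input for a band mode.

    ``allbands`` concatenates the five band EpochSets along the channel axis
    in the fixed order delta, theta, alpha, beta, gamma (rows 0..C-1 are the
    delta block, and so on); single-band / fullband modes select the matching
    EpochSet unchanged.
    """
    if mode not in BAND_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "allbands":
        if mode not in per_band:
            raise ValueError(f"mode {mode!r} not present in per_band mapping")
        return replace(per_band[mode], band_mode=mode)
    missing = [b for b in BAND_ORDER if b not in per_band]
    if missing:
        raise ValueError(f"allbands requires all five bands; missing {missing}")
    sets = [per_band[b] for b in BAND_ORDER]
    ref = sets[0]
    for s in sets[1:]:
        if s.n_epochs != ref.n_epochs or not np.array_equal(s.subject_ids, ref.subject_ids) \
                or not np.array_equal(s.labels, ref.labels):
            raise ValueError("per-band epoch sets are misaligned")
    data = np.concatenate([s.data for s in sets], axis=1)
    return EpochSet(data=data, subject_ids=ref.subject_ids.copy(),
                    labels=ref.labels.copy(), sfreq=ref.sfreq,
                    band_mode="allbands", units=ref.units)


def fit_normalizer(train: EpochSet, fold_id: int = -1) -> NormStats:
    """Estimate per-(c,t) mean/std over training-fold epochs.

    Population convention (divide by N); sigma clamped at 1e-6 so constant
    locations do not blow up the subsequent division.
    """
    if train.units != "uV":
        raise ValueError("normalizer must be fitted on physical-unit epochs")
    if train.n_epochs < 2:
        raise ValueError("need at least 2 epochs to fit normalization stats")
    mu = train.data.mean(axis=0)
    sigma = train.data.std(axis=0)  # population (ddof=0)
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    return NormStats(mu=mu, sigma=sigma, fold_id=fold_id)


def apply_normalizer(epochs: EpochSet, stats: NormStats) -> EpochSet:
    """Z-score epochs with previously fitted stats; units become normalized."""
    if epochs.data.shape[1:] != stats.mu.shape:
        raise ValueError(
            f"shape mismatch: epochs {epochs.data.shape[1:]} vs stats {stats.mu.shape}")
    data = (epochs.data - stats.mu[None]) / stats.sigma[None]
    return replace(epochs, data=data, units="normalized")
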