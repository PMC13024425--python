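"""Synthetic multi-subject resting-state EEG cohorts.

Generates per-subject continuous recordings that emulate high-density
resting EEG: 1/f ("pink") background activity plus one narrowband
oscillation per canonical band per channel.  Class-conditional effects are
expressed as per-band amplitude multipliers applied to the positive (MDD)
class, which makes band-power differences between classes directly
controllable — the positive class's band-b power scales as the square of
``effect[b]``.

The generator is fully deterministic given the cohort seed.  Optional
artifacts (50 Hz line noise, blink-like frontal transients) are injected by
:func:`inject_artifacts` so that notch filtering and amplitude-based epoch
rejection have something to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BAND_ORDER, CANONICAL_BANDS

__all__ = ["CohortSpec", "RawRecording", "generate_cohort", "inject_artifacts"]

# Base oscillation amplitudes (µV, sinusoid-equivalent: band RMS = amp/sqrt(2)),
# one per canonical band.  Chosen so that a clean recording stays within the
# ±100 µV rejection threshold (Gaussian tails included) even when class
# effects double individual band amplitudes, while keeping each band's
# oscillatory power well above the pink-noise floor in that band.
BASE_AMP_UV = {"delta": 11.0, "theta": 3.5, "alpha": 5.5, "beta": 3.0, "gamma": 5.0}

#: RMS of the pink-noise background (µV).
NOISE_RMS_UV = 3.5

#: Relative jitter of per-channel oscillation amplitudes around the base value.
AMP_JITTER = 0.1

#: Blink artifact template parameters (raised cosine).
BLINK_DUR_S = 0.4
BLINK_PEAK_UV = 150.0
BLINK_N_CHANNELS = 8


@dataclass(frozen=True)
class RawRecording:
    """One subject's continuous multi-channel EEG in µV."""

    subject_id: str
    label: int  # 0 = HC, 1 = MDD
    data: np.ndarray  # (channels, samples), µV
    sfreq: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def replace_data(self, data: np.ndarray, sfreq: float | None = None,
                     channel_names: list[str] | None = None) -> "RawRecording":
        return RawRecording(
            subject_id=self.subject_id,
            label=self.label,
            data=data,
            sfreq=self.sfreq if sfreq is None else sfreq,
            channel_names=self.channel_names if channel_names is None else channel_names,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect`` maps band name -> amplitude multiplier applied to the positive
    (MDD) class; power in that band scales with the multiplier squared.
    """

    n_subjects_per_class: int = 10
    duration: float = 60.0  # seconds
    sfreq: float = 250.0  # Hz
    n_channels: int = 128
    effect: dict[str, float] = field(default_factory=dict)
    line_noise_amp: float = 0.0  # µV
    blink_rate: float = 0.0  # events/min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_subjects_per_class < 1:
            raise ValueError("need at least one subject per class")
        max_hi = max(b.hi for b in CANONICAL_BANDS.values())
        if self.sfreq < 2 * max_hi:
            raise ValueError(
                f"Nyquist violation: sfreq {self.sfreq} Hz cannot represent the "
                f"{max_hi} Hz upper band edge (need >= {2 * max_hi} Hz)"
            )
        for band, mult in self.effect.items():
            if band not in CANONICAL_BANDS:
                raise ValueError(f"unknown band {band!r} in effect map")
            if mult <= 0:
                raise ValueError(f"effect[{band}] must be > 0, got {mult}")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sfreq: float, rms: float) -> np.ndarray:
    """Per-channel-independent pink noise via 1/f spectral shaping."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    # 1/f amplitude shaping; leave DC at zero, avoid blow-up below 0.5 Hz.
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 0.5))
    spec *= shape
    pink = np.fft.irfft(spec, n=n_samples, axis=1)
    std = pink.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return pink / std * rms


def _subject_signal(rng: np.random.Generator, spec: CohortSpec, positive: bool) -> np.ndarray:
    """Pink background plus one narrowband stochastic oscillation per band.

    Band components are spectrally masked white noise (independent of the
    background), per-channel independent, RMS-normalized to amp/sqrt(2) so a
    component with amplitude A carries the same band power A^2/2 as a
    sinusoid of amplitude A.  Narrowband noise rather than pure tones: real
    EEG rhythms wander within their band, so no subject carries a fixed
    single-frequency fingerprint.
    """
    n_samples = int(round(spec.duration * spec.sfreq))
    data = _pink_noise(rng, spec.n_channels, n_samples, spec.sfreq, NOISE_RMS_UV)
    white = rng.standard_normal((spec.n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / spec.sfreq)
    for band_name in BAND_ORDER:
        band = CANONICAL_BANDS[band_name]
        base = BASE_AMP_UV[band_name]
        mult = spec.effect.get(band_name, 1.0) if positive else 1.0
        # small margin keeps component power strictly inside [lo, hi] so
        # Welch integration over the band captures essentially all of it
        margin = 0.05 * (band.hi - band.lo)
        mask = (freqs >= band.lo + margin) & (freqs <= band.hi - margin)
        comp = np.fft.irfft(spectrum * mask, n=n_samples, axis=1)
        rms = comp.std(axis=1, keepdims=True)
        rms[rms == 0] = 1.0
        amp = base * mult * (1.0 + AMP_JITTER * rng.uniform(-1, 1, size=spec.n_channels))
        # disjoint frequency supports make the five components mutually
        # orthogonal even though they share one white-noise draw
        data += comp / rms * (amp[:, None] / np.sqrt(2.0))
    return data


def generate_cohort(spec: CohortSpec) -> list[RawRecording]:
    """Generate a balanced cohort of ``2 * n_subjects_per_class`` recordings.

    Deterministic: the same spec (including seed) yields bit-identical data.
    Subjects are named ``hc01..`` / ``mdd01..``; labels are 0 (HC) / 1 (MDD).
    """
    rng = np.random.default_rng(spec.seed)
    channel_names = [f"E{i + 1}" for i in range(spec.n_channels)]
    recordings: list[RawRecording] = []
    for label, prefix in ((0, "hc"), (1, "mdd")):
        for k in range(spec.n_subjects_per_class):
            data = _subject_signal(rng, spec, positive=(label == 1))
            rec = RawRecording(
                subject_id=f"{prefix}{k + 1:02d}",
                label=label,
                data=data,
                sfreq=spec.sfreq,
                channel_names=list(channel_names),
            )
            if spec.line_noise_amp > 0 or spec.blink_rate > 0:
                rec = inject_artifacts(
                    rec,
                    blink_rate=spec.blink_rate,
                    line_noise_amp=spec.line_noise_amp,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            recordings.append(rec)
    return recordings


def _blink_template(sfreq: float) -> np.ndarray:
    n = max(int(round(BLINK_DUR_S * sfreq)), 3)
    # raised cosine: 0 at the edges, BLINK_PEAK_UV at the centre
    win = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))
    return BLINK_PEAK_UV * win


def inject_artifacts(rec: RawRecording, blink_rate: float = 0.0,
                     line_noise_amp: float = 0.0, seed: int = 0) -> RawRecording:
    """Add 50 Hz line noise and blink-like frontal transients.

    ``blink_rate`` is in events/min (Poisson process); blinks are raised-cosine
    pulses of 0.4 s, 150 µV peak, applied to the first 8 channels.  With both
    arguments at zero the recording is returned unchanged.
    """
    if blink_rate < 0 or line_noise_amp < 0:
        raise ValueError("blink_rate and line_noise_amp must be >= 0")
    if blink_rate == 0 and line_noise_amp == 0:
        return rec
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    n_samples = data.shape[1]
    t = np.arange(n_samples) / rec.sfreq
    if line_noise_amp > 0:
        data += line_noise_amp * np.sin(2 * np.pi * 50.0 * t)[None, :]
    if blink_rate > 0:
        duration_min = n_samples / rec.sfreq / 60.0
        n_events = rng.poisson(blink_rate * duration_min)
        template = _blink_template(rec.sfreq)
        n_front = min(BLINK_N_CHANNELS, data.shape[0])
        for _ in range(n_events):
            start = int(rng.integers(0, max(n_samples - len(template), 1)))
            stop = min(start + len(template), n_samples)
            data[:n_front, start:stop] += template[: stop - start]
    return rec.replace_data(data)
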