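"""Canonical EEG frequency bands.

The five classical rhythms used throughout the package, in the fixed order
delta, theta, alpha, beta, gamma.  This order also defines the channel-block
layout of the ``allbands`` input representation (5C channels = five stacked
128-channel band-filtered copies of an epoch).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz.

    Invariant: ``0 < lo < hi``.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got {self.lo}, {self.hi}")


#: Fixed, documented band order.  ``allbands`` concatenation follows this order.
BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")

CANONICAL_BANDS = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 70.0),
}

#: Full analysis band (band-pass edges of the default preprocessing).
FULLBAND_LO = 0.5
FULLBAND_HI = 70.0
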