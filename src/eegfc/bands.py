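"""Canonical EEG frequency bands.

The five rhythm bands plus the broadband range used by the pipeline.
Band edges follow the common clinical-EEG convention: delta 0.5-4 Hz,
theta 4-8, alpha 8-12, beta 12-30, low-gamma 30-45; broadband is the
full analysed range 0.5-45 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low ({self.low_hz}) < high ({self.high_hz})"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


DELTA = BandSpec("delta", 0.5, 4.0)
THETA = BandSpec("theta", 4.0, 8.0)
ALPHA = BandSpec("alpha", 8.0, 12.0)
BETA = BandSpec("beta", 12.0, 30.0)
LOW_GAMMA = BandSpec("low_gamma", 30.0, 45.0)
BROADBAND = BandSpec("broadband", 0.5, 45.0)

#: The five rhythm bands, low to high.
RHYTHM_BANDS = (DELTA, THETA, ALPHA, BETA, LOW_GAMMA)

BANDS: dict[str, BandSpec] = {
    b.name: b for b in (*RHYTHM_BANDS, BROADBAND)
}


def get_band(name: str) -> BandSpec:
    try:
        return BANDS[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; known: {sorted(BANDS)}") from None
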