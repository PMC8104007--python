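"""Canonical EEG frequency-band definitions.

The five bands used throughout the package follow the quantitative-EEG
convention for resting-state studies: delta (1-3 Hz), theta (4-7.5 Hz),
alpha1 (8-10 Hz), alpha2 (10.5-13 Hz) and beta (14-30 Hz).  The regional
parieto-occipital regressor uses the merged alpha band (8-13 Hz) unless a
sub-band is requested.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz (inclusive bin selection)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: lo ({self.lo}) must be < hi ({self.hi})")

    def contains(self, freq: float) -> bool:
        return self.lo <= freq <= self.hi


DELTA = BandDefinition("delta", 1.0, 3.0)
THETA = BandDefinition("theta", 4.0, 7.5)
ALPHA1 = BandDefinition("alpha1", 8.0, 10.0)
ALPHA2 = BandDefinition("alpha2", 10.5, 13.0)
BETA = BandDefinition("beta", 14.0, 30.0)

#: merged alpha band for the regional parieto-occipital regressor
ALPHA = BandDefinition("alpha", 8.0, 13.0)

DEFAULT_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA1, ALPHA2, BETA)

BAND_BY_NAME: dict[str, BandDefinition] = {
    b.name: b for b in (*DEFAULT_BANDS, ALPHA)
}


def get_band(name: str) -> BandDefinition:
    """Look up one of the canonical bands by name."""
    try:
        return BAND_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(BAND_BY_NAME)}"
        ) from None
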