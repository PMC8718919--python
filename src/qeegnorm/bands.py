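"""Frequency-band definitions and the 19-channel 10-20 montage.

Band edges follow the conventional QEEG partition: delta 1-4, theta 4-8,
alpha 8-12, beta 12-30 and gamma 30-45 Hz tile the analysis range without
overlap.  ``beta3`` (25-30 Hz, the high-beta sub-band used in anxiety work)
is carried as an additional feature; it is a sub-interval of beta and is
therefore excluded from partition/additivity arithmetic.

Intervals are half-open ``[low, high)`` by convention so the partition bands
cover the analysis range without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )


#: All tabulated bands, including the beta3 sub-band.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
    "beta3": BandDefinition("beta3", 25.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}

#: Names of the non-overlapping bands that tile 1-45 Hz.
PARTITION_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: All band names in canonical order.
BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: 19-channel international 10-20 montage, in conventional order.
MONTAGE_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Coarse scalp region of each montage channel (used for spatial trend offsets).
CHANNEL_REGION: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal", "F7": "frontal", "F3": "frontal",
    "Fz": "frontal", "F4": "frontal", "F8": "frontal",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "C3": "central", "Cz": "central", "C4": "central",
    "P3": "parietal", "Pz": "parietal", "P4": "parietal",
    "O1": "occipital", "O2": "occipital",
}


def check_band(band: str) -> BandDefinition:
    """Return the definition for *band* or raise a configuration error."""
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; known bands: {sorted(BANDS)}") from None


def check_channel(channel: str) -> str:
    """Return *channel* if it belongs to the 10-20 montage, else raise."""
    if channel not in MONTAGE_1020:
        raise ValueError(
            f"unknown channel {channel!r}; expected one of the 10-20 montage labels"
        )
    return channel
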