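"""Frequency band definitions for narrowband connectivity analysis.

Band-averaged connectivity uses 3-s trials for all bands above 3 Hz and
12-s trials for the delta band, so that the delta band contains enough
discrete Fourier bins (1/12 Hz spacing) to be averaged meaningfully.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A narrowband frequency interval with its trial length.

    Parameters
    ----------
    name : str
        Band label (``delta``, ``theta``, ``alpha``, ``low_beta``,
        ``high_beta``, ``low_gamma``).
    f_low, f_high : float
        Band edges in Hz, inclusive on both ends when selecting
        Fourier bins.
    trial_length : float
        Trial duration in seconds used for this band's cross-spectra
        (12 s for delta, 3 s otherwise).
    """

    name: str
    f_low: float
    f_high: float
    trial_length: float

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError(f"band {self.name}: f_low must be < f_high")
        if self.trial_length <= 0:
            raise ValueError("trial_length must be positive")


DEFAULT_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.5, 3.0, 12.0),
    "theta": BandSpec("theta", 4.0, 7.0, 3.0),
    "alpha": BandSpec("alpha", 8.0, 13.0, 3.0),
    "low_beta": BandSpec("low_beta", 13.0, 20.0, 3.0),
    "high_beta": BandSpec("high_beta", 20.0, 30.0, 3.0),
    "low_gamma": BandSpec("low_gamma", 30.0, 50.0, 3.0),
}

BAND_ORDER = tuple(DEFAULT_BANDS)


def get_band(name: str) -> BandSpec:
    try:
        return DEFAULT_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known bands: {', '.join(DEFAULT_BANDS)}"
        ) from None
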