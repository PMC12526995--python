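"""FMCW radar parameterisation.

The radar transmits linear frequency chirps of bandwidth ``B`` starting at
carrier ``fc``; one *frame* (one slow-time sample) is emitted every
``slow_time_interval_s`` seconds.  Range is encoded in the beat frequency of
the de-chirped (IF) signal, displacement in the phase evolution of a range
bin across frames.
"""

from __future__ import annotations

from dataclasses import dataclass

SPEED_OF_LIGHT = 2.99792458e8  # m/s


@dataclass(frozen=True)
class RadarConfig:
    """Parameters of a sawtooth FMCW radar.

    Defaults follow a 77 GHz automotive-band sensor with 3.99 GHz sweep
    bandwidth, three chirps per 0.5 ms frame and 128 fast-time samples per
    chirp.  The chirp duration is not a quantity any slow-time result depends
    on; 50 us keeps the frequency slope within hardware norms.
    """

    carrier_frequency_hz: float = 77.0e9
    bandwidth_hz: float = 3.99e9
    chirp_duration_s: float = 50e-6
    slow_time_interval_s: float = 0.5e-3
    samples_per_chirp: int = 128
    chirps_per_frame: int = 3
    n_frames: int = 50_000
    tx_amplitude: float = 1.0
    rx_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.carrier_frequency_hz <= 0:
            raise ValueError("carrier frequency must be positive")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth must be positive")
        if self.chirp_duration_s <= 0:
            raise ValueError("chirp duration must be positive")
        if self.slow_time_interval_s <= 0:
            raise ValueError("frame period must be positive")
        if self.samples_per_chirp < 2:
            raise ValueError("need at least 2 fast-time samples")

    @property
    def wavelength_m(self) -> float:
        """Carrier wavelength lambda = c / fc (~3.893 mm at 77 GHz)."""
        return SPEED_OF_LIGHT / self.carrier_frequency_hz

    @property
    def center_wavelength_m(self) -> float:
        """Wavelength at the chirp centre frequency fc + B/2.

        The phase of a range-compressed peak advances at the sweep's centre
        frequency, so displacement recovered from chirp-level data scales
        with this wavelength rather than the carrier's.
        """
        return SPEED_OF_LIGHT / (self.carrier_frequency_hz + self.bandwidth_hz / 2)

    @property
    def prf_hz(self) -> float:
        """Slow-time sampling rate (frame repetition frequency)."""
        return 1.0 / self.slow_time_interval_s

    @property
    def frequency_slope_hz_s(self) -> float:
        """Chirp slope Sw = B / T."""
        return self.bandwidth_hz / self.chirp_duration_s

    @property
    def range_resolution_m(self) -> float:
        """Range-bin width c / (2B)."""
        return SPEED_OF_LIGHT / (2 * self.bandwidth_hz)

    @property
    def fast_time_sample_rate_hz(self) -> float:
        return self.samples_per_chirp / self.chirp_duration_s

    @property
    def max_unambiguous_range_m(self) -> float:
        """Largest standoff whose IF beat stays below fast-time Nyquist."""
        # fb = Sw * 2R/c <= fs/2  =>  R <= c * N / (4 B)
        return SPEED_OF_LIGHT * self.samples_per_chirp / (4 * self.bandwidth_hz)
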