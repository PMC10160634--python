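"""Pulsed measurement schedule.

One measuring round is a short actinic pulse followed by darkness; the pulse
both initiates greening of the etiolated seedling and excites the chlorophyll
fluorescence that the camera integrates. The schedule therefore defines both
the light dose delivered to the sample and the timestamps of the acquired
frames. Defaults: 50 ms pulses of 470 nm blue light at 240 µmol photons
m⁻² s⁻¹, one round every 2 min, for 4 h — 120 rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chlorokin.errors import InvalidProtocolError


@dataclass(frozen=True)
class MeasurementProtocol:
    """Schedule of pulse-plus-dark measuring rounds.

    Attributes
    ----------
    round_duration_s
        Length of one round (pulse + darkness), seconds.
    pulse_duration_ms
        Actinic/excitation pulse length, milliseconds. The camera integration
        is synchronized with the pulse.
    total_duration_min
        Total protocol length, minutes.
    actinic_wavelength_nm
        Peak wavelength of the actinic LEDs.
    actinic_intensity
        Photon flux density at the sample, µmol photons m⁻² s⁻¹.
    detection_band_nm
        Closed wavelength interval passed by the detection filter set.
    """

    round_duration_s: float = 120.0
    pulse_duration_ms: float = 50.0
    total_duration_min: float = 240.0
    actinic_wavelength_nm: float = 470.0
    actinic_intensity: float = 240.0
    detection_band_nm: tuple[float, float] = (680.0, 750.0)

    def __post_init__(self) -> None:
        for name in ("round_duration_s", "pulse_duration_ms", "total_duration_min"):
            if getattr(self, name) <= 0:
                raise InvalidProtocolError(f"{name} must be positive, got {getattr(self, name)}")
        if self.pulse_duration_ms > self.round_duration_s * 1000.0:
            raise InvalidProtocolError(
                f"pulse ({self.pulse_duration_ms} ms) does not fit in a "
                f"round ({self.round_duration_s} s)"
            )
        if self.n_rounds() < 1:
            raise InvalidProtocolError("protocol shorter than one round")

    def n_rounds(self) -> int:
        """Number of complete rounds that fit in the protocol."""
        return int(self.total_duration_min * 60.0 // self.round_duration_s)

    def to_dict(self) -> dict:
        return {
            "round_duration_s": self.round_duration_s,
            "pulse_duration_ms": self.pulse_duration_ms,
            "total_duration_min": self.total_duration_min,
            "actinic_wavelength_nm": self.actinic_wavelength_nm,
            "actinic_intensity": self.actinic_intensity,
            "detection_band_nm": list(self.detection_band_nm),
        }


def build_protocol(
    total_duration_min: float = 240.0,
    round_duration_s: float = 120.0,
    pulse_duration_ms: float = 50.0,
    intensity: float = 240.0,
    wavelength: float = 470.0,
) -> MeasurementProtocol:
    """Validate and build a :class:`MeasurementProtocol`.

    Raises
    ------
    InvalidProtocolError
        If any duration is non-positive or the pulse does not fit in a round.
    """
    return MeasurementProtocol(
        round_duration_s=round_duration_s,
        pulse_duration_ms=pulse_duration_ms,
        total_duration_min=total_duration_min,
        actinic_wavelength_nm=wavelength,
        actinic_intensity=intensity,
    )


def frame_times(protocol: MeasurementProtocol) -> np.ndarray:
    """Timestamps (minutes) of each frame, one per round.

    The timestamp of round ``k`` marks the start of its pulse; the frame
    integrated during that pulse carries that timestamp, so ``t_0 = 0`` is the
    first-ever illumination of the etiolated sample.
    """
    step_min = protocol.round_duration_s / 60.0
    return np.arange(protocol.n_rounds()) * step_min


def light_dose(protocol: MeasurementProtocol, n_rounds_elapsed: int) -> float:
    """Cumulative actinic dose after ``n_rounds_elapsed`` rounds, µmol photons m⁻².

    Each round delivers ``intensity × pulse_duration``; the dose is linear in
    the number of rounds because pulse timing and intensity are identical for
    all rounds.
    """
    if n_rounds_elapsed < 0:
        raise ValueError(f"round count must be non-negative, got {n_rounds_elapsed}")
    if n_rounds_elapsed > protocol.n_rounds():
        raise ValueError(
            f"round count {n_rounds_elapsed} exceeds protocol length {protocol.n_rounds()}"
        )
    return n_rounds_elapsed * protocol.actinic_intensity * protocol.pulse_duration_ms / 1000.0
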