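"""Stimulus parameters of the flicker-conditioning design.

Two grating conditions drive the visual system at the same flicker rate:
a near-equiluminant blue-on-yellow "tritan" grating that biases S-cone
(koniocellular) signals, and a high-contrast achromatic "luminance"
grating. Both flicker at 7.5 Hz for 4 s per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DegenerateDataError

#: Flicker rate of the gratings (Hz); the frequency tagged in the EEG.
DRIVING_FREQUENCY_HZ = 7.5


@dataclass(frozen=True)
class StimulusParams:
    """Photometric and geometric parameters of one grating condition."""

    driving_frequency_hz: float
    adapter_luminance_cd_m2: float
    grating_luminance_cd_m2: float
    visual_angle_deg: float
    spatial_frequency_cpd: float
    flicker_duration_s: float
    condition_name: str

    def __post_init__(self) -> None:
        if self.driving_frequency_hz <= 0:
            raise ConfigurationError("driving frequency must be positive")
        if self.adapter_luminance_cd_m2 < 0 or self.grating_luminance_cd_m2 < 0:
            raise ConfigurationError("luminances must be non-negative")
        if self.grating_luminance_cd_m2 < self.adapter_luminance_cd_m2:
            raise ConfigurationError(
                "grating luminance must be >= adapter luminance"
            )

    @property
    def michelson_contrast(self) -> float:
        return michelson_contrast(
            self.grating_luminance_cd_m2, self.adapter_luminance_cd_m2
        )


#: Bright-yellow adapter with a slightly brighter blue-added grating.
TRITAN = StimulusParams(
    driving_frequency_hz=DRIVING_FREQUENCY_HZ,
    adapter_luminance_cd_m2=55.30,
    grating_luminance_cd_m2=58.86,
    visual_angle_deg=3.10,
    spatial_frequency_cpd=16.0,
    flicker_duration_s=4.0,
    condition_name="tritan",
)

#: Black adapter with a white grating (full luminance contrast).
LUMINANCE = StimulusParams(
    driving_frequency_hz=DRIVING_FREQUENCY_HZ,
    adapter_luminance_cd_m2=0.05,
    grating_luminance_cd_m2=78.95,
    visual_angle_deg=3.10,
    spatial_frequency_cpd=16.0,
    flicker_duration_s=4.0,
    condition_name="luminance",
)

CONDITIONS = ("tritan", "luminance")
STIMULI = ("CS+", "CS-")


def michelson_contrast(l_max: float, l_min: float) -> float:
    """Michelson contrast (L_max - L_min) / (L_max + L_min).

    Parameters are luminances in cd/m². Raises
    :class:`DegenerateDataError` when both luminances are zero and
    :class:`ConfigurationError` for negative or mis-ordered inputs.
    """
    if l_min < 0 or l_max < 0:
        raise ConfigurationError("luminances must be non-negative")
    if l_max < l_min:
        raise ConfigurationError("l_max must be >= l_min")
    if l_max + l_min == 0:
        raise DegenerateDataError("contrast undefined for two zero luminances")
    return (l_max - l_min) / (l_max + l_min)
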