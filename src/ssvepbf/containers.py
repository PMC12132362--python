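"""In-memory containers shared by the generator and the processing stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .montage import SensorMontage

#: Epoch bounds used throughout: 600 ms pre- to 3800 ms post-stimulus.
EPOCH_T_MIN_MS = -600.0
EPOCH_T_MAX_MS = 3800.0
SAMPLING_RATE_HZ = 500.0


def epoch_times_ms(rate_hz: float = SAMPLING_RATE_HZ,
                   t_min_ms: float = EPOCH_T_MIN_MS,
                   t_max_ms: float = EPOCH_T_MAX_MS) -> np.ndarray:
    """Epoch time axis, inclusive of both bounds (2201 samples at 500 Hz)."""
    step = 1000.0 / rate_hz
    n = int(round((t_max_ms - t_min_ms) / step)) + 1
    return t_min_ms + step * np.arange(n)


@dataclass
class RawRecording:
    """Continuous multichannel voltage recording with trial-onset events.

    ``data`` is channels x samples in µV; ``events`` carries one row per
    trial (column ``sample`` = stimulus-onset sample plus the schedule
    columns phase/condition/stimulus/...).
    """

    data: np.ndarray
    rate_hz: float
    montage: SensorMontage
    events: pd.DataFrame
    ocular_ids: tuple[str, ...] = ()
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_sensors:
            raise ConfigurationError("data must be (n_channels, n_samples)")
        if len(self.events):
            s = self.events["sample"].to_numpy()
            if not (np.diff(s) > 0).all():
                raise ConfigurationError("event samples must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawRecording":
        return RawRecording(
            data=self.data.copy(),
            rate_hz=self.rate_hz,
            montage=self.montage,
            events=self.events.copy(),
            ocular_ids=self.ocular_ids,
            provenance=list(self.provenance),
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)


@dataclass
class EpochSet:
    """Epoched voltages: trials x channels x time with per-trial labels."""

    data: np.ndarray  # (n_trials, n_channels, n_times) µV
    times_ms: np.ndarray
    labels: pd.DataFrame
    montage: SensorMontage
    rate_hz: float = SAMPLING_RATE_HZ
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ConfigurationError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[2] != len(self.times_ms):
            raise ConfigurationError("time axis does not match data")
        if self.data.shape[1] != self.montage.n_sensors:
            raise ConfigurationError("channel axis does not match montage")
        if len(self.labels) != self.data.shape[0]:
            raise ConfigurationError("label count must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            labels=self.labels.copy().reset_index(drop=True),
            montage=self.montage,
            rate_hz=self.rate_hz,
            provenance=list(self.provenance),
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def time_indices(self, t_start_ms: float, t_stop_ms: float) -> np.ndarray:
        """Indices of samples within [t_start, t_stop] (inclusive)."""
        return np.flatnonzero(
            (self.times_ms >= t_start_ms - 1e-9) & (self.times_ms <= t_stop_ms + 1e-9)
        )


@dataclass
class PupilRaw:
    """Per-trial pupil-diameter traces (mm) with NaN-marked missing runs."""

    traces: np.ndarray  # (n_trials, n_times) mm, NaN where missing
    times_ms: np.ndarray
    labels: pd.DataFrame
    rate_hz: float = SAMPLING_RATE_HZ
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.traces.ndim != 2 or self.traces.shape[1] != len(self.times_ms):
            raise ConfigurationError("traces must be (n_trials, n_times)")
        if len(self.labels) != self.traces.shape[0]:
            raise ConfigurationError("label count must equal trial count")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.traces) <= 0 if np.isfinite(self.traces).any() else False:
                raise ConfigurationError("pupil diameters must be positive")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.traces)

    def copy(self) -> "PupilRaw":
        return PupilRaw(
            traces=self.traces.copy(),
            times_ms=self.times_ms.copy(),
            labels=self.labels.copy().reset_index(drop=True),
            rate_hz=self.rate_hz,
            provenance=list(self.provenance),
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)
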