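"""Seeded synthetic EEG, pupil and expectancy-rating generators.

The EEG forward model is deliberately simple but matches every
assumption the downstream analysis makes: a 7.5 Hz driven oscillation
whose scalp amplitude is a Gaussian bump centred on Oz, multiplied on
CS+ trials by the ground-truth conditioning gain inside declared
sensor/time windows, superposed on 1/f background noise. Blinks are
large slow frontal deflections shared with the ocular channels through
a fixed front-to-back exponential propagation vector, which makes the
regression-based blink correction exactly identifiable. Channel noise
RMS varies channel-to-channel within a bounded (uniform ±20%) range, as
real impedance differences do; the bound keeps the artifact-control
statistics well behaved on clean data.

Two entry points generate EEG: :func:`simulate_subject_eeg` produces a
continuous recording (with inter-trial intervals, blinks, bad channels
and transients) for exercising the full preprocessing chain, and
:func:`simulate_subject_epochs` produces already-epoched data without
artifact processes — the cheap path used for statistics-scale cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (EpochSet, PupilRaw, RawRecording, SAMPLING_RATE_HZ,
                         epoch_times_ms)
from .errors import ConfigurationError
from .montage import SensorMontage
from .stimuli import CONDITIONS, DRIVING_FREQUENCY_HZ

# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class EffectWindow:
    """One conditioning effect: CS+ gain > 1 at given sensors and times."""

    condition: str
    sensors: tuple[str, ...]
    t_start_ms: float
    t_stop_ms: float
    gain: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.gain) or self.gain < 1.0:
            raise ConfigurationError("gain must be finite and >= 1")


@dataclass(frozen=True)
class GroundTruthEffect:
    """Programmed multiplicative CS+ envelope gains (1 everywhere else)."""

    windows: tuple[EffectWindow, ...] = ()

    def validate(self, montage: SensorMontage) -> None:
        for w in self.windows:
            montage.indices(w.sensors)  # raises on unknown sensor
            if w.condition not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {w.condition!r}")

    def gain_matrix(self, condition: str, montage: SensorMontage,
                    times_ms: np.ndarray) -> np.ndarray:
        """(n_channels, n_times) CS+ gain profile for one condition."""
        g = np.ones((montage.n_sensors, len(times_ms)))
        for w in self.windows:
            if w.condition != condition:
                continue
            t = (times_ms >= w.t_start_ms) & (times_ms <= w.t_stop_ms)
            g[np.ix_(montage.indices(w.sensors), t)] *= w.gain
        return g

    @classmethod
    def null(cls) -> "GroundTruthEffect":
        return cls(())

    @classmethod
    def default_conditioning(cls, gain: float = 1.3) -> "GroundTruthEffect":
        """Early occipital effects in both conditions, late anterior in tritan."""
        return cls(
            (
                EffectWindow("tritan", ("65", "66", "69", "70", "75"), 0.0, 1000.0, gain),
                EffectWindow("luminance", ("75", "83", "84", "89", "90"), 0.0, 1000.0, gain),
                EffectWindow(
                    "tritan",
                    ("29", "30", "35", "36", "80", "87", "104", "105"),
                    1500.0, 2500.0, gain,
                ),
            )
        )


# ---------------------------------------------------------------------------
# noise model


@dataclass(frozen=True)
class EegNoiseParams:
    """Background/artifact model for the EEG generator (units µV, Hz, ms)."""

    one_over_f_slope: float = 1.0
    noise_rms_uv: float = 10.0
    channel_rms_jitter: float = 0.3     # uniform ± fraction across channels
    ssvep_amp_uv: float = 2.0           # driven amplitude at the Oz peak
    topography_sigma_deg: float = 35.0  # width of the occipital bump
    topography_floor: float = 0.4       # scalp-wide fraction of peak amplitude
    blink_rate_hz: float = 0.2
    blink_amp_uv: float = 250.0
    blink_duration_ms: float = 300.0
    blink_propagation_tau_rad: float = 0.5
    bad_channels: tuple[str, ...] = ()
    bad_channel_noise_factor: float = 8.0
    transient_rate_hz: float = 0.01     # per channel
    transient_amp_uv: float = 150.0
    transient_duration_ms: float = 40.0

    def quiet(self) -> "EegNoiseParams":
        """Noise-free variant (pure forward model)."""
        return replace(self, noise_rms_uv=0.0, blink_rate_hz=0.0,
                       bad_channels=(), transient_rate_hz=0.0)


def one_over_f_noise(shape: tuple[int, ...], n_samples: int, rate_hz: float,
                     slope: float, rms: float | np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f**slope.

    Synthesised in the frequency domain: independent complex Gaussian
    rfft coefficients scaled by f**(-slope/2) (DC zero), normalised so
    each series has the requested RMS. ``rms`` broadcasts over ``shape``.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-slope / 2.0)
    coeff = rng.standard_normal((*shape, len(freqs))) + 1j * rng.standard_normal(
        (*shape, len(freqs))
    )
    x = np.fft.irfft(coeff * scale, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    amp = np.broadcast_to(np.asarray(rms, dtype=float), shape)[..., None]
    return x / sd * amp


def _ssvep_topography(montage: SensorMontage, params: EegNoiseParams) -> np.ndarray:
    """Driven amplitude per sensor: occipital Gaussian bump on a scalp-wide
    floor (the driven response is measurable over the whole scalp, which is
    what makes anterior conditioning effects possible at all)."""
    oz = montage.positions[montage.index("Oz")]
    cosang = np.clip(montage.positions @ oz, -1, 1)
    ang_deg = np.rad2deg(np.arccos(cosang))
    bump = np.exp(-(ang_deg ** 2) / (2 * params.topography_sigma_deg ** 2))
    return params.ssvep_amp_uv * (
        params.topography_floor + (1.0 - params.topography_floor) * bump
    )


def blink_propagation(montage: SensorMontage,
                      tau_rad: float = 0.5) -> np.ndarray:
    """Fixed front-to-back exponentially decaying blink weight vector."""
    front = np.array([0.0, 1.0, 0.0])
    ang = np.arccos(np.clip(montage.positions @ front, -1, 1))
    w = np.exp(-ang / tau_rad)
    if montage.ocular_ids:
        w[montage.ocular_indices()] = 1.0
    return w


def _carrier(times_ms: np.ndarray, ramp_ms: float = 50.0,
             duration_ms: float = 4000.0,
             freq_hz: float = DRIVING_FREQUENCY_HZ) -> np.ndarray:
    """Unit 7.5 Hz sinusoid gated to the stimulation interval with cosine
    on/off ramps; zero before onset and after offset."""
    t = times_ms / 1000.0
    x = np.sin(2 * np.pi * freq_hz * t)
    env = np.zeros_like(t)
    on = (times_ms >= 0) & (times_ms <= duration_ms)
    env[on] = 1.0
    rise = on & (times_ms < ramp_ms)
    env[rise] = 0.5 * (1 - np.cos(np.pi * times_ms[rise] / ramp_ms))
    fall = on & (times_ms > duration_ms - ramp_ms)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (duration_ms - times_ms[fall]) / ramp_ms))
    return x * env


def _channel_rms(montage: SensorMontage, params: EegNoiseParams,
                 rng: np.random.Generator) -> np.ndarray:
    jit = params.channel_rms_jitter
    factors = rng.uniform(1.0 - jit, 1.0 + jit, montage.n_sensors)
    rms = params.noise_rms_uv * factors
    for ch in params.bad_channels:
        rms[montage.index(ch)] *= params.bad_channel_noise_factor
    return rms


def _cell_signal_matrices(montage: SensorMontage, truth: GroundTruthEffect,
                          params: EegNoiseParams, times_ms: np.ndarray
                          ) -> dict[tuple[str, str], np.ndarray]:
    """(condition, stimulus) -> (n_ch, n_t) driven-signal waveforms."""
    topo = _ssvep_topography(montage, params)
    carrier = _carrier(times_ms)
    out = {}
    for cond in CONDITIONS:
        gain = truth.gain_matrix(cond, montage, times_ms)
        out[(cond, "CS+")] = topo[:, None] * gain * carrier
        out[(cond, "CS-")] = topo[:, None] * carrier
    return out


# ---------------------------------------------------------------------------
# EEG generators


def simulate_subject_eeg(schedule: pd.DataFrame, montage: SensorMontage,
                         truth: GroundTruthEffect, params: EegNoiseParams | None = None,
                         seed: int = 0, iti_range_s: tuple[float, float] = (3.0, 7.0),
                         rate_hz: float = SAMPLING_RATE_HZ) -> RawRecording:
    """Continuous recording for one subject, artifacts included."""
    params = params or EegNoiseParams()
    truth.validate(montage)
    rng = np.random.default_rng(seed)
    n_trials = len(schedule)
    itis = rng.uniform(*iti_range_s, n_trials)
    stim_s = 4.0
    lead_s = 2.0
    onsets_s = lead_s + np.cumsum(itis) - itis[0] + stim_s * np.arange(n_trials)
    n_samples = int(round((onsets_s[-1] + stim_s + 1.0) * rate_hz))
    onset_samples = np.round(onsets_s * rate_hz).astype(int)

    rms = _channel_rms(montage, params, rng)
    if params.noise_rms_uv > 0:
        data = one_over_f_noise((montage.n_sensors,), n_samples, rate_hz,
                                params.one_over_f_slope, rms, rng)
    else:
        data = np.zeros((montage.n_sensors, n_samples))

    # driven oscillation per trial
    step_ms = 1000.0 / rate_hz
    n_stim = int(round(stim_s * rate_hz)) + 1
    t_stim_ms = step_ms * np.arange(n_stim)
    cell_sig = _cell_signal_matrices(montage, truth, params, t_stim_ms)
    for k in range(n_trials):
        cell = (schedule["condition"].iat[k], schedule["stimulus"].iat[k])
        s = onset_samples[k]
        data[:, s: s + n_stim] += cell_sig[cell]

    # blinks: Poisson train, raised-cosine waveform, shared propagation
    if params.blink_rate_hz > 0:
        w = blink_propagation(montage, params.blink_propagation_tau_rad)
        n_blinks = rng.poisson(params.blink_rate_hz * n_samples / rate_hz)
        blink_len = int(round(params.blink_duration_ms / step_ms))
        wave = params.blink_amp_uv * 0.5 * (1 - np.cos(
            2 * np.pi * np.arange(blink_len) / blink_len))
        for s in np.sort(rng.integers(0, n_samples - blink_len, n_blinks)):
            data[:, s: s + blink_len] += w[:, None] * wave[None, :]

    # brief transient artifacts in random channels
    if params.transient_rate_hz > 0:
        tr_len = max(2, int(round(params.transient_duration_ms / step_ms)))
        spike = np.sin(np.pi * np.arange(tr_len) / (tr_len - 1))
        for ch in range(montage.n_sensors):
            for s in rng.integers(
                0, n_samples - tr_len,
                rng.poisson(params.transient_rate_hz * n_samples / rate_hz),
            ):
                data[ch, s: s + tr_len] += rng.choice([-1, 1]) * params.transient_amp_uv * spike

    events = schedule.copy().reset_index(drop=True)
    events.insert(0, "sample", onset_samples)
    return RawRecording(
        data=data,
        rate_hz=rate_hz,
        montage=montage,
        events=events,
        ocular_ids=montage.ocular_ids,
        provenance=[f"simulated subject (seed={seed}, continuous)"],
    )


def simulate_subject_epochs(schedule: pd.DataFrame, montage: SensorMontage,
                            truth: GroundTruthEffect,
                            params: EegNoiseParams | None = None,
                            seed: int = 0,
                            rate_hz: float = SAMPLING_RATE_HZ,
                            phase: str | None = "acquisition") -> EpochSet:
    """Directly epoched simulation without blink/transient processes.

    Statistically equivalent to the continuous path after perfect
    artifact control: driven signal plus 1/f noise per trial. Used for
    cohort-scale simulations where the preprocessing chain itself is
    not under test.
    """
    params = params or EegNoiseParams()
    truth.validate(montage)
    rng = np.random.default_rng(seed)
    labels = schedule if phase is None else schedule[schedule["phase"] == phase]
    labels = labels.reset_index(drop=True)
    times = epoch_times_ms(rate_hz)
    n_trials, n_ch, n_t = len(labels), montage.n_sensors, len(times)
    rms = _channel_rms(montage, params, rng)
    if params.noise_rms_uv > 0:
        data = one_over_f_noise((n_trials, n_ch), n_t, rate_hz,
                                params.one_over_f_slope,
                                np.broadcast_to(rms, (n_trials, n_ch)), rng)
    else:
        data = np.zeros((n_trials, n_ch, n_t))
    cell_sig = _cell_signal_matrices(montage, truth, params, times)
    for cell, sig in cell_sig.items():
        idx = np.flatnonzero(
            (labels["condition"] == cell[0]) & (labels["stimulus"] == cell[1])
        )
        if idx.size:
            data[idx] += sig[None, :, :]
    return EpochSet(
        data=data,
        times_ms=times,
        labels=labels.copy(),
        montage=montage,
        rate_hz=rate_hz,
        provenance=[f"simulated epochs (seed={seed}, phase={phase})"],
    )


# ---------------------------------------------------------------------------
# pupil


@dataclass(frozen=True)
class PupilEffectParams:
    """Constriction/re-dilation model of the pupil response (mm, ms)."""

    base_mm: float = 4.0
    plateau_mm: dict = field(
        default_factory=lambda: {"tritan": 0.24, "luminance": -0.52}
    )
    constriction_mm: dict = field(
        default_factory=lambda: {"tritan": 0.45, "luminance": 1.35}
    )
    constriction_tau_ms: float = 500.0
    cs_plus_increment_mm: float = 0.06
    ramp_start_ms: float = 1000.0
    ramp_stop_ms: float = 2000.0
    noise_rms_mm: float = 0.02
    missing_rate_hz: float = 0.1
    missing_duration_ms: tuple[float, float] = (100.0, 400.0)


def _pupil_profiles(times_ms: np.ndarray, p: PupilEffectParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Constriction transient c(t) in [0, 1] and plateau ramp s(t)."""
    t = np.clip(times_ms, 0, None)
    c = (t / p.constriction_tau_ms) * np.exp(1.0 - t / p.constriction_tau_ms)
    frac = np.clip(
        (times_ms - p.ramp_start_ms) / (p.ramp_stop_ms - p.ramp_start_ms), 0, 1
    )
    s = 0.5 * (1 - np.cos(np.pi * frac))
    return c, s


def simulate_subject_pupil(schedule: pd.DataFrame,
                           params: PupilEffectParams | None = None,
                           seed: int = 0,
                           rate_hz: float = SAMPLING_RATE_HZ) -> PupilRaw:
    """Per-trial pupil traces with blink gaps and a CS+ re-dilation effect.

    Each trace shows stimulus-evoked constriction (deeper in the bright
    luminance condition) followed by re-dilation to a condition-specific
    plateau, raised by ``cs_plus_increment_mm`` on CS+ trials. Missing
    runs (NaN) are inserted at Poisson blink times.
    """
    params = params or PupilEffectParams()
    rng = np.random.default_rng(seed)
    times = epoch_times_ms(rate_hz)
    c, s = _pupil_profiles(times, params)
    n_trials = len(schedule)
    traces = np.empty((n_trials, len(times)))
    for k in range(n_trials):
        cond = schedule["condition"].iat[k]
        inc = params.cs_plus_increment_mm if schedule["stimulus"].iat[k] == "CS+" else 0.0
        mean = (
            params.base_mm
            + (params.plateau_mm[cond] + inc) * s
            - params.constriction_mm[cond] * c
        )
        noise = one_over_f_noise((), len(times), rate_hz, 2.0,
                                 params.noise_rms_mm, rng)
        traces[k] = mean + noise
    # blink gaps
    dur_s = (times[-1] - times[0]) / 1000.0
    step_ms = 1000.0 / rate_hz
    for k in range(n_trials):
        for _ in range(rng.poisson(params.missing_rate_hz * dur_s)):
            length = int(round(rng.uniform(*params.missing_duration_ms) / step_ms))
            start = rng.integers(0, len(times) - length)
            traces[k, start: start + length] = np.nan
    labels = schedule.copy().reset_index(drop=True)
    return PupilRaw(
        traces=traces,
        times_ms=times,
        labels=labels,
        rate_hz=rate_hz,
        provenance=[f"simulated pupil (seed={seed})"],
    )


# ---------------------------------------------------------------------------
# expectancy ratings


OCCASIONS = ("H", "A1", "A2", "E")


@dataclass(frozen=True)
class RatingEffect:
    """CS+ minus CS- expectancy shift per rating occasion (0-10 scale)."""

    shifts: dict = field(
        default_factory=lambda: {"H": 0.0, "A1": 3.0, "A2": 4.7, "E": 3.3}
    )
    cs_minus_mean: float = 1.5
    sigma: float = 2.1  # per-cell rating noise SD


def simulate_expectancy_ratings(schedule: pd.DataFrame | None = None,
                                effect: RatingEffect | None = None,
                                n_subjects: int = 50,
                                seed: int = 0) -> pd.DataFrame:
    """Ratings per subject x occasion x condition x stimulus, clipped to [0, 10]."""
    effect = effect or RatingEffect()
    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(n_subjects):
        for occ in OCCASIONS:
            for cond in CONDITIONS:
                for stim in ("CS+", "CS-"):
                    mean = effect.cs_minus_mean + (
                        effect.shifts[occ] if stim == "CS+" else 0.0
                    )
                    rows.append(
                        {
                            "subject": subj,
                            "occasion": occ,
                            "condition": cond,
                            "stimulus": stim,
                            "rating": float(
                                np.clip(mean + effect.sigma * rng.standard_normal(), 0, 10)
                            ),
                        }
                    )
    return pd.DataFrame(rows)
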