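"""End-to-end orchestration: simulate -> preprocess -> envelope -> stats.

A :class:`RunConfig` fixes every degree of freedom (seed, cohort size,
montage, noise and effect parameters, artifact-control thresholds,
filter settings, resampling counts, analysis windows); a run writes CSV
tables, the shared HDF5 containers, optional topography snapshots and a
machine-readable manifest, and is byte-reproducible from the config.

Two profiles are bundled: ``ci`` (8 subjects, 32 sensors, 500 draws,
50 ms statistics grid, epoch-level simulation) for fast checks, and
``paper`` (50 subjects, 129 sensors, 2000 draws) at study scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import EPOCH_T_MAX_MS, EPOCH_T_MIN_MS
from .errors import ConfigurationError
from .montage import SensorMontage, montage_129, montage_32
from .preprocessing import (bandpass_eeg, condition_average_reference_baseline,
                            correct_blinks, epoch)
from .pupil import (REDILATION_WINDOWS_MS, baseline_and_average,
                    interpolate_missing, lowpass_pupil)
from .scads import (ScadsConfig, flag_and_interpolate_global,
                    flag_and_interpolate_trialwise, reject_trials,
                    scads_quality)
from .schedule import make_trial_schedule
from .simulate import (EegNoiseParams, GroundTruthEffect, PupilEffectParams,
                       RatingEffect, simulate_expectancy_ratings,
                       simulate_subject_eeg, simulate_subject_epochs,
                       simulate_subject_pupil)
from .ssvep import hilbert_envelope, narrowband_filter
from .stats import ConditioningBFModel, paired_ttest
from .stimuli import CONDITIONS


@dataclass
class RunConfig:
    seed: int = 1
    n_subjects: int = 8
    montage: str = "32"                      # "32" | "129"
    simulation: str = "epochs"               # "epochs" | "continuous"
    effect_gain: float = 1.3                 # CS+ gain; 1.0 = null world
    noise: EegNoiseParams = field(default_factory=EegNoiseParams)
    scads: ScadsConfig = field(default_factory=ScadsConfig)
    bandpass_hz: tuple[float, float] = (3.0, 25.0)
    narrowband_hz: tuple[float, float] = (7.0, 8.0)
    n_boot: int = 500
    n_null: int = 500
    decimate_ms: float = 50.0                # statistics time grid step
    early_window_ms: tuple[float, float] = (0.0, 1000.0)
    late_window_ms: tuple[float, float] = (1500.0, 2500.0)
    pupil_window: str = "main"
    bf_threshold: float = 2.0
    iti_range_s: tuple[float, float] = (3.0, 7.0)
    pupil: PupilEffectParams = field(default_factory=PupilEffectParams)
    ratings: RatingEffect = field(default_factory=RatingEffect)
    save_containers: bool = False
    make_plots: bool = False

    def ground_truth(self) -> GroundTruthEffect:
        if self.effect_gain == 1.0:
            return GroundTruthEffect.null()
        return GroundTruthEffect.default_conditioning(self.effect_gain)

    def build_montage(self) -> SensorMontage:
        if self.montage == "32":
            return montage_32()
        if self.montage == "129":
            return montage_129()
        raise ConfigurationError(f"unknown montage {self.montage!r}")

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("noise", EegNoiseParams), ("scads", ScadsConfig),
                         ("pupil", PupilEffectParams), ("ratings", RatingEffect)):
            if key in d and isinstance(d[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
                d[key] = typ(**sub)
        for key in ("bandpass_hz", "narrowband_hz", "early_window_ms",
                    "late_window_ms", "iti_range_s"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def profile(name: str, **overrides) -> RunConfig:
    if name == "ci":
        cfg = RunConfig(n_subjects=8, montage="32", n_boot=500, n_null=500,
                        simulation="epochs", decimate_ms=50.0)
    elif name == "paper":
        cfg = RunConfig(n_subjects=50, montage="129", n_boot=2000, n_null=2000,
                        simulation="continuous", decimate_ms=50.0,
                        iti_range_s=(3.0, 7.0))
    else:
        raise ConfigurationError(f"unknown profile {name!r}")
    return dataclasses.replace(cfg, **overrides)


def validate_config(config: RunConfig) -> list[str]:
    """List configuration violations without running anything."""
    issues = []
    if config.n_subjects < 2:
        issues.append("n_subjects must be >= 2")
    if config.n_boot < 1 or config.n_null < 1:
        issues.append("bootstrap/permutation counts must be positive")
    for name in ("early_window_ms", "late_window_ms"):
        lo, hi = getattr(config, name)
        if not (EPOCH_T_MIN_MS <= lo < hi <= EPOCH_T_MAX_MS):
            issues.append(
                f"{name} ({lo}, {hi}) must lie inside the epoch "
                f"({EPOCH_T_MIN_MS}..{EPOCH_T_MAX_MS} ms)"
            )
    if config.pupil_window not in REDILATION_WINDOWS_MS:
        issues.append(f"pupil_window must be one of {list(REDILATION_WINDOWS_MS)}")
    if config.montage not in ("32", "129"):
        issues.append("montage must be '32' or '129'")
    if config.simulation not in ("epochs", "continuous"):
        issues.append("simulation must be 'epochs' or 'continuous'")
    if not 0 < config.bandpass_hz[0] < config.bandpass_hz[1] < 250:
        issues.append("bandpass cutoffs invalid")
    if not 0 < config.narrowband_hz[0] < config.narrowband_hz[1] < 250:
        issues.append("narrowband cutoffs invalid")
    if config.effect_gain < 1.0:
        issues.append("effect_gain must be >= 1")
    if config.decimate_ms <= 0:
        issues.append("decimate_ms must be positive")
    return issues


def preprocess_subject(raw, config: RunConfig):
    """Continuous recording -> clean acquisition epochs + retention report."""
    raw = bandpass_eeg(raw, *config.bandpass_hz)
    raw = correct_blinks(raw)
    epochs = epoch(raw)
    acq = epochs.labels["phase"] == "acquisition"
    epochs.data = epochs.data[np.asarray(acq)]
    epochs.labels = epochs.labels.loc[acq].reset_index(drop=True)
    quality = scads_quality(epochs, config.scads)
    epochs, gflags = flag_and_interpolate_global(epochs, quality, config.scads)
    epochs, tflags = flag_and_interpolate_trialwise(epochs, quality, config.scads,
                                                    gflags)
    quality2 = scads_quality(epochs, config.scads)
    epochs, rejected, retention = reject_trials(epochs, quality2, config.scads)
    return epochs, quality, retention


def subject_envelope(subject: int, config: RunConfig, montage: SensorMontage,
                     seed: np.random.SeedSequence):
    """Simulate and process one subject; return (cells, env, retention)."""
    sub_seed = int(seed.generate_state(1)[0] % (2**31))
    schedule = make_trial_schedule(sub_seed)
    truth = config.ground_truth()
    if config.simulation == "continuous":
        raw = simulate_subject_eeg(schedule, montage, truth, config.noise,
                                   seed=sub_seed, iti_range_s=config.iti_range_s)
        epochs, _, retention = preprocess_subject(raw, config)
    else:
        epochs = simulate_subject_epochs(schedule, montage, truth, config.noise,
                                         seed=sub_seed)
        retention = None
    avg = condition_average_reference_baseline(epochs)
    filtered = narrowband_filter(avg, *config.narrowband_hz)
    env = hilbert_envelope(filtered)
    return env, retention


def envelope_differences(envelopes: list, decimate_idx: np.ndarray
                         ) -> dict[str, np.ndarray]:
    """Per-condition (n_subjects, n_channels, n_times) CS+ - CS- arrays."""
    diffs = {c: [] for c in CONDITIONS}
    for env in envelopes:
        lab = env.labels
        for cond in CONDITIONS:
            plus = np.flatnonzero((lab["condition"] == cond) & (lab["stimulus"] == "CS+"))[0]
            minus = np.flatnonzero((lab["condition"] == cond) & (lab["stimulus"] == "CS-"))[0]
            diffs[cond].append(
                env.envelope[plus][:, decimate_idx] - env.envelope[minus][:, decimate_idx]
            )
    return {c: np.stack(v) for c, v in diffs.items()}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write all declared artifacts.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    issues = validate_config(config)
    if issues:
        raise ConfigurationError("; ".join(issues))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    montage = config.build_montage()
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects + 2)

    envelopes, retentions = [], []
    for s in range(config.n_subjects):
        env, retention = subject_envelope(s, config, montage, subject_seeds[s])
        envelopes.append(env)
        if retention is not None:
            retention.insert(0, "subject", s)
            retentions.append(retention)

    times = envelopes[0].times_ms
    step = int(round(config.decimate_ms / (times[1] - times[0])))
    decimate_idx = np.arange(0, len(times), max(1, step))
    dec_times = times[decimate_idx]
    diffs = envelope_differences(envelopes, decimate_idx)

    results = {}
    bf_frames = []
    cluster_rows = []
    for i, cond in enumerate(CONDITIONS):
        model = ConditioningBFModel(diffs[cond], channel_ids=montage.ids,
                                    times_ms=dec_times)
        res = model.fit(n_boot=config.n_boot, n_null=config.n_null,
                        seed=np.random.SeedSequence(config.seed + 10_000 + i))
        results[cond] = res
        frame = res.to_frame()
        frame.insert(0, "condition", cond)
        bf_frames.append(frame)
        for wname, win in (("early", config.early_window_ms),
                           ("late", config.late_window_ms)):
            for c in res.clusters(win, montage, config.bf_threshold):
                cluster_rows.append(
                    {
                        "condition": cond, "window": wname,
                        "window_start_ms": win[0], "window_stop_ms": win[1],
                        "sensors": "|".join(c.sensors),
                        "window_avg_log10_bf": c.window_avg_log10_bf,
                        "peak_log10_bf": c.peak_log10_bf,
                        "peak_latency_ms": c.peak_latency_ms,
                        "peak_sensor": c.peak_sensor,
                    }
                )
    pd.concat(bf_frames, ignore_index=True).to_csv(outdir / "bf_map.csv", index=False)
    pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.csv", index=False)

    trans = results["tritan"].transitive(results["luminance"])
    tf = results["tritan"].to_frame()[["sensor", "time_ms"]]
    tf["transitive_log10_bf"] = trans.ravel()
    tf.to_csv(outdir / "transitive_bf.csv", index=False)

    if retentions:
        pd.concat(retentions, ignore_index=True).to_csv(
            outdir / "retention.csv", index=False
        )

    # pupil chain
    pupil_rows = []
    for s in range(config.n_subjects):
        sub_seed = int(subject_seeds[s].generate_state(2)[1] % (2**31))
        schedule = make_trial_schedule(sub_seed)
        acq = schedule[schedule["phase"] == "acquisition"].reset_index(drop=True)
        praw = simulate_subject_pupil(acq, config.pupil, seed=sub_seed)
        praw = lowpass_pupil(praw)
        praw = interpolate_missing(praw)
        _, _, win = baseline_and_average(praw, window=config.pupil_window)
        win.insert(0, "subject", s)
        pupil_rows.append(win)
    pupil_table = pd.concat(pupil_rows, ignore_index=True)
    pupil_table.to_csv(outdir / "pupil_windowed_means.csv", index=False)

    # expectancy ratings and paired t-tests
    ratings = simulate_expectancy_ratings(
        effect=config.ratings, n_subjects=config.n_subjects,
        seed=int(subject_seeds[-1].generate_state(1)[0] % (2**31)),
    )
    ratings.to_csv(outdir / "ratings.csv", index=False)
    trows = []
    for occ in ("H", "A1", "A2", "E"):
        for cond in CONDITIONS:
            sub = ratings[(ratings["occasion"] == occ) & (ratings["condition"] == cond)]
            wide = sub.pivot(index="subject", columns="stimulus", values="rating")
            r = paired_ttest(wide["CS+"].to_numpy(), wide["CS-"].to_numpy())
            trows.append({"occasion": occ, "condition": cond, "t": r.t,
                          "df": r.df, "p": r.p, "cohens_d": r.cohens_d})
    pd.DataFrame(trows).to_csv(outdir / "expectancy_ttests.csv", index=False)

    if config.make_plots:
        from .plotting import plot_bf_topomap

        for cond, res in results.items():
            for wname, win in (("early", config.early_window_ms),
                               ("late", config.late_window_ms)):
                plot_bf_topomap(
                    res.window_average(win), montage,
                    title=f"{cond} {wname} window log10BF",
                    path=outdir / f"topo_{cond}_{wname}.png",
                )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "package_version": __version__,
        "n_subjects": config.n_subjects,
        "montage": config.montage,
        "seed": config.seed,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
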