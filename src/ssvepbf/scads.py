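"""Statistical control of artifacts in dense sensor arrays (SCADS).

Per (trial, channel) three artifact-sensitive statistics are computed:
rectified (absolute) mean amplitude, standard deviation, and maximum
transient sample-to-sample voltage change. Each statistic is divided by
its median over the evaluation pool and the three ratios are averaged
into a dimensionless compound quality index, so the index is scale-free
(value ~1 for typical data).

Channels whose *global* index (the median over trials of the per-trial
statistics, median-normalised across channels) exceeds the across-channel
median + 2.5 SD are interpolated in every trial. Per-trial channel
flags use one shared threshold, median + 2.5 SD of the pooled
(trial, channel) index distribution; flagged cells are interpolated
within that trial only. Finally a trial is rejected when its index
(maximum over channels) exceeds 1.25x the median across trials.
Designated ocular channels are excluded from evaluation by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet
from .errors import DataQualityError, DegenerateDataError
from .spline import interpolation_weights

PARAM_NAMES = ("abs_mean_uv", "std_uv", "max_transient_uv")


@dataclass
class ScadsConfig:
    global_sds: float = 2.5           # SDs above the median, global channel flags
    trial_sds: float = 2.5            # SDs above the median, trial-level flags
    rejection_factor: float = 1.25    # x median of the trial index
    spline_order: int = 4
    spline_terms: int = 7
    spline_ridge: float = 1e-5
    max_global_bad_fraction: float = 0.2  # safety rail, not from the method
    robust_scale: bool = False        # use 1.4826*MAD instead of SD
    trialwise_threshold: str = "pooled"   # "pooled" | "within_trial"
    exclude_ocular: bool = True

    def scale(self, values: np.ndarray) -> float:
        if self.robust_scale:
            return 1.4826 * float(np.median(np.abs(values - np.median(values))))
        return float(np.std(values))


@dataclass
class QualityTable:
    """SCADS statistics, compound indices, and accumulated flags."""

    params: np.ndarray           # (n_trials, n_ch, 3)
    compound: np.ndarray         # (n_trials, n_ch)
    global_params: np.ndarray    # (n_ch, 3)
    global_compound: np.ndarray  # (n_ch,)
    channel_ids: list[str]
    evaluated: np.ndarray        # (n_ch,) bool, channels in the pool
    global_bad: np.ndarray = field(default=None)        # (n_ch,) bool
    trial_bad_channel: np.ndarray = field(default=None)  # (n_trials, n_ch) bool
    trial_rejected: np.ndarray = field(default=None)     # (n_trials,) bool

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per (trial, channel)."""
        n_t, n_c = self.compound.shape
        t, c = np.meshgrid(np.arange(n_t), np.arange(n_c), indexing="ij")
        df = pd.DataFrame(
            {
                "trial": t.ravel(),
                "channel": np.array(self.channel_ids)[c.ravel()],
                "abs_mean_uv": self.params[..., 0].ravel(),
                "std_uv": self.params[..., 1].ravel(),
                "max_transient_uv": self.params[..., 2].ravel(),
                "compound_index": self.compound.ravel(),
            }
        )
        if self.trial_bad_channel is not None:
            df["flag_trial_channel"] = self.trial_bad_channel.ravel()
        if self.global_bad is not None:
            df["flag_global_channel"] = self.global_bad[c.ravel()]
        if self.trial_rejected is not None:
            df["flag_trial_rejected"] = self.trial_rejected[t.ravel()]
        return df


def _three_params(x: np.ndarray) -> np.ndarray:
    """abs mean, SD, max |sample-to-sample change| over the last axis."""
    return np.stack(
        [
            np.abs(x).mean(axis=-1),
            x.std(axis=-1),
            np.abs(np.diff(x, axis=-1)).max(axis=-1),
        ],
        axis=-1,
    )


def scads_quality(epochs: EpochSet, cfg: ScadsConfig | None = None) -> QualityTable:
    """Compute the compound quality index per (trial, channel) and per channel."""
    cfg = cfg or ScadsConfig()
    if epochs.n_trials == 0:
        raise DegenerateDataError("cannot evaluate quality of an empty EpochSet")
    n_ch = epochs.montage.n_sensors
    evaluated = np.ones(n_ch, dtype=bool)
    if cfg.exclude_ocular and epochs.montage.ocular_ids:
        evaluated[epochs.montage.ocular_indices()] = False

    params = _three_params(epochs.data)  # (n_trials, n_ch, 3)
    pool = params[:, evaluated, :].reshape(-1, 3)
    med = np.median(pool, axis=0)
    if np.any(med == 0):
        raise DegenerateDataError("a quality parameter has zero median")
    compound = (params / med).mean(axis=-1)

    # global index: per-channel median over trials of the three statistics
    # ("bad throughout the recording"); a median is immune to single-trial
    # transients, which belong to the trial-level flags instead
    gparams = np.median(params, axis=0)
    gmed = np.median(gparams[evaluated], axis=0)
    if np.any(gmed == 0):
        raise DegenerateDataError("a global quality parameter has zero median")
    gcompound = (gparams / gmed).mean(axis=-1)
    return QualityTable(
        params=params,
        compound=compound,
        global_params=gparams,
        global_compound=gcompound,
        channel_ids=list(epochs.montage.ids),
        evaluated=evaluated,
    )


def flag_and_interpolate_global(
    epochs: EpochSet, quality: QualityTable, cfg: ScadsConfig | None = None
) -> tuple[EpochSet, np.ndarray]:
    """Interpolate globally bad channels in every trial.

    A channel is globally bad when its global compound index exceeds
    median + ``global_sds`` x SD across evaluated channels. Aborts with
    :class:`DataQualityError` when more than ``max_global_bad_fraction``
    of channels are flagged.
    """
    cfg = cfg or ScadsConfig()
    gc = quality.global_compound
    ev = quality.evaluated
    thr = np.median(gc[ev]) + cfg.global_sds * cfg.scale(gc[ev])
    flags = (gc > thr) & ev
    quality.global_bad = flags
    if flags.sum() > cfg.max_global_bad_fraction * ev.sum():
        raise DataQualityError(
            f"{int(flags.sum())}/{int(ev.sum())} channels globally bad "
            f"(> {cfg.max_global_bad_fraction:.0%} guard)"
        )
    out = epochs.copy()
    bad_idx = np.flatnonzero(flags)
    if bad_idx.size:
        sources = np.flatnonzero(~flags & ev)
        pos = epochs.montage.positions
        w = interpolation_weights(pos[sources], pos[bad_idx], cfg.spline_order,
                                  cfg.spline_terms, cfg.spline_ridge)
        out.data[:, bad_idx, :] = np.einsum("bk,tks->tbs", w, out.data[:, sources, :])
    out.log(
        "global SCADS: flagged "
        + (", ".join(epochs.montage.ids[i] for i in bad_idx) if bad_idx.size else "none")
    )
    return out, flags


def flag_and_interpolate_trialwise(
    epochs: EpochSet, quality: QualityTable, cfg: ScadsConfig | None = None,
    global_flags: np.ndarray | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Interpolate per-trial bad channels.

    One shared threshold — median + ``trial_sds`` x SD of the pooled
    (trial, channel) compound indices — is applied to every cell
    (``trialwise_threshold="within_trial"`` recomputes it per trial).
    Channels already globally interpolated are never re-flagged.
    """
    cfg = cfg or ScadsConfig()
    if global_flags is None:
        global_flags = (
            quality.global_bad
            if quality.global_bad is not None
            else np.zeros(epochs.montage.n_sensors, dtype=bool)
        )
    eligible = quality.evaluated & ~global_flags
    comp = quality.compound
    flags = np.zeros_like(comp, dtype=bool)
    if cfg.trialwise_threshold == "pooled":
        pool = comp[:, eligible].ravel()
        thr = np.median(pool) + cfg.trial_sds * cfg.scale(pool)
        flags[:, eligible] = comp[:, eligible] > thr
    elif cfg.trialwise_threshold == "within_trial":
        for t in range(comp.shape[0]):
            row = comp[t, eligible]
            thr = np.median(row) + cfg.trial_sds * cfg.scale(row)
            flags[t, eligible] = comp[t, eligible] > thr
    else:
        raise DegenerateDataError(
            f"unknown trialwise_threshold {cfg.trialwise_threshold!r}"
        )
    quality.trial_bad_channel = flags
    out = epochs.copy()
    pos = epochs.montage.positions
    for t in np.flatnonzero(flags.any(axis=1)):
        bad_idx = np.flatnonzero(flags[t])
        sources = np.flatnonzero(eligible & ~flags[t])
        w = interpolation_weights(pos[sources], pos[bad_idx], cfg.spline_order,
                                  cfg.spline_terms, cfg.spline_ridge)
        out.data[t, bad_idx, :] = w @ out.data[t, sources, :]
    out.log(f"trialwise SCADS: {int(flags.sum())} (trial, channel) cells interpolated")
    return out, flags


def reject_trials(
    epochs: EpochSet, quality: QualityTable, cfg: ScadsConfig | None = None
) -> tuple[EpochSet, np.ndarray, pd.DataFrame]:
    """Drop trials whose index exceeds ``rejection_factor`` x median.

    The trial-level scalar is the maximum over evaluated channels of the
    (trial, channel) compound index (quality should be recomputed after
    interpolation). Returns the surviving epochs, the rejected trial
    indices, and a per-condition-cell retention report.
    """
    cfg = cfg or ScadsConfig()
    scalar = quality.compound[:, quality.evaluated].max(axis=1)
    thr = cfg.rejection_factor * float(np.median(scalar))
    rejected = scalar > thr
    quality.trial_rejected = rejected
    if rejected.all():
        raise DataQualityError("all trials rejected")
    out = epochs.copy()
    out.data = out.data[~rejected]
    out.labels = out.labels.loc[~rejected].reset_index(drop=True)
    out.log(f"trial rejection: removed {int(rejected.sum())}/{len(rejected)} trials")
    by = [c for c in ("condition", "stimulus") if c in epochs.labels.columns]
    if by:
        total = epochs.labels.groupby(by, sort=True).size().rename("n_total")
        kept = out.labels.groupby(by, sort=True).size().rename("n_kept")
        report = pd.concat([total, kept], axis=1).fillna(0).astype(int).reset_index()
        report["retention"] = report["n_kept"] / report["n_total"]
    else:
        report = pd.DataFrame(
            {"n_total": [len(rejected)], "n_kept": [int((~rejected).sum())]}
        )
        report["retention"] = report["n_kept"] / report["n_total"]
    return out, np.flatnonzero(rejected), report
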