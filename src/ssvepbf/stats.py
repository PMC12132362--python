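"""Non-parametric bootstrapped Bayes factors for sensor x time maps.

The hypothesis is directional: the ssVEP envelope is larger for CS+
than CS- at a given sensor and time point. For each condition the
per-subject CS+ minus CS- envelope difference enters two resampling
schemes with B = 2000 draws each:

* **effect draws** — subject-level bootstrap: for each draw, sample n
  subjects with replacement and average their difference maps (one
  subject sample per draw, shared by every sensor/time cell, so the
  spatial and temporal correlation of the map is preserved);
* **null draws** — within-subject label permutation: each subject's
  difference has its sign flipped with probability 1/2 (swapping the
  CS labels negates the difference) before the same subject-level
  resampling and averaging.

Evidence is the exceedance probability p that a random effect draw is
larger than a random null draw (the all-pairs fraction, computed by
sorting), clipped to [1/(B+1), B/(B+1)] so the posterior odds stay
finite; against flat prior odds of 1 the Bayes factor is
BF10 = p / (1 - p), reported as log10. Two conditions' maps combine
into transitive Bayes factors log10(BF_a / BF_b) = log10BF_a - log10BF_b.
No multiplicity correction is applied; evidence is read off the
Jeffreys-style thresholds (0.5/1/1.5/2).

The module follows the statsmodels convention: build a
:class:`ConditioningBFModel` from a subject x channel x time difference
array, call :meth:`~ConditioningBFModel.fit`, and read estimates,
labels, clusters and summary tables off the returned
:class:`BFMapResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateDataError
from .montage import SensorMontage

# ---------------------------------------------------------------------------
# resampling primitives


def _check_diff(diff: np.ndarray) -> np.ndarray:
    diff = np.asarray(diff, dtype=float)
    if diff.ndim < 2:
        raise ConfigurationError("difference array must be (n_subjects, ...)")
    if diff.shape[0] < 2:
        raise ConfigurationError("need at least 2 subjects")
    if not np.isfinite(diff).all():
        raise DegenerateDataError("non-finite values in difference array")
    return diff.reshape(diff.shape[0], -1)


def _resample_counts(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """(B, n) multiplicity matrix of subject draws with replacement."""
    idx = rng.integers(0, n, size=(n_boot, n))
    counts = np.zeros((n_boot, n))
    np.add.at(counts, (np.repeat(np.arange(n_boot), n), idx.ravel()), 1.0)
    return counts


def bootstrap_effect(diff: np.ndarray, n_boot: int = 2000,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Subject-level bootstrap draws of the mean difference, (B, n_cells).

    Each draw samples n subjects with replacement and averages their
    difference maps jointly across all cells (one subject sample per
    draw), implemented as a multiplicity-matrix product.
    """
    d = _check_diff(diff)
    rng = np.random.default_rng(rng)
    counts = _resample_counts(d.shape[0], n_boot, rng)
    return counts @ d / d.shape[0]


def permutation_null(diff: np.ndarray, n_boot: int = 2000,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Sign-flip-then-bootstrap null draws of the mean difference.

    Per draw the condition labels are re-randomised within each subject
    (sign flip with probability 1/2, assigned to subjects before the
    resampling so a subject drawn twice keeps one sign), then subjects
    are resampled with replacement and averaged.
    """
    d = _check_diff(diff)
    rng = np.random.default_rng(rng)
    n = d.shape[0]
    signs = rng.integers(0, 2, size=(n_boot, n)) * 2.0 - 1.0
    counts = _resample_counts(n, n_boot, rng)
    return (counts * signs) @ d / n


def exceedance_probability(effect_draws: np.ndarray,
                           null_draws: np.ndarray) -> np.ndarray:
    """All-pairs fraction P(effect draw > null draw), per cell, by sorting.

    Strictly-greater counting; ties do not count as exceedance. Equal to
    the brute-force double loop exactly.
    """
    e = np.atleast_2d(np.asarray(effect_draws, dtype=float).T).T
    n = np.atleast_2d(np.asarray(null_draws, dtype=float).T).T
    if e.size == 0 or n.size == 0:
        raise DegenerateDataError("empty draw set")
    if not (np.isfinite(e).all() and np.isfinite(n).all()):
        raise DegenerateDataError("non-finite draws")
    out = np.empty(e.shape[1])
    for c in range(e.shape[1]):
        ns = np.sort(n[:, c])
        out[c] = np.searchsorted(ns, e[:, c], side="left").sum() / (
            e.shape[0] * n.shape[0]
        )
    return out if effect_draws.ndim > 1 else out[0]


def log_bayes_factor(effect_draws: np.ndarray, null_draws: np.ndarray,
                     clip_b: int | None = None) -> np.ndarray:
    """log10 BF10 from the clipped exceedance probability.

    ``clip_b`` defaults to the number of effect draws; p is clipped to
    [1/(B+1), B/(B+1)], bounding |log10BF| at log10(B).
    """
    p = exceedance_probability(effect_draws, null_draws)
    b = clip_b if clip_b is not None else np.atleast_2d(np.asarray(effect_draws).T).shape[1]
    p = np.clip(p, 1.0 / (b + 1), b / (b + 1.0))
    return np.log10(p / (1.0 - p))


JEFFREYS_BINS = (
    (2.0, "decisive"),
    (1.5, "very strong"),
    (1.0, "strong"),
    (0.5, "substantial"),
)


def jeffreys_label(log10_bf) -> np.ndarray | str:
    """Evidence category for (arrays of) log10 Bayes factors."""
    x = np.asarray(log10_bf, dtype=float)
    if not np.isfinite(x).all():
        raise DegenerateDataError("non-finite log10BF")
    out = np.full(x.shape, "anecdotal/none", dtype=object)
    for lo, name in JEFFREYS_BINS:
        out[(x >= lo) & (out == "anecdotal/none")] = name
    return out if x.ndim else str(out[()])


def transitive_bf(log10_bf_a: np.ndarray, log10_bf_b: np.ndarray) -> np.ndarray:
    """log10 of the ratio of Bayes factors: log10BF_a - log10BF_b."""
    a = np.asarray(log10_bf_a, dtype=float)
    b = np.asarray(log10_bf_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("Bayes-factor maps have mismatched grids")
    return a - b


def ztransform_joint(effect_draws: np.ndarray, null_draws: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Standardise both draw sets with their pooled mean and SD.

    The joint transform preserves the relative location of the two
    distributions (the null is generally not centred at zero after it).
    """
    e = np.asarray(effect_draws, dtype=float)
    n = np.asarray(null_draws, dtype=float)
    pooled = np.concatenate([e.ravel(), n.ravel()])
    sd = pooled.std()
    if sd == 0:
        raise DegenerateDataError("zero pooled SD")
    mu = pooled.mean()
    return (e - mu) / sd, (n - mu) / sd


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: int
    p: float
    cohens_d: float


def paired_ttest(x, y=None) -> PairedTTestResult:
    """Classical paired t-test; pass differences, or two paired samples.

    Cohen's d is the mean difference over the SD of the differences.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ConfigurationError("need at least 2 paired observations")
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTTestResult(t=0.0, df=d.size - 1, p=1.0, cohens_d=0.0)
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2 * sps.t.sf(abs(t), d.size - 1)
    return PairedTTestResult(t=float(t), df=d.size - 1, p=float(p),
                             cohens_d=float(d.mean() / sd))


# ---------------------------------------------------------------------------
# model / results


@dataclass
class ClusterSummary:
    """Adjacency-connected group of sensors above threshold in a window."""

    sensors: tuple[str, ...]
    window_ms: tuple[float, float]
    window_avg_log10_bf: float
    peak_log10_bf: float
    peak_latency_ms: float
    peak_sensor: str


class ConditioningBFModel:
    """Bootstrapped Bayes-factor model of a CS+ minus CS- difference map.

    Parameters
    ----------
    differences : ndarray, (n_subjects, n_channels, n_times)
        Per-subject envelope differences (µV).
    channel_ids, times_ms : axis labels (optional; defaults to indices).
    direction : "greater" (default, CS+ > CS-), "less", or "two_sided".
    """

    def __init__(self, differences: np.ndarray, channel_ids=None,
                 times_ms=None, direction: str = "greater"):
        differences = np.asarray(differences, dtype=float)
        if differences.ndim == 2:
            differences = differences[:, :, None]
        if differences.ndim != 3:
            raise ConfigurationError(
                "differences must be (n_subjects, n_channels, n_times)"
            )
        _check_diff(differences)
        if direction not in ("greater", "less", "two_sided"):
            raise ConfigurationError(f"unknown direction {direction!r}")
        self.differences = differences
        self.n_subjects, self.n_channels, self.n_times = differences.shape
        self.channel_ids = (
            list(channel_ids) if channel_ids is not None
            else [str(i) for i in range(self.n_channels)]
        )
        self.times_ms = (
            np.asarray(times_ms, dtype=float) if times_ms is not None
            else np.arange(self.n_times, dtype=float)
        )
        self.direction = direction

    @classmethod
    def from_envelopes(cls, envelopes: np.ndarray, cs_plus_index: int,
                       cs_minus_index: int, **kwargs) -> "ConditioningBFModel":
        """Build from (n_subjects, n_cells, n_channels, n_times) envelopes."""
        env = np.asarray(envelopes, dtype=float)
        return cls(env[:, cs_plus_index] - env[:, cs_minus_index], **kwargs)

    def fit(self, n_boot: int = 2000, n_null: int = 2000,
            seed: int | np.random.SeedSequence | None = None,
            keep_draws: bool = False) -> "BFMapResults":
        """Run both resampling schemes and map log10 BF10 per cell."""
        if n_boot < 1 or n_null < 1:
            raise ConfigurationError("draw counts must be positive")
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        eff_ss, null_ss = ss.spawn(2)
        d = self.differences.reshape(self.n_subjects, -1)
        eff = bootstrap_effect(d, n_boot, np.random.default_rng(eff_ss))
        null = permutation_null(d, n_null, np.random.default_rng(null_ss))
        p = exceedance_probability(eff, null)
        if self.direction == "less":
            p = 1.0 - p
        elif self.direction == "two_sided":
            p = np.maximum(p, 1.0 - p)
        b = min(n_boot, n_null)
        p_clipped = np.clip(p, 1.0 / (b + 1), b / (b + 1.0))
        log10_bf = np.log10(p_clipped / (1.0 - p_clipped))
        return BFMapResults(
            model=self,
            log10_bf=log10_bf.reshape(self.n_channels, self.n_times),
            exceedance_p=p.reshape(self.n_channels, self.n_times),
            n_boot=n_boot,
            n_null=n_null,
            seed_entropy=ss.entropy,
            effect_draws=eff if keep_draws else None,
            null_draws=null if keep_draws else None,
        )


@dataclass
class BFMapResults:
    """Fitted Bayes-factor map with draw bookkeeping and summaries."""

    model: ConditioningBFModel
    log10_bf: np.ndarray      # (n_channels, n_times)
    exceedance_p: np.ndarray  # unclipped
    n_boot: int
    n_null: int
    seed_entropy: int | None = None
    effect_draws: np.ndarray | None = field(default=None, repr=False)
    null_draws: np.ndarray | None = field(default=None, repr=False)

    @property
    def log10_bf01(self) -> np.ndarray:
        """Evidence for the null, log10 BF01 = -log10 BF10."""
        return -self.log10_bf

    @property
    def jeffreys_labels(self) -> np.ndarray:
        return jeffreys_label(self.log10_bf)

    def draws_at(self, channel: str | int, time_ms: float
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Effect and null draws for one cell (recomputed if not kept)."""
        ch = (self.model.channel_ids.index(channel)
              if isinstance(channel, str) else int(channel))
        t = int(np.argmin(np.abs(self.model.times_ms - time_ms)))
        cell = ch * self.model.n_times + t
        if self.effect_draws is not None:
            return self.effect_draws[:, cell], self.null_draws[:, cell]
        ss = np.random.SeedSequence(self.seed_entropy)
        eff_ss, null_ss = ss.spawn(2)
        d = self.model.differences.reshape(self.model.n_subjects, -1)
        eff = bootstrap_effect(d, self.n_boot, np.random.default_rng(eff_ss))
        null = permutation_null(d, self.n_null, np.random.default_rng(null_ss))
        return eff[:, cell], null[:, cell]

    def window_average(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Per-channel mean log10BF over a time window (inclusive)."""
        t = self.model.times_ms
        m = (t >= window_ms[0] - 1e-9) & (t <= window_ms[1] + 1e-9)
        if not m.any():
            raise ConfigurationError("window outside the analysed time axis")
        return self.log10_bf[:, m].mean(axis=1)

    def clusters(self, window_ms: tuple[float, float], montage: SensorMontage,
                 threshold: float = 2.0) -> list[ClusterSummary]:
        """Adjacency-connected sensor groups with window average > threshold.

        The threshold is strict: a sensor at exactly the threshold is
        excluded. Isolated supra-threshold sensors are reported as
        singleton clusters. Peak latency is constrained to the window.
        """
        avg = self.window_average(window_ms)
        idx_map = montage.indices(self.model.channel_ids)
        members = np.flatnonzero(avg > threshold)
        t = self.model.times_ms
        tmask = (t >= window_ms[0] - 1e-9) & (t <= window_ms[1] + 1e-9)
        clusters: list[ClusterSummary] = []
        unvisited = set(members.tolist())
        while unvisited:
            seed_ch = unvisited.pop()
            comp = {seed_ch}
            stack = [seed_ch]
            while stack:
                i = stack.pop()
                for j in list(unvisited):
                    if montage.adjacency[idx_map[i], idx_map[j]]:
                        unvisited.discard(j)
                        comp.add(j)
                        stack.append(j)
            comp_idx = np.array(sorted(comp))
            sub = self.log10_bf[np.ix_(comp_idx, np.flatnonzero(tmask))]
            pk = np.unravel_index(np.argmax(sub), sub.shape)
            clusters.append(
                ClusterSummary(
                    sensors=tuple(self.model.channel_ids[i] for i in comp_idx),
                    window_ms=tuple(window_ms),
                    window_avg_log10_bf=float(avg[comp_idx].mean()),
                    peak_log10_bf=float(sub[pk]),
                    peak_latency_ms=float(t[tmask][pk[1]]),
                    peak_sensor=self.model.channel_ids[comp_idx[pk[0]]],
                )
            )
        clusters.sort(key=lambda c: -c.window_avg_log10_bf)
        return clusters

    def transitive(self, other: "BFMapResults") -> np.ndarray:
        """Transitive map log10(BF_self / BF_other), elementwise."""
        if self.log10_bf.shape != other.log10_bf.shape or not np.array_equal(
            self.model.times_ms, other.model.times_ms
        ):
            raise ConfigurationError("Bayes-factor maps have mismatched grids")
        return transitive_bf(self.log10_bf, other.log10_bf)

    def to_frame(self) -> pd.DataFrame:
        """Long-format map: sensor, time_ms, log10BF, exceedance p, label."""
        ch = np.repeat(self.model.channel_ids, self.model.n_times)
        t = np.tile(self.model.times_ms, self.model.n_channels)
        return pd.DataFrame(
            {
                "sensor": ch,
                "time_ms": t,
                "log10_bf": self.log10_bf.ravel(),
                "exceedance_p": self.exceedance_p.ravel(),
                "label": self.jeffreys_labels.ravel(),
            }
        )

    def summary(self, windows: dict[str, tuple[float, float]] | None = None,
                montage: SensorMontage | None = None,
                threshold: float = 2.0) -> str:
        """Readable report: grid, draw counts, peak cell, window clusters."""
        lines = [
            "Bootstrapped Bayes-factor map",
            "=" * 39,
            f"subjects: {self.model.n_subjects}   "
            f"channels: {self.model.n_channels}   "
            f"time points: {self.model.n_times}",
            f"effect draws: {self.n_boot}   null draws: {self.n_null}   "
            f"direction: {self.model.direction}",
        ]
        pk = np.unravel_index(np.argmax(self.log10_bf), self.log10_bf.shape)
        lines.append(
            f"peak log10BF = {self.log10_bf[pk]:.2f} at sensor "
            f"{self.model.channel_ids[pk[0]]}, {self.model.times_ms[pk[1]]:.0f} ms "
            f"({jeffreys_label(float(self.log10_bf[pk]))})"
        )
        for name, win in (windows or {}).items():
            lines.append(f"window {name} {win[0]:.0f}-{win[1]:.0f} ms:")
            if montage is None:
                avg = self.window_average(win)
                i = int(np.argmax(avg))
                lines.append(
                    f"  max window-averaged log10BF = {avg[i]:.2f} at sensor "
                    f"{self.model.channel_ids[i]}"
                )
            else:
                cl = self.clusters(win, montage, threshold)
                if not cl:
                    lines.append(f"  no sensors with window average > {threshold}")
                for c in cl:
                    lines.append(
                        f"  cluster {','.join(c.sensors)}: avg {c.window_avg_log10_bf:.2f}, "
                        f"peak {c.peak_log10_bf:.2f} at {c.peak_latency_ms:.0f} ms "
                        f"({c.peak_sensor})"
                    )
        return "\n".join(lines)
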