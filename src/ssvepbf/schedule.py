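"""Trial schedule of the conditioning task.

160 trials in three phases: 20 habituation, 120 acquisition, 20
extinction. Trial types are the four condition x stimulus cells
(tritan/luminance x CS+/CS-), equiprobable within each phase and
pseudo-randomized with a cap on runs of identical types. The aversive
US is delivered on every acquisition CS+ trial (100% reinforcement) and
never in habituation or extinction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .stimuli import CONDITIONS, STIMULI

PHASES = ("habituation", "acquisition", "extinction")
PHASE_TRIALS = {"habituation": 20, "acquisition": 120, "extinction": 20}
N_TRIALS = 160
MAX_RUN = 3  # longest allowed run of identical condition x stimulus types


def _shuffle_with_run_cap(cells: list[tuple[str, str]], rng: np.random.Generator,
                          max_run: int = MAX_RUN) -> list[tuple[str, str]]:
    """Seeded shuffle rejected until no trial type repeats > max_run times."""
    cells = list(cells)
    for _ in range(1000):
        perm = [cells[i] for i in rng.permutation(len(cells))]
        run, ok = 1, True
        for a, b in zip(perm, perm[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return perm
    raise ConfigurationError("could not satisfy run-length cap")  # pragma: no cover


def make_trial_schedule(seed: int, orientation_cs_plus: int = 45) -> pd.DataFrame:
    """Build a full 160-trial schedule.

    Returns a DataFrame with columns ``trial, phase, condition, stimulus,
    orientation_deg, reinforced``. ``orientation_cs_plus`` is the grating
    tilt assigned to CS+ (counterbalanced across subjects in the design).
    """
    if orientation_cs_plus not in (45, 135):
        raise ConfigurationError("orientation_cs_plus must be 45 or 135")
    rng = np.random.default_rng(seed)
    rows = []
    for phase in PHASES:
        n = PHASE_TRIALS[phase]
        per_cell = n // 4
        cells = [(c, s) for c in CONDITIONS for s in STIMULI for _ in range(per_cell)]
        for cond, stim in _shuffle_with_run_cap(cells, rng):
            rows.append(
                {
                    "phase": phase,
                    "condition": cond,
                    "stimulus": stim,
                    "orientation_deg": orientation_cs_plus
                    if stim == "CS+"
                    else (180 - orientation_cs_plus),
                    "reinforced": phase == "acquisition" and stim == "CS+",
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(len(df)))
    validate_schedule(df)
    return df


def validate_schedule(df: pd.DataFrame) -> None:
    """Raise ConfigurationError if the schedule violates the design."""
    if len(df) != N_TRIALS:
        raise ConfigurationError(f"expected {N_TRIALS} trials, got {len(df)}")
    counts = df["phase"].value_counts()
    for phase, n in PHASE_TRIALS.items():
        if counts.get(phase, 0) != n:
            raise ConfigurationError(f"phase {phase} must have {n} trials")
    acq = df[df["phase"] == "acquisition"]
    cell = acq.groupby(["condition", "stimulus"]).size()
    if not (cell == 30).all() or len(cell) != 4:
        raise ConfigurationError("acquisition must have 30 trials per cell")
    want = (df["phase"] == "acquisition") & (df["stimulus"] == "CS+")
    if not (df["reinforced"] == want).all():
        raise ConfigurationError("reinforcement must be acquisition CS+ only")
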