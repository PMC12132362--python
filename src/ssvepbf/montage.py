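"""Sensor montages: positions on the unit sphere and a neighbour graph.

The dense-array net used for this kind of recording has 129 sensors with
numeric labels ("1".."129"); a handful correspond to 10-20 landmarks
(Oz = 75, O1 = 70, O2 = 83, Pz = 62, C3 = 36, C4 = 104, Cz = 129) and four
periocular sensors (8, 25, 126, 127) double as ocular (EOG-like) channels.
No coordinates are published for this study, so the packaged layout is a
synthetic but geometrically plausible stand-in: the named landmarks sit at
approximately standard scalp positions, the occipital and anterior sensor
groups reported as clusters are placed adjacent to their landmarks, and
the remaining ids fill the scalp on a Fibonacci spiral.

Adjacency is defined by a geodesic-distance cap of 1.55x the median
nearest-neighbour distance, which yields ~5-7 neighbours per sensor on
either layout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigurationError

#: alias -> numeric id for the landmarks named in reports.
LANDMARKS = {
    "Oz": "75",
    "O1": "70",
    "O2": "83",
    "Pz": "62",
    "C3": "36",
    "C4": "104",
    "Cz": "129",
}

OCULAR_IDS = ("8", "25", "126", "127")

ADJACENCY_FACTOR = 1.55


def _unit(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector from polar angle theta (from vertex) and azimuth phi
    (0 = anterior, 90 = right ear, 180 = posterior)."""
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


# Hand-placed sensors: landmarks, reported cluster members, ocular channels.
_PLACED: dict[str, tuple[float, float]] = {
    "129": (0.0, 0.0),      # Cz
    "62": (45.0, 180.0),    # Pz
    "75": (90.0, 180.0),    # Oz
    # left occipital group around O1
    "70": (88.0, 196.0),    # O1
    "65": (76.0, 198.0),
    "66": (80.0, 208.0),
    "69": (92.0, 208.0),
    # right occipital group around O2
    "83": (88.0, 164.0),    # O2
    "84": (92.0, 152.0),
    "89": (80.0, 152.0),
    "90": (76.0, 162.0),
    # left central-anterior group around C3
    "36": (45.0, 270.0),    # C3
    "35": (45.0, 252.0),
    "30": (32.0, 260.0),
    "29": (30.0, 280.0),
    # right central-anterior group around C4
    "104": (45.0, 90.0),    # C4
    "105": (32.0, 100.0),
    "87": (45.0, 108.0),
    "80": (30.0, 80.0),
    # left parietal singletons (kept mutually non-adjacent)
    "47": (65.0, 240.0),
    "52": (85.0, 220.0),
    # periocular / ocular channels
    "8": (95.0, 30.0),
    "25": (95.0, 330.0),
    "126": (110.0, 20.0),
    "127": (110.0, 340.0),
}


@dataclass
class SensorMontage:
    """Sensor identifiers, unit-sphere positions and neighbour relation."""

    ids: list[str]
    positions: np.ndarray  # (n, 3), unit norm
    adjacency: np.ndarray  # (n, n) bool, symmetric, irreflexive
    ocular_ids: tuple[str, ...] = ()
    names: dict[str, str] = field(default_factory=dict)  # alias -> id

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ConfigurationError("duplicate sensor ids in montage")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ConfigurationError("montage positions must have unit norm")
        a = self.adjacency
        if a.shape != (len(self.ids),) * 2 or not (a == a.T).all() or a.diagonal().any():
            raise ConfigurationError("adjacency must be symmetric and irreflexive")

    @property
    def n_sensors(self) -> int:
        return len(self.ids)

    def index(self, sensor: str) -> int:
        """Row index of a sensor id or landmark alias."""
        sensor = self.names.get(sensor, sensor)
        try:
            return self.ids.index(sensor)
        except ValueError:
            raise ConfigurationError(f"sensor {sensor!r} not in montage") from None

    def indices(self, sensors) -> np.ndarray:
        return np.array([self.index(s) for s in sensors], dtype=int)

    def neighbors(self, sensor: str) -> list[str]:
        i = self.index(sensor)
        return [self.ids[j] for j in np.flatnonzero(self.adjacency[i])]

    def angular_distance(self, a: str, b: str) -> float:
        """Geodesic distance in radians between two sensors."""
        cosv = float(np.clip(self.positions[self.index(a)] @ self.positions[self.index(b)], -1, 1))
        return float(np.arccos(cosv))

    def ocular_indices(self) -> np.ndarray:
        return self.indices(self.ocular_ids)

    def subset(self, keep_ids) -> "SensorMontage":
        """Montage restricted to ``keep_ids`` with adjacency recomputed."""
        idx = self.indices(keep_ids)
        pos = self.positions[idx]
        ids = [self.ids[i] for i in idx]
        return SensorMontage(
            ids=ids,
            positions=pos,
            adjacency=_adjacency_from_positions(pos),
            ocular_ids=tuple(s for s in self.ocular_ids if s in ids),
            names={k: v for k, v in self.names.items() if v in ids},
        )


def _adjacency_from_positions(pos: np.ndarray) -> np.ndarray:
    gram = np.clip(pos @ pos.T, -1.0, 1.0)
    dist = np.arccos(gram)
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    cap = ADJACENCY_FACTOR * float(np.median(nn))
    adj = dist <= cap
    np.fill_diagonal(adj, False)
    return adj


def build_positions_129() -> tuple[list[str], np.ndarray]:
    """Deterministically construct the synthetic 129-sensor layout."""
    placed = {k: _unit(*v) for k, v in _PLACED.items()}
    taken = np.array(list(placed.values()))
    # Fibonacci spiral over the scalp cap, skipping points too close to
    # hand-placed sensors; golden-angle azimuth, polar angle 0..112 deg.
    golden = np.pi * (3.0 - np.sqrt(5.0))
    candidates = []
    n_spiral = 220
    for k in range(n_spiral):
        # area-uniform in cos(theta) over the cap
        c = 1.0 - (1.0 - np.cos(np.deg2rad(112.0))) * (k + 0.5) / n_spiral
        th = np.arccos(c)
        ph = (k * golden) % (2 * np.pi)
        candidates.append(
            np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])
        )
    min_sep = np.cos(np.deg2rad(9.0))
    fillers = []
    for p in candidates:
        if taken.size and (taken @ p).max() > min_sep:
            continue
        fillers.append(p)
        taken = np.vstack([taken, p])
    free_ids = [str(i) for i in range(1, 130) if str(i) not in _PLACED]
    if len(fillers) < len(free_ids):  # pragma: no cover - construction guard
        raise ConfigurationError("spiral produced too few filler positions")
    ids = list(_PLACED) + free_ids
    pos = np.vstack([np.array(list(placed.values())), np.array(fillers[: len(free_ids)])])
    order = np.argsort([int(i) for i in ids])
    return [ids[i] for i in order], pos[order]


def _montage_from_rows(rows) -> SensorMontage:
    ids = [r[0] for r in rows]
    pos = np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorMontage(
        ids=ids,
        positions=pos,
        adjacency=_adjacency_from_positions(pos),
        ocular_ids=tuple(i for i in OCULAR_IDS if i in ids),
        names=dict(LANDMARKS),
    )


def montage_129() -> SensorMontage:
    """Full 129-sensor layout, loaded from the packaged coordinates file."""
    ref = resources.files("ssvepbf.data").joinpath("montage129_synthetic.csv")
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        rows = list(reader)
    return _montage_from_rows(rows)


#: ids retained in the reduced test layout: all landmarks, the reported
#: cluster members, the ocular channels, plus frontal/temporal fillers.
MONTAGE_32_IDS = [
    "129", "62", "75", "70", "65", "66", "69", "83", "84", "89", "90",
    "36", "35", "30", "29", "104", "105", "87", "80", "47", "52",
    "8", "25", "126", "127",
    "28", "108", "110", "122", "125", "15", "72",
]


def montage_32() -> SensorMontage:
    """Reduced 32-sensor layout for fast tests and the CI profile."""
    return montage_129().subset(MONTAGE_32_IDS)
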