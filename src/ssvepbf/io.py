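"""HDF5 container with JSON metadata sidecar.

Schema (one group per object kind, schema version in the sidecar):

* ``/data``         float array (raw: channels x samples; epochs:
                    trials x channels x time; pupil: trials x time)
* ``/times_ms``     time axis where applicable
* ``/labels_json``  per-trial labels / events, a pandas DataFrame
                    serialised with ``orient="split"``
* ``/montage/{ids,positions,ocular}``  enough to rebuild the montage
                    (adjacency is recomputed by rule on load)

The sidecar ``<file>.json`` repeats the shape/rate metadata and the
provenance log so containers are inspectable without HDF5 tooling.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, PupilRaw, RawRecording
from .montage import SensorMontage, _adjacency_from_positions, LANDMARKS

SCHEMA_VERSION = 1


def _write_labels(g: h5py.Group, df: pd.DataFrame) -> None:
    g.create_dataset("labels_json", data=df.to_json(orient="split"))


def _read_labels(g: h5py.Group) -> pd.DataFrame:
    raw = g["labels_json"][()]
    if isinstance(raw, bytes):
        raw = raw.decode()
    return pd.read_json(StringIO(raw), orient="split").reset_index(drop=True)


def _write_montage(g: h5py.Group, montage: SensorMontage) -> None:
    mg = g.create_group("montage")
    mg.create_dataset("ids", data=np.array(montage.ids, dtype="S"))
    mg.create_dataset("positions", data=montage.positions)
    mg.create_dataset("ocular", data=np.array(montage.ocular_ids, dtype="S"))


def _read_montage(g: h5py.Group) -> SensorMontage:
    mg = g["montage"]
    ids = [s.decode() for s in mg["ids"][()]]
    pos = mg["positions"][()]
    ocular = tuple(s.decode() for s in mg["ocular"][()])
    return SensorMontage(
        ids=ids,
        positions=pos,
        adjacency=_adjacency_from_positions(pos),
        ocular_ids=ocular,
        names={k: v for k, v in LANDMARKS.items() if v in ids},
    )


def _sidecar(path: Path, meta: dict) -> None:
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def save_raw(path, raw: RawRecording) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "raw"
        f.attrs["rate_hz"] = raw.rate_hz
        f.create_dataset("data", data=raw.data, compression="gzip", compression_opts=1)
        _write_labels(f, raw.events)
        _write_montage(f, raw.montage)
    _sidecar(path, {
        "schema_version": SCHEMA_VERSION, "kind": "raw",
        "rate_hz": raw.rate_hz, "shape": list(raw.data.shape),
        "ocular_ids": list(raw.ocular_ids), "provenance": raw.provenance,
    })


def load_raw(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        montage = _read_montage(f)
        raw = RawRecording(
            data=f["data"][()], rate_hz=float(f.attrs["rate_hz"]),
            montage=montage, events=_read_labels(f),
            ocular_ids=montage.ocular_ids,
        )
    meta = json.loads(Path(str(path) + ".json").read_text())
    raw.provenance = list(meta.get("provenance", []))
    return raw


def save_epochs(path, epochs: EpochSet) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "epochs"
        f.attrs["rate_hz"] = epochs.rate_hz
        f.create_dataset("data", data=epochs.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("times_ms", data=epochs.times_ms)
        _write_labels(f, epochs.labels)
        _write_montage(f, epochs.montage)
    _sidecar(path, {
        "schema_version": SCHEMA_VERSION, "kind": "epochs",
        "rate_hz": epochs.rate_hz, "shape": list(epochs.data.shape),
        "provenance": epochs.provenance,
    })


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        epochs = EpochSet(
            data=f["data"][()], times_ms=f["times_ms"][()],
            labels=_read_labels(f), montage=_read_montage(f),
            rate_hz=float(f.attrs["rate_hz"]),
        )
    meta = json.loads(Path(str(path) + ".json").read_text())
    epochs.provenance = list(meta.get("provenance", []))
    return epochs


def save_pupil(path, pupil: PupilRaw) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "pupil"
        f.attrs["rate_hz"] = pupil.rate_hz
        f.create_dataset("data", data=pupil.traces, compression="gzip",
                         compression_opts=1)
        f.create_dataset("times_ms", data=pupil.times_ms)
        _write_labels(f, pupil.labels)
    _sidecar(path, {
        "schema_version": SCHEMA_VERSION, "kind": "pupil",
        "rate_hz": pupil.rate_hz, "shape": list(pupil.traces.shape),
        "provenance": pupil.provenance,
    })


def load_pupil(path) -> PupilRaw:
    with h5py.File(path, "r") as f:
        pupil = PupilRaw(
            traces=f["data"][()], times_ms=f["times_ms"][()],
            labels=_read_labels(f), rate_hz=float(f.attrs["rate_hz"]),
        )
    meta = json.loads(Path(str(path) + ".json").read_text())
    pupil.provenance = list(meta.get("provenance", []))
    return pupil
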