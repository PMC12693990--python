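"""Dataset persistence and run manifests.

Two interchange formats: a compressed array bundle (``.npz``, lossless) and a
human-readable long-format CSV (``sample_id, electrode, sample_index,
current_mA, label``).  Bundle round-trips are bit-exact; CSV round-trips are
exact to the 17-significant-digit decimal representation (< 1e-9 absolute for
currents in the tens of mA).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Dataset, SampleRecord
from .waveform import WaveformSpec, spec_from_yaml, spec_to_yaml

__all__ = ["write_dataset", "read_dataset", "dataset_hash", "write_manifest"]


def dataset_hash(ds: Dataset) -> str:
    """SHA-256 of the concatenated currents + labels, for manifests."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(ds.X_concat).tobytes())
    h.update(np.ascontiguousarray(ds.y).tobytes())
    return h.hexdigest()


def write_dataset(ds: Dataset, path) -> None:
    """Write a dataset; format chosen by extension (.npz bundle or .csv long)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            X_concat=ds.X_concat,
            y=ds.y,
            electrode_names=np.array(ds.electrode_names),
            waveform_spec_yaml=np.array(spec_to_yaml(ds.waveform_spec)),
        )
    elif path.suffix == ".csv":
        L = ds.n_samples_per_electrode
        frames = []
        for sid, rec in enumerate(ds.records):
            for ei, e in enumerate(ds.electrode_names):
                frames.append(
                    pd.DataFrame(
                        {
                            "sample_id": sid,
                            "electrode": e,
                            "sample_index": np.arange(L),
                            "current_mA": rec.currents[ei],
                            "label": rec.label,
                        }
                    )
                )
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.17g"
        )
    else:
        raise ValueError(f"unrecognized dataset extension {path.suffix!r} "
                         "(expected .npz or .csv)")


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            X = z["X_concat"]
            y = z["y"]
            names = tuple(str(n) for n in z["electrode_names"])
            spec = spec_from_yaml(str(z["waveform_spec_yaml"]))
        return _from_matrix(X, y, names, spec)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        required = {"sample_id", "electrode", "sample_index", "current_mA", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"CSV missing columns: {sorted(missing)}")
        names = tuple(dict.fromkeys(df["electrode"]))  # first-appearance order
        sids = np.sort(df["sample_id"].unique())
        L = int(df["sample_index"].max()) + 1
        X = np.empty((len(sids), len(names) * L))
        y = np.empty(len(sids), dtype=df["label"].dtype)
        for r, sid in enumerate(sids):
            sub = df[df["sample_id"] == sid]
            if len(sub) != len(names) * L:
                raise ValueError(
                    f"sample {sid}: expected {len(names)} x {L} rows, found {len(sub)}"
                )
            for ei, e in enumerate(names):
                seg = sub[sub["electrode"] == e].sort_values("sample_index")
                X[r, ei * L : (ei + 1) * L] = seg["current_mA"].to_numpy()
            y[r] = sub["label"].iloc[0]
        return _from_matrix(X, y, names, WaveformSpec())
    raise ValueError(f"unrecognized dataset extension {path.suffix!r} "
                     "(expected .npz or .csv)")


def _from_matrix(X, y, names, spec) -> Dataset:
    n_e = len(names)
    if X.ndim != 2 or X.shape[1] % n_e:
        raise ValueError(
            f"matrix shape {X.shape} inconsistent with {n_e} electrodes: "
            f"expected columns divisible by {n_e}"
        )
    L = X.shape[1] // n_e
    records = tuple(
        SampleRecord(label=y[i].item() if hasattr(y[i], "item") else y[i],
                     currents=X[i].reshape(n_e, L))
        for i in range(len(X))
    )
    return Dataset(records=records, electrode_names=tuple(names), waveform_spec=spec)


def write_manifest(path, **entries) -> dict:
    """Write a JSON run manifest (seeds, hashes, sizes, timestamps)."""
    payload = dict(entries)
    payload.setdefault(
        "created", datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return payload
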