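"""HDF5 / CSV readers and writers for recordings and trial epochs.

Raw-recording container layout::

    /intensity/wl1   (channels x samples)   attrs: wavelength_nm
    /intensity/wl2   (channels x samples)
    /events/onset    (n,) int               sample indices
    /events/label    (n,) str
    attrs: fs, subject_id

Epochs files store ``/trials/{i}/data`` with label/subject/fs attributes; a
JSON sidecar (``<file>.json``) records the full preprocessing configuration
for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import HemoSignal, RawRecording, TrialEpoch


def write_raw_h5(raw: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("intensity")
        for i, name in enumerate(("wl1", "wl2")):
            ds = grp.create_dataset(name, data=raw.intensity[i])
            ds.attrs["wavelength_nm"] = raw.wavelengths[i]
        ev = f.create_group("events")
        ev.create_dataset("onset", data=np.array([o for o, _ in raw.events], dtype=np.int64))
        ev.create_dataset("label", data=np.array([l for _, l in raw.events], dtype="S8"))
        f.attrs["fs"] = raw.fs
        f.attrs["subject_id"] = raw.subject_id


def read_raw_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        wl = (float(f["intensity/wl1"].attrs["wavelength_nm"]),
              float(f["intensity/wl2"].attrs["wavelength_nm"]))
        intensity = np.stack([f["intensity/wl1"][()], f["intensity/wl2"][()]])
        onsets = f["events/onset"][()]
        labels = [l.decode() for l in f["events/label"][()]]
        return RawRecording(intensity=intensity, wavelengths=wl,
                            fs=float(f.attrs["fs"]),
                            events=list(zip(onsets.tolist(), labels)),
                            subject_id=str(f.attrs["subject_id"]))


def read_raw_csv(intensity_csv, events_csv, fs: float,
                 wavelengths: tuple[float, float]) -> RawRecording:
    """Long-format reader: columns (subject, channel, wavelength, sample_index,
    value) plus an events table (onset_sample, class_label)."""
    df = pd.read_csv(intensity_csv)
    required = {"subject", "channel", "wavelength", "sample_index", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"intensity CSV must have columns {sorted(required)}")
    subjects = df["subject"].unique()
    if subjects.size != 1:
        raise ValueError(f"expected a single subject per CSV, got {subjects.tolist()}")
    channels = np.sort(df["channel"].unique())
    wls = np.sort(df["wavelength"].unique())
    if wls.size != 2:
        raise ValueError(f"expected exactly two wavelengths, got {wls.tolist()}")
    n_samples = int(df["sample_index"].max()) + 1
    intensity = np.full((2, channels.size, n_samples), np.nan)
    ch_pos = {c: i for i, c in enumerate(channels)}
    wl_pos = {w: i for i, w in enumerate(wls)}
    intensity[df["wavelength"].map(wl_pos), df["channel"].map(ch_pos),
              df["sample_index"]] = df["value"]
    if np.isnan(intensity).any():
        raise ValueError("intensity CSV does not cover every (wavelength, channel, sample)")
    ev = pd.read_csv(events_csv)
    events = list(zip(ev["onset_sample"].astype(int), ev["class_label"]))
    return RawRecording(intensity=intensity, wavelengths=wavelengths, fs=fs,
                        events=events, subject_id=str(subjects[0]))


def write_epochs_h5(trials: list[TrialEpoch], path, config: dict | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("trials")
        for i, tr in enumerate(trials):
            ds = grp.create_dataset(str(i), data=tr.data)
            ds.attrs["class_label"] = tr.class_label
            ds.attrs["subject_id"] = tr.subject_id
            ds.attrs["fs"] = tr.fs
            ds.attrs["t0_offset"] = tr.t0_offset
            ds.attrs["channels"] = np.asarray(tr.channels, dtype=np.int64)
            ds.attrs["signal_kind"] = tr.signal_kind
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config or {}, indent=2, default=str))


def read_epochs_h5(path) -> list[TrialEpoch]:
    trials = []
    with h5py.File(path, "r") as f:
        grp = f["trials"]
        for key in sorted(grp, key=int):
            ds = grp[key]
            trials.append(TrialEpoch(
                data=ds[()], fs=float(ds.attrs["fs"]),
                t0_offset=float(ds.attrs["t0_offset"]),
                class_label=str(ds.attrs["class_label"]),
                subject_id=str(ds.attrs["subject_id"]),
                channels=tuple(int(c) for c in ds.attrs["channels"]),
                signal_kind=str(ds.attrs["signal_kind"])))
    return trials


def write_hemo_h5(sig: HemoSignal, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dHbO", data=sig.dHbO)
        f.create_dataset("dHbR", data=sig.dHbR)
        ev = f.create_group("events")
        ev.create_dataset("onset", data=np.array([o for o, _ in sig.events], dtype=np.int64))
        ev.create_dataset("label", data=np.array([l for _, l in sig.events], dtype="S8"))
        f.attrs["fs"] = sig.fs
        f.attrs["subject_id"] = sig.subject_id


def read_hemo_h5(path) -> HemoSignal:
    with h5py.File(path, "r") as f:
        onsets = f["events/onset"][()]
        labels = [l.decode() for l in f["events/label"][()]]
        return HemoSignal(dHbO=f["dHbO"][()], dHbR=f["dHbR"][()],
                          fs=float(f.attrs["fs"]),
                          events=list(zip(onsets.tolist(), labels)),
                          subject_id=str(f.attrs["subject_id"]))
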