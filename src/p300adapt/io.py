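"""Readers and writers: EDF for continuous EEG, HDF5 for epoch containers.

EDF reading is delegated to :func:`mne.io.read_raw_edf`; writing uses a
minimal built-in EDF encoder (16-bit, one data record per second with an
optional fractional final record) sufficient for lossless-within-quantization
round trips. Stimulus events travel either as EDF+ annotations (read only)
or as a sidecar tab-separated file with columns ``sample_index`` and
``label`` — the convention this project uses when writing.

The epoch container is a single HDF5 file with datasets ``epochs``,
``times_ms``, ``channel_names`` and optionally ``labels`` and ``baseline``,
plus attributes ``subject_id``, ``domain_tag``, ``sampling_rate`` and
``schema_version``. Unknown extra datasets/attributes from newer minor
schema versions are ignored on read.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .containers import (
    ContinuousRecording,
    EpochSet,
    EventMarker,
    SchemaError,
    NONTARGET,
    TARGET,
)

SCHEMA_VERSION = "1.0"


class EDFFormatError(ValueError):
    """File is not a valid EDF/EDF+ file; the message names the bad field."""


class UnsupportedLayoutError(ValueError):
    """Valid EDF, but a layout this reader does not support (e.g. mixed rates)."""


# ---------------------------------------------------------------------------
# events sidecar


def read_events_tsv(path: str | os.PathLike) -> list[EventMarker]:
    """Read a sidecar events file (TSV columns: sample_index, label)."""
    events: list[EventMarker] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["sample_index", "label"]:
            raise SchemaError(
                f"events file must start with 'sample_index\\tlabel', got {header!r}"
            )
        for line in fh:
            if not line.strip():
                continue
            idx, label = line.strip().split("\t")[:2]
            events.append(EventMarker(int(idx), label))
    return events


def write_events_tsv(events: list[EventMarker], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_index\tlabel\n")
        for ev in events:
            fh.write(f"{ev.sample_index}\t{ev.label}\n")


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value: str, width: int, field_name: str) -> bytes:
    out = value.encode("ascii")
    if len(out) > width:
        raise EDFFormatError(f"EDF header field {field_name!r} too long: {value!r}")
    return out.ljust(width)


def write_edf(recording: ContinuousRecording, path: str | os.PathLike,
              events_path: Optional[str | os.PathLike] = None) -> None:
    """Write a recording as plain 16-bit EDF.

    Physical min/max are taken per channel from the data, so the
    quantization step is ``(pmax - pmin) / (2**16 - 1)``. Events are written
    to ``events_path`` (defaults to ``<path>.events.tsv``) as a sidecar TSV.
    """
    path = Path(path)
    x = recording.samples
    n_samples, n_ch = x.shape
    fs = recording.sampling_rate
    # One record per second keeps reader compatibility; a short final record
    # is avoided by padding declared in n_records only when evenly divisible.
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        # non-integer rate: single record holding everything
        spr = n_samples
        n_records = 1
        record_dur = n_samples / fs
    else:
        if n_samples % spr:
            pad = spr - (n_samples % spr)
            x = np.vstack([x, np.repeat(x[-1:, :], pad, axis=0)])
            warnings.warn(
                f"padding recording by {pad} samples to fill the last EDF record",
                stacklevel=2,
            )
            n_samples = x.shape[0]
        n_records = n_samples // spr
        record_dur = 1.0

    pmin = x.min(axis=0)
    pmax = x.max(axis=0)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((x - pmin) / scale + dmin).astype("<i2")

    header = bytearray()
    header += _edf_field("0", 8, "version")
    header += _edf_field(recording.subject_id or "X", 80, "patient")
    header += _edf_field("Startdate X", 80, "recording")
    header += _edf_field("01.01.00", 8, "startdate")
    header += _edf_field("00.00.00", 8, "starttime")
    header += _edf_field(str(256 * (1 + n_ch)), 8, "header_bytes")
    header += _edf_field("", 44, "reserved")
    header += _edf_field(str(n_records), 8, "n_records")
    dur_str = f"{record_dur:.6f}".rstrip("0").rstrip(".") if record_dur != int(record_dur) else str(int(record_dur))
    header += _edf_field(dur_str[:8], 8, "record_duration")
    header += _edf_field(str(n_ch), 4, "n_signals")

    def per_channel(fmt, width, name):
        for value in fmt:
            header.extend(_edf_field(value, width, name))

    per_channel([ch for ch in recording.channel_names], 16, "label")
    per_channel(["" for _ in range(n_ch)], 80, "transducer")
    per_channel(["uV" for _ in range(n_ch)], 8, "dimension")
    per_channel([f"{v:.8g}"[:8] for v in pmin], 8, "physical_min")
    per_channel([f"{v:.8g}"[:8] for v in pmax], 8, "physical_max")
    per_channel([str(dmin) for _ in range(n_ch)], 8, "digital_min")
    per_channel([str(dmax) for _ in range(n_ch)], 8, "digital_max")
    per_channel(["" for _ in range(n_ch)], 80, "prefiltering")
    per_channel([str(spr) for _ in range(n_ch)], 8, "samples_per_record")
    per_channel(["" for _ in range(n_ch)], 32, "reserved_signal")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[r * spr:(r + 1) * spr, :]
            fh.write(block.T.tobytes())  # EDF stores each signal contiguously

    if events_path is None:
        events_path = str(path) + ".events.tsv"
    if recording.events:
        write_events_tsv(recording.events, events_path)


def read_edf(path: str | os.PathLike,
             events_path: Optional[str | os.PathLike] = None,
             reorder_to_montage: bool = False) -> ContinuousRecording:
    """Read an EDF/EDF+ file into a :class:`ContinuousRecording`.

    Samples are returned in microvolts and in the file's channel order
    (``reorder_to_montage=True`` permutes into the canonical montage).
    Events come from, in priority order: the explicit ``events_path``
    sidecar, a ``<path>.events.tsv`` sidecar if present, else EDF+
    annotations whose description is ``target``/``nontarget``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size < 256:
        raise EDFFormatError(f"{path}: file shorter than the 256-byte EDF header")
    with open(path, "rb") as fh:
        version = fh.read(8)
    if not version.startswith(b"0"):
        raise EDFFormatError(f"{path}: bad EDF version field {version!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # surface mne's parse failure with context
            raise EDFFormatError(f"{path}: not readable as EDF ({exc})") from exc
    rates = {info_ch["sfreq"] if "sfreq" in info_ch else raw.info["sfreq"] for info_ch in [raw.info]}
    if len(rates) != 1:
        raise UnsupportedLayoutError("mixed per-channel sampling rates are unsupported")

    data = raw.get_data().T * 1e6  # mne returns volts
    names = list(raw.ch_names)

    events: list[EventMarker] = []
    sidecar = Path(events_path) if events_path else Path(str(path) + ".events.tsv")
    if sidecar.exists():
        events = read_events_tsv(sidecar)
    elif len(raw.annotations):
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
            if desc in (TARGET, NONTARGET):
                events.append(EventMarker(int(round(onset * raw.info["sfreq"])), desc))

    rec = ContinuousRecording(
        samples=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=names,
        subject_id=str(path.stem),
        events=events,
    )
    if reorder_to_montage:
        rec = rec.reorder_channels()
    return rec


def edf_quantization_step(recording: ContinuousRecording) -> np.ndarray:
    """Per-channel digitization step of :func:`write_edf` for this data."""
    pmin = recording.samples.min(axis=0)
    pmax = recording.samples.max(axis=0)
    pmax = np.where(pmax - pmin < 1e-12, pmin + 1.0, pmax)
    return (pmax - pmin) / (2**16 - 1)


# ---------------------------------------------------------------------------
# epoch container (HDF5)


def write_epochs(epoch_set: EpochSet, path: str | os.PathLike) -> None:
    """Write an :class:`EpochSet` losslessly to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epoch_set.epochs)
        f.create_dataset("times_ms", data=epoch_set.times_ms)
        f.create_dataset(
            "channel_names",
            data=np.array([c.encode() for c in epoch_set.channel_names]),
        )
        if epoch_set.labels is not None:
            f.create_dataset("labels", data=epoch_set.labels)
        if epoch_set.baseline is not None:
            f.create_dataset("baseline", data=epoch_set.baseline)
        f.attrs["subject_id"] = epoch_set.subject_id
        f.attrs["domain_tag"] = epoch_set.domain_tag
        f.attrs["sampling_rate"] = epoch_set.sampling_rate
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_epochs(path: str | os.PathLike) -> EpochSet:
    """Read an epoch container; unknown extra fields are ignored."""
    with h5py.File(path, "r") as f:
        for ds in ("epochs", "times_ms", "channel_names"):
            if ds not in f:
                raise SchemaError(f"{path}: missing required dataset {ds!r}")
        for attr in ("subject_id", "domain_tag", "sampling_rate"):
            if attr not in f.attrs:
                raise SchemaError(f"{path}: missing required attribute {attr!r}")
        return EpochSet(
            epochs=f["epochs"][()],
            times_ms=f["times_ms"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_names=[c.decode() for c in f["channel_names"][()]],
            subject_id=str(f.attrs["subject_id"]),
            domain_tag=str(f.attrs["domain_tag"]),
            labels=f["labels"][()] if "labels" in f else None,
            baseline=f["baseline"][()] if "baseline" in f else None,
        )
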