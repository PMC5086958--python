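"""Readers and writers: BrainVision triplets and the epoch container.

BrainVision recordings (.vhdr/.vmrk/.eeg) are read through mne. A
minimal writer (INT16 multiplexed, one resolution per channel) is
provided for fixture round trips; it is not a general-purpose exporter.
Epochs round-trip losslessly through an HDF5 container that stores the
voltage array, labels, time axis, rejection mask and provenance log.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import ContinuousEEG, EpochedEEG

__all__ = [
    "read_brainvision",
    "write_brainvision",
    "write_epochs",
    "read_epochs",
    "CONTAINER_VERSION",
]

CONTAINER_VERSION = 1


def read_brainvision(header_path: str | Path) -> ContinuousEEG:
    """Read a BrainVision triplet into a continuous recording (μV).

    The companion .vmrk and .eeg files named in the header must exist
    and the binary payload must be a whole number of multiplexed frames
    (silently truncated files are rejected). Markers become
    ``(sample_index, label)`` events; "Stimulus/TMS" markers map to the
    label ``"TMS"``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"missing header file: {header_path}")
    fields = {}
    for line in header_path.read_text(encoding="utf-8", errors="replace").splitlines():
        if "=" in line and not line.startswith(";"):
            key, _, val = line.partition("=")
            fields.setdefault(key.strip(), val.strip())
    for key in ("DataFile", "MarkerFile"):
        if key not in fields:
            raise ValueError(f"header lacks {key} entry: {header_path}")
        companion = header_path.parent / fields[key]
        if not companion.exists():
            raise FileNotFoundError(f"missing companion file: {companion}")
    n_ch = int(fields.get("NumberOfChannels", 0))
    data_file = header_path.parent / fields["DataFile"]
    frame_bytes = 2 * n_ch  # INT16 multiplexed
    if n_ch and data_file.stat().st_size % frame_bytes != 0:
        raise ValueError(
            f"truncated data file {data_file}: {data_file.stat().st_size} bytes "
            f"is not a whole number of {frame_bytes}-byte frames")

    import mne

    raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> μV
    events = []
    for ann in raw.annotations:
        label = ann["description"]
        if "/" in label:
            label = label.split("/", 1)[1]
        if label == "New Segment":
            continue
        events.append((int(round(ann["onset"] * raw.info["sfreq"])), label))
    eeg = ContinuousEEG(data, float(raw.info["sfreq"]), list(raw.ch_names), events)
    eeg.log("read_brainvision", path=str(header_path))
    return eeg


def write_brainvision(
    continuous: ContinuousEEG,
    stem: str | Path,
    resolution: float = 0.1,
) -> Path:
    """Write a minimal INT16 multiplexed BrainVision triplet.

    ``resolution`` is the μV-per-bit quantization step. Values are
    clipped to the int16 range. Returns the header path.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    name = stem.name
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = continuous.n_channels
    header = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / continuous.sfreq:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=INT_16",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(continuous.channel_labels, start=1):
        header.append(f"Ch{i}={ch},,{resolution},µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for j, (sample, label) in enumerate(continuous.events, start=2):
        markers.append(f"Mk{j}=Stimulus,{label},{sample + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    quantized = np.clip(np.round(continuous.data / resolution), -32768, 32767)
    quantized.astype("<i2").T.tofile(eeg)  # multiplexed: sample-major
    return vhdr


def write_epochs(epochs: EpochedEEG, path: str | Path) -> Path:
    """Write epochs to the HDF5 container (lossless round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "tmseeg-epochs"
        f.attrs["version"] = CONTAINER_VERSION
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["tmin"] = epochs.tmin
        f.attrs["channel_labels"] = json.dumps(epochs.channel_labels)
        f.attrs["provenance"] = json.dumps(epochs.provenance)
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("rejection_mask", data=epochs.rejection_mask)
    return path


def read_epochs(path: str | Path) -> EpochedEEG:
    """Read epochs from the HDF5 container; rejects newer versions."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "tmseeg-epochs":
            raise ValueError(f"{path} is not a tmseeg epoch container")
        version = int(f.attrs["version"])
        if version > CONTAINER_VERSION:
            raise ValueError(
                f"container version {version} is newer than supported "
                f"version {CONTAINER_VERSION}")
        epochs = EpochedEEG(
            f["data"][()],
            float(f.attrs["sfreq"]),
            float(f.attrs["tmin"]),
            json.loads(f.attrs["channel_labels"]),
            f["rejection_mask"][()],
            json.loads(f.attrs["provenance"]),
        )
    return epochs
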