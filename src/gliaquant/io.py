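"""Readers and writers for volumes and spike recordings.

Volumes are stored as multi-page TIFF with a JSON sidecar
(``<stem>.json``) carrying the voxel size in µm, channel names, and — for
phantoms — the ground truth. Voxel size can alternatively come from
OME-TIFF metadata; a volume without any voxel-size source is an error.
Spike recordings round-trip through JSON (with a flat-CSV export of the
spike times).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .ephys import CellRecording, StimulusEpoch
from .imaging import VolumeImage
from .synthdata import PhantomGroundTruth

__all__ = [
    "write_volume",
    "read_volume",
    "read_ground_truth",
    "write_recording",
    "read_recording",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(
    path: str | Path,
    volume: VolumeImage,
    ground_truth: PhantomGroundTruth | None = None,
) -> Path:
    """Write a volume as float32 TIFF plus a JSON sidecar; returns the sidecar path."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume.data, dtype=np.float32), photometric="minisblack")
    meta: dict[str, Any] = {
        "voxel_size_um": list(volume.voxel_size),
        "channel_names": list(volume.channel_names),
    }
    if ground_truth is not None:
        meta["ground_truth"] = ground_truth.to_dict()
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_volume(path: str | Path, channel_order: list[str] | None = None) -> VolumeImage:
    """Read a TIFF volume with voxel metadata.

    Voxel size and channel names come from the JSON sidecar when present,
    otherwise from OME metadata. A missing voxel size is a hard error —
    volumes are meaningless without physical scale. ``channel_order``
    optionally reorders/subsets channels by name.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 3-D or 4-D TIFF, got shape {data.shape}")

    sidecar = _sidecar_path(path)
    voxel_size = None
    channel_names = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = meta.get("voxel_size_um")
        channel_names = meta.get("channel_names")
    else:
        with tifffile.TiffFile(path) as tf:
            ome = tf.ome_metadata
        if ome:
            voxel_size = _ome_voxel_size(ome)
    if voxel_size is None:
        raise ValueError(
            f"{path}: no voxel size found; provide a sidecar {sidecar.name} with "
            "field 'voxel_size_um' or OME PhysicalSize metadata"
        )
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[0])]
    vol = VolumeImage(data, tuple(voxel_size), tuple(channel_names))
    if channel_order is not None:
        idx = []
        for name in channel_order:
            if name not in vol.channel_names:
                raise KeyError(
                    f"{path}: channel map references {name!r}, not among {list(vol.channel_names)}"
                )
            idx.append(vol.channel_names.index(name))
        vol = VolumeImage(vol.data[idx], vol.voxel_size, tuple(channel_order))
    return vol


def _ome_voxel_size(ome_xml: str) -> tuple[float, float, float] | None:
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome_xml)
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            try:
                return (
                    float(elem.attrib["PhysicalSizeZ"]),
                    float(elem.attrib["PhysicalSizeY"]),
                    float(elem.attrib["PhysicalSizeX"]),
                )
            except KeyError:
                return None
    return None


def read_ground_truth(path: str | Path) -> PhantomGroundTruth:
    """Load phantom ground truth from a volume's JSON sidecar."""
    sidecar = _sidecar_path(Path(path))
    meta = json.loads(sidecar.read_text())
    if "ground_truth" not in meta:
        raise ValueError(f"{sidecar}: no 'ground_truth' field")
    return PhantomGroundTruth(**meta["ground_truth"])


def write_recording(path: str | Path, recording: CellRecording) -> Path:
    """Write a spike recording as JSON; also emits ``<stem>.spikes.csv``."""
    path = Path(path)
    doc = {
        "spike_times": [float(t) for t in recording.spike_times],
        "epochs": [
            {
                "kind": e.kind,
                "onset": e.onset,
                "duration": e.duration,
                "trial": e.trial,
                "filament_index": e.filament_index,
            }
            for e in recording.epochs
        ],
        "depth_um": recording.depth,
        "receptive_field_mm": recording.receptive_field,
        "animal": recording.animal,
        "group": recording.group,
    }
    path.write_text(json.dumps(doc, indent=1))
    csv_path = path.with_suffix(".spikes.csv")
    lines = ["spike_time_s"] + [repr(float(t)) for t in recording.spike_times]
    csv_path.write_text("\n".join(lines) + "\n")
    return path


def read_recording(path: str | Path) -> CellRecording:
    doc = json.loads(Path(path).read_text())
    epochs = [
        StimulusEpoch(
            kind=e["kind"],
            onset=e["onset"],
            duration=e["duration"],
            trial=e.get("trial", 0),
            filament_index=e.get("filament_index"),
        )
        for e in doc.get("epochs", [])
    ]
    rf = doc.get("receptive_field_mm")
    return CellRecording(
        spike_times=np.asarray(doc["spike_times"], dtype=float),
        epochs=epochs,
        depth=doc.get("depth_um"),
        receptive_field=[tuple(v) for v in rf] if rf else None,
        animal=doc.get("animal"),
        group=doc.get("group"),
    )
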