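"""Quantification of 3D multi-channel fluorescence volumes.

Measures microglial engulfment as nested intersection volumes
(fiber ∩ lysosome ∩ microglia) and synaptic puncta counts/volumes from
binarized z-stacks, per rectangular ROI, with per-channel threshold
provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "RoiSpec",
    "EngulfmentResult",
    "PunctaResult",
    "binarize_channel",
    "intersect_masks",
    "mask_volume",
    "crop_roi",
    "quantify_engulfment",
    "quantify_puncta",
    "batch_quantify",
]

#: 26-connected neighborhood used for 3-D component labeling.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VolumeImage:
    """A multi-channel 3-D voxel grid with physical voxel sizes.

    Parameters
    ----------
    data :
        Intensity array of shape ``(channel, z, y, x)``; non-negative.
    voxel_size :
        Voxel edge lengths in µm, ordered ``(dz, dy, dx)``.
    channel_names :
        One label per channel.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 4:
            raise ValueError(f"expected (c, z, y, x) data, got shape {data.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be 3 positive values, got {self.voxel_size}")
        if len(self.channel_names) != data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {data.shape[0]} channels"
            )
        if data.size and float(data.min()) < 0:
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3-D intensity grid for channel ``name``."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}"
            ) from None
        return self.data[idx]


@dataclass(frozen=True)
class BinaryMask:
    """A 3-D boolean grid carrying the voxel size of its source volume."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    threshold_method: str | None = None
    threshold_value: float | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise ValueError(f"expected 3-D mask, got shape {data.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be 3 positive values, got {self.voxel_size}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest given in µm in the (y, x) plane.

    ``origin`` is the (y, x) corner in µm, ``extent`` the (height, width) in
    µm. ``z_range`` is either ``None`` (full stack) or an explicit half-open
    voxel slice interval ``(z0, z1)``.
    """

    name: str
    origin: tuple[float, float] = (0.0, 0.0)
    extent: tuple[float, float] | None = None
    z_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.extent is not None and any(e <= 0 for e in self.extent):
            raise ValueError(f"ROI extent must be positive, got {self.extent}")
        if self.z_range is not None and self.z_range[1] <= self.z_range[0]:
            raise ValueError(f"empty z_range {self.z_range}")


@dataclass(frozen=True)
class EngulfmentResult:
    """Per-ROI engulfment volumes in µm³ with threshold provenance.

    ``lysosome_volume`` is the volume of the lysosome signal restricted to
    microglia; ``engulfed_volume`` is fiber signal inside that compartment.
    The nesting ``engulfed <= lysosome <= microglia`` holds by construction.
    """

    roi: str
    microglia_volume: float
    lysosome_volume: float
    engulfed_volume: float
    threshold_record: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.engulfed_volume <= self.lysosome_volume <= self.microglia_volume):
            raise ValueError(
                "nesting violated: engulfed="
                f"{self.engulfed_volume} lysosome={self.lysosome_volume} "
                f"microglia={self.microglia_volume}"
            )


@dataclass(frozen=True)
class PunctaResult:
    """Per-ROI puncta count and total volume (µm³)."""

    roi: str
    count: int
    total_volume: float
    size_filter: int = 0
    threshold_record: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.count < 0 or self.total_volume < 0:
            raise ValueError("count and total_volume must be >= 0")
        if (self.count == 0) != (self.total_volume == 0.0):
            raise ValueError("count == 0 iff total_volume == 0")


def binarize_channel(
    volume: VolumeImage,
    channel: str,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> BinaryMask:
    """Binarize one channel of a volume.

    ``method='otsu'`` picks the Otsu threshold from the channel histogram and
    keeps voxels strictly above it; ``method='fixed'`` keeps voxels at or
    above ``fixed_value``. The method and value used are recorded on the
    returned mask for provenance.
    """
    data = volume.channel(channel)
    if method == "otsu":
        if fixed_value is not None:
            raise ValueError("fixed_value is only valid with method='fixed'")
        if data.size == 0 or float(data.max()) == float(data.min()):
            raise ValueError(
                f"channel {channel!r} has constant intensity; Otsu thresholding is "
                "undefined — use method='fixed' with an explicit threshold"
            )
        thr = float(threshold_otsu(data))
        mask = data > thr
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        thr = float(fixed_value)
        mask = data >= thr
    else:
        raise ValueError(f"unknown method {method!r}; expected 'otsu' or 'fixed'")
    return BinaryMask(mask, volume.voxel_size, threshold_method=method, threshold_value=thr)


def intersect_masks(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Voxelwise logical AND of two or more masks of identical geometry."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to intersect")
    first = masks[0]
    out = first.data.copy()
    for m in masks[1:]:
        if m.data.shape != first.data.shape:
            raise ValueError(f"mask shape mismatch: {m.data.shape} vs {first.data.shape}")
        if m.voxel_size != first.voxel_size:
            raise ValueError(
                f"voxel size mismatch: {m.voxel_size} vs {first.voxel_size}"
            )
        out &= m.data
    return BinaryMask(out, first.voxel_size)


def mask_volume(mask: BinaryMask) -> float:
    """Physical volume of the mask: true-voxel count × (dz·dy·dx) in µm³."""
    dz, dy, dx = mask.voxel_size
    return float(np.count_nonzero(mask.data)) * dz * dy * dx


def _roi_slices(
    volume: VolumeImage, roi: RoiSpec
) -> tuple[slice, slice, slice]:
    """Convert a µm-space ROI to half-open voxel slices (floor origin, ceil end)."""
    nz, ny, nx = volume.spatial_shape
    if roi.z_range is None:
        z0, z1 = 0, nz
    else:
        z0, z1 = roi.z_range
        if z0 < 0 or z1 > nz:
            raise ValueError(f"ROI {roi.name!r} z_range {roi.z_range} outside stack of depth {nz}")
    _, dy, dx = volume.voxel_size
    oy, ox = roi.origin
    if roi.extent is None:
        y0, y1 = 0, ny
        x0, x1 = 0, nx
    else:
        hy, wx = roi.extent
        y0 = math.floor(oy / dy)
        x0 = math.floor(ox / dx)
        y1 = math.ceil((oy + hy) / dy)
        x1 = math.ceil((ox + wx) / dx)
    if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
        raise ValueError(
            f"ROI {roi.name!r} voxel bounds y[{y0}:{y1}] x[{x0}:{x1}] exceed "
            f"volume extent (ny={ny}, nx={nx})"
        )
    return slice(z0, z1), slice(y0, y1), slice(x0, x1)


def crop_roi(volume: VolumeImage, roi: RoiSpec) -> VolumeImage:
    """Spatially crop a volume to an ROI; channels are preserved."""
    sz, sy, sx = _roi_slices(volume, roi)
    return VolumeImage(volume.data[:, sz, sy, sx], volume.voxel_size, volume.channel_names)


def _resolve_threshold(
    thresholds: Mapping[str, object] | None, channel: str
) -> tuple[str, float | None]:
    """Look up the threshold setting for a channel.

    ``thresholds`` maps channel name to either the string ``'otsu'`` or a
    ``('fixed', value)`` pair / bare number. Missing entries default to Otsu.
    """
    if thresholds is None or channel not in thresholds:
        return "otsu", None
    setting = thresholds[channel]
    if isinstance(setting, str):
        if setting != "otsu":
            raise ValueError(f"unknown threshold setting {setting!r} for channel {channel!r}")
        return "otsu", None
    if isinstance(setting, (int, float)):
        return "fixed", float(setting)
    method, value = setting  # type: ignore[misc]
    return str(method), float(value)


def quantify_engulfment(
    volume: VolumeImage,
    microglia_ch: str,
    lysosome_ch: str,
    fiber_ch: str,
    roi: RoiSpec | None = None,
    thresholds: Mapping[str, object] | None = None,
) -> EngulfmentResult:
    """Measure nested engulfment volumes for one ROI.

    Binarizes the three channels, then reports the microglia volume, the
    lysosome-within-microglia volume (lysosome ∩ microglia) and the engulfed
    fiber volume (fiber ∩ lysosome ∩ microglia), all in µm³.
    """
    if roi is None:
        roi = RoiSpec(name="full")
    sub = crop_roi(volume, roi)
    record: dict[str, tuple[str, float]] = {}
    masks: dict[str, BinaryMask] = {}
    for ch in (microglia_ch, lysosome_ch, fiber_ch):
        method, value = _resolve_threshold(thresholds, ch)
        m = binarize_channel(sub, ch, method=method, fixed_value=value)
        masks[ch] = m
        record[ch] = (m.threshold_method or method, float(m.threshold_value))
    mg = masks[microglia_ch]
    lyso_in_mg = intersect_masks([masks[lysosome_ch], mg])
    engulfed = intersect_masks([masks[fiber_ch], masks[lysosome_ch], mg])
    return EngulfmentResult(
        roi=roi.name,
        microglia_volume=mask_volume(mg),
        lysosome_volume=mask_volume(lyso_in_mg),
        engulfed_volume=mask_volume(engulfed),
        threshold_record=record,
    )


def quantify_puncta(
    volume: VolumeImage,
    channel: str,
    roi: RoiSpec | None = None,
    threshold: object | None = None,
    min_voxels: int = 0,
) -> PunctaResult:
    """Count and measure 3-D puncta in one channel.

    The channel is binarized, labeled with 26-connectivity, and components
    smaller than ``min_voxels`` are discarded. Returns the object count and
    the summed volume in µm³.
    """
    if roi is None:
        roi = RoiSpec(name="full")
    sub = crop_roi(volume, roi)
    method, value = _resolve_threshold({channel: threshold} if threshold is not None else None, channel)
    mask = binarize_channel(sub, channel, method=method, fixed_value=value)
    labels, n = ndimage.label(mask.data, structure=_STRUCT_26)
    if n > 0 and min_voxels > 0:
        sizes = np.bincount(labels.ravel())[1:]
        keep = sizes >= min_voxels
        n = int(keep.sum())
        total_voxels = int(sizes[keep].sum())
    else:
        total_voxels = int(np.count_nonzero(mask.data))
    dz, dy, dx = volume.voxel_size
    return PunctaResult(
        roi=roi.name,
        count=int(n),
        total_volume=total_voxels * dz * dy * dx,
        size_filter=min_voxels,
        threshold_record={channel: (mask.threshold_method or method, float(mask.threshold_value))},
    )


class QCWarning(UserWarning):
    """Raised (as a warning) for quality-control issues, e.g. too few sections."""


def batch_quantify(
    entries: Iterable[Mapping[str, object]],
    *,
    rois: Sequence[RoiSpec] | None = None,
    microglia_ch: str | None = None,
    lysosome_ch: str | None = None,
    fiber_ch: str | None = None,
    puncta_ch: str | None = None,
    thresholds: Mapping[str, object] | None = None,
    min_voxels: int = 0,
    min_sections: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Quantify a batch of sections and aggregate per animal.

    Each entry must provide ``volume`` (a :class:`VolumeImage`), ``animal``
    and ``section``. One table row is produced per section × ROI. Animals
    contributing fewer than ``min_sections`` sections trigger a QC warning
    (the conventional minimum is 6 sections per animal).

    Returns ``(table, per_animal, warnings)`` where ``per_animal`` holds
    per-animal means of the numeric columns, grouped by ROI.
    """
    if rois is None:
        rois = [RoiSpec(name="full")]
    do_engulfment = microglia_ch is not None
    if do_engulfment and (lysosome_ch is None or fiber_ch is None):
        raise ValueError("engulfment quantification needs microglia, lysosome and fiber channels")
    if not do_engulfment and puncta_ch is None:
        raise ValueError("nothing to quantify: set engulfment channels and/or puncta_ch")

    rows = []
    for entry in entries:
        for key in ("volume", "animal", "section"):
            if key not in entry:
                raise KeyError(f"batch entry missing required metadata field {key!r}")
        vol: VolumeImage = entry["volume"]  # type: ignore[assignment]
        for roi in rois:
            row: dict[str, object] = {
                "animal": entry["animal"],
                "section": entry["section"],
                "roi": roi.name,
            }
            if do_engulfment:
                eng = quantify_engulfment(
                    vol, microglia_ch, lysosome_ch, fiber_ch, roi=roi, thresholds=thresholds
                )
                row.update(
                    microglia_um3=eng.microglia_volume,
                    lysosome_um3=eng.lysosome_volume,
                    engulfed_um3=eng.engulfed_volume,
                )
                method, value = eng.threshold_record[microglia_ch]
                row.update(threshold_method=method, threshold_value=value)
            if puncta_ch is not None:
                pr = quantify_puncta(
                    vol,
                    puncta_ch,
                    roi=roi,
                    threshold=None if thresholds is None else thresholds.get(puncta_ch),
                    min_voxels=min_voxels,
                )
                row.update(puncta_count=pr.count, puncta_um3=pr.total_volume)
            rows.append(row)

    table = pd.DataFrame(rows)
    qc: list[str] = []
    section_counts = table.groupby("animal")["section"].nunique()
    for animal, n_sections in section_counts.items():
        if n_sections < min_sections:
            msg = (
                f"animal {animal!r} has only {n_sections} section(s); "
                f"at least {min_sections} expected"
            )
            qc.append(msg)
            warnings.warn(msg, QCWarning, stacklevel=2)

    numeric = [c for c in table.columns if table[c].dtype.kind in "fi" and c != "section"]
    per_animal = table.groupby(["animal", "roi"], as_index=False)[numeric].mean()
    return table, per_animal, qc
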