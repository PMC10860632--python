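"""Single-unit spike-train analysis.

Evoked firing rates over 1-s windows, the inclusive 10 Hz filament-threshold
rule, the adaptation ratio R (spikes in the second half-second of a
threshold stimulus over spikes in the first), exact 1-D 2-means
classification into adapting and nonadapting cells, the exact two-sided
binomial ratio test, and receptive-field areas.

All time windows are half-open ``[t0, t1)``: a spike exactly at the 0.5 s
split belongs to the second half-window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "FILAMENT_FORCE_G",
    "StimulusEpoch",
    "CellRecording",
    "AdaptiveClassification",
    "firing_rate",
    "evoked_response",
    "vf_threshold",
    "adaptive_ratio",
    "kmeans_boundary",
    "ratio_binomial_test",
    "receptive_field_area",
    "classify_cohort",
]

#: von Frey filament index -> force in grams.
FILAMENT_FORCE_G: dict[int, float] = {
    1: 0.008,
    2: 0.02,
    3: 0.04,
    4: 0.07,
    5: 0.16,
    6: 0.40,
    7: 0.60,
    8: 1.0,
    9: 1.7,
    10: 2.0,
}

#: Default evoked-rate criterion (Hz) for the filament threshold, inclusive.
RATE_THRESHOLD_HZ = 10.0

#: Depth range (µm) outside which a recording is QC-flagged (not rejected).
DEPTH_RANGE_UM = (200.0, 550.0)


@dataclass(frozen=True)
class StimulusEpoch:
    """One annotated stimulus application."""

    kind: str  # {"brush", "vf", "spontaneous"}
    onset: float  # s
    duration: float  # s
    trial: int = 0
    filament_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("brush", "vf", "spontaneous"):
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0")
        if (self.kind == "vf") != (self.filament_index is not None):
            raise ValueError("filament_index must be given iff kind='vf'")
        if self.filament_index is not None and self.filament_index not in FILAMENT_FORCE_G:
            raise ValueError(f"filament_index {self.filament_index} not in 1-10")


@dataclass
class CellRecording:
    """Spike times plus stimulus annotations for one sorted unit."""

    spike_times: np.ndarray  # s, nondecreasing
    epochs: list[StimulusEpoch] = field(default_factory=list)
    depth: float | None = None  # µm below cord surface
    receptive_field: list[tuple[float, float]] | None = None  # mm, paw template
    animal: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if st.size > 1 and np.any(np.diff(st) < 0):
            raise ValueError("spike_times must be nondecreasing")
        self.spike_times = st

    @property
    def depth_in_range(self) -> bool | None:
        """Whether the recording depth falls in the expected 200–550 µm band."""
        if self.depth is None:
            return None
        lo, hi = DEPTH_RANGE_UM
        return lo <= self.depth <= hi

    def count_spikes(self, t0: float, t1: float) -> int:
        """Number of spikes in the half-open window [t0, t1)."""
        i0, i1 = np.searchsorted(self.spike_times, [t0, t1], side="left")
        return int(i1 - i0)


@dataclass(frozen=True)
class AdaptiveClassification:
    """Result of partitioning a cohort into adapting / nonadapting cells."""

    r_values: np.ndarray  # per labeled cell
    boundary: float
    labels: tuple[str, ...]  # "adapting" | "nonadapting", aligned with r_values
    excluded: tuple[int, ...] = ()  # original indices of cells with undefined R
    boundary_mode: str = "kmeans"  # "kmeans" | "fixed"

    def __post_init__(self) -> None:
        r = np.asarray(self.r_values, dtype=float)
        if not np.all(np.isfinite(r)):
            raise ValueError("labeled cells must have finite R")
        for ri, lab in zip(r, self.labels):
            expected = "adapting" if ri < self.boundary else "nonadapting"
            if lab != expected:
                raise ValueError(f"label {lab!r} inconsistent with R={ri} vs boundary={self.boundary}")
        object.__setattr__(self, "r_values", r)


def firing_rate(recording: CellRecording, t0: float, t1: float) -> float:
    """Mean firing rate (Hz) over the half-open window [t0, t1)."""
    if t1 <= t0:
        raise ValueError(f"empty window [{t0}, {t1})")
    return recording.count_spikes(t0, t1) / (t1 - t0)


def _matching_epochs(
    recording: CellRecording, kind: str, filament_index: int | None
) -> list[StimulusEpoch]:
    return [
        e
        for e in recording.epochs
        if e.kind == kind and (filament_index is None or e.filament_index == filament_index)
    ]


def evoked_response(
    recording: CellRecording,
    kind: str = "vf",
    filament_index: int | None = None,
    analysis_window: float = 1.0,
) -> float:
    """Evoked rate: spike count in the first second of each matching epoch,
    divided by the window length and averaged over trials (no baseline
    subtraction). Warns when the trial count differs from the usual three.
    """
    epochs = _matching_epochs(recording, kind, filament_index)
    if not epochs:
        raise ValueError(
            f"no epochs matching kind={kind!r}, filament_index={filament_index}"
        )
    if len(epochs) != 3:
        warnings.warn(
            f"{len(epochs)} trial(s) for kind={kind!r} filament={filament_index}; "
            "3 expected",
            stacklevel=2,
        )
    rates = [
        recording.count_spikes(e.onset, e.onset + analysis_window) / analysis_window
        for e in epochs
    ]
    return float(np.mean(rates))


def vf_threshold(
    recording: CellRecording, rate_threshold: float = RATE_THRESHOLD_HZ
) -> int | None:
    """First (weakest) filament whose evoked rate reaches ``rate_threshold``.

    The criterion is inclusive: an evoked rate exactly at the threshold
    qualifies. Returns ``None`` when no filament qualifies.
    """
    filaments = sorted(
        {e.filament_index for e in recording.epochs if e.kind == "vf"}
    )
    if not filaments:
        raise ValueError("recording has no vf epochs")
    for f in filaments:
        if evoked_response(recording, "vf", f) >= rate_threshold:
            return f
    return None


def adaptive_ratio(
    recording: CellRecording, filament_index: int
) -> float | None:
    """Adaptation ratio R at the given (threshold) filament.

    R = spikes in [onset+0.5, onset+1) / spikes in [onset, onset+0.5),
    with counts pooled across all trials of that filament. Returns ``None``
    (cell excluded) when the pooled first-half count is zero.
    """
    epochs = _matching_epochs(recording, "vf", filament_index)
    if not epochs:
        raise ValueError(f"no vf epochs for filament {filament_index}")
    for e in epochs:
        if e.duration < 1.0:
            raise ValueError(
                f"epoch at t={e.onset} lasts {e.duration} s; >= 1 s required for R"
            )
    first = sum(recording.count_spikes(e.onset, e.onset + 0.5) for e in epochs)
    second = sum(recording.count_spikes(e.onset + 0.5, e.onset + 1.0) for e in epochs)
    if first == 0:
        warnings.warn(
            "zero spikes in pooled first half-window; R undefined, cell excluded",
            stacklevel=2,
        )
        return None
    return second / first


def kmeans_boundary(r_values: Sequence[float]) -> tuple[float, tuple[str, ...]]:
    """Exact 1-D 2-means split of R values.

    Scans all sorted splits for the global minimum of within-cluster sum of
    squares; the boundary is the midpoint of the two cluster centroids and
    the lower cluster is labeled adapting. Values at or above the boundary
    are nonadapting.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size < 2 or not np.all(np.isfinite(r)):
        raise ValueError("need >= 2 finite values")
    if np.unique(r).size < 2:
        raise ValueError("all values identical; no 2-means boundary exists")
    order = np.argsort(r, kind="stable")
    s = r[order]
    n = s.size
    csum = np.cumsum(s)
    csq = np.cumsum(s**2)
    k = np.arange(1, n)  # size of the left cluster
    left_sse = csq[k - 1] - csum[k - 1] ** 2 / k
    rsum = csum[-1] - csum[k - 1]
    rsq = csq[-1] - csq[k - 1]
    right_sse = rsq - rsum**2 / (n - k)
    best = int(np.argmin(left_sse + right_sse)) + 1
    mu_lo = float(csum[best - 1] / best)
    mu_hi = float((csum[-1] - csum[best - 1]) / (n - best))
    boundary = 0.5 * (mu_lo + mu_hi)
    labels = tuple("adapting" if v < boundary else "nonadapting" for v in r)
    return boundary, labels


def ratio_binomial_test(k: int, n: int, p0: float = 1.0 / 3.0) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood rule.

    Under X ~ Binomial(n, p0), sums P(X = j) over all outcomes j whose
    probability does not exceed P(X = k) (with a tiny relative tolerance for
    floating-point ties). Used against the expected 1:2
    nonadapting:adapting ratio (p0 = 1/3).
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"need 0 < p0 < 1, got {p0}")
    j = np.arange(n + 1)
    from scipy.stats import binom

    pmf = binom.pmf(j, n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1.0 + 1e-12)].sum()))


def receptive_field_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Area of a simple polygon (shoelace; orientation-independent).

    Vertices are (x, y) in mm; the result is mm². Raises for fewer than
    three vertices or a self-intersecting outline.
    """
    if len(vertices) < 3:
        raise ValueError("a receptive-field polygon needs >= 3 vertices")
    poly = Polygon(vertices)
    if not poly.is_valid or poly.area == 0.0:
        raise ValueError("receptive-field polygon is self-intersecting or degenerate")
    return float(poly.area)


def classify_cohort(
    recordings: Sequence[CellRecording],
    boundary: float | None = None,
    rate_threshold: float = RATE_THRESHOLD_HZ,
    filament: int | None = None,
) -> tuple[AdaptiveClassification, pd.DataFrame]:
    """Classify a cohort of cells into adapting and nonadapting groups.

    For each cell the filament threshold and adaptation ratio R are computed
    at that threshold. Cells without a qualifying filament or with undefined
    R are excluded (with a warning). Labels come from the exact 2-means
    boundary over the included R values, or from a fixed ``boundary`` (e.g.
    0.33) when one is supplied; either way R >= boundary means nonadapting.

    When ``filament`` is given, R is evaluated at that filament for every
    cell instead of at the cell's own threshold filament. This is needed for
    strongly adapting cells whose 1-s evoked rate never reaches the
    threshold criterion even though the applied stimulus drove them.

    Returns the classification plus a per-cell summary table (one row per
    recording, excluded cells included with empty label).
    """
    if not recordings:
        raise ValueError("empty cohort")
    rows = []
    r_list: list[float] = []
    included_idx: list[int] = []
    for i, rec in enumerate(recordings):
        row: dict[str, object] = {
            "cell": i,
            "animal": rec.animal,
            "group": rec.group,
            "depth_um": rec.depth,
            "depth_in_range": rec.depth_in_range,
        }
        thr = vf_threshold(rec, rate_threshold=rate_threshold) if filament is None else filament
        row["vf_threshold"] = thr
        r: float | None = None
        if thr is not None:
            r = adaptive_ratio(rec, thr)
            row["evoked_vf_hz"] = evoked_response(rec, "vf", thr)
        else:
            warnings.warn(f"cell {i}: no filament reached {rate_threshold} Hz; excluded", stacklevel=2)
        try:
            row["evoked_brush_hz"] = evoked_response(rec, "brush")
        except ValueError:
            row["evoked_brush_hz"] = None
        if rec.receptive_field is not None:
            row["rf_area_mm2"] = receptive_field_area(rec.receptive_field)
        row["r"] = r
        rows.append(row)
        if r is not None and math.isfinite(r):
            r_list.append(r)
            included_idx.append(i)

    if not r_list:
        raise ValueError("no cell in the cohort has a defined R")

    if boundary is None:
        bnd, labels = kmeans_boundary(r_list)
        mode = "kmeans"
    else:
        bnd = float(boundary)
        labels = tuple("adapting" if r < bnd else "nonadapting" for r in r_list)
        mode = "fixed"

    excluded = tuple(i for i in range(len(recordings)) if i not in set(included_idx))
    clf = AdaptiveClassification(
        r_values=np.asarray(r_list),
        boundary=bnd,
        labels=labels,
        excluded=excluded,
        boundary_mode=mode,
    )
    table = pd.DataFrame(rows)
    label_col = [None] * len(recordings)
    for idx, lab in zip(included_idx, labels):
        label_col[idx] = lab
    table["label"] = label_col
    table["boundary_used"] = bnd
    table["boundary_mode"] = mode
    return clf, table
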