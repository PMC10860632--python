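"""Seeded synthetic-data generators with attached ground truth.

Every input the quantification pipeline consumes can be generated here:
engulfment phantoms (nested microglia/lysosome/fiber compartments with
voxel-exact ground-truth volumes), non-touching puncta fields, inhomogeneous
Poisson spike recordings with adapting or nonadapting stimulus responses,
and two-group normal cohorts with a stated effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .ephys import CellRecording, StimulusEpoch
from .imaging import VolumeImage

__all__ = [
    "EngulfmentPhantomSpec",
    "PhantomGroundTruth",
    "SpikeSimSpec",
    "CohortSpec",
    "PlacementError",
    "gen_engulfment_phantom",
    "gen_puncta_phantom",
    "gen_spike_recording",
    "gen_cohort",
    "expected_adaptive_ratio",
]

FOREGROUND = 200.0  # phantom foreground intensity (arbitrary units)


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed in the grid without overlap."""


@dataclass(frozen=True)
class EngulfmentPhantomSpec:
    """Parameters for an engulfment phantom volume.

    Microglia are blobs (unions of overlapping spheres), lysosomes are
    spheres fully inside microglia, and fiber fragments are short cylinders
    that are either fully engulfed (inside a lysosome) or placed clear of
    all microglia.
    """

    grid_shape: tuple[int, int, int] = (40, 128, 128)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)  # µm
    n_microglia: int = 3
    lysosome_fraction: float = 0.2
    n_fiber_fragments: int = 10
    engulfed_fraction: float = 0.5
    blur_sigma: float = 0.0  # µm, isotropic Gaussian
    noise_sd: float = 0.0  # additive Gaussian, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lysosome_fraction <= 1.0):
            raise ValueError(f"lysosome_fraction must be in [0,1], got {self.lysosome_fraction}")
        if not (0.0 <= self.engulfed_fraction <= 1.0):
            raise ValueError(f"engulfed_fraction must be in [0,1], got {self.engulfed_fraction}")
        if self.n_microglia < 0 or self.n_fiber_fragments < 0:
            raise ValueError("counts must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Voxel-exact volumes (µm³) of the pre-blur, pre-noise masks."""

    true_microglia_volume: float = 0.0
    true_lysosome_volume: float = 0.0
    true_engulfed_volume: float = 0.0
    true_puncta_count: int = 0
    true_puncta_volume: float = 0.0

    def __post_init__(self) -> None:
        if not (
            0.0
            <= self.true_engulfed_volume
            <= self.true_lysosome_volume
            <= self.true_microglia_volume
        ):
            raise ValueError("ground-truth nesting violated")
        if self.true_puncta_count < 0 or self.true_puncta_volume < 0:
            raise ValueError("puncta ground truth must be >= 0")

    def to_dict(self) -> dict[str, float]:
        return {
            "true_microglia_volume": self.true_microglia_volume,
            "true_lysosome_volume": self.true_lysosome_volume,
            "true_engulfed_volume": self.true_engulfed_volume,
            "true_puncta_count": self.true_puncta_count,
            "true_puncta_volume": self.true_puncta_volume,
        }


@dataclass(frozen=True)
class SpikeSimSpec:
    """Parameters for a simulated single-unit recording.

    Adapting cells fire at ``peak_rate * exp(-t / decay_tau)`` during the
    stimulus; nonadapting cells at a constant ``peak_rate``. Spontaneous
    activity runs at ``spontaneous_rate`` throughout the recording.
    """

    cell_class: str = "adapting"  # or "nonadapting"
    peak_rate: float = 40.0  # Hz
    decay_tau: float = 0.15  # s, adapting only
    spontaneous_rate: float = 0.5  # Hz
    n_trials: int = 3
    stimulus_duration: float = 2.0  # s
    seed: int = 0
    filament_index: int = 5
    spontaneous_duration: float = 60.0  # s before first stimulus
    inter_trial_interval: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.cell_class not in ("adapting", "nonadapting"):
            raise ValueError(f"cell_class must be 'adapting' or 'nonadapting', got {self.cell_class!r}")
        if self.peak_rate < 0 or self.spontaneous_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be > 0")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group normal cohort with specified means and SDs."""

    n_per_group: int = 20
    group_means: tuple[float, float] = (0.0, 1.0)
    group_sds: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if any(s <= 0 for s in self.group_sds):
            raise ValueError("group_sds must be > 0")


# ---------------------------------------------------------------------------
# geometry helpers (work in µm space; voxel membership = voxel-center test)


def _voxel_centers(grid_shape, voxel_size):
    zs = (np.arange(grid_shape[0]) + 0.5) * voxel_size[0]
    ys = (np.arange(grid_shape[1]) + 0.5) * voxel_size[1]
    xs = (np.arange(grid_shape[2]) + 0.5) * voxel_size[2]
    return zs, ys, xs


def _paint_sphere(mask, grid_shape, voxel_size, center, radius):
    """Set voxels whose center lies within ``radius`` µm of ``center``."""
    zs, ys, xs = _voxel_centers(grid_shape, voxel_size)
    dz2 = (zs - center[0]) ** 2
    dy2 = (ys - center[1]) ** 2
    dx2 = (xs - center[2]) ** 2
    inside = (
        dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
    ) <= radius**2
    mask |= inside


def _paint_cylinder(mask, grid_shape, voxel_size, center, axis, half_length, radius):
    """Set voxels inside a finite cylinder (µm space)."""
    zs, ys, xs = _voxel_centers(grid_shape, voxel_size)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    d = np.stack([Z - center[0], Y - center[1], X - center[2]])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = axis[0] * d[0] + axis[1] * d[1] + axis[2] * d[2]
    rad2 = (d[0] - proj * axis[0]) ** 2 + (d[1] - proj * axis[1]) ** 2 + (
        d[2] - proj * axis[2]
    ) ** 2
    mask |= (np.abs(proj) <= half_length) & (rad2 <= radius**2)


def _random_unit_vector(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _extent_um(grid_shape, voxel_size):
    return tuple(n * d for n, d in zip(grid_shape, voxel_size))


# ---------------------------------------------------------------------------


def gen_engulfment_phantom(
    spec: EngulfmentPhantomSpec,
) -> tuple[VolumeImage, PhantomGroundTruth]:
    """Generate a 3-channel engulfment phantom and its ground truth.

    Channels are ``('microglia', 'lysosome', 'fiber')``. Lysosome voxels are
    a strict subset of microglia voxels and engulfed fiber fragments lie
    entirely inside lysosome voxels, so the ground-truth volumes nest by
    construction. Ground truth refers to the pre-blur, pre-noise masks.
    Identical spec (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    gs, vs = spec.grid_shape, spec.voxel_size
    ext = _extent_um(gs, vs)

    mg_mask = np.zeros(gs, dtype=bool)
    lyso_mask = np.zeros(gs, dtype=bool)
    fiber_mask = np.zeros(gs, dtype=bool)

    # --- microglia: blobby unions of spheres; cells kept mutually disjoint
    soma: list[tuple[np.ndarray, float]] = []  # (center, effective radius incl. lobes)
    for i in range(spec.n_microglia):
        placed = False
        for _ in range(500):
            r = rng.uniform(3.0, 4.5)
            reach = 1.5 * r  # soma plus offset lobes
            lo = np.array([reach] * 3)
            hi = np.array(ext) - reach
            if np.any(hi <= lo):
                break
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - c2) > reach + reach2 + 1.0 for c2, reach2 in soma):
                soma.append((c, reach))
                _paint_sphere(mg_mask, gs, vs, c, r)
                for _ in range(2):  # overlapping lobes make the blob irregular
                    off = _random_unit_vector(rng) * rng.uniform(0.2, 0.5) * r
                    _paint_sphere(mg_mask, gs, vs, c + off, rng.uniform(0.5, 0.75) * r)
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not place microglia {i} without overlap")
    soma_radii = [reach / 1.5 for _, reach in soma]

    # --- lysosomes: one sphere per cell, fully inside the soma sphere
    lysosomes: list[tuple[np.ndarray, float]] = []
    if spec.lysosome_fraction > 0:
        for (c, _), r in zip(soma, soma_radii):
            r_lys = r * spec.lysosome_fraction ** (1.0 / 3.0)
            max_off = max(r - r_lys, 0.0)
            off = _random_unit_vector(rng) * rng.uniform(0.0, 0.8 * max_off)
            _paint_sphere(lyso_mask, gs, vs, c + off, r_lys)
            lysosomes.append((c + off, r_lys))
    lyso_mask &= mg_mask  # subset invariant (holds already; enforced for safety)

    # --- fiber fragments: short cylinders, engulfed ones strictly inside a lysosome
    n_eng = int(round(spec.engulfed_fraction * spec.n_fiber_fragments))
    if n_eng > 0 and not lysosomes:
        raise PlacementError(
            "cannot place engulfed fiber fragments: no lysosomes (lysosome_fraction=0 "
            "or n_microglia=0)"
        )
    for i in range(n_eng):
        c_lys, r_lys = lysosomes[int(rng.integers(len(lysosomes)))]
        frag_r = 0.45 * r_lys
        half_len = 0.45 * r_lys
        # keep the whole cylinder inside the lysosome sphere
        budget = r_lys - np.hypot(half_len, frag_r) - 1e-6
        if budget <= 0:
            raise PlacementError(f"lysosome too small to contain fiber fragment {i}")
        off = _random_unit_vector(rng) * rng.uniform(0.0, budget)
        _paint_cylinder(fiber_mask, gs, vs, c_lys + off, _random_unit_vector(rng), half_len, frag_r)
    n_free = spec.n_fiber_fragments - n_eng
    for i in range(n_free):
        placed = False
        for _ in range(500):
            half_len = rng.uniform(1.0, 2.0)
            frag_r = rng.uniform(0.5, 0.8)
            reach = np.hypot(half_len, frag_r)
            lo = np.array([reach] * 3)
            hi = np.array(ext) - reach
            if np.any(hi <= lo):
                break
            c = rng.uniform(lo, hi)
            # clear of every microglial blob so only engulfed signal overlaps
            if all(np.linalg.norm(c - c2) > reach2 + reach + 1.0 for c2, reach2 in soma):
                _paint_cylinder(fiber_mask, gs, vs, c, _random_unit_vector(rng), half_len, frag_r)
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not place free fiber fragment {i} outside microglia")

    voxel_vol = float(np.prod(vs))
    truth = PhantomGroundTruth(
        true_microglia_volume=int(mg_mask.sum()) * voxel_vol,
        true_lysosome_volume=int(lyso_mask.sum()) * voxel_vol,
        true_engulfed_volume=int((fiber_mask & lyso_mask).sum()) * voxel_vol,
    )

    data = np.stack(
        [m.astype(np.float32) * FOREGROUND for m in (mg_mask, lyso_mask, fiber_mask)]
    )
    data = _blur_and_noise(data, vs, spec.blur_sigma, spec.noise_sd, rng)
    vol = VolumeImage(data, vs, ("microglia", "lysosome", "fiber"))
    return vol, truth


def _blur_and_noise(data, voxel_size, blur_sigma, noise_sd, rng):
    if blur_sigma > 0:
        sigma_vox = [blur_sigma / d for d in voxel_size]
        data = np.stack(
            [ndimage.gaussian_filter(ch, sigma=sigma_vox) for ch in data]
        ).astype(np.float32)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
        data = np.clip(data, 0.0, None, dtype=np.float32, casting="unsafe")
    return data.astype(np.float32)


def gen_puncta_phantom(
    grid_shape: tuple[int, int, int] = (24, 96, 96),
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1),
    n_puncta: int = 25,
    radius_range: tuple[float, float] = (0.3, 0.8),
    seed: int = 0,
    blur_sigma: float = 0.0,
    noise_sd: float = 0.0,
) -> tuple[VolumeImage, PhantomGroundTruth]:
    """Generate a single-channel field of non-touching spheroidal puncta.

    Puncta are spheres (radius drawn from ``radius_range``, in µm) separated
    by at least one empty voxel in every direction, so 26-connected labeling
    recovers the exact count. Ground truth holds the exact count and total
    voxel volume of the pre-blur masks.
    """
    if n_puncta < 0:
        raise ValueError("n_puncta must be >= 0")
    rng = np.random.default_rng(seed)
    ext = _extent_um(grid_shape, voxel_size)
    gap = 2.0 * max(voxel_size)  # guarantees >= 1 empty voxel between surfaces

    mask = np.zeros(grid_shape, dtype=bool)
    placed: list[tuple[np.ndarray, float]] = []
    for i in range(n_puncta):
        ok = False
        for _ in range(2000):
            r = rng.uniform(*radius_range)
            lo = np.array([r + gap] * 3)
            hi = np.array(ext) - (r + gap)
            if np.any(hi <= lo):
                break
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - c2) > r + r2 + gap for c2, r2 in placed):
                placed.append((c, r))
                _paint_sphere(mask, grid_shape, voxel_size, c, r)
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place punctum {i} of {n_puncta} with a >=1 voxel gap"
            )

    voxel_vol = float(np.prod(voxel_size))
    n_true = sum(1 for c, r in placed if _sphere_has_voxels(grid_shape, voxel_size, c, r))
    truth = PhantomGroundTruth(
        true_puncta_count=n_true,
        true_puncta_volume=int(mask.sum()) * voxel_vol,
    )
    data = mask.astype(np.float32)[None] * FOREGROUND
    data = _blur_and_noise(data, voxel_size, blur_sigma, noise_sd, rng)
    vol = VolumeImage(data, voxel_size, ("puncta",))
    return vol, truth


def _sphere_has_voxels(grid_shape, voxel_size, center, radius) -> bool:
    tmp = np.zeros(grid_shape, dtype=bool)
    _paint_sphere(tmp, grid_shape, voxel_size, center, radius)
    return bool(tmp.any())


# ---------------------------------------------------------------------------
# spike trains


def _thinned_poisson(rng, t0, t1, rate_fn, rate_max):
    """Inhomogeneous Poisson times on [t0, t1) by thinning against rate_max."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    keep = rng.uniform(0.0, 1.0, size=n) < rate_fn(cand - t0) / rate_max
    return cand[keep]


def expected_adaptive_ratio(decay_tau: float) -> float:
    """Closed-form expected R for the exponentially adapting rate model.

    Ratio of the rate integral over [0.5, 1) s to the integral over
    [0, 0.5) s: ``(exp(-0.5/tau) - exp(-1/tau)) / (1 - exp(-0.5/tau))``.
    """
    e_half = np.exp(-0.5 / decay_tau)
    e_full = np.exp(-1.0 / decay_tau)
    return float((e_half - e_full) / (1.0 - e_half))


def gen_spike_recording(spec: SpikeSimSpec) -> CellRecording:
    """Simulate one cell's spike train with annotated stimulus epochs.

    The recording starts with a spontaneous-only stretch, then ``n_trials``
    stimulus epochs of ``stimulus_duration`` seconds separated by the
    inter-trial interval. Spontaneous activity is an independent homogeneous
    Poisson process over the whole recording, added to the evoked process.
    """
    rng = np.random.default_rng(spec.seed)
    epochs: list[StimulusEpoch] = [
        StimulusEpoch(kind="spontaneous", onset=0.0, duration=spec.spontaneous_duration, trial=0)
    ]
    spikes: list[np.ndarray] = []

    t = spec.spontaneous_duration
    for trial in range(spec.n_trials):
        onset = t
        epochs.append(
            StimulusEpoch(
                kind="vf",
                onset=onset,
                duration=spec.stimulus_duration,
                trial=trial,
                filament_index=spec.filament_index,
            )
        )
        if spec.cell_class == "adapting":
            tau = spec.decay_tau
            rate_fn = lambda trel: spec.peak_rate * np.exp(-trel / tau)  # noqa: E731
        else:
            rate_fn = lambda trel: np.full_like(trel, spec.peak_rate, dtype=float)  # noqa: E731
        spikes.append(_thinned_poisson(rng, onset, onset + spec.stimulus_duration, rate_fn, spec.peak_rate))
        t = onset + spec.stimulus_duration + spec.inter_trial_interval

    total_duration = t
    if spec.spontaneous_rate > 0:
        spikes.append(
            _thinned_poisson(
                rng,
                0.0,
                total_duration,
                lambda trel: np.full_like(trel, spec.spontaneous_rate, dtype=float),
                spec.spontaneous_rate,
            )
        )

    spike_times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
    depth = float(rng.uniform(200.0, 550.0))
    rf = _random_rf_polygon(rng)
    return CellRecording(
        spike_times=spike_times,
        epochs=epochs,
        depth=depth,
        receptive_field=rf,
        group=spec.cell_class,
    )


def _random_rf_polygon(rng, n_vertices: int = 8) -> list[tuple[float, float]]:
    """Star-shaped simple polygon on a paw template (mm coordinates)."""
    cx, cy = rng.uniform(2.0, 6.0, size=2)
    # evenly spaced angles with bounded jitter: keeps every angular gap < pi,
    # so the star polygon around (cx, cy) is guaranteed simple
    step = 2.0 * np.pi / n_vertices
    angles = np.arange(n_vertices) * step + rng.uniform(-0.4 * step, 0.4 * step, n_vertices)
    radii = rng.uniform(0.5, 1.5, size=n_vertices)
    return [
        (float(cx + r * np.cos(a)), float(cy + r * np.sin(a)))
        for r, a in zip(radii, angles)
    ]


def gen_cohort(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw two independent normal samples with the specified means and SDs."""
    rng = np.random.default_rng(spec.seed)
    a = rng.normal(spec.group_means[0], spec.group_sds[0], size=spec.n_per_group)
    b = rng.normal(spec.group_means[1], spec.group_sds[1], size=spec.n_per_group)
    return a, b
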