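"""Run orchestration: configuration, stage wiring, manifests and reports.

A run is driven by one config mapping (typically loaded from YAML) and one
global seed, which is split deterministically per stage. Stage outputs are
CSV/JSON files with a stable column order and a schema-version header
comment; every QC warning raised by any module is collected into the run
manifest.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .ephys import classify_cohort, ratio_binomial_test
from .imaging import RoiSpec, batch_quantify
from .io import read_ground_truth, read_recording, read_volume, write_recording, write_volume
from .stats import bootstrap_distribution, effect_size, welch_t
from .synthdata import (
    CohortSpec,
    EngulfmentPhantomSpec,
    SpikeSimSpec,
    gen_cohort,
    gen_engulfment_phantom,
    gen_puncta_phantom,
    gen_spike_recording,
)

SCHEMA_VERSION = 1
_STAGES = ("simulate", "engulfment", "puncta", "ephys", "stats")


@dataclass
class RunManifest:
    """Summary of one pipeline run: config snapshot, counts, warnings."""

    config: dict[str, Any]
    seed: int
    version: str = __version__
    schema_version: int = SCHEMA_VERSION
    stages: list[str] = field(default_factory=list)
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def write(self, outdir: Path) -> Path:
        self.finished = time.time()
        path = outdir / "manifest.json"
        path.write_text(
            json.dumps(
                {
                    "version": self.version,
                    "schema_version": self.schema_version,
                    "seed": self.seed,
                    "stages": self.stages,
                    "row_counts": self.row_counts,
                    "warnings": self.warnings,
                    "config": self.config,
                    "started": self.started,
                    "finished": self.finished,
                },
                indent=1,
            )
        )
        return path


def write_table(df: pd.DataFrame, path: Path) -> None:
    """Write a CSV with the schema-version header comment (stable column order)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# gliaquant schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed).spawn(len(_STAGES))[_STAGES.index(stage)]


def run_pipeline(
    config: Mapping[str, Any],
    subcommand: str,
    outdir: str | Path,
    seed: int = 0,
) -> RunManifest:
    """Execute one or all pipeline stages into ``outdir``.

    ``subcommand`` is one of ``simulate | engulfment | puncta | ephys |
    stats | all``. Output is deterministic given config + seed. Any stage
    error is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(config)
    manifest = RunManifest(config=config, seed=seed)

    stages = list(_STAGES) if subcommand == "all" else [subcommand]
    for stage in stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown subcommand {stage!r}; expected one of {_STAGES + ('all',)}")
        runner = globals()[f"_stage_{stage}"]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                runner(config.get(stage, {}), outdir, _stage_seed(seed, stage), manifest)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages.append(stage)
        manifest.warnings.extend(f"{stage}: {w.message}" for w in caught)

    manifest.write(outdir)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: Mapping[str, Any], outdir: Path, seq, manifest: RunManifest) -> None:
    child = seq.spawn(4)
    n_animals = int(cfg.get("n_animals", 2))
    n_sections = int(cfg.get("n_sections", 6))

    # engulfment phantoms
    phantom_dir = outdir / "phantoms"
    phantom_dir.mkdir(exist_ok=True)
    base = dict(cfg.get("phantom", {}))
    rng = np.random.default_rng(child[0])
    index_rows = []
    for a in range(n_animals):
        for s in range(n_sections):
            spec = EngulfmentPhantomSpec(**{**base, "seed": int(rng.integers(2**31))})
            vol, truth = gen_engulfment_phantom(spec)
            name = f"animal{a}_section{s}.tif"
            write_volume(phantom_dir / name, vol, ground_truth=truth)
            index_rows.append({"file": name, "animal": f"A{a}", "section": s})
    write_table(pd.DataFrame(index_rows), phantom_dir / "index.csv")
    manifest.row_counts["phantoms"] = len(index_rows)

    # puncta phantoms
    puncta_dir = outdir / "puncta_phantoms"
    puncta_dir.mkdir(exist_ok=True)
    pbase = dict(cfg.get("puncta", {}))
    rng = np.random.default_rng(child[1])
    index_rows = []
    for a in range(n_animals):
        for s in range(n_sections):
            vol, truth = gen_puncta_phantom(**{**pbase, "seed": int(rng.integers(2**31))})
            name = f"puncta_animal{a}_section{s}.tif"
            write_volume(puncta_dir / name, vol, ground_truth=truth)
            index_rows.append({"file": name, "animal": f"A{a}", "section": s})
    write_table(pd.DataFrame(index_rows), puncta_dir / "index.csv")
    manifest.row_counts["puncta_phantoms"] = len(index_rows)

    # spike recordings
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(exist_ok=True)
    ecfg = dict(cfg.get("ephys", {}))
    n_adapting = int(ecfg.pop("n_adapting", 6))
    n_nonadapting = int(ecfg.pop("n_nonadapting", 3))
    rng = np.random.default_rng(child[2])
    i = 0
    for cls, n in (("adapting", n_adapting), ("nonadapting", n_nonadapting)):
        for _ in range(n):
            # adapting cells need a high onset rate for the 10 Hz 1-s rule to fire
            kwargs = dict(ecfg)
            kwargs.setdefault("peak_rate", 150.0 if cls == "adapting" else 40.0)
            spec = SpikeSimSpec(cell_class=cls, seed=int(rng.integers(2**31)), **kwargs)
            write_recording(rec_dir / f"cell{i:03d}.json", gen_spike_recording(spec))
            i += 1
    manifest.row_counts["recordings"] = i

    # cohort table for the stats stage
    ccfg = dict(cfg.get("cohort", {}))
    rng = np.random.default_rng(child[3])
    spec = CohortSpec(seed=int(rng.integers(2**31)), **ccfg)
    a, b = gen_cohort(spec)
    rows = [{"group": "control", "id": f"c{i}", "value": v} for i, v in enumerate(a)]
    rows += [{"group": "treated", "id": f"t{i}", "value": v} for i, v in enumerate(b)]
    write_table(pd.DataFrame(rows), outdir / "cohort.csv")
    manifest.row_counts["cohort"] = len(rows)


def _load_indexed_volumes(input_dir: Path, channel_order=None):
    index = read_table(input_dir / "index.csv")
    entries = []
    for _, row in index.iterrows():
        vol = read_volume(input_dir / row["file"], channel_order=channel_order)
        entries.append(
            {"volume": vol, "animal": row["animal"], "section": row["section"], "file": row["file"]}
        )
    return entries


def _parse_rois(cfg) -> list[RoiSpec] | None:
    rois = cfg.get("rois")
    if not rois:
        return None
    return [
        RoiSpec(
            name=r["name"],
            origin=tuple(r.get("origin", (0.0, 0.0))),
            extent=tuple(r["extent"]) if r.get("extent") else None,
            z_range=tuple(r["z_range"]) if r.get("z_range") else None,
        )
        for r in rois
    ]


def _stage_engulfment(cfg: Mapping[str, Any], outdir: Path, seq, manifest: RunManifest) -> None:
    input_dir = Path(cfg.get("input", outdir / "phantoms"))
    ch = cfg.get("channels", {})
    entries = _load_indexed_volumes(input_dir)
    table, per_animal, qc = batch_quantify(
        entries,
        rois=_parse_rois(cfg),
        microglia_ch=ch.get("microglia", "microglia"),
        lysosome_ch=ch.get("lysosome", "lysosome"),
        fiber_ch=ch.get("fiber", "fiber"),
        thresholds=cfg.get("thresholds"),
        min_sections=int(cfg.get("min_sections", 6)),
    )
    write_table(table, outdir / "engulfment.csv")
    write_table(per_animal, outdir / "engulfment_per_animal.csv")
    manifest.row_counts["engulfment"] = len(table)


def _stage_puncta(cfg: Mapping[str, Any], outdir: Path, seq, manifest: RunManifest) -> None:
    input_dir = Path(cfg.get("input", outdir / "puncta_phantoms"))
    entries = _load_indexed_volumes(input_dir)
    table, per_animal, qc = batch_quantify(
        entries,
        rois=_parse_rois(cfg),
        puncta_ch=cfg.get("channel", "puncta"),
        thresholds=cfg.get("thresholds"),
        min_voxels=int(cfg.get("min_voxels", 0)),
        min_sections=int(cfg.get("min_sections", 6)),
    )
    write_table(table, outdir / "puncta.csv")
    write_table(per_animal, outdir / "puncta_per_animal.csv")
    manifest.row_counts["puncta"] = len(table)


def _stage_ephys(cfg: Mapping[str, Any], outdir: Path, seq, manifest: RunManifest) -> None:
    input_dir = Path(cfg.get("input", outdir / "recordings"))
    paths = sorted(input_dir.glob("*.json"))
    if not paths:
        raise FileNotFoundError(f"no recording JSON files in {input_dir}")
    recordings = [read_recording(p) for p in paths]
    boundary = cfg.get("boundary")  # None -> data-driven k-means
    filament = cfg.get("filament")
    clf, table = classify_cohort(
        recordings,
        boundary=None if boundary is None else float(boundary),
        rate_threshold=float(cfg.get("rate_threshold", 10.0)),
        filament=None if filament is None else int(filament),
    )
    table.insert(0, "file", [p.name for p in paths])
    write_table(table, outdir / "cells.csv")

    n_labeled = len(clf.labels)
    k_nonadapting = sum(1 for lab in clf.labels if lab == "nonadapting")
    summary = pd.DataFrame(
        [
            {
                "n_cells": len(recordings),
                "n_labeled": n_labeled,
                "n_excluded": len(clf.excluded),
                "n_adapting": n_labeled - k_nonadapting,
                "n_nonadapting": k_nonadapting,
                "boundary": clf.boundary,
                "boundary_mode": clf.boundary_mode,
                "binomial_p_vs_one_third": ratio_binomial_test(k_nonadapting, n_labeled),
            }
        ]
    )
    write_table(summary, outdir / "cohort_summary.csv")
    manifest.row_counts["cells"] = len(table)


def _stage_stats(cfg: Mapping[str, Any], outdir: Path, seq, manifest: RunManifest) -> None:
    input_path = Path(cfg.get("input", outdir / "cohort.csv"))
    df = read_table(input_path)
    for col in ("group", "value"):
        if col not in df.columns:
            raise ValueError(f"{input_path}: tidy input needs a {col!r} column")
    groups = cfg.get("comparisons")
    if groups is None:
        names = list(dict.fromkeys(df["group"]))
        groups = [[names[0], names[1]]] if len(names) >= 2 else []
    n_boot = int(cfg.get("n_boot", 5000))
    n_perm = int(cfg.get("n_perm", 5000))
    alpha = float(cfg.get("alpha", 0.05))
    stats_seed = int(np.random.default_rng(seq).integers(2**31))

    rows = []
    plot_data: dict[str, Any] = {}
    for ga, gb in groups:
        a = df.loc[df["group"] == ga, "value"].to_numpy()
        b = df.loc[df["group"] == gb, "value"].to_numpy()
        es = effect_size(a, b, n_boot=n_boot, n_perm=n_perm, alpha=alpha, seed=stats_seed)
        t, dof, p_t = welch_t(a, b)
        rows.append(
            {
                "comparison": f"{gb} vs {ga}",
                "mean_diff": es.mean_difference,
                "ci_low": es.ci_low,
                "ci_high": es.ci_high,
                "perm_p": es.permutation_p,
                "welch_t": t,
                "welch_df": dof,
                "welch_p": p_t,
                "n_boot": n_boot,
                "n_perm": n_perm,
                "alpha": alpha,
                "seed": stats_seed,
                "perm_sides": "two-sided",
            }
        )
        boot = bootstrap_distribution(a, b, n_boot=n_boot, seed=stats_seed)
        qs = np.linspace(0.0, 1.0, 101)
        plot_data[f"{gb} vs {ga}"] = {
            "quantiles": qs.tolist(),
            "values": np.quantile(boot, qs).tolist(),
        }
    write_table(pd.DataFrame(rows), outdir / "effects.csv")
    (outdir / "effects_bootstrap.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "comparisons": plot_data}, indent=1)
    )
    manifest.row_counts["effects"] = len(rows)
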