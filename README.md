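# gliaquant

A tested, reusable pipeline for three kinds of analysis commonly combined in
studies of microglial pruning of sensory circuits:

- **imaging** — quantification of microglial engulfment in multi-channel 3D
  fluorescence volumes as nested intersection volumes
  (fiber ∩ lysosome ∩ microglia, in µm³), and 3D synaptic-puncta
  segmentation/counting (26-connected components), per rectangular ROI, with
  per-channel threshold provenance and per-animal batch aggregation.
- **ephys** — single-unit spike-train analysis: evoked rates over 1-s
  windows, the inclusive 10 Hz von Frey filament-threshold rule, the
  adaptation ratio *R* (spikes in 0.5–1 s over spikes in 0–0.5 s of a
  threshold stimulus, pooled across trials), exact 1-D 2-means
  classification into adapting/nonadapting cells, an exact two-sided
  binomial test against a 1:2 population ratio, and receptive-field areas.
- **stats** — estimation statistics: unpaired mean differences with
  5000-sample BCa bootstrap 95% CIs, two-sided permutation p-values, and
  Welch's t.
- **synthdata** — seeded generators for every input the pipeline consumes,
  with exact ground truth attached: engulfment phantoms (nested
  microglia/lysosome/fiber compartments), non-touching puncta fields,
  inhomogeneous-Poisson spike trains (exponentially adapting or constant
  stimulus responses), and two-group normal cohorts. Nothing needs to be
  downloaded to test any stage end to end.

## CLI

```sh
gliaquant all --seed 0 --outdir out            # simulate -> quantify -> stats
gliaquant simulate --config run.yaml --outdir out
gliaquant engulfment --outdir out              # reads out/phantoms/
gliaquant ephys --outdir out                   # reads out/recordings/
gliaquant stats --outdir out                   # reads out/cohort.csv
```

Subcommands: `simulate | engulfment | puncta | ephys | stats | all`. The
single `--seed` is split deterministically per stage; rerunning with the
same config and seed reproduces every CSV byte for byte. Each run writes
`manifest.json` (config snapshot, row counts, and every QC warning raised).

Volumes are TIFF z-stacks with a JSON sidecar carrying `voxel_size_um`,
channel names, and (for phantoms) the ground truth; OME `PhysicalSize*`
metadata is also understood. Spike recordings are JSON (spike times, epoch
annotations, receptive-field polygon, depth). Stats input is a tidy CSV
(`group,id,value`).

## Notes on defaults

- Binarization defaults to per-channel Otsu with the chosen value always
  logged; any channel can be overridden with a fixed threshold. On channels
  where foreground occupies a tiny fraction of voxels (e.g. sparse fiber
  fragments under noise), global Otsu collapses into the noise floor — use
  fixed thresholds there (the blurred-phantom recovery tests use half the
  foreground intensity).
- Windows are half-open `[t0, t1)` everywhere; *R* pools counts across
  trials (sum/sum) and is undefined (cell excluded, warned) when the pooled
  first-half count is zero; `R >= boundary` classifies as nonadapting.
- The permutation test is two-sided on |mean difference| with the
  (b+1)/(N+1) estimator (never exactly 0); exhaustive enumeration engages
  automatically for small groups. BCa falls back to the percentile interval
  (with a warning) when z0 is degenerate or the jackknife variance is zero.
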