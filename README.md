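# oscimap

Analysis toolkit for slow (3–12 Hz) subthreshold-oscillation voltage-imaging
movies: per-pixel Welch band-power mapping, density-based clustering of
synchronously oscillating pixels, imaging–electrophysiology comparison,
coherence/phase analyses around stimulation, and radial profiling of dye
staining — together with synthetic ground-truth generators so every stage is
testable without any external data.

## Library overview

| Module | Contents |
| --- | --- |
| `oscimap.synthetic` | `generate_sto_movie`, `generate_paired_ephys`, `generate_staining_field`, `random_scene`, `dye_solution_molarity` — ground-truth movies (clustered sinusoidal oscillators, bleaching, noise, stimulation entrainment), paired voltage traces, staining images |
| `oscimap.preprocess` | `Movie`/`EphysTrace` types, TIFF I/O with metadata sidecars, `crop`, `bleach_correct`, `dff`, `detrend_trace` (0.25 s running median), `downsample_ephys` (bin-averaging) |
| `oscimap.spectral` | `welch_psd` (1 s Hann segments, 50 % overlap), `band_power_map` (default band 3–12 Hz, half-open), `normalize_to_max`, `threshold_quantile` (default 0.90), `zscore_filter`, `psd_vs_distance` |
| `oscimap.clustering` | `neuron_footprint_pixels` (110 µm at 18 µm/px → 29), `cluster_pixels` (OPTICS, min cluster size 5), `cluster_trace`, `cluster_geometry` |
| `oscimap.coherence` | sliding auto/cross-correlograms (lagged Pearson), `shuffle_null`, `windowed_covariance` + `coherence_image`, `cross_psd`, `prepost_spectrum_ratio`, `timepoint_correlation_matrix` |
| `oscimap.anatomy` | `radial_profile`, `half_max_radius`, `cell_radial_profile` (20 µm discs, 18 × 20° segments), `compartment_stats` (nucleus 0–3.5 µm, cytosol 3.5–10 µm, neuropil >10 µm), `segment_variability` |

## CLI

An end-to-end run on synthetic data:

```bash
oscimap simulate  --out-dir sim --seed 1 --n-clusters 3
oscimap map       --movie sim/movie.tif --out-dir map
oscimap cluster   --psd-dir map --movie sim/movie.tif --out-dir clusters
oscimap coherence --traces clusters/traces.csv --frame-rate 40 --out-dir coh
oscimap anatomy   --image stain.tif --pixel-pitch-um 0.44 --out-dir anat
```

All commands take `--config <yaml>` (flat key–value file; flags override,
unknown keys are rejected) and write a provenance JSON (parameters, input
hashes, package version) next to their products. Exit codes: 0 success,
2 configuration error, 3 data-format error, 4 numerical failure.

Movies are multi-page TIFFs; frame rate and pixel pitch travel in the TIFF
description tag or a `<file>.meta.yaml` sidecar (`frame_rate_hz`,
`pixel_pitch_um`) — a missing frame rate is an error, never a silent
default.

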