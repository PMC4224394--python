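# septrack

Quantitative analysis of endosome dynamics in live-cell fluorescence
movies: spot detection, photobleaching correction, particle tracking,
motility classification, and dwell-time / colocalization analysis of
coat-protein-positive vesicles on reference organelles — with a
synthetic two-channel movie generator providing exact ground truth for
every stage.

## The problem

Coat-coated early endosomes at the cell periphery alternate between
pauses on septin-decorated actin filaments and short directed runs
(~1 µm/s), and dock transiently (~1 min in unperturbed cells, tens of
seconds under septin depletion) on cargo-loaded endosomal structures.
Quantifying this from TIRF time series requires a chain of image
measurements — sub-pixel spot localization, bleach-robust intensities,
identity-preserving linking, a motility criterion, and association
bookkeeping with censoring — each of which must be validated. `septrack`
implements the full chain and tests it by parameter recovery on
simulated movies whose ground truth is known exactly.

## Core methods

- **À-trous wavelet spot detection.** Undecimated B3-spline wavelet
  transform; per-scale robust thresholds (k·1.4826·MAD, k = 3) on detail
  scales {2, 3}; watershed splitting of multi-peak components; sub-pixel
  intensity-weighted centroids over the background-subtracted image.
  The transform satisfies exact additivity: Σ detail planes + residual
  = input.
- **Bleach correction** by multiplicative intensity normalization of
  each frame to a reference level.
- **Global linking** between consecutive frames by linear assignment on
  `w_d·d/gate + w_i·|ΔI|/I_scale`, gating radius 5 px, birth/death
  allowed, no gap closing; tracks of ≥ 6 consecutive frames retained.
- **Motility criterion.** A step of Euclidean displacement < 3 px is
  immobile, ≥ 3 px motile; speeds convert via pixel size and frame
  interval (1 px/frame at 143 nm / 154 ms = 0.93 µm/s). Mean motile-step
  speed is reported over motile steps only.
- **Object-based colocalization and dwell.** Fraction of objects whose
  nearest partner-channel centroid lies within 3 px; association runs of
  tracks on reference structures (sticky assignment, optional 1-frame
  gap absorption), censored-run flagging, and dwell statistics excluding
  censored events.
- **Reporting.** Replicate aggregation (mean ± sample SD) and classical
  single-factor ANOVA per time point.

## Worked example

Simulate a control-condition movie (600 frames, 143 nm pixels, 475 ms
frame interval, directed speed 1 µm/s, 60 s mean bound dwell), run the
full pipeline, and recover the motion and dwell parameters:

```python
import septrack as st
from septrack.pipeline import AnalysisParams, simulate_and_analyze, pooled_motile_speed

cfg = st.control_config(seed=2)
result = simulate_and_analyze(cfg, params=AnalysisParams(max_gap_frames=1))

speed, n_tracks = pooled_motile_speed([result.metrics])
dwell = st.dwell_stats(result.events, censoring="exclude", min_frames=3)
print(f"{len(result.tracks)} tracks; motile speed {speed:.3f} um/s "
      f"({n_tracks} tracks); mean dwell {dwell.mean_s:.1f} s (n={dwell.n})")
```

prints

```
42 tracks; motile speed 1.001 um/s (31 tracks); mean dwell 49.4 s (n=13)
```

i.e. the configured 1.0 µm/s directed speed is recovered to 0.1% from
the motile steps of 31 retained tracks, while the 13 uncensored docking
events of a single 4.7-minute acquisition average 49 s against a
configured 60 s mean — dwell estimation needs acquisitions long relative
to the dwell, which is exactly what the dedicated recovery checks use
(28.5-minute series; see `docs/methods.md`).

The same stages are available from the shell:

```sh
septrack simulate --out sim/ --seed 3
septrack detect --in sim/movie.tif --channel coat --bleach-correct --out det.csv
septrack track --in det.csv --out tracks.csv
septrack motility --in tracks.csv --pixel-size-nm 143 --frame-interval-ms 475 --out metrics.csv
septrack pipeline --out run/ --seed 3        # everything, one config
```

## Layout

```
src/septrack/
  config.py      simulation configs and acquisition presets
  simulate.py    filament field, two-state motion model, rendering, ground truth
  io.py          TIFF + sidecar movies, CSV table schemas
  preprocess.py  bleach correction, à-trous transform, spot detection
  tracking.py    frame linking (LAP), track assembly, length filter
  motility.py    step classification, physical-unit track metrics
  association.py object colocalization, association runs, dwell statistics
  reporting.py   replicate aggregation, one-way ANOVA, plots
  pipeline.py    end-to-end convenience used by the CLI and tests
  validation.py  recall/precision and track-recovery scoring vs ground truth
  cli.py         `septrack` command-line interface
```

`docs/methods.md` documents the models, parameter choices, and known
limitations.
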