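# Methods

`septrack` quantifies the dynamics of coat-protein-positive endosomes in
two-channel live-cell (TIRF) movies: where the objects are, how they move
between filament-bound pauses and directed runs, and how long they stay
associated with reference organelles. Because the workflow is usually
applied to data that cannot be redistributed, the package ships a
synthetic-movie generator with exact ground truth; every stage of the
measurement pipeline is validated by parameter recovery against that
generator.

## Image formation and the synthetic generator

Objects are rendered as 2-D Gaussians (default `psf_sigma_px = 1.3`,
i.e. ~190 nm at 143 nm pixels, a diffraction-limited spot) on a uniform
background (default 100 counts). Signal **and** background are scaled by
`exp(-t / bleach_tau_frames)` — treating the diffuse background as
autofluorescence that fades with the dye — so multiplicative intensity
normalization is the exact inverse of bleaching. The camera model is
Poisson shot noise plus additive Gaussian read noise
(`read_noise_sd = 2`), the standard EMCCD/sCMOS approximation. Per-object
peak amplitudes vary ±15% around `spot_amplitude = 300` and are constant
in time, which is what makes intensity informative for linking identity.

Motion is a two-state continuous-time Markov switch with exponential
sojourns: a **bound** state (object parked at a binding site, per-frame
Gaussian jitter `localization_jitter_px = 0.3`) and a **motile** state
(directed motion at `motile_speed_um_s` with a heading that diffuses at
`heading_diffusion_rad = 0.4` rad/√s). Exponential sojourns are the
minimal assumption that makes dwell-time recovery a well-posed test;
directed (not Brownian) motility is used because the phenomenon being
emulated has a characteristic speed (~1 µm/s). Boundaries are
reflective, keeping the object count constant so detection recall is
well defined.

Binding happens at discrete **sites**: filament points kept pairwise
separated by `max(binding_exclusion_px, association radius + flicker
margin)` ≈ 4.5 px. This encodes vesicle volume exclusion (one occupant
per site at a time), and guarantees that a bound object is either firmly
inside or firmly outside a reference object's association radius — an
anchor sitting *on* the radius would otherwise generate dozens of
spurious one-frame association intervals through jitter. Objects
returning near a previously used free site reuse it.

The filament field is a set of persistent random-walk polylines
(25 filaments, persistence 20 px on a 128×128 field), a static stand-in
for the decorated actin cytoskeleton; filament dynamics are out of scope.

### Reference channel and colocalization ground truth

Reference structures (endosome analogues) are rendered larger and dimmer
(`sigma_px = 2.6`, amplitude 180). In the default **static** mode a
subset of binding sites is selected — random order, greedy, stopping at
the prefix whose realized coverage is closest to the target — so that
`coloc_fraction` (default 0.5) of all object-frames lies within the
association radius (default 3 px) of some reference object. Selected
sites keep `max(2·radius, 3·sigma_ref)` mutual separation so they remain
resolvable as distinct detections. The construction achieves the target
to within the granularity of one bound interval, which is inside
binomial 3σ at the default 600-frame, 12-object regime. In very long
acquisitions the pool of admissible well-separated sites can cap the
realized fraction below the target (observed ~0.31–0.37 vs 0.5 at 3600
frames); the fraction-recovery guarantee is therefore stated for the
600-frame regime.

A **transient** mode (`coloc_profile`, one probability per frame)
instead ties each reference object's lifetime to one bound interval,
kept with the profile probability at the interval's start; this produces
time-varying colocalization courses (e.g. ramp-up/ramp-down with a
configured peak window).

Ground truth records exact positions and states per frame, the bound
intervals with their sites, per-frame reference positions, and the
*geometric* association intervals (maximal frame runs with the nearest
existing reference within the radius).

### Acquisition presets

`control_config()`: 600 frames, 143 nm pixels, **475 ms** frame
interval, speed 1.0 µm/s, mean bound dwell 60 s, mean motile excursion
6 s. The 475 ms interval is the trajectory-series regime: at this
sampling a 1 µm/s run covers 3.32 px/frame, above the 3-px step
criterion, whereas at the 154 ms default interval the same object moves
only 1.08 px/frame and no genuinely motile step could ever be labelled
motile — the criterion is tied to its acquisition regime. The 6 s
excursion time (paths of ~6 µm) is chosen so successive binding events
are separable at the association radius and sampling interval; with
much shorter excursions a third of unbinding events re-dock at the same
site within a frame or two and successive sojourns blur into one
measured association run. `septin_depleted_config()` shortens the bound
dwell to 25 s (20–30 s phenotype) at unchanged speed.

## Measurement pipeline

**Bleach correction** rescales every frame multiplicatively so its mean
(or median) matches a reference level (first frame, or the global median
level). It is exact on noiseless exponentially bleached data; on Poisson
data it restores levels to within shot noise. A frame with non-positive
level is a hard error naming the frame.

**Spot detection** uses the isotropic undecimated (à-trous) wavelet
transform with the separable B3-spline kernel (1,4,6,4,1)/16, zeros
inserted at dyadic spacings, mirror boundaries. Detail planes sum back
to the input exactly (the additivity is a tested invariant, to 1e-9).
Detection thresholds each selected detail plane (defaults: scales 2 and
3 of 3) at `k_mad = 3` times a robust noise scale (1.4826 × MAD about
the plane median — insensitive to the spots themselves), intersects the
masks, and takes 8-connected components of at least `min_area_px = 2`.
Because two nearby spots stay above threshold between their peaks
whenever the saddle clears the noise floor (out to ~8 px separation at
high SNR), components containing several local maxima of the band-passed
image are split by a watershed seeded at those maxima; secondary maxima
closer than 3 px to a stronger one or below 25% of the component peak
are absorbed rather than split. Sub-pixel positions are
intensity-weighted centroids over the background-subtracted image
(background = the smooth à-trous residual); Gaussian fitting is
deliberately not used, since the downstream motility criterion is
phrased in terms of centroid resolution. Coordinates are 0-based,
pixel-center, x = column.

**Linking** is a global one-to-one assignment between consecutive
frames with cost `w_dist·d/gate + w_int·|ΔI|/intensity_scale`
(defaults: gate 5 px, w_dist 1, w_int 0.5, intensity_scale = median
detection intensity), pairs beyond the gate forbidden. Among
gate-feasible assignments the solver maximizes the number of links and
then minimizes total cost (linear assignment with birth/death dummies;
the dummy cost exceeds any feasible total, and a forbidden link costs
more than a death plus a birth). Tracks are chains of links; a missed
detection always ends a track (no gap closing), isolated single-frame
detections are discarded, and the standard false-track filter keeps
only tracks of ≥ 6 consecutive frames. Detections are canonically
sorted within each frame before linking, so the track set does not
depend on input row order; equal-cost assignment ties are resolved by
the deterministic solver.

**Motility**: per consecutive step, Euclidean displacement of sub-pixel
centroids; strictly below 3 px (the centroid-resolution criterion) is
immobile, at or above it motile. Track metrics are reported in physical
units via the movie calibration: path length, net displacement,
duration, immobile fraction, mean speed over motile steps only (missing
— never 0 — for tracks without motile steps), and the label-independent
mean step speed for transparency. A displacement of 1 px/frame at
143 nm / 154 ms corresponds to 0.93 µm/s.

**Association and dwell**: colocalization is object-based — the
fraction of A-objects whose nearest B-centroid lies within a radius
(default 3 px, the same spatial scale as the motility criterion) — and
is intentionally asymmetric. For dwell analysis the reference channel
needs stable identities that survive single-frame detection dropouts,
so its detections are clustered over time (running-mean centroids,
2.5 px join radius, linear interpolation across dropout frames —
reference structures do not blink) rather than run through the
no-gap-closing tracker. Association runs per coat track are maximal
frame runs within the radius of one reference, with sticky assignment
(the current reference is kept while it stays in range); runs of the
same reference separated by at most `max_gap_frames` unassociated
frames merge (0 by default; 1 absorbs single-frame dropouts). Runs
touching a track's first or last frame are flagged censored. Dwell
summaries exclude censored events by default (their duration is only a
lower bound) and can exclude events shorter than a few frames — brief
passes of motile objects through the radius, not docking; for a
memoryless dwell process this truncation shifts the mean only by about
the cutoff (~1.4 s at 3 frames × 475 ms).

Dwell estimation needs the acquisition to be long relative to the dwell:
excluding censored events from a window only ~5 mean dwells long biases
the mean of an exponential sojourn 20–30% low (intervals that would
outlast the remaining window are censored away). The dedicated dwell
checks therefore run 3600-frame acquisitions (28.5 min at 475 ms, ~28
mean dwells), where the residual bias is a few percent.

**Reporting**: replicate series are aligned by nearest time bin and
aggregated as mean ± sample SD (n−1); condition comparisons run
classical single-factor ANOVA per time point (F = MS_between/MS_within,
p from the F distribution; degenerate variance cases defined explicitly:
identical groups F = 0/p = 1, zero within-variance F = ∞/p = 0). No
multiple-testing correction is applied across time points, and outputs
record that. Plots cover mean ± SD time courses and trajectory overlays.

## What the generator does and does not emulate

It reproduces the statistical structure the pipeline measures: spot
density and SNR regimes, two-state switching with exponential sojourns,
bleaching, shot/read noise, object-based colocalization with ground
truth. It does **not** model exposure-time motion blur (200 ms exposures
within 475 ms intervals), filament remodeling, 3-D defocus, camera gain
calibration, cargo degradation, or merging/splitting of organelles.
Passing recovery tests therefore demonstrates correctness of the
measurement chain under the stated image-formation model, not robustness
to every property of real acquisitions.

## Numerical and protocol choices

- All randomness flows from one integer seed through independent named
  streams (field / trajectories / rendering); fixed seed gives
  bit-identical movies and ground truth.
- Speed recovery protocol: ten 600-frame control movies, mean motile-step
  speed pooled over retained tracks weighted by motile-step count.
- Dwell recovery protocol: two 3600-frame, 16-object control movies,
  association radius 3 px, max_gap_frames 1, censored events and events
  shorter than 3 frames excluded; the mean is reported in minutes.
- Track-recovery bookkeeping: per-frame matching (optimal one-to-one
  within 2 px); a predicted track's identity is its majority-matched
  object; a true object is recovered when majority-identity tracks cover
  ≥ 80% of its frames; identity switches and purity are reported
  separately rather than voiding coverage.

## Known limitations

- Very long acquisitions can realize less colocalization than configured
  (admissible-site saturation, above).
- The motility criterion is a fixed displacement threshold; no MSD or
  HMM state inference is attempted, by design.
- Dwell means are estimated by censoring exclusion, not by survival
  analysis; with the long-acquisition protocol the residual bias is a
  few percent, but for short windows a Kaplan–Meier style estimator
  would be required.
- The linker has no motion model and no gap closing; fast objects are
  linkable only while their per-frame displacement stays within the
  gate radius.
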