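# Methods

This note documents the models, estimators and numerical choices behind
`endorecycle`, what the synthetic-data generators do and do not emulate, and
the known limitations of each stage.

## Conventions

Pixel coordinates are 0-based with `x` = column and `y` = row; positions
refer to pixel centres. Physical distances are Euclidean pixel distances
times `pixel_size_nm`. Time is carried explicitly per frame
(`frame_times_s`); photoactivation frames are flagged on the movie and
excluded from baseline and plateau statistics. Missing calibration is a
hard error — every biologically meaningful threshold here (the 320 nm
nearest-neighbour radius above all) is physical, so a silent 1 px = 1 unit
default would corrupt results.

## Synthetic time-lapse model

All generators share one optical and camera model: vesicles render as
isotropic 2D Gaussians of width `psf_sigma_px` (default 1.3–1.5 px, matching
a diffraction-limited spot at ~100–160 nm pixels); spot amplitude is set
from a target SNR defined as peak over background noise SD, where the
background noise combines Poisson shot noise on the camera baseline with
Gaussian read noise. Noise is applied as Poisson on expected photons
followed by additive Gaussian read noise, both optional (`noise=False`
gives exact, conservation-testable frames). Rendering uses ±5σ local
windows, so total intensity is conserved to better than 0.5 % away from
edges; moving spots are clipped to a margin that keeps them fully rendered.
All generators are bit-deterministic given (params, seed).

### Sorting assay

Cargo vesicles photoactivate inside a circular region during the pulse
frames (five pulses at 2.5 s intervals, then 150 frames at 2.5 s — the
standard confocal pulse-chase protocol) and then alternate between a *free*
state (Brownian steps, optional centripetal drift emulating dynein-directed
transport) and an *in-compartment* state (parked on one of a fixed set of
disc-shaped marker endosomes) as a two-state continuous-time process with
rates `k_entry_per_s` and `k_exit_per_s`. Per frame of length Δt the
transition probabilities are `1 − exp(−k Δt)`, which reproduces the
continuous-time relaxation `exp(−(k_in + k_out) t)` exactly at the frame
grid. Two physical constraints keep the rendered movie faithful to the
state labels:

- free vesicles are excluded from the marker discs (a step landing on an
  endosome is projected just outside it) — a vesicle colocalized with the
  marker *is* in the compartment, so chance overlap would falsify truth;
- a vesicle that exits buds out to just beyond the endosome rim before
  resuming free diffusion.

Truth records the exact per-frame occupancy fraction, per-vesicle
membership, positions and activation cohorts. Defaults (200 vesicles, 32
endosomes of radius 3 px in a 160² image at 160 nm/px, SNR 5) give vesicle
and endosome densities visually comparable to confocal data of a T cell at
this magnification.

### Recycling assay

The photoactivated pool starts in a central compartment disc (after
`n_baseline_frames` dark frames; photoactivation spans 10 cycles at 30 s,
the two-photon protocol). The recycled portion of the compartment intensity
is split into `n_quanta` vesicle quanta with i.i.d. exponential departure
times (rate `delivery_rate_per_s`, default ln 2 / 375 s so that
half-delivery lands at the measured compartment-to-membrane half-time);
each quantum transits as a moving spot and then joins a plasma-membrane
annulus. A resident PM baseline signal (`pm_baseline_fraction`, default
0.25 of the compartment intensity) is present throughout — without it the
percent-increase-over-baseline normalization would divide by a noise-level
sum. In `aggregated` mode quanta depart in merged groups, emulating the
optogenetically clustered control. Truth records the cumulative delivered
fraction per frame.

### TIRF fusion assay

Events arrive as a Poisson process (rate `event_rate_per_min`) at uniform
positions; each renders as a spot whose peak decays exponentially
(`decay_tau_s`, default 1 s) while its Gaussian width grows linearly
(`spread_rate_per_s`) — the classic signature of vesicle collapse into the
membrane. Every event carries a coincident partner-channel spot; for a
co-fusion event (probability `cofusion_fraction`) the partner peak falls by
`partner_drop_fraction` (default 0.5) over the event, otherwise it stays
constant. The default 200 ms frame interval is the coarse end of the TIRF
acquisition range; the detector requires events to persist at least one
frame, so events much faster than the frame interval are out of scope.

### Grouped traces and aggregation

`simulate_group_traces` draws two groups of per-cell traces that share a
baseline and differ by `effect_size_sd × noise_sd` from the divergence time
onward (`inf` = exchangeable null). `simulate_aggregation` places vesicles
on a jittered grid and merges spatially adjacent groups of `merge_factor`
at the switch frame, summing amplitudes (intensity conservation is exact in
noise-free mode); a remainder that `merge_factor` does not divide stays
unmerged with a warning.

## Quantification

### Segmentation

Masks are produced by thresholding a lightly smoothed frame (Gaussian σ = 1
px). The default threshold is Otsu computed in the log-intensity domain
after normalising by the median — the log transform keeps the threshold
between background and the dimmest structures when bright aggregates
stretch the histogram, and the median normalisation makes the threshold
exactly equivariant under uniform intensity rescaling. For channels whose
foreground spans a large dynamic range (single free vesicles next to
many-vesicle clusters, as in the cargo channel of the sorting assay) even
log-domain Otsu drifts above the dimmest spots; there the threshold is
additionally capped at the robust background level plus `noise_cap_sigma`
(6 by default in the incorporation trace) times the MAD-estimated noise.
Objects smaller than `min_object_px` are removed. A fixed-value threshold
mode is available, and a constant image under Otsu is an explicit error.
Thresholds are recomputed per frame by default; a fixed-threshold mode
(computed on the frame of maximal total intensity) exists for
flicker-sensitive traces.

### Endosomal incorporation

Per frame, the percentage of endosomal photoactivated intensity inside the
marker compartment: numerator = background-subtracted cargo intensity
within (cargo mask ∩ marker mask), denominator = within the cargo mask.
The denominator is deliberately the *endosomal* cargo signal, not the
whole-image signal (a whole-image option exists): the quantity asks where
the labelled endosomal pool sits, and a whole-image denominator would mix
in the positive-noise bias of summing camera noise over the full frame.
Frames with an empty cargo mask yield NaN, never a fabricated 0. Values are
clipped to [0, 100].

### Recycling trace

Per frame, the photoactivated channel is thresholded (linear-domain Otsu:
the compact photoactivated compartment is far brighter per pixel than
diffuse membrane signal, so the threshold separates them); thresholded
objects lying mostly (> 50 %) within the PM band are membrane signal and
are retained, the rest are dilated by a safety margin and removed; the
remaining signal is summed within the PM band and expressed as percent
increase over the mean of the pre-activation baseline frames.
Photoactivation frames are NaN in the output.

### Kinetic summaries

`exit_slope` is an OLS fit of the trace from `regression_start_s` (default
50 s) to the end. `half_maximal_time` defines the plateau as the mean of
the final three timepoints and returns the first crossing of plateau/2,
linearly interpolated between bracketing frames; a trace that never reaches
it returns NaN ("not reached"). `window_mean` averages over the 900–1200 s
plateau window by default. `total_recycling_halftime` adds the sorting and
recycling half-times.

### Vesicle detection, tracking, nearest neighbours

Detection is single-scale Laplacian-of-Gaussian filtering with 3×3
local-maximum selection, a robust (MAD-based) response threshold at
`detection_threshold_sigma` (default 5), and intensity-weighted subpixel
centroid refinement. Tracking links closest (track end, detection) pairs
first within `max_link_distance_px`, with gap closing up to
`max_gap_frames`; a globally optimal Hungarian mode exists but greedy is
the default for transparency. The nearest-neighbour fraction uses a k-d
tree and counts distances ≤ 320 nm (ties at the threshold count as within);
it equals a brute-force O(n²) scan exactly. The randomized control
repositions each A detection uniformly over the cell mask minus the
exclusion region (subpixel-jittered within the chosen pixel), keeps B
fixed, and averages over `n_iter` = 100 draws; under a uniform B of density
ρ its expectation is `1 − exp(−ρ π r²)`, which the tests verify. The
construction of this null — uniform resampling of positions with counts
preserved — is one defensible choice among several; it is recorded in
output provenance.

### Fusion events

Automated detection replaces blinded visual identification, with three
config-exposed criteria: (a) appearance — no detection within 1 px over the
preceding `fusion_absence_lookback` frames; (b) peak ≥
`detection_threshold_sigma` × the MAD-estimated background noise; (c)
within `fusion_confirm_frames`, second-moment width growth ≥ 20 % or peak
decay below 50 %. Two guards suppress artefacts: candidates whose
measurement window does not fit inside the frame are skipped, and a
candidate must still be bright (≥ 40 % of its peak) on the following frame,
which removes single-frame noise spikes that would otherwise satisfy the
decay criterion trivially. "Maximum intensity" is always the per-frame
maximum within a fixed (2r+1)² window (r = 3 px) centred on the detected
position, never re-centred. The co-fusion rule is strict: an event carries
the partner protein iff `(I_init − mean of last three maxima) / I_init >
0.15`; an exactly-15 % drop is negative, and a non-positive initial maximum
is unclassifiable (excluded from both numerator and denominator of the
co-fusion fraction). The drop is measured on the partner channel — the
protein being tested for presence — with the option to swap. A bleach
prefix (e.g. the 2 s membrane pre-bleach of TIRF acquisitions) can be
excluded from detection via `bleach_prefix_s`.

### Spatial metrics

Dispersion is the intensity-weighted mean distance from the cell's centre
of mass, in µm. "Centre of mass" is the intensity-weighted centroid of the
analysed channel within the cell mask (binary-centroid mode available):
the phrase is ambiguous but the weighted centroid is the natural partner of
an intensity-weighted distance. Output is absolute µm; normalisation by the
cell-mask equivalent radius is optional. Circularity is 4π·area/perimeter²
per labelled region with a Crofton (4-direction) perimeter estimate —
pixel-edge perimeters bias the circularity of discs far below 1 — capped at
1.0. Aggregation metrics run the spot detector per frame and report count
and mean integrated-intensity traces.

### Statistics

The rank-sum p-value is exact for combined n ≤ 16 — full enumeration of
group assignments on midranks, so ties are handled — and otherwise uses the
normal approximation with tie and continuity corrections. The exact branch
matters because these assays pool 3–7 cells per group. The divergence time
is the earliest timepoint T with p(t) ≤ α for *all* t ≥ T, including the
final timepoint; this "all subsequent" rule makes the family-level false
call rate conservative relative to α, which the null-calibration test
confirms. The boundary is ≤ α (not < α). Slope comparison fits a pooled
OLS model with group, time and group×time terms and returns the two-sided
p of the interaction — the classic equal-slopes ANCOVA test. The one-sample
t against a normalised 100 % mean, the unpaired Student's t of experiment
means (Welch optional), and the two-sided variance F-test
(F = larger/smaller s², p = 2·tail capped at 1) are standard; note the
convention conflict in this literature between "non-parametric Student's
t-test" phrasings — both the parametric t (default, matching how figure
annotations are usually produced) and the rank-sum alternative are
provided rather than resolving the contradiction.

## Problem sizes in tests and the acceptance script

The recovery checks run at the assay-default sizes: one 150-frame sorting
movie at 200 vesicles; a 48-frame recycling movie; one 10-min TIRF movie at
2 events/min for detection and one at 20 events/min (~200 events) for the
co-fusion fraction; 100 simulated trace-set seeds for divergence recovery
and 200 for null calibration; 100 random configurations for the
nearest-neighbour brute-force identity; 500 seeds for the equal-slopes null
uniformity. The closed-form half-time check averages occupancy over 8
replicate simulations, because a single 200-vesicle run carries binomial
noise of several seconds in its half-crossing.

## What passing tests do and do not show

The generators share their optical model with the detector assumptions
(Gaussian spots, uniform background), so recovery results certify the
estimators' correctness under the stated model, not performance on real
data with autofluorescence gradients, focus drift, photobleaching, or
3D motion through the focal plane. Specifically not emulated: z-motion
(single-plane assays by design), bleaching (no correction is applied by
default; an optional mono-exponential correction is flagged in provenance),
non-Gaussian PSF tails, and stage drift. The incorporation readout
tolerates ~±8 percentage points of mask-induced bias at SNR 5; on dimmer
real data the noise-cap threshold should be revisited.

## Known limitations

- Tracking is nearest-neighbour with short gap closing; it is not meant for
  dense or fast-moving fields (no motion model, no merge/split handling).
- The fusion detector requires events to outlive one frame interval and
  will under-count at frame intervals much longer than the decay constant.
- Circularity depends on the segmentation feeding it; the Crofton estimator
  is accurate for convex blobs but still biased for 1-px-wide structures.
- The divergence procedure applies no multiple-testing correction across
  timepoints beyond the "all subsequent" rule, by design.
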