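# Methods

This note documents the models, operational definitions and numerical
choices behind `lipodrop`, in the spirit of a methods supplement: what
each stage assumes, which parameters matter, and what the synthetic
validation does and does not establish.

## Segmentation hierarchy

**Nuclei.** The nuclear channel is smoothed (Gaussian, σ = 4 px),
thresholded by adaptive Otsu (per-window Otsu on overlapping tiles,
linearly interpolated between tile centres; windows at least as large
as the image reduce to the global threshold; tiles whose intensity
spread is under 20% of the image's inherit the global value, which
keeps pure-background tiles from thresholding noise), hole-filled, and
optionally declumped by a watershed seeded at maxima of a strongly
smoothed copy (σ = lo/10, minimum peak separation 0.8·lo, where
`lo` is the lower bound of the accepted nucleus diameter). Seeds not
separated by an intensity valley (path minimum above 90% of the dimmer
peak's elevation) are merged before the watershed — a flat-topped
object carries many spurious plateau maxima but no valleys. Objects
with equivalent diameter outside `nucleus_diameter_px = (100, 250)` are
discarded. The size gate doubles as the false-positive filter, so the
stage assumes nuclei are the only objects in that size range.

**Cells.** Foreground is the global Otsu threshold of the cytoplasm
channel (nucleus pixels are always foreground). Each foreground pixel
is assigned to the nucleus seed of minimal path cost, computed by
multi-source Dijkstra on the 8-connected pixel graph with edge weight
`d · (λ + (1 − λ)·|ΔI|/s)` — `d` the Euclidean step, `ΔI` the intensity
difference, `s` a robust intensity range (1st–99th percentile), and
`λ = propagation_lambda ∈ [0, 1]` (default 0.5). With λ = 1 or uniform
intensity this is the geodesic nearest-seed partition (Voronoi within
the foreground); smaller λ makes intensity boundaries expensive to
cross. Every cell contains its seed by construction.

**Droplets.** The neutral-lipid channel (a maximum projection for
z-stacks) is decomposed with the undecimated à-trous transform: level-j
smoothing applies the B3-spline kernel (1/16, 1/4, 3/8, 1/4, 1/16)
with taps spaced 2^(j−1) px separably (mirror boundary); detail plane
j is the difference of consecutive smooths, and the planes plus the
final smooth reconstruct the input exactly (this telescoping identity
is asserted to 1e−9 in the tests). Candidate pixels must exceed
`wavelet_k = 3` times the per-plane robust noise scale (MAD × 1.4826)
in **every** plane of a band. Two bands are used — small droplets on
levels (2, 3), large on (3, 4) — and their union is refined. Level 1
is deliberately not in the default small band: at SNR ≈ 5 its noise
scale exceeds the response of sub-resolution droplets, so requiring a
level-1 crossing costs recall with no precision gain; the split is
exposed as `atrous_levels_small/large` for data with different spot
scales.

*Refinement.* Around each candidate component (padded crop), a local
threshold is applied: by default `bg + 0.5·(peak − bg)`, with the peak
taken from a lightly smoothed copy (σ = 0.6 px) and `bg` the image
median; the contour is evaluated on the **raw** crop, intersected with
the smoothed support and hole-filled. The half-peak rule tracks the
half-maximum contour of a blurred disc and is empirically unbiased for
the projected area of disc-like droplets (median signed error ≈ 0 on
planted fields), whereas a local Otsu threshold systematically
over-grows small droplet masks (median area error ≈ 45–90% depending
on smoothing); Otsu refinement remains available as
`refine_method="otsu"`. Evaluating the contour on the raw crop rather
than the smoothed one removes the area inflation the smoothing would
otherwise introduce (largest for Gaussian-shaped spots). A candidate
whose smoothed peak does not clear the noise floor by
`peak_gate_k = 5` robust sigmas is dropped — the per-plane 3σ wavelet
crossings alone admit correlated-noise blobs at low SNR.

*Declumping.* Touching droplets are split by a watershed seeded at
local maxima (minimum separation 2 px) of the smoothed crop, but only
where a genuine intensity valley separates the peaks — the path
minimum between two peaks must fall below `merge_valley_fraction`
(default 0.9) of the dimmer peak's elevation, transitively grouped
otherwise. Without the valley gate, plateau noise on a single droplet
seeds spurious splits; without the split, droplet pairs at 1–1.5 px
gaps merge and both cluster statistics and pair tracking degrade.

*Fragment merging.* After detection, records whose masks lie within
1 px of each other (equivalently: 4-adjacent or overlapping — checked
on a label map) are merged when the minimum background-subtracted
intensity along the straight path between their intensity-weighted
centroids exceeds `merge_valley_fraction` times the dimmer record's
mean — i.e. no true valley. Merging runs to a fixed point; the merged
record is recomputed from the union mask and keeps the smallest id.
Count never increases; no area shrinks.

Records carry `area_um2 = |mask| · pixel_size_um²` and
`equivalent_diameter_um = 2·√(area/π)`; coordinates are 0-based
(row, col); areas are in μm² with a default calibration of
0.133 μm/px (so 2 px = 0.266 μm), configurable everywhere.

## Clustering

Two droplets are linked when the minimum Euclidean distance between
their mask pixel centres is ≤ `threshold_px` (default 2 px); the
minimum is attained on boundary pixels for disjoint masks, and overlap
counts as zero. The centre-to-centre definition was chosen over
counting intervening background pixels; the two differ by a constant
≈ 1 px and the threshold is a parameter. Clusters are the transitive
closure (connected components) of this relation **within one cell**;
droplets outside every cell are excluded; components of size 1 are
singletons, not clusters. The implementation (union-find with a
bounding-box prefilter and KD-trees on boundary pixels) is verified to
agree exactly with an O(n²) full-mask brute-force closure oracle on
1,000 random configurations.

Cluster statistics: arithmetic mean and sample standard deviation
(divisor n − 1, exposed as `ddof`; exact 0 for identical areas) of
member areas; per cell, `rate_k = 100 · #clusters of size k / #LDs`
for k ∈ {2, 3, 4, 5, ≥6} (the open bucket makes the partition
exhaustive; Σ_k k·rate_k/100 equals the clustered fraction ≤ 1), and a
left-closed right-open area histogram over
{0, 0.5, 1.0, 1.5, 2.0, ∞} μm². Cells without droplets report missing
rates, not zeros.

## Marker patches

Foci are per-section local maxima above a preset minimum intensity
(absolute, or the 99.5th percentile of the stack when unset — the
manual criterion made reproducible), merged across adjacent sections
(within `z_merge_um = 0.6` axially and `assign_radius_um` laterally)
at the brightest section, greedily by brightness. Only droplets with
equivalent diameter ≥ `min_ld_diameter_um = 1.0` are eligible hosts.
A focus is assigned to every eligible droplet whose boundary lies
within `assign_radius_um = 0.3` (on the order of the lateral
resolution); with three or more candidates the two nearest are kept
(ties to the lower id). A focus on exactly two droplets whose mutual
gap is within the cluster threshold is a contact-site patch, counted
once per pair.

## Time-lapse dynamics

Per-frame detections are linked by minimum-cost bipartite matching of
centroids (scipy's Hungarian solver), gated at
`max_displacement_um = 0.8` per frame; unmatched detections open
tracks, tracks unseen for more than `max_missing = 2` frames close. A
closing track whose last position falls inside another track's current
mask, with the combined area roughly conserved, is annotated as a
fusion rather than an error.

Pair association states are computed on frames where both tracks are
observed: associated iff boundary gap ≤ threshold. Two debouncing
devices suppress segmentation flicker, which otherwise dominates the
strict every-frame classification below: leaving the associated state
requires the gap to exceed `threshold + hysteresis_px`
(default 2.5 px, i.e. release at ≈ 4.5 px — midway between the 2-px
association criterion and the ≈ 8-px separation of genuinely
dissociated pairs), and the state sequence is median-filtered over
`smooth_frames = 5`. Consequence: a pair separating more slowly than
the release threshold is flagged a few frames late, and separations
that never exceed ≈ 4.5 px are not seen at all; both are acceptable
for dissociation events that move droplets well apart, and both
devices can be disabled (`hysteresis_px=0, smooth_frames=1`).

A pair associated at the window start is **static** if associated in
every observed frame of the 5-min window (150 frames at 2 s), else
**dynamic**; shorter series are evaluated as observed and flagged
truncated. A **dissociation event** starts a dissociated run of at
least `persistence_frames = 3` that follows an associated run of at
least the same length; re-association and further events are allowed.
The persistence criterion and the marker rule below are operational
definitions of what a human scorer judges by eye, and are parameters.
When measured event counts are compared with a ground-truth state
sequence, the same persistence definition is applied to both sides
(`count_persistent_dissociations`); raw state transitions at high
turnover rates include short-lived separations the event definition
deliberately excludes.

An event is **marker positive** when the mean marker intensity in a
disc of `roi_radius_um = 0.3` at the event site (centroid midpoint at
the last associated frame) exceeds the frame's robust background
(median + 3 × 1.4826·MAD) in any frame from
`t_event − pre_window_frames` (default 5) to the end of the
dissociated run; timing is **before** if the first exceedance precedes
the event frame, else **during**.

Under two-state Markov kinetics the probability that an associated
pair never dissociates within a window T is exp(−k_dissoc·T),
independent of the re-association rate; this closed form is the oracle
for the static-fraction estimator.

## Synthetic data

The generator renders what the analysis assumes, with every random
draw from one seeded generator (same spec + seed ⇒ bit-identical
output): cells as non-touching discs (nucleus diameter 110–160 px
by default, cell radius 2.2× the nucleus radius) on a jittered grid;
per cell a Poisson(100) number of droplets with log-normal areas
(median 0.2 μm², shape σ = 0.7, minimum rasterized radius 1.3 px),
~90% below 0.5 μm² — the small-droplet-dominated distribution typical
of oleic-acid-loaded cells; a `cluster_fraction` (default 0.3) of
droplets laid out as chains with rasterized boundary gaps verified in
(0.5, 2] px, while distinct entities keep ≥ 6 px, so the planted
cluster partition provably equals the gap-closure; intensities as
blurred indicator discs (PSF σ = 0.8 px) with Poisson–Gaussian noise
calibrated so the background s.d. equals `foreground/snr` (the offset
is raised to 4σ when needed so clipping at zero cannot distort the
calibration; snr = ∞ renders exactly). Marker stacks plant 3D Gaussian
foci (σ 1.5 px lateral, 1 plane axial) on eligible droplet surfaces,
at contacts, and optionally on isolated ineligible droplets (to test
the 1 μm cutoff), with pairwise separations large enough that the
z-merge rule cannot conflate them.

Movies place independent droplet pairs on a grid; each pair toggles
between an associated geometry (rasterized gap verified ≤ 1.45 px —
comfortably inside the criterion, with an intensity valley the
detector can split) and a dissociated geometry (gap 8 px) by exact
continuous-time simulation of a two-state Markov chain sampled at the
frame interval, with an optional fusion rate replacing the pair by one
droplet of summed area. Dissociations are marker-positive with a set
probability; positive events render a focus at the pair midpoint from
3 frames before the separation ("before" onsets, default 70%) or from
the separation frame ("during"), until re-association. Pair radii are
clipped to 2.0–3.2 px so the planted geometry stays within what the
detector resolves at these gaps.

What the generator does **not** emulate — spatially varying PSFs,
photobleaching, intracellular background structure, droplet motility
between events, refractive artefacts of label-free contrast — bounds
what the tests show: passing them demonstrates the algorithms are
correct and well-calibrated under the stated image-formation model,
not that the defaults are optimal for any particular microscope.

## Validation scales

The test-suite and `scripts/acceptance.py` exercise: 1,000 random
cluster configurations (≤ 30 droplets) against the brute-force oracle;
wavelet reconstruction on 100 random 256² images; planted-field
recovery on 20 cells / ≥ 1,000 droplets at SNR 5 (detection F1 ≥ 0.9,
median area error ≤ 20%, nucleus and cell counts exact); kinetics on
300-pair, 151-frame movies for k_dissoc ∈ {0, ln2/150, 5·ln2/150} s⁻¹
(static fraction within the 95% binomial interval of exp(−kT); event
count within 10% of the persistence-filtered planted log); marker
fractions {0.2, 0.6, 0.9} over ≥ 200 planted events (binomial
recovery; onset-timing agreement ≥ 90%); and noiseless foci stacks
(per-droplet counts within 10%, contact flags exact, 1 μm cutoff
respected in 100% of planted sub-threshold droplets). These sizes are
the package's chosen validation scales; larger fields change runtimes,
not conclusions.

## Known limitations

* The detector is tuned for spot-like droplets up to ~8 px radius;
  much larger droplets need deeper wavelet bands (`atrous_levels_large`).
* Area estimates assume a locally flat background; strong background
  gradients bias the half-peak contour.
* Tracking is nearest-neighbour in a single frame gap; it will swap
  identities if droplets pass within the displacement gate of each
  other between frames.
* The hysteresis/median debouncing trades a few frames of event-onset
  latency for state stability (see above).
* Cluster analysis is 2D (maximum projections); droplets stacked in z
  appear closer than they are.
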