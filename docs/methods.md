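# Methods

## Motor-clutch model of adhesion growth

The simulator in `rushquant.clutch` couples a myosin-motor ensemble to a set
of explicit substrate binding sites ("clutches"). Motors pull actin rearward
with a linear force–velocity relation

    v = v0 * max(0, 1 - sum(F_i) / (n_motors * F_stall)),

where `F_i` is the force in bound clutch `i`. Each bound clutch is a series
spring (clutch stiffness `k_c` in series with substrate stiffness `k_sub`,
effective `k_eff = (1/k_c + 1/k_sub)^-1`) loaded at the retrograde speed, so
its force grows until it unbinds. Unbinding follows a catch–slip law,

    k_off(F) = k_c0 * exp(-F / F_catch) + k_s0 * exp(F / F_slip),

the standard two-exponential form for the integrin–fibronectin bond: the bond
first strengthens with force (catch branch) and then fails (slip branch).
Free sites bind integrins at rate `k_on * d_int`, where `d_int` is the
implicit integrin density (integrins/µm²). Talin in each engaged clutch
unfolds with Bell kinetics, `k_unfold(F) = k_u0 * exp(F / F_u)`, and refolds
at a constant rate. Every unfolding event is read as adhesion reinforcement
and raises the density by `d_add`, capped at `cap_factor * d_int0`
(default 3×). Density never decreases: the model describes growth only, so
the normalized trace starts at exactly 1, is nondecreasing and never exceeds
the cap. Changed availability of newly delivered integrins is modeled purely
through `d_add` (0.01 vs 0.005 integrins/µm² are the two conditions of
interest); the explicit site count is held fixed.

**Integration.** Fixed-timestep Monte Carlo: forces are updated
deterministically, then each transition fires with probability
`1 - exp(-k * dt)`. Binding may saturate (probability → 1 in the
fast-binding limit); for the force-dependent and recovery transitions a rate
with `k * dt > 1` raises an error advising a smaller `dt`, and the
constructor warns when `dt` × the largest zero-force rate ≥ 0.1. The default
`dt = 0.02 s` over `t_end = 1800 s` (recorded every 1 s) halves-and-converges:
the mean trace at `dt = 0.01 s` lies inside the Monte-Carlo error band of the
`dt = 0.02 s` run (tested). A single integer seed makes a trace bit-
reproducible; multi-seed runs derive child seeds by unit increments. An
event-driven Gillespie simulation of the single-site bind/unbind chain serves
as an independent kinetics oracle in the test suite only.

**Parameters.** All coefficients are configuration (`ClutchParams` /
JSON), not code. The shipped defaults are placeholders drawn from the
published motor-clutch model family (motor stall force 2 pN, 50 motors,
unloaded flow 110 nm/s, clutch 1 pN/nm on a stiff 10 pN/nm substrate, 30
explicit sites) chosen once under two constraints: (i) every attainable
transition rate satisfies `k * dt < 1` at the maximum possible clutch load
`n_motors * F_stall = 100 pN`, and (ii) growth unfolds on the tens-of-minutes
timescale over which adhesion growth is observed, with the two `d_add`
conditions clearly separated and below the cap (final normalized density
≈ 2.2 vs ≈ 1.6 at 30 min). Quantitative conclusions drawn from the simulator
are restricted to value-robust properties: the unit start, monotone growth,
the 3× cap, ordering in `d_add`, and the flat-line null limits (`d_add = 0`,
`k_u0 = 0`, or no motors together with zero baseline unfolding flux — with
motors absent there is no force, but the Bell rate at zero force is still
`k_u0`, so flatness additionally requires `k_u0 = 0`).

## Synthetic-data generators

The generators in `rushquant.synth` exist to make every downstream operator
testable with exact ground truth; they emulate the *structure* of the assays,
not their optics.

**Two-channel time-lapse.** The cell is a radial shape whose edge moves
linearly in time inside configurable angular sectors (positive speed =
protrusion; defaults: one protruding and one retracting wedge on an 8 µm
cell, 0.1 µm/px, 1 min/frame, 40 frames). Adhesions are elongated structures
near the edge, oriented radially, rendered as anisotropic Gaussians
(σ ratio 4:1) over an elliptical label footprint; each nucleates at its
distal tip (the endpoint farther from the cell centroid) and extends inward.
The cargo channel follows the secretory schedule: perinuclear ER texture
before the release frame; a Golgi blob for `golgi_residence` (default
15 min) after release; then surface accumulation ramping in over 10 min —
adhesion-targeted in FN mode (with a tip-to-center front that traverses an
adhesion in 10 min, so distal sub-areas light up first) or spatially uniform
in collagen mode, plus an optional extra term in protruding sectors. Camera
noise is scaled-Poisson (variance/mean = photon gain) followed by Gaussian
read noise, and stacks are 16-bit.

**TIRF flash movies.** Static frame-0 geometry; a configured number of
instantaneous flashes (Gaussian spots, σ 1.5 px) that decay exponentially
(default time constant 2 frames). A fraction ρ (`fa_bias`) of events is
placed within 0.5 µm of an adhesion pixel, the rest uniform over the cell
mask. Adhesion footprints also carry a static marker level (default 80 above
the 100-count background) so that last-frame segmentation — the route the
end-to-end pipeline uses to build the adhesion mask — has real structure to
find. Default flashes are bright (amplitude 300 on background 100, about
30× the background noise SD), matching the high-contrast nature of pHluorin
surface flashes; this keeps detector behavior governed by the ratio
threshold rather than by noise marginality, which is what the detection
recall/precision checks are meant to exercise.

**Micropatterns and scalar fixtures.** Line, dual-line and dot patterns are
exact rasterizations (a 9 µm line at 0.1 µm/px is exactly 90 px wide); the
cargo image is multiplied by the stated enrichment on pattern pixels. Scalar
fixtures draw per-cell surface/total signals from log-normals with known
locations (scale 0 is the valid degenerate case; negative scale errors) and
produce band pairs with exact mature/immature ratios.

What the generators deliberately omit: realistic PSFs, vesicle transport,
photobleaching, cell-to-cell variability and drift. Tests passing on these
movies demonstrate that the operators implement their definitions correctly
and behave statistically as designed — not that the defaults reproduce any
particular experimental magnitude.

## Quantification operators

**Adhesions.** Global threshold (Otsu default, method selectable, optional
Gaussian pre-smoothing), 8-connected labeling, area filter `> 0.6 µm²`
(strict). When a cell mask is supplied the threshold is computed from
in-cell intensities only, so the cell/outside contrast does not dominate the
histogram. Cargo recruitment is the mean cargo intensity over adhesion pixels,
always normalized to the pre-release value in the same region. Tracks come
from greedy nearest-centroid linking with a displacement gate (default 1 µm
per frame) and are filtered to lifetime ≥ 15 min and edge distance ≤ 2 µm
(the edge-proximity radius is a configurable choice; the lifetime bound is
inclusive). The 4-area profile ranks ROI pixels by projection on the
principal axis oriented from the distal tip, splits at the 25/50/75 rank
quantiles (counts equal ±1; Area 1 contains the tip) and normalizes each
area to its own intensity 2.5 min before cargo appearance, where appearance
is the first post-release frame whose ROI mean exceeds 1.5× the pre-release
mean. Zero baselines are flagged, not divided.

**Exocytosis.** Each frame is divided by its predecessor (ε = 1 added to
both to stabilize near-zero pixels). Pixels above the ratio threshold
(default 2.0; thresholds ≤ 1 are rejected) inside the cell mask are labeled;
spots ≥ 4 px become events at their excess-ratio-weighted centroid, and a
spot within 3 px of an event in the previous ratio frame is merged as its
decay tail. Distances to adhesions use the exact Euclidean distance
transform of the adhesion mask (segmented from the last frame when run
end-to-end). The null is uniform over cell-mask pixels with, by default, as
many points as events; the comparison is a classic unpaired Student's t test
(two-sided), with a seeded label-permutation test as the alternative.

**Polarity.** Protruding/retracting regions are the set differences of
consecutive cell masks; cumulative regions are unions over a configurable
window (default: the whole movie). This is a deliberately simplified stand-in
for contour-tracking spatiotemporal maps: it classifies the same pixels
without estimating edge velocities. The longest protrusion is the maximum
distance-transform value of the initial-mask complement over pixels gained by
the final mask. Cell masks derive from the cargo channel by Otsu + largest
component + hole fill. Line profiles are bilinear interpolations at uniform
steps with an on/off-pattern flag from the nearest mask pixel; dot
recruitment is the mean-on over mean-off ratio inside the cell.

**Scalar metrics.** The surface-delivery index divides the geometric mean of
the surface-label signal by that of the total signal per time point and
subtracts the T0 ratio (geometric means computed in log space; nonpositive
samples are rejected rather than offset). The maturation ratio is the upper
(mature) over lower (immature) band intensity.

## Problem sizes and numerics

Default analysis sizes keep every check cheap and statistically meaningful:
50 seeds per clutch condition; 10^5 steps for the single-site kinetics
comparison (within 3 Monte-Carlo SE of the Gillespie oracle); 100 seeded
pipeline runs per bias condition for the exocytosis statistics (192×192 px,
20 frames, 40 events per run); 10^5 samples for log-normal recovery (±1%).
Ties in the ROI quantile split are resolved by stable sort order, with an
explicit fix-up guaranteeing the tip stays in Area 1. Degenerate inputs
(blank frames, empty masks, zero baselines) either return empty/flagged
results or raise, as documented per function.

## Known limitations

- The clutch parameter set is a documented placeholder for the antecedent
  model's published table; orderings and limits are robust to it, absolute
  growth magnitudes are not.
- Track linking is greedy nearest-centroid; it is adequate for the sparse,
  near-stationary adhesions generated here, not for dense or fast scenes.
- The protrusion/retraction operator ignores sub-pixel edge motion and
  cannot distinguish ruffling from net protrusion.
- Detection performance figures are specific to the generator's contrast
  regime; dimmer flashes than roughly twice the background will not clear a
  ratio threshold of 2.
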