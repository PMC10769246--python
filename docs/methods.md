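# Methods

## The measurement being emulated

flashmap models multiplexed FLASH-PAINT imaging of the Golgi apparatus.  In
FLASH-PAINT, each protein species carries an antibody- or nanobody-coupled
single-stranded DNA docking site; dye-labelled imager strands bind the
docking site transiently through an adapter, producing stochastic blinking
that is localized to nanometre precision.  After a species' imaging round an
eraser strand sequesters its adapter, silencing it, and the next species is
imaged — seven species in sequential rounds on one sample.  The analysis
output is a species-by-species matrix of median cross-distances between
super-resolved signals, restricted to neighbor pairs closer than 500 nm,
from which the cis-to-trans ordering of Golgi sub-compartments can be read.

The pipeline has four stages, each usable on its own:

1. **Simulation** (`flashmap.geometry`, `flashmap.simulate`) — a
   parameterized layered-Golgi ground truth and a generative model of the
   acquisition, at two fidelity levels.
2. **Localization** (`flashmap.localize`) — spot detection and sub-pixel
   PSF fitting for rendered camera frames, plus blink linking.
3. **Registration** (`flashmap.register`) — within-round drift correction
   by redundant cross-correlation (RCC) and rigid cross-round alignment.
4. **Proximity** (`flashmap.proximity`) — neighbor-filtered cross-species
   distance statistics with bootstrap confidence intervals.

## Geometry model

The Golgi ribbon is a 2-D polyline backbone; each species' layer is the
backbone offset along the local normal by its *axial offset* (the cis→trans
coordinate after near-TIRF projection) and optionally along the tangent.
Coordinates are nm, origin top-left, x right, y down; rounds and frames are
0-based, and round *r* images species *r*.

Two presets exist.  `two_layer` is two parallel straight ribbons separated
by a configurable Δ (default 60 nm, 4 µm long, 200 sites/µm) — the
controlled phantom for calibration and oracle comparisons.  `golgi7` is the
seven-target panel on a circular-arc backbone (default 8 µm of arc spanning
240°), with default axial offsets GM130 0, GRASP65 10, VPS13B 30, Giantin
80, Golgin97 190, TGN46 210 nm and β-COP displaced 300 nm tangentially.
These offsets are configuration defaults chosen to reproduce the expected
qualitative cis→trans ordering; they are **not** measured ultrastructure,
and the true offsets between these markers are unknown, so they remain
fully configurable.

The backbone is an arc rather than a straight line for an identifiability
reason: on a straight ribbon the offset between two layers is itself a
rigid translation, so any translation-based cross-round alignment can (and
will) silently cancel the biological separation being measured.  On a
curved ribbon the layer offset follows the varying normal and is not
expressible as a translation.  See "Known limitations".

Docking sites are laid on each layer as a 1-D Poisson process with the
species' linear density, thinned by the labeling efficiency (default 0.7),
and displaced per coordinate by Gaussian noise of sd
`sqrt(membrane_jitter² + linkage_sigma²)`; the linkage term (default 6 nm)
models the antibody/nanobody offset between epitope and docking strand.

## Acquisition model

Defaults mirror the emulated protocol: 7 rounds × 30,000 frames at 25 ms
exposure, 108 nm pixels, PSF sd 130 nm.  Binding kinetics are a discrete
two-state telegraph process at frame resolution: dwell times are geometric
with mean 500 frames dark and 3 frames bright (order-of-magnitude DNA-PAINT
values at tens-of-nM imager; sub-frame kinetics are irrelevant at 25 ms
exposure and are not modelled).  Event photon counts are Poisson with mean
`n_frames × photons_per_frame` (default 800 photons/frame).

Erasure is modelled by a single residual fraction ε (default 0): after each
erasure every site of the erased species independently stays active with
probability ε, so species *s* contaminates round *r* with probability
ε^(r−s) per site.  ε = 1 is rejected (contamination would never decay).
Hybridization kinetics of the eraser itself are out of scope.

Stage drift is a Gaussian random walk (default step 0.05 nm/frame) plus a
linear component (default (0.01, 0.005) nm/frame), anchored at zero at
frame 0.

*List mode* converts each blink event directly into one localization at the
site's position + drift at the event's middle frame + isotropic Gaussian
error of sd `psf_sigma/sqrt(photons)` — this makes the downstream analysis
testable in seconds.  *Frame mode* renders 16-bit camera frames
(pixel-integrated Gaussian PSF, Poisson photons and background, default 5
photons/px/frame) and exercises the full localization path.

## Localization

Candidates are local maxima of the 3×3 box-smoothed frame above
`median + k·(1.4826·MAD)` (default k = 5); maxima closer than
2·ceil(σ_psf/a) px are merged keeping the brighter (ties: smaller row, then
column).  Each ROI (half-size `ceil(2σ_psf/a)+1` px) is fit by maximum
likelihood under Poisson noise with a pixel-integrated symmetric 2-D
Gaussian plus flat background, optimized by L-BFGS-B with analytic
gradients, 50-iteration budget and relative tolerance 1e-6; non-converged
fits fall back to the centroid and are dropped (and counted) by
`localize_movie`.  The reported per-axis precision is the standard
background-corrected formula

    σ_loc² = σ_a²/N · (16/9 + 8π σ_a² b / (N a²)),   σ_a² = σ_psf² + a²/12

with fitted photon count N, background b and PSF width σ_psf.  On rendered
frames at N = 1000, b = 10, the measured RMSE is ≈ 0.9× this value; the
formula is a slight over-estimate, which is the conservative direction.

Blink linking merges same-round localizations within 100 nm in consecutive
frames (allowing one dark frame) into their inverse-variance-weighted mean
with summed photons, so long binding events contribute one record rather
than one per frame — otherwise event duration would weight the distance
medians.

## Registration

RCC splits each round into 10 equal temporal segments, renders each as a
2-D histogram (2.5 nm bins, 5 nm Gaussian blur), measures all 45 pairwise
shifts by FFT cross-correlation with 3-point quadratic sub-bin
interpolation (search window ±500 nm), and solves the overdetermined
system by least squares, anchored at each round's first segment.  Single
spurious pairwise peaks are removed by iterative worst-pair rejection
(residual > max(3× median residual, 2 bins)), never disconnecting a
segment.  Per-frame drift is piecewise-linear through segment mid-frames
with linear extrapolation at the edges.

The bin/blur choice was calibrated on the simulator (the emulated study
does not state its values): on a straight dense ribbon the along-ribbon
shift information lives entirely in the labeling speckle, which a 10 nm
blur destroys; 2.5 nm bins with 5 nm blur give worst-case trajectory RMSE
≈ 2.6 nm across drift regimes, against ≈ 0.6 nm in the structure-rich
axis.

Cross-round alignment renders each drift-corrected round and translates it
onto a reference round (default round 0) by the windowed correlation peak
(±2 µm); rotation/scale are not fit, since the field and instrument are
unchanged between rounds.  Rounds whose windowed normalized correlation
falls below 0.01 are reported as non-overlapping rather than aligned.

## Proximity statistics

For an ordered species pair A→B, the default statistic is the distance of
each A localization to its nearest B localization (k-d tree, verified
exactly against an exhaustive scan), retained iff ≤ r_max = 500 nm
(inclusive).  The per-pair summary is the median of retained distances
(mean of central two for even n); cells with fewer than 10 retained
distances are flagged invalid, never silently dropped.  An `all_pairs` mode
(every cross pair within r_max) is provided because the emulated analysis
does not state which convention it used; it produces a symmetric matrix.
Self-species cells exclude only the identical record.  Confidence intervals
are percentile bootstrap (default B = 1000) over resampled query-species
localizations; measured coverage at nominal 95% is within 90–98%.

The nearest-neighbor median has a known positive floor at zero separation
(set by localization error and site density); this floor is quantified in
the test suite against the Monte-Carlo oracle rather than subtracted.

## What the synthetic data does and does not show

The generator reproduces the features the analysis depends on: layered
geometry with controllable separations, telegraph blinking with realistic
event statistics, photon-dependent localization error, drift, imperfect
erasure, labeling efficiency and linkage error.  It does **not** model 3-D
structure (the acquisition is treated as a 2-D projection), photobleaching
or imager depletion, sCMOS pixel noise, multi-emitter overlap beyond what
the detector merge handles, or realistic Golgi morphology (areas and
varying local density rather than idealized curves).  Passing tests show
the *analysis chain* is correct and well calibrated under this model; they
do not validate the biological values of the preset offsets.

## Known limitations

- **Alignment of structurally disjoint rounds is ill-posed.**  Each round
  images a different species.  Translation alignment by image correlation
  assumes the rounds share dominant structure; on idealized thin-curve
  phantoms separated by more than the rendering blur this fails, and the
  correlation peak instead matches one flank of a layer onto another,
  biasing separations low.  Real acquisitions are 2-D textured areas with
  heavy cross-round overlap, which is what makes the approach workable in
  practice.  The proximity studies in the acceptance analysis therefore run
  on unaligned (zero-drift) list-mode data, and alignment accuracy is
  validated on shared-structure rounds; `registration.align` can be
  disabled in the run config.
- **β-COP's tangential offset is a geometric accident of curvature.**  On a
  straight ribbon, shifting a homogeneous curve along itself is nearly the
  identity, so a tangential offset would be invisible to neighbor
  distances.  On the arc backbone the 300 nm tangent step leaves the circle
  by ≈ ℓ²/2R ≈ 24 nm radially, which is what actually separates β-COP in
  the default panel.  Modelling β-COP faithfully would need a
  punctate/disjoint structure, not an offset copy of the ribbon.
- The along-ribbon component of drift on a uniform straight ribbon is
  recoverable only through labeling speckle; its null-case error
  (~2.4 nm RMSE at σ_loc = 5 nm) is several-fold larger than the
  across-ribbon error.
- Reduced problem sizes are used in tests and the acceptance analysis
  (3,000-frame rounds for list-mode studies; 3 rounds × 2,000 frames for
  the frame-mode end-to-end run); all statistics scale with acquisition
  length, and the defaults remain the full 7 × 30,000-frame protocol.

## Determinism

Every stochastic stage takes a seed; the pipeline fans a master seed out
per stage via `SeedSequence(master, spawn_key=(stage_index,))`, recorded in
the manifest, so stages can be re-run in isolation and two runs of the same
config are byte-identical in all numeric outputs.
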