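# Methods

This note documents the models, conventions and parameter choices behind
omegaquant, and what validation on synthetic data does and does not
establish.

## Kinetic model of an omegasome event

Each event is a piecewise-linear diameter trajectory d(t):

* **Expansion** — linear rise from the initial spot size `d_spot_um`
  (default 0.2 µm) to the event's maximum diameter `d_max` over
  `t_expansion_s`.
* **Maturation** — constant at `d_max` for `t_maturation_s`.
* **Constriction** — linear fall to zero over `t_constriction_s`. Stalling
  (ATPase-mutant) events interrupt the fall with a constant plateau at
  `stall_diameter_um` for `stall_duration_s`; the falling time is split in
  proportion to the diameter covered, i.e. one closure speed before and
  after the plateau.

The linear ramps are a modeling choice: measured diameter curves are
smooth but no functional form is established, and linear segments make
every ground-truth boundary exactly recoverable. Defaults follow the
measured wild-type kinetics at 2-s frame intervals: phase means
100/100/150 s (≈350-s lifetime; reported per-phase and total averages in
the literature differ by ~20 s, and the per-phase values are used), with
per-event normal sds of 15/15/20 s chosen so total lifetimes span roughly
the observed 200–450 s range. Mutant presets stall at 0.8 µm with mean
plateau durations of 150 s (ATP-binding mutant) and 100 s (hydrolysis
mutant), making the preset mean lifetimes 500 s and 450 s. Maximum
diameters are normal (1.0 ± 0.25 µm) clipped to 0.5–1.5 µm; stalling events
additionally require `d_max ≥ stall + 0.2 µm`, because a plateau closer
than about two detection tolerances to the maximum is indistinguishable
from the maturation hold and its "stall duration" would be meaningless.
An optional constant-closure-speed mode (`constriction_rate_um_per_s`)
couples constriction time to `d_max`, which is the regime in which lifetime
correlates with size.

Cargo (p62/LC3B) recruitment is Bernoulli per event
(`p_recruit_cargo`, default 0.8) with a normal onset delay
(10 ± 5 s after appearance). Event centers are placed uniformly with a
minimum pairwise separation of twice the largest expected diameter;
crowded-field behavior is deliberately out of scope. The same
random-variate sequence is consumed for every genotype, so configurations
that differ only in how draws are used (e.g. zero stall duration) produce
identical timelines.

## Rendering conventions

* Pixels are 0.08 µm (defaults), with pixel centers at integer (row, col)
  coordinates. The annulus radial profile is Gaussian with
  σ_r = √(psf² + (thickness/2.355)²) (PSF σ 0.1 µm, ring thickness
  0.15 µm FWHM).
* **The nominal diameter is the outer half-maximum diameter**: the annulus
  centerline is drawn at radius d/2 − √(2 ln 2)·σ_r. A thresholded Feret
  diameter reads the *outer* edge of a ring, so with a centerline-at-d/2
  convention every measured diameter would carry a ~2σ_r ≈ 0.25 µm positive
  bias; with the outer-edge convention the measurement recovers the
  programmed value to well under a pixel (residual bias ≈ +0.03–0.06 µm,
  from the Otsu level sitting near but not exactly at half maximum). In
  the thin-optics limit the two conventions coincide and the radial
  intensity peak sits at d/2.
* Rings narrower than 2×PSF σ are drawn as filled Gaussian spots
  (σ = √(psf² + (d/4)²)) — sub-resolution rings are indistinguishable from
  spots. Consequently the *measured* diameter has a floor of ≈0.23 µm;
  a track's readout saturates there during the final seconds.
* Cargo is a PSF-smoothed disk filling the lumen and shrinking with the
  ring, with the footprint floored at one PSF σ: cargo is recruited from
  the spot stage onward, and a sub-resolution cargo mass still images as a
  diffraction-limited punctum. Without the floor, "recruited" small-ring
  events would carry no measurable cargo signal by construction.
* Noise: Poisson on signal + background (default background 100, ring
  amplitude 400 — SNR ≳ 15 at the defaults; an SNR ≥ 5 regime is what the
  validation targets), then Gaussian read noise (σ 3), clipped at zero.
  Identical configurations (including seed) render bit-identical movies.

## Segmentation (ringtrack)

The per-track loop mirrors the manual-seed protocol: per frame, a 50×50 px
ROI around the seed; Otsu threshold over a 256-bin histogram of the ROI's
own range; strictly-above-threshold foreground; 8-connected components;
particles **larger than** 3 px (strict reading, i.e. ≥4 px); candidates
with centroids within 10 px of the ROI center; the largest-area candidate
wins (ties: smaller center distance, then lower label). The ROI recenters
on the last centroid by default (`follow_centroid`), and a track ends
after 3 consecutive frames without a surviving particle.

Numerical and robustness choices:

* **Otsu in exact integer arithmetic.** Between-class variance is
  maximized as an integer fraction in bin-index units (an affine map of
  the bin centers, so the argmax is unchanged). Floating-point
  formulations of the same quantity disagree at the 10⁻¹² level and flip
  ties between adjacent bins; integer arithmetic makes the
  lowest-threshold tie-break exact. A constant window returns its own
  value, yielding an empty foreground rather than an error.
* **Degenerate-threshold guard.** On a structure-free (noise-only) ROI,
  Otsu splits the noise distribution near its median; at ~50 % foreground
  density an 8-connected component percolates across the ROI, passes the
  area and centrality filters, and would keep a dead track alive
  indefinitely. Components larger than ROI-area/4 (configurable
  `max_area_px`) are therefore discarded; genuine omegasome masks are an
  order of magnitude smaller.  A complementary contrast gate requires the
  selected particle's mean intensity to exceed the window median by 5
  window MADs (`min_contrast_mads`, disableable): upper-tail noise clumps
  below the area cap otherwise survive sporadically and extend dead tracks
  by a few frames with arbitrary diameters.
* **Feret on pixel centers** (max pairwise distance, computed on the
  convex hull but equal to the all-pairs maximum). The outline/corner
  convention used by some tools (≈1 px larger) is available as
  `convention="corners"`; the default is documented because it shifts
  diameters by up to one pixel.

## Dynamics

Profiles: diameter = Feret × pixel size; interior gaps of ≤3 frames are
linearly interpolated; smoothing is a centered 5-frame rolling median
(edges truncated) — at 2-s cadence this spans 10 s, enough to remove
single-frame segmentation flicker without flattening 100-s-scale phases.
Tracks with fewer than 5 measured frames are skipped.

Phase boundaries: the **earliest** time at the smoothed maximum starts
constriction (a flat maximum must not defer it); the last measured frame
is full constriction; maturation begins when the smoothed diameter first
exceeds a ring-resolvability threshold (0.3 µm ≈ 3×PSF σ, configurable;
a lumen-intensity-dip detector is provided as an alternative). These are
automated proxies: the expansion/maturation split in particular does not
reproduce a visual "ring with visible lumen" annotation, and on the
simulator the measured "constriction" span includes the maturation hold
(the maximum is reached at the end of expansion). Validation therefore
compares the recoverable boundaries — first time at maximum, and
disappearance — against ground truth.

Stall detection is two-stage:

1. **Candidate plateau** — on the constriction limb (after the track first
   drops below `d_max − 0.1 µm`; the hold at maximum is maturation, not a
   stall), ignoring frames below a 0.45 µm analysis floor (the spot-size
   measurement floor plateaus trivially), find the longest run whose
   smoothed values all lie within 0.1 µm of the run's own median.
2. **Flat core** — such a band run necessarily annexes ~tolerance/rate
   ≈ 15 s of each constriction flank, so the reported interval is the
   longest sub-run whose local slope (centered least-squares fit over 11
   frames) stays within 0.0035 µm/s ≈ half the typical wild-type closure
   rate. A stall is reported when the core spans ≥30 s; the stall
   diameter is the core's median. A steadily constricting track has no
   flat core and is never reported as stalled, however slowly it closes.

All tolerances (0.1 µm band, 30 s minimum, slope window/threshold, 0.45 µm
floor) are configurable; the defaults are set relative to the 2-s cadence,
0.08 µm pixels and wild-type closure rate. Constriction success is a final
smoothed diameter below 0.5 µm. Size classes use half-open bins with
default edges 0.5/0.8/1.1/1.4 µm (the published figure does not print its
bins; these are package defaults). Trajectory ensembles align tracks at
first appearance (or at maximum diameter) and report per-timepoint mean
with Student-t 95 % CI where at least 3 tracks contribute. The
size–lifetime association is Spearman's rank correlation with average
ranks on ties.

## Recruitment

Per measured frame, the cargo ratio is mean cargo intensity over the
**filled** particle footprint (ring plus lumen — the cargo sits inside the
ring, and rim-only averaging dilutes small-ring signal) divided by the
median cargo intensity in a surrounding annulus (2 px margin, 4 px wide,
distance-transform based; it shrinks with a warning at ROI borders, and a
non-positive background is guarded). An event is recruited when the ratio
exceeds 1.5 for at least 3 consecutive frames; onset is the first frame of
the first qualifying run. Threshold and persistence are package choices —
no numeric criterion is established for "acquired p62" — and both are
echoed in the outputs. Because the statistic is a ratio, classification is
invariant to uniform intensity scaling of the cargo channel. Recruited
fractions carry exact Clopper–Pearson 95 % intervals.

## Puncta analysis

* **Rolling-ball background**: grayscale opening with a flat disk (not the
  sliding-paraboloid variant), implemented by decomposing the disk into
  one 1-D van Herk min/max filter per disk row — exact (verified against a
  direct footprint opening) and O(radius) per pixel instead of O(radius²).
  Idempotent up to clipping; within one radius of the border the
  background is underestimated because the disk no longer fits.
* **Dot segmentation**: global threshold at median + 5×MAD of the
  corrected image (both statistics scale with intensity, so counts are
  scale-invariant while sum intensities scale linearly), 8-connected
  components of ≥4 px. The original analysis ran in a commercial package
  with unstated parameters; these are documented package choices.
* **Cells**: nuclei by Otsu + hole filling + a 100-px minimum size; each
  dot is assigned to the nearest nucleus centroid (Voronoi territories —
  no membrane stain is assumed; exact ties go to the lower cell id); the
  cell count is the nucleus count.
* **Co-occurrence**: a dot co-occurs when ≥1 of its pixels overlaps the
  other channel's dot mask; both directions are reported.

The synthetic fixed-cell fields place a Poisson number of dots per cell,
each ≥6 px from its neighbours and strictly nearest its own nucleus, so
per-cell counts are recoverable exactly and recovery failures indicate
pipeline defects rather than ambiguous truth.

## Statistics

The unit of analysis is the independent experiment: raw per-cell/per-track
values are condensed to one mean per (condition, experiment) and all tests
run on those means. One-way ANOVA is paired with Dunnett's many-to-one
comparisons against the named control (multivariate-t, equal variances,
via `scipy.stats.dunnett`; the randomized quadrature is given a fixed
internal generator so reports are reproducible, and adjusted p-values are
clipped to be ≥ the unadjusted pooled-variance t-test p). With a single
treatment group the adjustment is void and Dunnett reduces to the
two-sample t-test (to quadrature accuracy, ~10⁻³). Normality screens
(Shapiro–Wilk, D'Agostino, KS) are reported but never switch tests
automatically; Mann–Whitney and Kruskal–Wallis with a hand-written Dunn
post hoc (tie-corrected rank z-tests, Bonferroni or Šidák) are explicit
alternatives. The mKeima flux statistic is median(561-nm-excited) /
median(407-nm-excited) intensity over a sample's pre-gated events; gating
itself is out of scope.

Calibration: over 1000 null simulations (3 conditions × 3–4 experiments ×
20 values), the per-experiment ANOVA + Dunnett pipeline rejects at
4–5 % for a nominal 5 % level.

## Problem sizes and validation scope

The test suite and the acceptance script run entirely on synthetic data at
desk scale: cohorts of 50 wild-type / 30 mutant / 50 truncated events on
256×256 fields (10 events per movie, 200–360 frames), 100 tracked events
per recruitment estimate, 200 ground-truth events per correlation regime,
and 1000 null datasets for statistical calibration. These sizes put
simulation error well inside the tolerances being checked while keeping
the full suite to a few minutes.

Passing on synthetic data shows the chain of segmentation, measurement and
summary statistics is internally correct and recovers known kinetics under
realistic shot/read noise. It does **not** certify performance on real
movies: the generator omits photobleaching, stage drift, ER background
structure, neighbouring/crossing events, z-dimension effects and optical
aberrations, and its phase ramps are idealized. Parameters chosen here
(stall tolerances, recruitment threshold, dot threshold) would need
re-examination on real data.

## Known limitations

* Stalls at diameters ≤0.45 µm are undetectable by design (measurement
  floor), and stalls within ~0.2 µm of an event's maximum diameter merge
  with the maturation hold.
* The expansion/maturation boundary is a resolvability proxy, not the
  visual "ring" criterion; absolute expansion/maturation durations are not
  comparable to manual annotation.
* Measured diameters carry a sub-pixel positive bias (outer-edge reading
  at the Otsu level vs half maximum); at default optics this is
  ≈0.03–0.06 µm and is left uncorrected, matching how Feret-based
  diameters are reported in practice.
* Track termination via the 3-frame gap rule can clip a track's final
  frames when segmentation flickers near disappearance; lifetimes are
  accurate to ±1–2 frames, not exactly.
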