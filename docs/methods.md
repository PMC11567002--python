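# Methods

`relsite` quantifies single-vesicle release and retrieval from
fluorescence imaging of presynaptic boutons. This note documents the
models, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that
matter.

## The measurement chain

A near-TIRF movie of a field of boutons expressing a vesicular
pHluorin reporter is reduced to physiology in five stages:

1. **Candidate detection** (`detect.detect_candidates`). Each frame is
   compared against a rolling baseline (mean of the preceding 3
   frames) so that only *newly appearing* fluorescence — a fusion
   event — survives. The difference image is band-pass filtered
   (difference of Gaussians, scales 1 and 3 px) and local maxima are
   accepted only if three statistics each exceed `threshold` robust
   SDs: the matched-filter (band-pass) value, the raw difference
   amplitude at the peak pixel, and the 3×3 neighbourhood sum. A
   single matched-filter threshold cannot deliver a low false-positive
   rate at thresholds near 3: local maxima of a smooth correlated
   noise field concentrate near the threshold, so on a 16×16-px field
   about half the background frames would produce a spurious
   candidate. The three statistics are only partially correlated under
   noise, so their conjunction suppresses false positives by nearly
   two orders of magnitude while costing a few percent recall at
   signal-to-noise 10. The robust SD is a 3-sigma-clipped standard
   deviation, which stays calibrated in the presence of sparse spots.

2. **Sub-pixel localization** (`detect.fit_spots`). Each candidate
   seeds a least-squares fit of k *integrated* 2D Gaussian kernels
   plus a constant background over a 9×9-px window. The kernel
   integrates the Gaussian over each pixel's area rather than sampling
   it at the centre — at ~90 nm pixels relative to a ~110 nm PSF the
   sampled approximation would bias positions. Residuals are
   variance-stabilised (divided by √model, floored at one photon):
   photon noise scales with the signal, and unweighted residuals let
   the quiet background dominate the fit's noise estimate, which in
   our Monte-Carlo checks under-reported the centre SE by ~1.7×.
   With Poisson weighting the reported precision (propagated from the
   parameter covariance, scaled by the reduced chi-square) matches the
   empirical scatter of fitted centres within the 15–20% band across
   photon levels.

   The number of kernels k grows while a nested-model F-test improves
   the fit at α = 0.05, capped at 3 kernels per window; by
   construction ~5% of single-spot windows will accept a spurious
   second kernel — the candidate-nearest kernel is reported, so this
   inflates the reported k, not the event count. Fits that fail to
   converge, have non-positive amplitude, a singular covariance, or a
   centre SE above `max_precision_nm` (default 100 nm) are discarded
   and counted by reason.

3. **Event consolidation and ROI assignment**. Detections within
   100 nm and ≤1 frame apart are merged (a fusion event can straddle
   two 50 ms frames); the earliest detection represents the event.
   Events are assigned to bouton ROIs (polygons in the same nm
   coordinate frame; containment is boundary-inclusive, ties go to the
   first ROI in sorted-id order).

4. **Release sites** (`sites.cluster_events`). Events of one bouton
   are partitioned by complete-linkage agglomerative clustering with
   the dendrogram cut at the clustering diameter (default 50 nm,
   threshold inclusive). Complete linkage is the only standard linkage
   whose merge height *is* the maximum intra-cluster distance, so the
   cut guarantees every site's diameter ≤ the parameter; with complete
   linkage, cutting by height and post-checking cluster diameters
   coincide. Centroids are unweighted member means (a
   precision-weighted variant exists behind a flag, off by default —
   no weighting scheme is implied by the measurement definition).

5. **Active-zone geometry** (`azgeom`). The functional AZ is the
   convex hull of all of a bouton's events; its **centre is the mean
   event position**, not the hull-polygon centroid (exposed as
   `hull_polygon_centroid` for comparison). Boutons with <3
   non-collinear events are flagged degenerate: they carry zero area
   and are excluded from area summaries but keep a centre, so distance
   statistics remain defined. Distance distributions (event→centre,
   consecutive events) are histogrammed at 10 nm bins — below the
   localization precision, above numerical noise — as fractions of
   total events with cumulative curves. Group comparisons of pooled
   event-level distributions use the two-sample Kolmogorov–Smirnov
   test; per-bouton metrics use Mann–Whitney U (two groups) or
   Kruskal–Wallis (≥3), all delegated to scipy. Pooling across boutons
   at the event level is the default (`pooling="event"`); per-bouton
   averaging first is a config switch.

## Trace kinetics

ΔF/F₀ uses F₀ = mean over the pre-stimulus baseline window (30 frames
by default); a non-positive F₀ is rejected loudly since it indicates a
bad ROI or over-subtracted background. Release probability is simply
events per stimulus pulse; values above 1 are possible for multi-site
AZs and are not clipped.

For stimulus-train responses, exo- and endocytosis rates are line
slopes over the rise (within-stimulus) and early-decay segments. The
endocytic time constant τ comes from a nonlinear least-squares fit of
`f_inf + ΔF·exp(−(t−t_end)/τ)` to the post-stimulus segment, with the
amplitude anchored to the measured value at the end of stimulation
(ΔF_max is defined at the last stimulus frame, which is robust to
post-stimulus noise peaks; a free-amplitude mode exists). τ is bounded
in (0, 10 × segment length]; bound-pinned or failed fits are flagged
not-converged, and a flat or rising segment raises an explicit
non-decaying error rather than returning a junk τ.

The **fractional retrieval block** is ΔF at `t_end + 2·τ_control`
(linearly interpolated between frames — negligible error at 0.5 s
frames against τ of tens of seconds, but defined behaviour) divided by
ΔF_max. The control τ is computed once as the mean over the control
group's converged fits and applied to *every* group; a treated group's
own τ is never substituted. For an ideal exponential the block equals
`exp(−2·τ_c/τ)`: ≈0.135 when τ = τ_c, approaching 1 as endocytosis
stalls. ΔF is baseline-referenced by default; an asymptote-referenced
mode exists for traces that do not return to baseline. The quantity is
scale-invariant in the raw fluorescence by construction.

Sensor step responses (e.g. a matrix-targeted pyruvate sensor under
0→10→0 mM perfusion) are quantified as the maximum of a smoothed
ΔF/F₀ within a response window. Smoothing defaults to a 3-frame moving
mean because the raw maximum of a noisy trace is upward-biased; for
plateau read-outs, smoothing on the scale of the sensor time constant
and reading the settled plateau keeps the bias ≤2% at SNR 20.
Ratiometric indicators are handled by `channel_ratio` (frame-wise
ratio and its windowed mean; the denominator must be strictly
positive).

## Synthetic ground truth

The `synth` module generates everything the pipeline consumes, with
defaults mirroring the experimental conditions the pipeline targets:

* **Stimulus protocols**: 200 AP at 1 Hz (single-AP mapping, 50 ms
  frames), 100 AP at 10 Hz and 50 AP at 40 Hz (train responses, 2 Hz
  imaging), 30 baseline frames.
* **Active zones**: sites placed uniformly in a disk (300–600 nm
  AZ diameters are typical) by rejection sampling with a minimum
  spacing, default 60 nm — just above the 50 nm clustering diameter so
  planted sites are resolvable by construction; infeasible packings
  fail loudly. Observed event positions are true site positions plus
  isotropic Gaussian noise, default SD 27 nm, the precision regime of
  sparse-photon vesicle imaging. Per-site release is an independent
  Bernoulli draw per pulse (at most one event per site per pulse) —
  the simplest model consistent with single-AP release-probability
  accounting. Per-site rate heterogeneity is exposed via
  `rate_profile`; defaults are a design choice, not data-derived.
* **Movies**: integrated-Gaussian spots (PSF σ 110 nm at 87 nm/px,
  matching a high-NA TIRF objective with a large-pixel EMCCD) on a
  uniform background, with Poisson noise on signal+background. Photon
  sums over a spot are Poisson-distributed by construction.
* **Traces**: pHluorin trains rise linearly to f₀+ΔF over the
  stimulus window and decay single-exponentially; step sensors
  approach and leave their plateau mono-exponentially. Trace noise is
  additive Gaussian — real traces are background-subtracted ROI means
  over many pixels, so their noise is approximately Gaussian;
  shot-noise realism is confined to the movie renderer.

What the generator deliberately does **not** emulate: vesicle-pool
depletion and replenishment, calcium dynamics, photobleaching, focal
drift, multi-component endocytic decays, and luminescence photon
statistics. Passing recovery tests on this ground truth therefore
demonstrates the *analysis* is correct and calibrated on its model
class, not that real recordings satisfy the model: τ estimates, for
instance, acquire bias when the true decay is bi-exponential, which is
a documented sensitivity rather than a failure mode.

## Site-recovery calibration

Planted-site recovery experiments must size the clustering diameter to
the localization noise. The within-site max-pairwise distance of n
events at noise σ is ≈ 2σ√(2 ln C(n,2)); at σ = 10 nm and n = 20 this
is ~65 nm, so a 50 nm cut *splits* intact sites with probability ~0.2
per site and exact recovery of 8 sites is impossible at high
confidence. The recovery tests therefore use an 80 nm diameter —
above the scatter bound, below the planted 160 nm spacing — and
recover K = 8 exactly in ≥95% of seeds at σ = 10 nm, with recovery
degrading monotonically at σ = 27 and 50 nm. Conversely, at the
27 nm noise of real recordings the 50 nm production default sits
*inside* the within-site scatter, so cluster counts over-estimate the
number of distinct physical sites; comparisons between conditions
remain valid because both are measured with the same cut.

## Problem sizes and determinism

Test-suite and acceptance-script simulations are scaled to run on one
CPU: 120–200 point sets for oracle equivalence, 10⁶-sample Monte-Carlo
membership checks per hull, 150–250 noise realizations per photon
level for localization, 200 seeded AZs for recovery, 60 replicates for
the two-condition signature, and event-level experiments of 50–120 AZs
per condition. Every stochastic component takes an explicit seed
(numpy `default_rng`); the pipeline itself contains no randomness
after data generation, and reruns with identical config and inputs
are bit-identical (a config/data hash is recorded in the run report).

## Known limitations

* Detections are single-frame (plus the merge rule); no tracking.
* No drift, bleaching, or 3D localization.
* One fitted kernel is reported per candidate, so unresolved
  simultaneous events at neighbouring sites under-count multivesicular
  release; the sparse single-AP regime keeps this small.
* The PSF width is fixed at fit time, not co-estimated.
* Nested sampling structure (cultures/coverslips/boutons) is reported
  in counts but the statistical tests are flat, matching common
  practice for this measurement; a hierarchical model is out of scope.
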