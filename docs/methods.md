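# Methods

This note documents the models behind each `chromodyn` module, the defaults
that matter, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want to know.

## FRAP

**Model.** The corrected recovery curve is fitted on post-bleach frames only
to the one-phase association model

    Y(x) = Y0 + (Plateau − Y0) · (1 − exp(−K·x)),    x = t − t_bleach,

by bounded nonlinear least squares (`scipy.optimize.curve_fit`), with the
plateau parametrized as `Y0 + dP, dP ≥ 0` and `K > 0`.  Initialization: Y0
from the first post-bleach value, the plateau from the mean of the final 10%
of frames, K from the time the curve first crosses midway between them;
restarts scale the K guess by ×0.3/×3/×10/×0.1.  The half-time is
`ln 2 / K` exactly.

**Correction.** `(bleached − background) / (control − background)`,
normalized by the pre-bleach mean of that ratio.  Dividing by an unbleached
control ROI cancels any bleaching factor shared by all ROIs — in the
generator this is an explicit monoexponential acquisition-bleaching term, so
the correction is exact there.  A background-only mode is provided because
some protocols report uncorrected normalized intensities.

**Fractions.** `Fm = (Plateau − first post-bleach)/(pre-bleach − first
post-bleach)` with the *observed* first post-bleach value, not the fitted
Y0 — the two differ under noise and the convention matters for the immobile
fraction; the fitted Y0 is reported separately.  Fm is clamped to [0, 1]
with a warning because 2% multiplicative noise can push estimates a few
thousandths outside.

**Timing.** Fits use actual timestamps; the HP1α presets have nonuniform
sampling (two baseline frames 1 s apart, post-bleach frames every 5 s for
61 s) and would be badly fitted on frame indices.

## Tracking and events

Detection per frame: Gaussian smoothing (σ = 1 px), one movie-wide
threshold `median + 0.15·(p99.9 − median)` of the smoothed stack, and
watershed from local intensity maxima (minimum peak distance 4 px) so that
two nearby foci of unequal brightness are still split — a plain
threshold+label pass cannot separate a dim focus touching a bright one.
Centroids are intensity-weighted.

Linking: per frame pair, the Hungarian algorithm on Euclidean distance with
a hard gate (`max_disp_um`; default 3× the median nearest-neighbour
frame-to-frame displacement estimated from the data, and 1.5 µm in the
bundled time-lapse analyses).  A track that ends within the gate of a
continuing track is a coalescence; a track born within the gate of a
continuing track is a cleavage.  Event engagement is the fraction of tracks
of duration ≥ 10 min that participate in at least one event, reported per
cell and summarized as median with interquartile range.

MSD: time-averaged, `MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩_t`, lags capped at 25% of
the track length to bound estimator variance.  `α` and `D_app` come from
the regression of log MSD on log τ (`MSD = 4 D_app τ^α`); the velocity from
a nonnegative least-squares fit of `MSD = 4Dτ + (vτ)²`.  The directed-
diffusion velocity is a convention (MSD-based velocity definitions vary);
a model-free net-displacement/duration estimator is emitted alongside.

## Morphometry and colocalization

Segmentation: nuclei from a heavily smoothed image via three-class
multi-Otsu (lowest boundary) — plain Otsu can latch onto the
euchromatin/chromocenter contrast instead of background/nucleus — with a
contrast guard that returns no nuclei on featureless images.  Background is
a percentile (default median) of out-of-nucleus pixels; chromocenters are
thresholded on the background-subtracted image at the half-max between the
nucleoplasm median and the 99.9th percentile, so a focus' called boundary
sits at its half-intensity radius.  For batch analyses the thresholds are
parameters to hold constant across images and conditions.

Morphometry follows the mid-section convention: each label is measured at
its optimal focal plane (the z maximizing its cross-sectional area); the
major axis comes from the second-moment ellipse.  Pearson colocalization is
computed over in-label pixels at the mid-section; zero-variance labels are
excluded and counted.  Quartile binning sets boundaries at the control
sample's quartiles; boundary ties go to the lower bin.

## RNA-FISH localization

Classes, applied to the per-chromocenter overlap fractions of each focus:
*within* if the largest overlap exceeds 50%; otherwise *between* if two or
more chromocenters are contacted; otherwise *periphery* if exactly one is
contacted; *unassociated* if none is.  Exact 50% overlaps fall on the
sub-50% branch (the rule is stated with strict inequalities), and contact
(fraction > 0) is required — zero-overlap foci are reported separately as
unassociated rather than folded into the three primary classes.

## Droplet assay

Wells are thresholded midway between the median and the maximum, connected
components filtered by equivalent-circle diameter (≥ 1 µm) and circularity
(4πA/P² ≥ 0.6).  "Detectable droplets" means ≥ 5 passing objects per field;
both cutoffs are parameters because the original readout is visual.  The
critical concentration is the minimum concentration of the dilution series
with detection; a detection pattern that is non-monotone in concentration
is flagged as a QC failure rather than silently called.

## FLIM

The two-level mask marks Laplacian-of-Gaussian spot pixels inside nuclei as
heterochromatin and the remaining in-nucleus pixels as euchromatin.  Pooled
per-region histograms are fitted with `counts(t) = A·exp(−t/τ) + b` by
Poisson maximum likelihood — tail bins hold few photons, where least
squares is biased.  The optimizer works in log-parameter space
(Nelder–Mead); in the original box-constrained quasi-Newton form the wildly
different scales of (τ, A, b) caused premature convergence and a 5–15%
upward bias on τ.  Without an IRF the fit starts one bin past the histogram
peak; with an IRF the expected curve is the convolved, period-folded decay.
Because the decay is folded into the 25 ns repetition window (40 MHz), a
delta-IRF wrapped exponential is still proportional to `exp(−t/τ)` on the
window, so the tail model is exact and the estimator stays unbiased even at
τ = 5 ns.  Fits are refused below 1000 pooled photons.  Per-image region
lifetimes, not per-pixel values, are the statistical unit in condition
comparisons.

## Statistics

All condition contrasts use the two-sided Mann–Whitney U test: exact
enumeration when both groups have < 50 observations and no ties, otherwise
the normal approximation with tie correction.

## Synthetic generator

The generator encodes the study conditions in one registry file
(`chromodyn/data/presets.yaml`); identical (preset, seed) pairs produce
bit-identical outputs.

* **FRAP traces** — the generative inverse of the fitting model: constant
  pre-bleach signal, one-phase association post-bleach, a shared
  monoexponential acquisition-bleaching factor on all three ROIs, and
  multiplicative Gaussian noise (default sd 2% of the pre-bleach level).
  Preset kinetics: TALE control `t½ = 30 s`, mobile 75% (an ~25% immobile
  component); TALE after MSR depletion `t½ = 60 s` (recovery time doubled),
  mobile 70%; HP1α control `t½ = 8 s`, mobile 85%; HP1α after depletion
  `t½ = 13 s`, mobile 74%.  Bleach depth 0.30 is a typical spot-bleach
  value; intensities are arbitrary units throughout (absolute MSR RNA
  copy numbers are unknown, so no physical intensity scale is claimed).
* **Trajectories** — fractional Brownian motion (Davies–Harte circulant
  embedding, Cholesky fallback) with Hurst α/2, per-coordinate variance
  `2 d_app τ^α` (2D MSD `4 d_app τ^α`), plus constant drift in a random
  direction.  fBm is the standard stationary-increment model for
  anomalous chromatin motion; defaults α = 0.8, `d_app` 1·10⁻³ (control)
  vs 4·10⁻⁴ µm²/sᵅ (depleted) are in the range typical of chromatin loci.
* **Time-lapses** — 41 frames at 30 s (20 min), 12 (control) or 16
  (depleted; more, smaller chromocenters) Gaussian-blob foci in a 7 µm
  nucleus at 0.1 µm/px.  Fusion and fission fire as per-focus Poisson
  processes; a fusing partner is steered radially toward the survivor with
  a bounded per-frame step, holding ≥ 0.9 µm separation until the merge
  frame and side-stepping third foci; fission daughters appear 0.9 µm from
  the parent.  A pairwise repulsion keeps non-event foci ≥ 1.3 µm apart so
  that every true event — and only true events — is resolvable by the
  tracker; real chromocenters can of course pass near each other without
  fusing, which this generator deliberately does not emulate, so tracker
  scores on it bound performance only under resolvable conditions.  The
  event rates (0.0115 and 0.0055 events/focus/min for control and
  depleted) were calibrated once by truth-level simulation so that the
  fraction of ≥10-min tracks engaging in ≥1 event is ≈45% and ≈25%.
* **Nuclei with RNA foci** — chromocenter disks plus FISH-focus disks whose
  placement is verified against the rasterized truth masks to satisfy the
  sampled localization class (within / periphery / between with
  probabilities 0.17 / 0.64 / 0.19 in the control preset); each
  between-class focus owns a dedicated close chromocenter pair (boundary
  gap 0.22–0.34 µm).  Placements that fail bounded retries are recorded as
  skipped.
* **Droplet plates** — two-fold dilution series (200 → 1.6 µM plus 0);
  wells at or above a species' critical concentration receive ≥ 8 disks
  with log-normal diameters around the species' size scale; other wells
  only sub-threshold specks; a no-RNA species never forms droplets.
* **TCSPC histograms** — multinomial draws from the period-folded
  exponential (closed form for a delta IRF; numeric convolution for a
  Gaussian IRF), 256 bins over 25 ns.

**What passing tests show.**  The synthetic data share the estimators'
model families by construction (exponential recovery, fBm, disks, Poisson
decays), so recovery tests validate correctness of the implementations and
their noise behaviour — not robustness to model misspecification, uneven
illumination, z-drift, segmentation of touching nuclei, or real PSFs, which
real data would add.

## Problem sizes

The bundled validation runs use 45–50 traces per FRAP arm, 100 nuclei per
dynamics condition, ≥ 500 RNA foci, 100 random droplet plates and 100
simulated FLIM image pairs — sizes chosen to put binomial/sampling error
comfortably inside the tolerances being checked while keeping a full run in
minutes on one CPU.
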