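# Methods

## Background

Non-invasive quantification of regional cerebral blood flow (rCBF) with
99mTc-ECD avoids arterial sampling by reading the arterial input function
from a dynamic planar radionuclide angiogram of the chest acquired during
the bolus first pass, and the regional tracer distribution from a brain
SPECT acquired ~30 min later. `ecdquant` implements the two quantification
schemes in clinical use and a paired comparison between them:

* **IBUR** (improved brain uptake ratio): a fully automatic pipeline. The
  input ROI is placed at the pixel with the highest single-frame count
  (the ascending aorta during bolus transit); the aortic peak of its
  time-activity curve (TAC) is isolated from the preceding pulmonary peak
  and fitted with a gamma variate; the input counts are the analytic
  integral of the fit. Lassen-linearized regional SPECT counts divided by
  the input counts and scaled by a planar/SPECT cross-calibration factor
  (CCF) give the regional brain uptake ratio (rBUR), converted to flow by
  the H2(15)O-PET-derived line

      rCBF (ml/100g/min) = 3.23 · BUR + 4.66.

  mCBF is the mean rCBF over the basal-ganglia segments of the normal
  hemisphere.

* **PP** (Patlak plot): manual aortic-arch and hemispheric ROIs yield input
  and tissue TACs; plotting Cb(t)/Ca(t) against (∫₀ᵗ Ca dτ)/Ca(t) gives a
  line with slope Ku (the unidirectional uptake rate for an irreversibly
  trapped tracer). Ku, normalized by a scale constant, is the brain
  perfusion index (BPI), converted to flow by the 133Xe-derived line

      mCBF (ml/100g/min) = 2.60 · BPI + 19.8.

  Regional values are distributed over the Lassen-corrected SPECT counts,
  anchored so the basal-ganglia value equals mCBF exactly.

Both intercepts are the minimum flow each method can report; the large gap
between them (19.8 vs 4.66 ml/100g/min) is why the uptake-ratio method
resolves low-flow regions that the Patlak calibration compresses.

## Models and conventions

**Gamma variate.** The bolus model is C(t) = K (t−t0)^α exp(−(t−t0)/β) for
t > t0, else 0; peak at t0 + αβ; analytic integral K β^{α+1} Γ(α+1). The
input counts use the full [t0, ∞) integral of the fitted curve rather than
a finite-window quadrature: the analytic form is exact, noise-robust, and
independent of the acquisition cutoff.

**Peak splitting.** The aortic TAC is smoothed with a 3-point moving
average (configurable); the two most prominent local maxima are taken as
the pulmonary and aortic peaks. The aortic fit window runs from the valley
between them to the point where the curve falls below 30% of the aortic
peak, truncating recirculation before it biases the fit. Fewer than two
detectable peaks is an error directing the user to manual windows.

**Gamma fitting.** Bounded nonlinear least squares over (K, α, β, t0) with
α ∈ (0, 10], β ∈ (0, 60] s and t0 below the windowed peak time, initialized
by log-linearizing the windowed samples, with up to 3 perturbed restarts.
The bounds exclude degenerate spike fits on noisy 1 s frames.

**ROI geometry.** "Diameter of d pixels" means the Euclidean disc of radius
d/2 over pixel centers (inclusive), clipped to the grid — 13 pixels for the
standard 4-pixel input ROI. TAC counts are ROI totals (not means), which
preserves Poisson statistics for downstream integration. TAC samples sit at
frame midpoints.

**Lassen correction.** Flow-tracer retention saturates at high flow; the
linearization used is F/F_r = α (C/C_r) / (1 + α − C/C_r) with α = 1.5 by
default (the classical value; configurable, since published
implementations vary) and the reference count C_r taken as the
basal-ganglia mean of the normal side — the same anchor both methods use,
keeping their regional distributions consistent. Count ratios at or above
1 + α are outside the model's domain and raise an error naming the segment.

**Basal ganglia.** The 24-segment stereotaxic template has no single
"basal ganglia" segment; the default set is {lenticular nucleus, thalamus}
(the two deep gray segments), configurable.

**Patlak details.** The input integral is the cumulative trapezoid of the
raw arch TAC (a config switch substitutes a gamma-variate fit). Points
where the input falls below 5% of its peak are dropped; the default fit
window is all points after the input peak, where the first-pass transit is
over and the plot is linear. BPI = 100 · Ku by default; the scale is
explicit configuration because the original normalization constant is not
standardized, and every cross-method result in this package is either
evaluated at BPI = 0 or is scale-free (ranks, correlations, ratios).

**Comparison statistics.** OLS regression with Pearson r (two-sided p from
the t distribution, n−2 df), paired Student t and Wilcoxon signed-rank
tests reported side by side (published comparisons rarely state which was
used; the IQR-based summaries suggest nonparametric framing), and box-plot
summary tables with PP/IBUR ratios of minima, maxima and variances.
Percentiles use linear interpolation (type-7); variances use n−1.
rCBF-level comparisons treat each subject × segment as one observation.
All-zero paired differences return p = 1 with a warning; a constant
nonzero difference (zero-variance t statistic) returns p = 0 with a
warning.

## The synthetic acquisition simulator

The paper trail for this class of methods deposits no raw data, so the
package ships a forward simulator that generates the full input set with
known truth:

* **Planar scene** (default 64×64, 120 frames at 1 s, 4 mm pixels; the
  clinical 128×128 matrix is available through `GridSpec`): a pulmonary
  Gaussian blob with an early fast bolus (α=2, β=0.9 s, t0=2.5 s) partially
  overlapping the ascending-aorta spot, whose gamma-variate bolus (α=3,
  β=1.8 s, t0=9 s) peaks at ~1000 counts/frame in the standard 4-pixel ROI
  — making its center the global count maximum, the premise of automatic
  detection, while forcing the peak-splitting step to work for its answer.
  An aortic-arch spot shares the aortic time course (the Patlak input);
  brain pixels follow microsphere kinetics, accumulating Ku times the
  running trapezoidal integral of the arch-ROI curve, so the Patlak plot of
  the extracted TACs is exactly linear with slope Ku.
* **SPECT volume** (default 32³): an ellipsoidal brain split into 12 axial
  bands per hemisphere (a synthetic, purely geometric stand-in for the
  anatomical template). Per-segment counts are constructed by inverting
  the Lassen correction at the true α around a reference level solved so
  the basal-ganglia mean is its own fixed point — applying the forward
  correction therefore reproduces counts exactly linear in the true uptake
  ratio. Planar and SPECT count scales are linked by a known CCF
  (default 120, giving realistic hundreds of counts per voxel).
* **Truth wiring.** Per-segment flows vary around the subject's mCBF
  (CV 12%, clipped to 8–90 ml/100g/min), with the normal-side
  basal-ganglia pair pinned to a ±3% split so their mean is exact. SPECT
  counts encode flows through the inverse of the BUR calibration line, so
  the IBUR pipeline run with the true CCF and α recovers them. The Patlak
  slope is placed on the PP calibration scale via the empirical
  between-method relation IBUR = 1.25·PP − 17.5, so a simulated cohort
  reproduces the clinically observed systematic offset between the methods
  (PP higher and narrower at low flow) rather than pretending they agree.
* **Noise.** Optional per-pixel/per-voxel Poisson sampling of both
  modalities; everything is reproducible from an integer seed, and
  noiseless output is deterministic regardless of seed.

### What the simulator does not emulate

Projection-domain physics (attenuation, scatter, collimator blur, OSEM
reconstruction noise correlations), patient motion, anatomical shape,
dispersion/delay of the bolus between arch and ascending aorta, tracer
washout and recirculation. Passing recovery tests therefore demonstrates
the correctness of the analysis chain — detection, splitting, fitting,
integration, linearization, calibration — under the stated kinetic model,
not robustness to every artifact of real acquisitions.

## Problem sizes and numerical choices

Tests and the reproduction script run at the default desk-scale grids
(64×64 planar, 32³ SPECT), chosen to exercise every code path with
realistic count statistics. Recovery checks use one noiseless subject for
the Patlak oracle, a 15-subject noiseless cohort for end-to-end IBUR
recovery (matching the clinical cohort size), and 100 Poisson seeds for
noise robustness. Optimizer tolerances are 1e-14 (xtol/ftol/gtol);
the inverse-Lassen reference solve uses Brent's method to 1e-12.

## Known limitations

* The Eq-linear calibrations are taken as published constants; the package
  does not re-derive them from PET or 133Xe experiments.
* The uptake ratio uses segment mean counts with no decay correction
  between the 2-min angiogram and the 30-min SPECT; any such factor is
  absorbed into the CCF, as is conventional.
* The simulator's microsphere assumption makes Patlak exactly linear;
  real ECD kinetics show mild early washout that biases Ku slightly
  downward in practice.
* rBUR in the simulator is proportional to flow *minus the calibration
  intercept* (the quantity the calibration line inverts), not to flow
  itself; proportionality tests are stated against that quantity.
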