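# Methods

This note records the models implemented in `smallfield`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user should know before trusting a
number.

## Convolution beam model

The lateral dose distribution of a circular cone beam in water at a fixed
depth is modelled as a 2D convolution of a rotationally symmetric photon
fluence with a rotationally symmetric dose-deposition kernel,
`D(r) = ψ(r) ∗ K_D(r)`.  The model is linear in the fluence and carries no
spectral or depth dependence of its own: one kernel describes one depth.
Assumptions: radial symmetry of both factors (circular collimation, beam
axis perpendicular to the scan plane) and a spatially invariant kernel
across the field (valid for fields a few cm and below).

Numerics: the convolution is evaluated on a square Cartesian grid
(default spacing **0.1 mm**, the finest scan step used by the simulated
detector signals) by FFT, with zero padding; the grid must contain the
kernel support or a `TruncationError` is raised.  Kernel normalisation is
*stored*, never forced to one — the convolution fixes only the product's
shape, and all downstream metrics are normalisation independent (profiles
are normalised to the central axis).  Discontinuous sources (top-hat edges)
can optionally be sampled at sub-cell resolution (`supersample`) to reduce
the O(h) edge-quadrature error of cell-centre sampling.

Step decomposition represents a sampled fluence as
`ψ(r) = Σ wᵢ·1[r ≤ Rᵢ]` with plateaus taken at bin centres, so the
decomposition reproduces the input exactly there; trailing zero bins are
dropped and the outermost step is clipped to the sampled support, so an
ideal top-hat decomposes to a single step at its physical edge radius.

## Van Cittert deconvolution

The virtual fluence source is recovered from a measured profile by the
fixed-point iteration `ψ⁽ᵏ⁺¹⁾ = ψ⁽ᵏ⁾ + α(D − K∗ψ⁽ᵏ⁾)`, `ψ⁽⁰⁾ = D`.
Defaults: α = 1.0, at most 500 iterations, stop at a relative L2 residual
of 1e-4, with a non-negativity clip after each update (a fluence is
physical).  The profile is folded onto a radial axis and the forward
operator is the full 2D rotationally symmetric convolution evaluated along
a diameter — not a 1D convolution, which would distort the radial
geometry.

Optional regularisation: `smoothing_window` applies a moving average to
the **residual correction** each iteration.  Smoothing the iterate instead
was measured to bias the converged source (≈3% forward deviation in the
seeded noise test vs ≈0.5% for correction smoothing), so the correction
variant is implemented.  Nothing is smoothed unless requested.

A fundamental limit worth stating: the iteration recovers frequency f with
factor `1 − (1 − H(f))ᵏ`, where H is the kernel transfer.  For a Gaussian
kernel of σ = 0.5 mm and 500 iterations the effective cutoff is
≈1.3 cycles/mm, so an ideally *discontinuous* source edge is recovered only
as a ≈0.5 mm-wide ramp; the residual L2 distance to the ideal step is then
≈16% no matter how the iteration is tuned.  The recovered width (FWHM
within 0.1 mm) and the forward re-convolution (sub-1% of the central dose)
are the meaningful accuracy statements; pointwise L2 against a
discontinuous truth is band-limited.

Divergence (residual increasing for 5 consecutive iterations) aborts the
run with a warning and a partial result rather than an exception.

## Scan analytics

Field size is the full width at half maximum of the lateral profile;
penumbra is the 20–80% distance per edge.  Crossings are located by linear
interpolation between bracketing samples, taking the **outermost** crossing
on each side (robust to noisy shoulders); the field centre is the midpoint
of the two 50% crossings, mirroring how a detector is centred on the
radiation field.  No smoothing is applied to profiles by default — a 3 mm
profile is sharp enough that a 5-sample window visibly biases the
penumbra.  In the 2D radial geometry the FWHM of a top-hat beam sits
*slightly below* the nominal diameter (an edge point of a convex disk sees
slightly less than a half plane), typically by a few hundredths of a mm
for realistic kernels.

The depth of dose maximum is the argmax of a moving-average-smoothed PDD
(default window 5 samples) refined by a parabolic fit through the three
points around the discrete maximum; percentage doses at depth are linear
interpolations of the smoothed curve relative to its maximum.  Because the
build-up maximum is flat, single noisy scans estimate d_max with a spread
of a few tenths of a mm; the acceptance script averages five repeat scans
before analysis, as in routine commissioning.

## Detector response

The perturbation decomposition uses the four-step signal chain (full
detector → housing replaced by water → sensitive chip replaced by water →
point voxel), each factor being the ratio of adjacent signals normalised
to the 25 mm machine-specific reference (msr) field.  The product
telescopes *exactly* to the total correction; this identity is enforced at
1e-12 for signal-derived factor sets.

* "Point" dose is the average over a **0.2 mm** square voxel footprint —
  the scoring-voxel size of the reference transport calculations — not a
  single grid sample.
* Disk/voxel averages weight grid cells by covered area, approximated by
  5×5 sub-sampling of boundary cells.  On a 0.1 mm grid with a 0.75 mm
  disk radius this reproduces closed-form quadratic-profile means to
  ~1e-5 relative and a 10⁶-point Monte-Carlo oracle to <0.1%.
* Density over-responses of housing and chip are **data**, packaged from
  published factors in `data/perturbation_factors.csv` (with a provenance
  column); the package performs no radiation transport.  Components not
  published for a field size are stored as absent and never silently
  interpolated.  Two published roundings of the 3 mm housing factor exist
  (0.973 and 0.9725); both are stored and 0.9725 is used in the worked
  product.  The packaged printed totals (0.988, 0.998, 1.033 for 5, 4,
  3 mm) are carried verbatim even though the 3 mm component product rounds
  to 1.034 — a rounding inconsistency in the source data, preserved rather
  than "fixed".
* The geometric volume-averaging factor computed from the anchored
  synthetic 3 mm and 25 mm beams is ≈1.079, consistent with the published
  transport-derived 1.075; agreement at the 0.005 level is expected, not
  exact, since the published value includes transport effects the
  geometric average cannot see.
* The signal emulator scans the sensitive disk across a dose map and
  multiplies by the field-size-interpolated density over-response; its
  profiles are slightly broader than the underlying dose (≈0.1 mm in FWHM
  for the default 1.5 mm disk on the 3 mm beam), reproducing the known
  behaviour of diode scans in very small fields.

## Film dosimetry

The response variable is net optical density against an unexposed film of
the same batch, `netOD = log10(I_unexposed/I_exposed)`, computed on the red
channel — the dominant convention for this film type; the calibration is a
least-squares cubic netOD → dose over 0–2 Gy, required to be strictly
monotone on the calibrated range and to map zero response to within
±0.02 Gy of zero.  Beam-quality transfer between the calibration and
measurement beams is a unity factor in config (film response is weakly
energy dependent), adjustable.  Dose maps clip responses to the calibrated
range and refuse to proceed if more than 1% of pixels fall clearly outside
it.  Output factors are read from a 5×5-pixel central ROI after 5×5 median
filtering, with the field centre found from the 50% crossings of the two
orthogonal central profiles; the ROI must sit in the flat core (checked
against the centre pixel).  Uncertainty is type A (k=1) from the repeat
scatter of both fields, combined in quadrature.

## Output factors

`OR = M_det(f_clin)/M_det(f_msr)` from signal-per-MU readings; repeats give
the ratio of means with quadrature-combined standard errors.  The
field-size response fit is `OF(s) = p·sⁿ/(aⁿ+sⁿ)·(1 − e^{−b·s})` — a
saturating sigmoid (source-occlusion) times an exponential build-up
(phantom scatter) — fitted by bounded nonlinear least squares from five
deterministic starts, lowest residual sum winning.  On noiseless data the
parameters are recovered exactly.  With noise the *curve* is recovered
essentially unbiased, but the individual parameters are not identifiable:
the two saturating factors can trade roles, so (a, b, n) wander far more
than the curve does.  Users should interpret the fitted curve, not its
parameters.

## Synthetic-data generator

The generator defines the study conditions for all tests; every generator
is a pure function of (parameters, seed) and returns its ground truth
alongside the samples.

* **Lateral profiles**: top-hat fluence of the nominal diameter convolved
  with a two-Gaussian kernel (core σ = 0.85 mm, tail σ = 1.5 mm, tail
  weight 0.2), calibrated once so the 3 mm beam at 7 mm depth shows
  FWHM 3.01 mm and 20–80% penumbra 1.35 mm — the measured values for this
  beam.  With depth, the field size grows per an anchored table
  (3.0 → 4.8 mm between 7 and 250 mm depth) and the kernel broadens to
  track the measured penumbra growth (1.35 → ≈2.35 mm); values between
  anchors are linear interpolations, a modelling choice.  Scan noise is
  additive Gaussian at 0.5% of the maximum (short-dwell scanning).
* **Depth dose**: `A(1 − e^{−μ₁z})e^{−μ₂z}` with (μ₁, μ₂) solved so the
  3 mm cone peaks at 4.8 mm depth with 35.6% dose at 100 mm, and the
  25 mm reference cone at 7.8 mm with 41.2% — the measured anchors;
  coefficients for intermediate diameters are interpolated.
* **Film**: a monotone cubic netOD→dose truth (inverted numerically on a
  dense grid), 16-bit intensities, 1% multiplicative pixel noise, 600 dpi;
  green/blue channels darken with reduced sensitivity.
* **Detector readings**: a true output-factor curve (defaults p=1, a=3,
  b=1.1, n=3, shaped like the measured film output factors of this cone
  set) divided by the packaged total correction, so correcting the
  readings recovers the truth.

What the generator does **not** emulate: transport-code statistical noise,
scanner artefacts (vignetting, lateral response), beam inclination,
contamination electrons in the build-up region, energy-spectrum changes
with field size, and detector dose-rate or temperature dependences.
Passing tests therefore demonstrate the correctness of the analysis chain
under idealised radially symmetric conditions, not the accuracy of any
physical beam model.

## Problem sizes

Default grids: 0.1 mm spacing, profiles ±8–13 mm, PDDs 0–250 mm at
0.2 mm; deconvolution ≤500 iterations on ~160-point radial grids; film
images 40–80 px squares at 150–600 dpi; Monte-Carlo cross-checks 10⁶
points.  The full test suite runs in well under a minute and the
acceptance script in a few seconds.
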