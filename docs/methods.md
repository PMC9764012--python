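# Methods

## Scope and data model

The package models an experiment in which the surface gas concentration
over a thin skeletal muscle is stepped between O₂/CO₂ levels while single
capillaries are imaged.  The unit of analysis is the capillary-second:
per-second red-blood-cell (RBC) velocity (µm/s), lineal density
(cells/mm), tube hematocrit (%), supply rate (cells/s) and hemoglobin
oxygen saturation SO₂ (%).  Nine challenge regimes are built in: four O₂
steps (7–12, 12–7, 7–2, 2–7 %, CO₂ held at 5 %), four CO₂ steps (5–0,
0–5, 5–10, 10–5 %, O₂ held at 7 %) and one combined regime (7→2 % O₂ at
60 s, then 5→10 % CO₂ at 120 s), with N₂ as balance gas.  Time runs
t = 1..180 s at 1 Hz (1-min baseline + 2-min step), or 1..240 s for the
combined regime; placing the step at t = 60 s makes the fitted onset-delay
constraint `X0 > 60` meaningful.

## Response kinetics

Single-step responses follow a delayed mono-exponential,
Y(t) = Yb + Y0·(1 − e^−(t−X0)/τ) for t ≥ X0 and Y(t) = Yb before onset.
The pre-delay branch is a deliberate convention: the bare formula is
undefined for t < X0, and delayed-onset kinetics models conventionally
hold the baseline there, which also matches flat observed baselines.  The
combined regime uses a two-component model in which each component is
gated by its own delay (X2 ≥ X1); component 1 captures the O₂ response,
component 2 the CO₂ response.

τ is the time after onset to reach 1 − 1/e ≈ 63 % of the asymptotic
amplitude; this identity is verified in the test suite by direct
evaluation at t = X0 + τ.

## Constrained fitting

The least-squares objective over the fit window is non-smooth in the
delay(s) because of the onset indicator.  The fitter therefore:

1. scans a coarse delay grid (0.5 s for the mono delay; 2 s × 4 s for the
   two bi-exponential delays).  At each grid point the amplitudes
   (Yb, Y0[, Y2]) are solved in closed form by linear least squares and
   the time constant(s) optimised by bounded search on log τ — a 1-D
   Brent search for the mono model, a bounded 2-D least-squares for the
   bi model.  Ties in SSR break toward the smaller delay (ascending
   scan), and the τ search spans [10⁻³ s, 10 × window length];
2. polishes all free parameters with bounded trust-region least squares
   (`scipy.optimize.least_squares`, ftol = xtol = gtol = 1e-14,
   max 500 evaluations).  Although the residual has a derivative kink in
   the delay at each sample time, the squared residual is C¹ there, so
   the polish converges to machine precision on noiseless data (verified:
   interior-delay round trips recover parameters to 1e-6 relative for the
   mono model and 1e-4 for the bi model).

Constraint dialect: a strict bound "> 60" is encoded as a lower bound
60 + 1e-6; "= 60" pins the parameter out of the optimisation; "no set
value" leaves the parameter unbounded; a range such as 51–180 is the fit
*window*, not a parameter bound.  Published per-response constraint
variations (one "> 59" delay bound, one pinned delay, narrowed or
unbounded saturation windows) are carried in the parameter library rather
than hard-coded in the fitter.

A fit is flagged unidentifiable when the recovered amplitude is below a
noise floor (default 1e-6 of the data scale, overridable); the time
constant is then meaningless and reported as NaN, with the raw optimiser
solution retained in a debug field.  A flat series is the canonical case.
Non-convergence (all starts failing) yields a result carrying no
parameters.  The amplitude parameters themselves are left unbounded, as
in the published constraint sets.

On a bi-exponential fit of genuinely mono-exponential data the second
component is unidentifiable (any amplitude split with equal time
constants fits); the fitted *curve* is correct even though individual
parameters are not, and the tests compare curves in that case.

## Synthetic populations

Each capillary draws a baseline per simulated measure (velocity, lineal
density, SO₂) from a truncated normal around the population mean ± SD
(SO₂ truncated to [0, 100], velocity and density to ≥ 0) and an amplitude
perturbation (normal, SD configurable, default 0) applied as a shared
scale factor so that a capillary's two combined-challenge components keep
their proportion.  The kinetic curve is evaluated on the 1 Hz grid,
independent Gaussian observation noise is added per second, and samples
leaving physical bounds are clipped with a tallied warning.  Hematocrit
and supply rate are then **derived from the noisy velocity and density**
(not drawn independently), so the identity SR = v·LD/1000 holds exactly
in ground truth, as it must by construction.

Population parameter defaults are the published per-challenge baseline
means ± SDs and fit parameters, carried in `capkinetics.params`.  Two
points are package decisions where the source is silent: per-capillary
responses share the population time constant while amplitudes vary
(individual τ heterogeneity is unidentifiable from mean-trace fits
anyway), and the population-mean amplitude lives in the kinetic template
rather than being duplicated in the population spec.  Default observation
noise is zero; the examples use noise SDs of roughly 10 % of typical
baselines (20 µm/s, 5 cells/mm, 2 % SO₂), which visually match shaded
SEM bands at a few hundred capillaries.

Randomness uses a single root `SeedSequence` with per-capillary child
streams, recorded in the output sidecar; identical seeds reproduce
identical populations bit-for-bit.

## Kymograph rendering (forward optical model)

A space–time image is rows = position along the capillary (row 0 =
upstream), columns = frames.  Cells are advected along the space axis at
the per-second ground-truth velocity; each cell traces a streak of slope
velocity/(µm-per-px × fps) pixels per column.  Cell centres are laid out
by a single walk along the line with local spacing 1000/LD of the second
during which that stretch occupies the field, jittered uniformly within
±20 % of the spacing.  The jittered-regular layout (rather than a pure
Poisson process) reflects single-file capillary traffic, in which cells
cannot overlap, and keeps object counting meaningful at high density.

Transmitted intensity is I₀·10^(−OD) inside cells and I₀ outside.  At
420 nm (isosbestic) the cell OD is saturation-independent; at 438 nm it
interpolates linearly between calibration ODs at SO₂ = 0 and 100 %.
Additive Gaussian sensor noise is applied last, with negative intensities
clipped at zero.  Defaults (0.65 µm/px, 60 fps, 200 µm field, 6 µm cell
length, I₀ = 10⁴ counts, OD₄₂₀ = 0.35, OD₄₃₈ = 0.50/0.25) are explicit
configuration, chosen as typical for 10× intravital imaging — the
acquisition parameters of the source experiment are not public.

What the renderer does **not** emulate: motion blur within a frame,
partial-volume edge intensities, focus drift, vessel curvature,
beam-splitter misregistration, cell-to-cell SO₂ or shape variation, and
photon (shot) noise — sensor noise is additive Gaussian only.  Passing
round-trip tests therefore demonstrates correctness of the estimators'
geometry and algebra, not robustness to every real-world artifact.

## Hemodynamics recovery

*Velocity* — per 1 s block, an exhaustive projection-angle (Radon-style)
search: shear the block by a candidate slope and score the variance of
the time-averaged profile, which is maximal when streaks align.  Scoring
averages over time chunks short enough that the largest candidate shear
stays within the field; a golden-section refinement around the best
coarse candidate (121 slopes up to ±1500 µm/s by default) gives sub-pixel
slope accuracy.  Ties break toward smaller |velocity|; blocks with no
cells yield missing values with a zero quality flag; best slopes at the
search limit are flagged saturated.  Noise-free accuracy is ≲1 % across
50–600 µm/s (5 % is the guaranteed envelope).

*Lineal density* — per column, below-threshold runs at least half a cell
length long are counted and divided by the field length; the half-length
minimum also cancels edge-clipped partial cells, keeping counts unbiased
at the boundaries.  The threshold is an Otsu bimodal split per second
(midpoint fallback, constant override available).

*SO₂* — cells detected on the isosbestic image; per cell,
OD = −log₁₀(I/I₀) at both wavelengths and
SO₂ = 100·(OD₄₃₈/OD₄₂₀ − r₀)/(r₁₀₀ − r₀), the exact inverse of the
forward model (real-data calibration is out of scope).  Cells with no
measurable isosbestic absorbance are skipped — never reported as SO₂ = 0;
cell-free seconds are missing.  Per-cell values are clipped to [0, 100]
with the raw mean retained.

*Derived* — tube hematocrit Hct = 100·LD·V_rbc/(π(d/2)²·1000) (defaults
55 fL, 5 µm) and supply rate SR = v·LD/1000, exact arithmetic.  Frame-
level measurements aggregate to 1-second means with the contributing
frame count as quality flag; missing seconds propagate as missing.

## Onset statistics

Per capillary, the baseline score is the mean over the 51–60 s window;
each post-step second is tested by the paired difference against that
score (within-capillary, so between-capillary heterogeneity cancels).
The family of post-step seconds is adjusted Dunnett-style: under an iid
null the differences at two post seconds share the baseline term, giving
equicorrelation ρ = 1/(m+1) for an m-second baseline, and the adjusted
p-value is P(max over k seconds of |T| ≥ |t_obs|) for equicorrelated
t-variates.  Balanced designs use the exact mixing representation
(conditional independence given the shared normal factor and the χ²
denominator), integrated with 48-node Gauss–Hermite × Gauss–Legendre
quadrature — cross-checked in the tests against `scipy.stats.
multivariate_t` sampling and an internal Monte-Carlo path.  Designs made
unbalanced by missingness fall back to seeded Monte Carlo (100 000 draws)
of the same model with ν = smallest per-second df, dropping capillaries
per comparison only.

This construction replaces a full mixed-effects likelihood fit with the
explicit paired-comparison structure it represents; the trade-offs are
transparency and exactness under the stated null versus generality.  Each
second is studentized by its own variance (robust to variance changes
along the response), which departs from the common-variance assumption of
the classical procedure: with ~100+ capillaries the family-wise error is
calibrated (measured 0.062 at n = 100 against the 0.05 ± 0.02 band), but
with very few capillaries (ν ≲ 10) the nearly independent denominators
make the test anti-conservative (measured FWER ≈ 0.19 at n = 6).  The
intended operating range is tens to hundreds of capillaries, as in the
source experiments (n ≈ 80–300 per challenge).

The onset summary reports, per measure × challenge: baseline mean ± SD,
first post-step second with adjusted p < α (α = 0.05 default), and the
peak/nadir of the post-step means — direction taken from the sign of the
post-window mean minus baseline, ties counting as a peak — with its time
and adjusted p.  When no second is significant all response fields are
NA while the baseline is still reported.  The combined challenge produces
two summary rows per measure: post-low-O₂ seconds (61–120 s) against the
51–60 s baseline and post-high-CO₂ seconds (121–240 s) against the
111–120 s window.  Percent change is the plain arithmetic
100·(extreme − baseline)/baseline.

## Pipeline

`run_pipeline` composes the stages per challenge from a validated YAML/
JSON config: simulate → write ground truth → (optionally render and
re-analyze a configurable number of capillaries' kymographs) → fit each
measure's population mean trace under the library constraints → onset
statistics → plots and a manifest (config hash, seed, warning tallies,
per-stage timing).  Fits and statistics always run on the tabular ground
truth; the image layer validates the extraction chain on the capillaries
it renders.  Challenge failures are isolated and recorded; outputs are
byte-identical under identical config + seed (floats serialized at
10 significant digits).

## Numerical and scale choices

- Strict-inequality epsilon 1e-6 s on delay bounds.
- Quadrature: 48 nodes per axis; adjusted p-values accurate to ~5e-3 in
  the 0.01–0.10 range that decisions depend on.
- Test/validation problem sizes: STI round-trips use 6-s clips on a
  5 × 3 velocity × density grid spanning 50–600 µm/s and 10–100 cells/mm;
  the null-calibration study uses 1000 replicates of 100 capillaries ×
  120 post seconds; noisy-τ recovery uses 200 replicates at 5 %-of-
  amplitude noise.  These sizes make the full validation suite run in a
  few minutes while keeping Monte-Carlo standard errors well inside the
  asserted bands.

## Known limitations

- The SO₂ inversion shares its calibration with the renderer; applying it
  to real images requires an external calibration.
- The family adjustment is anti-conservative below ~10 capillaries (see
  above) and assumes the baseline window is complete.
- The velocity estimator assumes a single dominant streak orientation per
  second (single-file flow); reversing flow within a second is reported
  as the dominant orientation.
- Confidence intervals on τ are not provided; fits report point estimates
  and R² only.
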