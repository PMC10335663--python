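# Methods

This note records the models implemented in `pyoptode`, the assumptions they
rest on, the defaults that matter, and what the synthetic-data tests do and
do not demonstrate about real data.

## Sensing model

A platinum-porphyrin optode disk fluoresces red under blue excitation; the
red intensity is collisionally quenched by dissolved oxygen while the green
(antenna/reference) emission is oxygen-insensitive. Ratioing the two
channels cancels excitation-intensity and coating-thickness variation. Two
ratio definitions are carried side by side for every sample:

- `ratio_larsen = (red − green)/green`, the standard form for cameras with
  the internal IR-blocking filter removed;
- `ratio_simple = red/green`, used when the filter is intact, where the
  Larsen form can go negative (green exceeding red) and break curve fits.

They differ by exactly 1, so both carry the same information; what matters
is that calibration and measurement use the same definition (the
calibration registry stores which one each curve was fitted on, and
`build_timeseries` refuses a mismatch).

The response follows a modified Stern–Volmer law,

R(C) = R0·[α + (1−α)/(1 + Ksv·C)],

with C in % air saturation. Ksv values near 0.01 per % saturation make the
ratio fall by roughly half over the 0–100 % range. α is the non-quenchable
signal fraction; R never falls below α·R0, so inversion is only defined on
the open band (α·R0, R0]. Ratios above R0 are clamped to C = 0 with a
super-saturation warning (they indicate drift or a reading beyond the
zero-oxygen baseline); ratios at or below the floor raise an error rather
than extrapolate.

### Fitting

`fit_calibration` runs bounded nonlinear least squares with a deterministic
start (R0 from the lowest-concentration ratio, Ksv from a two-point
estimate, α from 0; no random restarts). By default α is fixed at 0 — the
two-parameter form is what per-disk coefficient tables report and it is
identifiable from as few as 3 distinct concentrations — with `fix_alpha_zero
= False` freeing the full three-parameter model (requires ≥ 4 distinct
concentrations). Whether the original per-disk tables were produced with α
free is not documented; fixing it by default reproduces those two-parameter
rows exactly, which is why it is the default here.

### Detection limits

LOD = |3.3σ/m| and LOQ = |10σ/m|. σ is the *population* (n-divisor)
standard deviation of repeated back-calculated measurements at a single
probe concentration (population σ is what reproduces the published 1.1±0.4 %
per-disk summary; the sample sd gives ±0.5). m is the OLS slope of
back-calculated vs true saturation over the linear dynamic range, 0.4–40 %
saturation by default, so m ≈ 1 %/% and σ, m, and the limits share units.
LOQ is stored as LOD·(10/3.3) so the ratio invariant holds exactly.
Reporting rounds LOD/LOQ to 2 decimals and summary statistics to 1 decimal.

### Calibration comparison

`compare_calibrations` is a two-sample Kolmogorov–Smirnov test with
rejection at p < 0.05. The samples compared are left to the caller; the
intended use is back-calculated concentrations evaluated over a shared grid
of ratio values spanning both calibrations, since that is the scale on which
two calibrations disagree in practice. Note that the two-sample KS test is
conservative at small n (its statistic is discrete): at n = 30 per side the
empirical null rejection rate at nominal 0.05 is ≈ 0.033, approaching 0.05
only as n grows. The null-calibration test in the acceptance suite therefore
uses n = 100 per side.

## Imaging

ROIs are caller-supplied circles (disk_id, center, radius); automatic disk
detection is deliberately out of scope — the workflow this supports is
drawing a circle over each engraved disk once per campaign. Conventions:
0-based pixel indices, origin top-left, x rightward, y downward; a pixel
belongs to an ROI when its center lies strictly inside the circle. Radii
below 3 px are rejected; at the ~100 px/mm² scale of the intended rigs, the
default 10 px radius gives ≥ 300 pixels per disk.

QC: the fraction of ROI pixels with red or green at full scale is recorded
per sample; QC fails when it reaches 1 % (cameras are deliberately exposed
near red-channel saturation for SNR, so a small guard band is needed but no
published cutoff exists — 1 % is this package's choice). A disk with zero
mean green yields NaN ratios and a failed QC flag without disturbing other
disks.

`render_synthetic_frame` is the forward model used for testing: green is
painted at a constant level inside each disk, red at the level that makes
the configured ratio definition reproduce the Stern–Volmer response exactly
before noise, then i.i.d. Gaussian noise is added, and the image is clipped
and quantised (8- or 16-bit). 16-bit with green ≈ 20000 DN keeps
quantisation error in recovered concentration below 0.01 % saturation; the
red level must stay within range, and the renderer refuses configurations
that would overflow rather than silently clipping the signal. No vignetting,
demosaic artifacts, or spatial heterogeneity within a disk are simulated, so
passing round-trip tests demonstrate the correctness of the extraction and
inversion arithmetic, not robustness to real optical non-idealities.

## Solubility, units, salinity

`o2_solubility` uses the Benson–Krause virial form (the basis of the USGS
solubility tables) for fresh water, scaled linearly by barometric pressure
relative to 1013.25 mbar; it is accepted over 0–40 °C. This choice
reproduces the published low-saturation equivalents (0.27 mg/L at 3 %,
0.1 mg/L at 1.1 %, both at 21 °C and 1013 mbar) at printed precision.
Salinity is corrected additively, DO_salt = DO − q·S with
q = −0.1903·t + 12.892 (t in °C); S is interpreted as the NaCl *mass
fraction* (salinity_pct/100) — the source formula does not state the unit,
and the fraction reading is the one consistent with q ≈ 9–13 mg/L per unit
S producing corrections of a few tenths of mg/L over the calibrated
0–3.5 % m/v range. Outside that range the linear form extrapolates with a
warning.

## Reactor gas exchange

Interior oxygen partial pressure obeys dp_i/dt = r·(p_a − p_i)/(H·V), with
the membrane area and thickness absorbed into the whole-tube permeability r
[mg/(min·bar)] — the tube is characterised as a system, not as a material.
The concentration-form solution is the exponential approach

C(t) = p_a·H − (p_a − p_0)·H·exp(−r·t/(H·V)).

`fit_permeability` fits r with p_0 and H free as nuisance parameters (so
the first data point and small temperature/pressure drifts cannot bias r),
V and p_a fixed, bounds r ≥ 0 and H > 0. Ambient p_a = 0.2095 × pressure.
A series that never departs from its mean carries no information about r;
such fits are flagged `r_identifiable = False` (flat-data check plus a
covariance check) instead of returning an arbitrary rate. Time is minutes
throughout the diffusion math; rates are reported per hour (`influx_rate`
= 60·r·(p_a − C/H)/V, positive below ambient equilibrium, antisymmetric
about it). H defaults to solubility/p_a when not co-fitted, tying Henry
bookkeeping to the solubility model.

Built-in reactor library (whole-tube r): plastic 50 mL centrifuge tube
3.02e-3, glass 40 mL VOA vial 1.75e-3, double-ended VOA vial 9.44e-4
mg/(min·bar), with nominal volumes 50/40/40 mL. The published "worst-case
concentration change rate" column associated with these permeabilities is
not reproducible from r, the nominal volumes and p_a = 0.2095 bar (the
original volume/pressure convention is unstated); this package's
`influx_rate` computes ≈ 0.77 mg/(L·hr) for the anoxic plastic tube where
0.60 is the published framing value, and the library treats that column as
descriptive context, not a target.

## Kinetics

Outlier handling is a Hampel filter: a point is masked when its deviation
from the centered rolling median (window 5) exceeds k = 3.5 × the rolling
MAD of the same window. The local MAD keeps steep-but-smooth stretches from
being flagged wholesale; a locally constant window (MAD 0) masks nothing.
Removing more than 20 % of points emits a warning rather than failing.

Segmentation is an exhaustive grid search over 0, 1, or 2 breakpoints
placed on observation times, with ordered phase labels drawn from
{first_order, zero_order, anoxic} (oxygen can only move toward anoxia).
Segment models: exponential `B + A·exp(−k(t−t0))` (3 parameters), straight
line (2), constant (1); each candidate is scored by Gaussian AICc with
breakpoints counted as parameters, minimum 4 points per segment, at least 8
unmasked points overall. Perfect fits are clamped to a common
data-scaled RSS floor so that on noiseless data ties are broken by
parsimony, not floating-point residue. The search is fully deterministic.
If no candidate is admissible the result falls back to a single flagged
linear phase. No published segmentation algorithm exists for these traces;
grid-search changepoints with an information criterion were chosen over
curvature heuristics for determinism and testability.

Rates: zero-order consumption is the sign-flipped least-squares slope of
the linear phase in mg/(L·hr); first-order k is from the exponential fit of
the first phase in 1/min. With `correct_diffusion`, the pointwise metabolic
rate u = −dC/dt + influx(C) is formed first (central differences computed
*within* each phase segment — a global gradient would straddle the
breakpoint kinks and bleed one phase's rate into its neighbour) and the
zero-order rate becomes the mean of u over the linear phase, k the
origin-constrained regression of u on C. Since influx ≥ 0 below ambient
equilibrium, corrected consumption can never fall below uncorrected there —
ignoring gas ingress biases consumption low, and the correction removes
that bias. Anoxia onset is the start of the constant phase, reported only
when that phase's mean concentration is below the calibration LOQ (when a
`DetectionLimits` is supplied) or below 5 % air saturation otherwise — a
plateau at mid-scale is a plateau, not anoxia. A series entirely below the
threshold reports anoxia from its first time point and no rates.

## Campaign simulator

`simulate_campaign` composes the whole forward chain: per-tube kinetics →
diffusive ingress → Stern–Volmer response → frame rendering with camera
noise, writing exactly the artifact set the real pipeline consumes (16-bit
TIFF frames, manifest CSV, ROI layout, calibration registry) plus truth
tables. The generating kinetic model has a first-order component k₁·C
active for a fixed initial window (default 10 min — a switch-off is needed
because a first-order term that never stops cannot hand over to a linear
phase), a zero-order component active while C exceeds an anoxia floor, and
influx throughout. Defaults emulate a typical short sediment incubation:
20 tubes, 2-min cadence, 70-min duration, C₀ ≈ 5.5 mg/L (well below air
saturation, as real tubes are by the time imaging starts), k₁ = 0.08/min,
zero-order 4.5 mg/(L·hr), floor 0.2 mg/L, 10 % tube-to-tube scatter, 30 DN
pixel noise at 16 bits. This trajectory shows the canonical
exponential→linear→flat shape with the transition near 10 min and anoxia
around 40 min.

Integration is forward Euler with step ≤ cadence/10 — deliberately a
different numerical route from the closed-form exponential the permeability
fitter uses, so simulator and fitter act as independent cross-checks
(order-1 convergence of the Euler path to the closed form is itself
asserted in the tests). Concentrations are clipped at zero.

What the simulator does *not* emulate: temperature drift and its effect on
calibration (no temperature-response model is included anywhere in the
package), photobleaching/drift of R0 over a campaign, optical heterogeneity
within disks, and non-Gaussian camera noise. Pipeline-closure tests
therefore validate the numerical chain under the stated noise model, not
field robustness.

## Numerical choices and degenerate inputs

- Inversion is closed-form and agrees with a bisection root-finder to 1e−6;
  round-trips hold to 1e−9 relative.
- All fits use deterministic initialisation; rerunning on identical input
  reproduces coefficients bit-for-bit.
- Tiny negative inversion results from rounding at R ≈ R0 are snapped to 0.
- A response slope indistinguishable from zero at float precision raises a
  metrology error rather than producing an absurd LOD.
- Identical permeability groups short-circuit the t-test to (0, 1) with a
  warning instead of dividing by zero variance.

## Known limitations

- Concentration unit inside the quenching law is % air saturation; Ksv from
  other unit conventions must be converted before use.
- The salinity correction is linear in S and calibrated only to 3.5 % m/v.
- No temperature-dependent calibration model; room temperature is assumed
  stable and equal between calibration and measurement.
- Segmentation assumes at most one of each phase in the canonical order;
  re-oxygenation events (e.g. a tube opened mid-run) will not be labeled
  sensibly, though the outlier mask will usually flag the excursion.
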