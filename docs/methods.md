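# Methods

## Size calibration

SEC separates by hydrodynamic size, so molecular weights of the pullulan
calibrants are converted to hydrodynamic radii before fitting. We use the
Mark–Houwink relation [η] = K·M^α together with the Einstein viscosity
relation for the equivalent-sphere hydrodynamic volume,

    Vh = 2 [η] M / (5 N_A),    Rh = (3 Vh / 4π)^(1/3),

with N_A fixed at 6.02214076×10²³ mol⁻¹. Units are handled explicitly: K is
in dL/g, so [η] is converted dL→mL (×100) and the volume cm³→nm³ (×10²¹).
With the default pullulan parameters (K = 2.427×10⁻⁴ dL/g, α = 0.6804,
DMSO at 90 °C) the 708,000 Da standard maps to Rh = 29.64 nm — the
calibration ceiling quoted as ≤ 30 nm — and the 342 Da standard to
0.41 nm. The relation is exactly invertible,
M = (5 N_A Vh / (2·100·K))^(1/(1+α)), and log-log linear with slope
(1+α)/3, which downstream code exploits.

The calibration itself is a least-squares polynomial of log₁₀(Rh) on
elution volume. The default order is 1: a linear log-size calibration is
the SEC norm, is exactly invertible and differentiable, and the simulator's
ground-truth calibration is linear, so order 1 is also what recovery tests
exercise. Regressing log₁₀(Rh) on V_el (rather than the reverse) makes the
Jacobian dV_el/dlog₁₀Rh needed by the trace conversion the analytic
reciprocal of the fitted derivative. The fit requires at least order+2
points, enforces strictly decreasing behaviour on a dense grid (larger
species elute first), and records the standards' V_el and Rh span; any
evaluation outside the V_el span is still returned but flagged
`extrapolated`, since DP assignment there is semi-quantitative.

Standard apexes are located on Savitzky–Golay-smoothed traces
(window 11, order 3) and refined by fitting a quadratic to all points above
75% of the apex height — the vertex beats the raw argmax by roughly an
order of magnitude in position noise. Apexes are assigned to molecular
weights purely by elution order (largest M first), which is the physics of
SEC and requires no annotation of individual traces.

## Trace reduction

The DRI detector responds to mass concentration, so a baseline-corrected
trace converts to a weight distribution per logarithmic size interval:
w = S_DRI(V_el)·|dV_el/dlog₁₀Rh|. All logarithms are base 10; the choice
only introduces constant factors that cancel after area or SNV
normalisation. The absolute value is taken because the calibration slope is
negative while w must be non-negative.

Baseline correction subtracts the straight line through the median signal
of the first and last 5% of points (configurable), clips negative residuals
smaller than 3× the anchor-region noise sd to zero, and retains (and logs)
larger negative excursions. Because genuine noise keeps ~0.13% of points
beyond 3σ, raw weight curves may carry small negative values;
non-negativity is enforced only after the explicit clipping that precedes
area normalisation.

Conversion to DP coordinates uses X = M(Rh)/162.2, the anhydroglucose
residue mass; the +18 Da water terminus is ignored as negligible above
DP ~6. In log coordinates this is an affine relabelling with constant slope
3/(1+α), so w is rescaled by the constant Jacobian (1+α)/3 and the curve
shape is preserved exactly. The number distribution follows from
w(log₁₀X) = X²·N_de(X), an exact, exactly invertible pointwise identity.

Distributions are evaluated on the chromatogram's native sampling, then
resampled by linear interpolation to a uniform 1000-point log₁₀DP grid
clipped to X ≥ 6 (the reported CLD coverage) for feature detection and
cross-run comparison. SNV normalisation uses the sample (n−1) standard
deviation and is applied to curves on a shared grid.

## Feature extraction

Peaks are local maxima of the Savitzky–Golay-smoothed curve (window 21,
order 3 on the 1000-point grid) with prominence at least 2% of the
smoothed curve's span; using the span rather than the maximum keeps peak
positions invariant under SNV (which shifts curves to zero mean). These
defaults make the noiseless reference fixtures report exactly their
generating modes and nothing else; both are configurable.

A shoulder — an unresolved component that flattens a flank without forming
its own maximum — is located at a local minimum of the smoothed second
derivative (the point of maximum concavity). This estimator is unaffected
by linear background and tracks the underlying component mode much better
than the midpoint of the slope plateau, which the neighbouring peak's flank
drags downhill (for the barley-type fixture: DP ≈ 21.4 recovered for a
true 21, versus ≈ 18.7 from the plateau criterion). Because differentiation
amplifies high-frequency noise, the second derivative uses a doubled
window (41 points), and candidates must clear both a 5% relative concavity
prominence and a 5σ noise floor estimated from the smoothing residuals via
the filter's coefficient norm. Resolved peak apexes are themselves
concavity minima, so candidates within one derivative window of a detected
peak are excluded.

The amylopectin/amylose split is the trapezoidal area fraction below/above
DP 100 (configurable); the boundary is inserted into the partition by
interpolation so the two fractions sum to 1 exactly. Chain-class fractions
integrate N(X) dX over DP < 25, [25, 50) and ≥ 50, normalised to sum to 1.

## The simulator and what it does (not) emulate

Ground-truth CLDs are mixtures of Gaussian components in log₁₀X — the
minimal shape matching real debranched-starch CLDs plotted on a log axis.
The instrument model applies a known linear true calibration anchored so
DP 6–10,000 spans 4.5–8.0 mL (a separation finishing in under 8 min at
0.3 mL/min), sampled every 0.001 mL over 3.9–8.6 mL; Gaussian band
broadening of 0.03 mL; linear baseline drift (0.01 signal units/mL); and
seeded white detector noise of 0.0025 signal units, about 0.2% of a
unit-mass peak. Simulated standards have a log-normal dispersity of
σ(log₁₀M) = 0.10 (Mw/Mn ≈ 1.05, typical of narrow pullulan kits); the
ten-standard kit spans the 342–708,000 Da endpoints with eight log-spaced
intermediates (the intermediates are a fixture choice, not vendor data).
The noiseless signal is mass-proportional and integrates to the injected
mass exactly (change of variables), which the conservation tests verify.

The three reference fixtures place their component modes at the CLD
features reported for smooth pea and barley starches (DP 13/16, 21, 44,
300, 1300); component widths and weight fractions are synthetic choices
made so the features are recoverable, and are not measurements of real
cultivars. With the default Mark–Houwink parameters the 1300-DP mode
(M ≈ 2.1×10⁵ Da, Rh ≈ 15 nm) lies inside the standards' calibration range —
the largest standard corresponds to DP ≈ 4365 — so only the distribution
tail beyond that, up to DP 10,000 (Rh ≈ 47 nm), exercises the extrapolated
flag.

What passing recovery tests show is that the reduction is self-consistent
and unbiased for smooth log-normal mixtures under Gaussian broadening and
white noise. Real chromatograms differ in ways the simulator does not
emulate: asymmetric (tailing) band broadening, heteroscedastic and
correlated detector noise, nonlinear baseline excursions, column-overload
distortion and DRI calibration drift. Recovery on fixtures is therefore a
necessary check of the mathematics, not a validation of instrument
performance. One identifiability limit is built in deliberately: the
pea_bc1 fixture's broad 150-DP component blends with its 300-DP neighbour
so completely that the true mixture's own concavity wrinkle (near DP 133,
~6% relative concavity prominence) does not survive band broadening — such
weak features are below what any detector of this type can report, and the
recovery tests require only analytically strong features (maxima, and
shoulders above a 10% concavity-prominence cut).

## Numerical choices and degenerate inputs

- Read/write uses 17-significant-digit text, lossless beyond 12 digits.
- Chromatograms require ≥ 16 samples, strictly increasing finite volumes.
- Calibration Jacobians below 10⁻¹² in |dlog₁₀Rh/dV_el| raise (degenerate
  calibration, e.g. a polynomial stationary point).
- Flat signals raise "no peak" (apex location) or return empty feature
  lists (peak detection); span thresholds are relative (10⁻⁹ of scale) so
  float round-off in constant curves is not mistaken for structure.
- SNV refuses constant input (sd = 0); area normalisation refuses
  zero-area curves.
- The simulator raises if > 1% of ground-truth mass falls outside the
  sampling window (computed analytically from component CDFs).
- All randomness flows through numpy Generators seeded explicitly;
  identical seeds give bit-identical traces.

## Known limitations

- Single Mark–Houwink parameter set: analytes are treated as
  hydrodynamically equivalent to the calibrant (reasonable for linear
  glucans vs pullulan; wrong for branched polymers).
- No deconvolution: overlapping components are reported as peaks/shoulders
  of the measured curve, not resolved into a parametric mixture.
- DP assignment beyond the largest standard is extrapolated and flagged,
  but still reported; quantitative claims there should be avoided.
- Time-indexed chromatograms assume a constant flow rate for the
  time→volume conversion.
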