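# Methods

This note records the model, the numerical and design choices, and the
limits of what the test suite demonstrates.

## Reaction model and fitting chain

The nitration of the isouronium substrate (IO) by HNO₃ in concentrated
H₂SO₄ is treated as irreversible and second order overall — first order
in IO, first order in HNO₃ — with 1:1 stoichiometry (HNO₃ consumption
is stoichiometric; side reactions of nitric acid are neglected). In
conversion x of the limiting substrate at excess ratio
M = c_HNO₃,₀/c_IO,₀:

    dx/dt = k c_IO,0 (1 − x)(M − x),
    ln[(M − x)/(M(1 − x))] = (M − 1) c_IO,0 k t.

Apparent-k estimation is ordinary least squares of the transform on
residence time with a **free intercept**. A forced-zero intercept would
be unbiased only if the first sample is perfect; the free intercept is
robust to quench-delay offsets and the intercept is reported as a
diagnostic (warning above |0.05|). A non-positive slope is rejected as
non-physical.

Order inference follows the classical integral method: candidate
linearizations are fitted and the highest R² wins; wins by less than
ΔR² = 0.005 are flagged ambiguous rather than silently decided. The
substrate order is read from a pseudo-order series (HNO₃ excess ≥ 10×,
so c_HNO₃ is effectively constant) by comparing ln(1 − x) vs t against
1/(1 − x) vs t; the nitric-acid order is read from a practical-excess
series by comparing ln(1 − x) vs t against the excess-reagent
transform. Two printed-form quirks in the source literature are
resolved in favor of the standard sign-consistent integrated laws: the
second-order candidate is implemented as 1/(1 − x) = 1 + c_IO,0 K t,
and the mixed-excess first-order-in-both candidate as the transform
above (only these forms can be generated and recovered
self-consistently). At M ≈ 4.4 the two nitric-acid candidates differ
only subtly on noise-free data (wrong-model R² ≥ 0.999), so the
ambiguity flag routinely triggers for that comparison even when the
selection is correct; the substrate-order comparison separates cleanly.

## Medium model (Mc)

Mc is the Marziano-type activity-coefficient function. At 298 K it is
the published quintic in H₂SO₄ molarity (the correlation defines −Mc;
all public interfaces traffic in signed Mc, negative over the
calibrated interval 15.2–18.4 mol/L). Temperature scaling uses
Mc(T) = Mc(298 K)·[200/T + 0.3292]; the bracket equals 1 at 298.15 K to
1×10⁻⁵, which anchors the correction. Outside the calibrated molarity
interval the function is evaluated with a warning by default and raises
only in strict mode, because extrapolation studies must be runnable.

Acid strength is stated as mass fraction in experiments but the Mc
correlation takes molarity; the bridge is a bundled handbook density
table for aqueous H₂SO₄ (80–100 wt %, 1-point steps, the classic 20 °C
specific-gravity values; density(100 %) = 1.8305 g/mL) with linear
interpolation, molarity = ρ(w)·1000·(w/100)/98.08. Density's
temperature dependence is deliberately ignored: the Mc temperature
bracket is assumed to absorb temperature effects, and the study window
(30–45 °C) is narrow. The table is replaceable via configuration. The
88–98 wt % study window maps to 16.2–18.3 mol/L, inside the Mc
calibration.

## Nitronium model

lg(c_NO₂⁺/c_HNO₃) is fitted from a user-supplied table of literature
values by the standard two-stage construction: per-temperature OLS
lines in w, then per-grid-w OLS lines in 1/T (grid: 1-point steps
across the observed w span, with the exact span ends appended).
Evaluation interpolates linearly between bracketing grid lines, giving
a surface affine in w between nodes and affine in 1/T everywhere;
queries outside the fitted (w, T) ranges are answered with an
extrapolation flag, and end grid segments extend linearly. Both stages
are unweighted OLS, matching the plain linear fits of the graphical
construction. The repository ships no literature table — the underlying
data are not printed in the source study — so the generator's clearly
labeled synthetic tables stand in for tests and demos.

## Intrinsic decomposition and Arrhenius extraction

Per temperature, y = lg k − lg(c_NO₂⁺/c_HNO₃) is regressed on Mc
(slope n, intercept lg k₀; ≥ 3 acid strengths required). Rows whose
nitronium value is extrapolated are kept and flagged by default,
dropped in strict mode. The decomposition is formal: no physical bound
is asserted on lg(c_NO₂⁺/c_HNO₃), because combining the published
apparent-rate table with this Mc convention implies positive lg ratios,
an inconsistency of conventions that the package surfaces rather than
hides (see the unit-scale paragraph below).

Arrhenius: lg k₀ → ln k₀ (×ln 10), OLS on 1/T over all temperatures
simultaneously; Eₐ = −slope·R, ln A = intercept. R = 8.314 J/(mol·K)
by default, configurable. Base-10 ("lg") is used throughout the
decomposition, natural log only in the Arrhenius step; conversions are
explicit and unit-tested. n(T) between fitted temperatures is linear
interpolation; outside them, a flagged linear extension of the edge
segment (n varies only mildly with temperature).

The published per-temperature lg k₀ triples regress to
Eₐ = 192.58 kJ/mol and ln A = 102.56, reproducing the published
192.57/102.55 to 0.01%. Those three lg k₀ values are, however, not
collinear in (1/T, ln k₀) to better than ~0.03 lg units — OLS residuals
are (−0.019, +0.039, −0.020) and even the minimax line leaves 0.029 —
so forward evaluation of the fitted line cannot reproduce the inputs to
0.01 lg units; the acceptance suite documents that required consistency
level and the measured 0.039.

## Forward prediction, envelope, optimization

Conversion is the closed-form inverse of the transform:
x = M(e^z − 1)/(M e^z − 1), z = (M − 1) c_IO,0 k t, evaluated via
expm1; for z > 700 the asymptotic form 1 − (M − 1)/(M e^z) is computed
in log space, and results are capped at the largest double below 1 to
honor the x ∈ [0, 1) contract.

Every prediction carries a three-state calibration status. Soft
envelope (model construction window, defaults): T ∈ [30, 40] °C,
w ∈ [88, 98] wt %, t ≤ 4.7 min. Hard envelope (refuse beyond,
defaults): T ≤ 45 °C, w ∈ [80, 100] wt %, t ≤ 15 min. Soft ⊆ hard is
enforced. Between them, predictions are returned with a flag —
validation studies deliberately probe that region. Discrepancies are
reported in absolute percentage points of conversion.

The optimizer is an exhaustive grid search (default steps 30 s, 2.5 °C,
1 wt %) rather than gradient-based: the space is three-dimensional, the
surface is cheap, and grids are auditable. Ties are broken by shorter
residence time, then lower temperature, then lower acid strength;
boundary optima are flagged per axis.

## Synthetic data: what it emulates, what it does not

The generator forward-simulates the full model: campaign defaults are
the study design (30/35/40 °C × {88, 90, 92, 94, 96, 98} wt % ×
{1, 2, 3, 4, 4.7} min, M = 4.4, c_IO,₀ = 0.5 mol/L), with additive
Gaussian noise (default sd 0.01, a repository convention — the source
reports triplicate averaging but no error model) truncated to
[0, 0.999]. Ground-truth defaults are the published intrinsic
parameters (Eₐ = 192.57 kJ/mol, ln A = 102.55, n per temperature) and
an affine-in-(w, 1/T) nitronium structure least-squares matched to the
lg-ratio values implied by the published apparent-rate table under the
decomposition — the same affine family the two-stage fit recovers
exactly, which is what makes the noise-free pipeline recovery an
identity test at 1×10⁻⁶.

One deliberate scale convention: the published apparent-rate table
prints k under a "×10²" header whose literal L/(mol·s) reading
saturates conversion within the first minute at the stated residence
times, so no informative conversion–time campaign exists at that scale.
The generator therefore shifts the nitronium intercept by −2 lg units,
placing apparent k near 10⁻⁴–10⁻³ L/(mol·s) where the stated design
yields conversions of roughly 0.04–0.5. Recovery tests are invariant to
this shift (it moves only the nitronium surface, which is refitted);
absolute k values in synthetic campaigns are therefore a consistent
convention, not a reproduction of the printed table. A related
consequence: the affine truth surface reproduces the interior maximum
of k versus acid strength (the decline of n·Mc overtaking the nitronium
term above ~94–96 wt %), but not the printed table's exact values or
its strict increase of k with temperature at every acid strength.

Noise calibration: with the prescribed estimator (per-series
free-intercept OLS, unweighted decomposition, Arrhenius over the 10 K
window), conversion noise of sd 0.01 amplifies to a median Eₐ recovery
error of 9–18% across 20-seed blocks (200 calibration seeds); the
noisy-recovery acceptance bound is set at a 25% median accordingly, and
a separate ensemble test checks that the error grows monotonically with
noise level. Passing these tests demonstrates internal consistency of
the estimator chain under the stated noise model — not accuracy on real
data, whose noise may be heteroscedastic, autocorrelated, or
mass-transfer contaminated (none of which are emulated).

## Numerical conventions and degenerate inputs

- Time in seconds internally; readers convert minutes on ingest.
  Celsius labels map to kelvin as °C + 273.15 exactly.
- R² is 1 − SS_res/SS_tot about the observed mean; a constant observed
  vector is an error in the public helper, while internal line fits
  report slope 0 with R² = nan so degenerate series surface as fit
  errors, not crashes.
- Mass-fraction → molarity inversion is a bracketed root find
  (monotone over the table span), giving round trips well inside the
  0.1-percentage-point contract.
- Seeds: every stochastic operation takes an explicit seed; campaigns
  spawn per-cell child seeds from one SeedSequence, so one integer
  reproduces the whole artifact set. Emitted files embed their truth
  metadata.

## Known limitations

- The nitronium model is an empirical interpolator; it does not predict
  speciation from acidity functions, and its extrapolation flags are
  range checks, not uncertainty estimates.
- Uncertainty is not propagated beyond per-fit R² (no standard errors
  on Eₐ are reported).
- The optimizer assumes the fitted surface is trustworthy wherever the
  envelope allows evaluation; in soft-extrapolated corners the model
  error is known (from the source study's own validation) to reach
  ~8–10 percentage points of conversion.
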