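# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `dnabow`, in the spirit of a package methods appendix.

## Physical constants and units

All mechanics use pN, nm and seconds.  The thermal energy is
k_BT = 0.0138065 pN·nm/K × 295.15 K = 4.075 pN·nm (22 °C, the assay
temperature); it is overridable through the `temperature` arguments.
Energies of landscapes and duplex stabilities are reported in k_BT.
The oxDNA-style unit registry maps −0.1 simulation energy units to
−1 k_BT and 0.1 simulation length units to 0.085 nm.

## Worm-like-chain end-to-end distribution and bow tension

The dsDNA arc is a worm-like chain (WLC) with contour length
L = 0.34 nm/bp × N and persistence length P (default 50 nm).  Its scalar
end-to-end distance density p(x) — Jacobian included, i.e. the density of
|R|, normalized to 1 on [0, L] — is evaluated with the
Becker–Rosa–Everaers-type interpolation of the WLC radial distribution,
which blends the flexible-chain (Daniels-like) expansion with the
stiff-chain (Shimada–Yamakawa-like) behavior through the dimensionless
stiffness κ = P/L.  The log-density is carried analytically alongside the
tabulated density so that log-derivatives in the deep tails are free of
floating-point underflow.

Validation: the density is compared bin-by-bin against an independent
discrete-WLC Monte-Carlo oracle (rigid segments, Gaussian bend angles of
variance ds/P per transverse direction).  Agreement is at the few-percent
level in the bulk of the distribution across κ from 0.1 to 10; the
largest deviations (~10–20%) occur in the extreme tails, in particular
within ~2% of full extension.  Tests therefore compare bin-integrated
masses with a tolerance of 3 Monte-Carlo standard deviations plus 5%,
excluding the outermost 2% of the range.

The bow tension is f(x₀) = −k_BT ∂log p/∂x at the bowstring extension
x₀.  `entropic_force` returns the signed log-derivative (positive =
chain resists extension); `bow_tension` and `bow_force_estimate` report
the positive tension the compressed arc exerts on the string, with
uncertainty |∂f/∂x|·σ(x) propagated from the extension spread.  The
log-derivative is evaluated on a cubic spline of log p to avoid noise
amplification; forces at the tabulated-grid boundary raise errors.

Because no external simulation trajectories ship with the package, the
bowstring operating point can be computed self-consistently: the
equilibrium extension x* solves tension_arc(x) = tension_string(x)
(Brent's method on the bracket between the string rest length and the
mode of p).  With the sequence-averaged unbound-string FER, this
substitute reproduces the expected monotone force ladder over the seven
arc lengths, 74 bp → ≈5.8 pN down to 252 bp → ≈2.0 pN, within the
~20–25% accuracy expected of replacing simulation-derived mean
extensions with a WLC/linear-FER equilibrium.

## Short (finite) chains

The Marko–Siggia interpolation assumes the thermodynamic limit.  For
short chains the package provides a finite-chain extension defined
through the tilted end-to-end density: x(f) = argmax_x [log p(x) +
fx/k_BT], i.e. the maximum-term estimate in the fixed-force ensemble.
It has a finite, positive zero-force extension (the mode of p), is
monotone in force, and converges to the Marko–Siggia curve for long
chains by ensemble equivalence (within 0.4% at 5 pN for a 1 kbp-scale
duplex; several percent residual for very flexible chains, where the
interpolated density itself is least accurate).  With both a 15-nt ssDNA
(0.70 nm/nt, P = 1 nm) and a 15-bp dsDNA treated as finite chains, the
extension crossover drops from 4.21 pN (Marko–Siggia) to ≈1.4 pN,
because free-end orientational fluctuations shorten the projected
extension of the short stiff duplex at low force.

Elastic parameter defaults: ssDNA P = 1.0 nm and contour 0.70 nm/nt,
dsDNA P = 50 nm and rise 0.34 nm/bp.  These standard values place the
ss/ds Marko–Siggia extension crossover — and hence the maximum of
ΔG°(f) — near 4.25 pN.  All are configurable; none are fitted.

## Rigid base-pair route to the bow force

Sequence-dependent intrinsic curvature is handled with a rigid base-pair
chain: per-step ground-state roll/tilt/twist angles (degrees) and
harmonic stiffnesses (k_BT/deg²), composed step-by-step into a 3-D path
(tilt about the local e1, roll about e2, twist about the helical axis,
then a rise translation).  The restrained energy
E = Σᵢ βᵢ(xᵢ−xᵢ₀)² + κ(r{xᵢ}−r₀)² is minimized by gradient descent with
backtracking (Armijo) line search; the force on the bowstring is read
off the restraint spring, f = 2κ(r−r₀).  The gradient of r with respect
to each angle is analytic — a rotation about a lab-frame axis moves all
downstream material rigidly, so ∂(end)/∂θ = axis × (end − pivot) — which
is exact and much cheaper than finite differences.  Minimization starts
from a conformation uniformly curved toward a rotational register angle;
scanning registers (uniform or seeded-random) yields the mean and spread
of the force over intrinsic-curvature phases.  The shipped default
parameter set is sequence-independent B-DNA (straight, twist 34.3°,
β = 0.02 k_BT/deg², consistent with a 50 nm persistence length); real
sequence-dependent tables can be loaded from CSV.

## smFRET analysis

Efficiency is E = I_A/(I_A+I_D) per frame; frames with non-positive
total intensity are invalid (NaN) and carry the previous state.  State
calling smooths with a centered moving average (window odd; default 5
frames) and applies hysteresis thresholding: enter the bound state above
the high threshold, leave below the low one.  Default thresholds sit at
the two efficiency-histogram modes' midpoint ± 0.1.  Dwell times are run
lengths × frame time.

Edge policies for the censored first/last runs:

* `drop_partial` (default, matching common practice): both boundary runs
  are discarded and rates come from mean dwells, k_off = 1/⟨τ_on⟩,
  k_on = 1/([c]⟨τ_off⟩).  When dwells are pooled across many short
  traces this estimator carries a small positive bias of order
  τ/T_trace (trajectories with more, hence shorter, dwells contribute
  more dwells to the pool).
* `keep`: boundary runs enter as ordinary dwells (biased short).
* `kaplan_meier`: the censoring-corrected route.  For a two-state Markov
  process the first run ends in an observed transition and is
  exponential by memorylessness; only the final run is right-censored.
  The rate estimate is the censored-exponential MLE, (number of complete
  dwells)/(total time in the state including the censored run), which is
  unbiased to O(1/N).  Recovery tests use this policy.

SEMs: analytic rate/√N (exponential dwells) and a seeded bootstrap over
dwells (default, 1000 resamples).  Both agree within ~few % on synthetic
data, and the reported SEM matches the true sampling spread of the
estimator in replicate simulations.

## Force-dependent rate laws and fitting

`rate_vs_force` integrates the extension gap Δx‡(f) by adaptive
quadrature for arbitrary FER objects and also returns the local slope
d log k/df = Δx‡(f)/k_BT.  For linear per-nucleotide FERs the closed
forms (quadratic in f on a log scale) agree with the quadrature to
better than 1e-8 relative — the module's central oracle.

The six-parameter simultaneous fit (a_u, b_u, a‡, b‡, k_on(0), k_off(0);
bound-state extension fixed at 0.34·n nm) is performed in log-rate space
with weights 1/σ²_log, where σ_log is the relative SEM of each rate.
In the transformed variables (log k(0), compliance 1/a, rest extension
b) the model is *linear*, so weighted linear least squares solves the
problem globally and exactly; a bounded trust-region refit guards the
rare noise realizations that push a compliance negative (physical
bounds: compliances in [1e-8, 1] nm/pN, rest extensions in [0, 10] nm).
Standard errors come from the Gauss–Markov covariance with a delta-method
transform to the reported parameterization.  The multi-start nonlinear
machinery originally envisaged for this fit is unnecessary once the
linearity is exploited.

The Marko–Siggia variant fixes the unbound and bound (P, L) and fits
(P‡, L‡, k_on(0), k_off(0)) by multi-start trust-region least squares in
log-parameters; the force→extension inversion is done by interpolating
the monotone f(z) relation on a dense fractional-extension grid (error
≪ the data noise, ~10⁴× faster than per-point root finding).  On shared
synthetic datasets the two model families rank transition-state
stiffness consistently (Spearman ρ ≈ 0.9 between a‡ and P‡ at 2%
measurement noise); at 5% noise the 7-force design identifies the
stiffness only weakly and the correlation degrades, which is a property
of the data, not of either model.

Thermodynamics: ΔG° = k_BT ln(k_on c₀/k_off) with c₀ = 1 M, positive for
a more stable duplex; ΔG°(f) = ΔG°(0) − ∫₀^f (x_u − x_b) df′.  With
Marko–Siggia FERs, ΔG°(f) is concave with its maximum at the extension
crossover (≈4.25 pN with the default parameters).  The nearest-neighbor
comparison sums unified DNA dinucleotide ΔH/ΔS values (shipped as an
editable CSV) at the configured temperature, with optional additive
corrections of +1 k_BT per dangling-end stack and +2 k_BT for a 5′
cyanine label.

## Free-energy landscapes

Biased samples along (extension x, base pairs n_bp) are inverted by
p_eq ∝ p_biased/W(n_bp), renormalized, and converted to
G = −k_BT log p_eq with the constant chosen so the global minimum is 0.
Default x bin width 0.085 nm.  Unsampled bins are +∞ and excluded from
minima; strata with fewer than 50 samples are flagged in metadata.  The
minimum-energy path takes the per-column argmin (ties break toward
smaller x); `path_offset` zeroes each column at its path value and is
idempotent.

## Synthetic data

Every generator is a pure function of (parameters, seed), using
numpy's `default_rng`.

* **Telegraph FRET traces**: exact exponential waiting times of a
  two-state Markov chain; framewise state = state at the frame midpoint
  (keeps ground truth unambiguous for state-calling tests); intensities
  are Gaussian around per-state efficiency means (defaults 0.2/0.8,
  σ_E = 0.05, total intensity 1000).  Not emulated: photophysics
  (blinking, bleaching), within-frame state mixing, intensity shot
  statistics — so passing recovery tests demonstrates correctness of the
  dwell/rate pipeline, not robustness to photophysical artifacts.
* **Rate tables**: log-normal perturbations of the closed-form laws on
  the calibrated force grid 1.6–6.25 pN (7 forces, 3 replicates, 5%
  log-noise by default).
* **Zipper landscape**: columns n_bp = 0..9 with harmonic extension
  profiles centered on the state FERs (unbound for n_bp = 0, transition
  state for n_bp = 1, bound for n_bp = 9, interpolated between); the
  nucleated column sits a configurable barrier (default 5 k_BT) above
  the melted reference and the zipped columns ~2 k_BT above it, so an
  exponentially increasing umbrella weight W(n_bp) = exp(0.3·n_bp) can
  flatten sampling, mirroring the umbrella protocol.  The toy is not
  sequence-resolved.
* **Discrete WLC chains**: rigid segments with independent Gaussian bend
  angles of variance ds/P per transverse direction.  The discretization
  biases the effective persistence length by O(ds/P); oracle tests use
  enough segments that this bias is below their tolerance.

## Problem sizes used in the test suite

Recovery studies run at desk scale: 100 seeded datasets for the
rate-model recovery; a 3×3 grid of (k_on·c, k_off) ∈ {0.1, 0.5, 2} s⁻¹
with 200 traces per cell (frame time 1/(200·fastest rate), duration
15/slowest rate) for the trace pipeline; 10⁵–10⁶ samples for Monte-Carlo
comparisons.  Statistical assertions use Gaussian coverage logic (e.g.
at least 16 of 18 z-scores within 2 SEM and none beyond 3.5) because an
unbiased estimator produces ~5% of |z| > 2 by construction.

## Known limitations

* The end-to-end density interpolation is least accurate very near full
  extension and for extreme flexibility; bow-force work (κ ≈ 0.6–2,
  compressed side) is far from those regimes.
* Linear FERs are trusted only below ~6–7 pN; no extensible/twistable
  WLC variants.
* Two-state FRET only: no hidden-Markov inference, no photobleaching
  correction, no multi-state kinetics.
* Single per-stratum umbrella weights (no multi-window WHAM).
* The self-consistent bow force replaces simulation-derived mean
  extensions; agreement with trajectory-based calibration is expected
  only at the ~1 pN level.
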