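# Methods

`isodx` reproduces, fully in silico, a diagnostic workflow for building
adsorption-isotherm models in liquid chromatography: simulate elution,
estimate isotherm parameters by maximum likelihood, detect underfitting with
a chi-square test, locate state-dependent ("faulty") parameters with a
Lagrange-multiplier score test, and substitute them with state-dependent
functions until the model passes. This note records the model equations, the
numerical choices, and what the synthetic data do and do not probe.

## Column model

The Equilibrium Dispersive Model (EDM) describes single-component elution
through a packed column of length L with total porosity eps_t. All band
broadening is lumped into one apparent dispersion coefficient D_app, and the
mobile and stationary phases are assumed in instantaneous equilibrium
through the isotherm q = f(C_m, phi). With the chain rule applied to the
stationary-phase accumulation term, the mass balance reads

    (1 + F f'(C_m)) dC_m/dt = -u_int dC_m/dx + D_app d2C_m/dx2,

where F = (1-eps_t)/eps_t is the volumetric phase ratio and
u_int = Q/(S eps_t) the interstitial velocity (S = pi D^2/4). The inlet is a
Danckwerts flux balance against a rectangular feed pulse of duration V/Q
starting at t_inj = 0; the outlet has zero concentration gradient. Isotherm
slopes are evaluated analytically (sympy differentiation of the form's
expression, lambdified once per simulation).

Discretization follows the common chromatographic practice of a uniform
100-cell grid with first-order backward (upwind) differences for convection
and second-order central differences for dispersion; the Danckwerts inlet is
imposed through a ghost value chosen so the scheme's inlet face flux equals
exactly u_int*C_in (making the discrete species balance close to integrator
tolerance), and the outlet ghost copies the last cell. Time integration is
LSODA with rtol 1e-6 / atol 1e-9 and a tridiagonal Jacobian band; the feed
pulse edges are integration-segment boundaries so the discontinuities are
never stepped over.

Two consequences of the first-order scheme are worth knowing. First, its
numerical dispersion u_int*dx/2 (~0.7 cm^2/min at the reference geometry) is
far larger than the physical D_app = 0.006 cm^2/min, so peak widths at the
default grid are scheme-dominated -- exactly as in the simulation platforms
this practice stems from. Estimation is unaffected because data generation
and fitting share one grid. Second, apex times converge at O(dx): halving
dx moves an apex by ~3-4%, shrinking monotonically on further refinement.
Mass conservation holds to 0.6% at 100 cells and 0.03% at 400 cells
(trapezoidal quadrature of the outlet included).

If the isotherm slope reaches -1/F anywhere on the feed concentration range,
the equation loses parabolicity; such parameter vectors are rejected up
front (`ModelValidityError`) and treated as infeasible by the estimator.

## Isotherms and the modification algebra

Forms are sympy expressions over (C_m, phi) and named parameters:
Langmuir, second-order Langmuir-Freundlich, the linear-solvent-strength
(LSS) modulated Langmuir family (fixed, exponentially modulated, or
quadratic-exponent saturation capacity), the quadratic isotherm
q = q_sat(bC + 2b'C^2)/(1 + bC + b'C^2), and constant-free polynomials with
an optional tanh-damped cubic term. In the LSS family the denominator
coefficient is read as b = K/q_sat, which makes q_sat the saturation
capacity and keeps the dimensions consistent.

A `ModificationRule` replaces one parameter with an expression over itself,
exactly one new parameter, and the states -- e.g.
q_sat -> q_sat exp(-S_c phi), S_b -> S_b + S_c phi, a_k -> a_k + a_{k+1} C_m,
a_3 -> a_3 + a_4 tanh(C_m). Applying a rule is symbolic substitution, so the
modified model provably nests its parent (set the new parameter to its
neutral value) and identities between parameterizations can be tested
pointwise to machine precision. For the tanh-damped cubic we implement the
resulting model q = a_1 C + a_2 C^2 + a_3 C^3 + a_4 tanh(C) C^3, i.e. the
damping rule acts multiplicatively on the cubic term's coefficient.

The Taylor utilities compute Maclaurin coefficients of the quadratic
isotherm by exact power-series division (c_k = n_k - b c_{k-1} - b' c_{k-2})
and the convergence radius as the smallest modulus among the complex roots
of 1 + b z + b' z^2. Note the exact fourth coefficient is
q_sat(4 b^2 b' - 2 b'^2 - b^4); the -b^4 term is often dropped in quoted
closed forms but is retained here (it is 0.4% of c_4 at the Case C values).

## In-silico experiments

The three case studies share one column (L=15 cm, D=0.46 cm, eps_t=0.635,
D_app=0.006 cm^2/min). Case A varies (V, phi) over five experiments at
C_in*=5 mg/mL, Q=1 mL/min with a capacity-modulated LSS Langmuir truth
(K=118.58, q_sat=34.45 mg/mL, S_a=9.36, S_b=7.50); Case B uses a slightly
different five-point design with a quadratic-exponent capacity truth
(S_b=3.10, S_c=4.20); Case C runs the 2^3 factorial corners of
V={0.5,2} mL x C_in*={1,6} mg/mL x Q={0.5,2} mL/min with the quadratic
isotherm truth (q_sat=123.2 mg/mL, b=0.04, b'=0.02 mL/mg). A Sobol design
helper generates quasi-random validation conditions in the same box.

Measurement noise is Gaussian, i.i.d. per point, homoscedastic within an
experiment, with sigma_i = 1% of experiment i's noiseless peak maximum. The
peak-referenced reading keeps the noise covariance diagonal, known, and
nonsingular at the baseline (a point-relative 1% would give zero baseline
variance and an unusable likelihood). All experiments of a case share one
reporting grid: 0.05-min spacing, horizon = the largest per-experiment time
at which the outlet falls below 1e-4 of its feed concentration, rounded up
to a whole minute. A common grid gives every experiment the same number of
points N_y, as the single-N_y likelihood assumes. At these settings Case A
spans 56 min (N_y = 1121 per experiment) and Case C 38 min (N_y = 761).

What the generator does not emulate: detector baseline drift and
saturation, flow and temperature fluctuations, injection-profile distortion,
gradient (time-varying phi) elution, or competitive multi-component
adsorption. Passing tests therefore demonstrate the statistical machinery
under the stated noise model, not robustness to real-detector artifacts.

## Estimation

The likelihood is Gaussian with known diagonal covariance (the generating
sigmas), so maximizing the log-likelihood Phi equals minimizing the
normalized squared residuals chi^2 = sum_i ||y_i - yhat_i||^2/sigma_i^2.
The optimizer exploits this: each start runs a bound-constrained
trust-region least-squares solver (scipy `least_squares`, TRF) on the
standardized residual vector with 2-point finite-difference Jacobians
(relative step 1e-4 in the scaled coordinates -- a step small enough for
accurate Gauss-Newton directions yet large enough that the integrator's
1e-6 relative solution error does not contaminate the differences; with a
1e-5 step the contaminated Jacobian stalls the trust region in shallow
valleys), which converges at the Gauss-Newton rate and reports the
projected gradient at the solution.
Positive physical parameters (K, q_sat, S_a, S_b, b, b', a_1) are searched
on a log10 scale; sign-free ones (S_c, higher polynomial coefficients)
linearly; all coordinates are affinely mapped to the unit box.

Starting points come from a scrambled Sobol sequence over the bounds box
(default 10 starts; the bundled case studies use 1-4 plus warm starts),
optionally preceded by deterministic extra starts: the box centre, or --
inside the diagnostic loop -- the parent model's estimate extended with the
new parameter at its neutral value. Warm nesting guarantees the refit can
only improve the likelihood. Because one likelihood evaluation costs N PDE
solves, the Sobol starts are triaged: every start gets a short local search
(10 trust-region iterations), and the most promising third is continued to
convergence (capped at ~200 trust-region iterations); deliberate extra
starts always get the full budget. Starts stranded on likelihood plateaus terminate quickly by
their small projected gradient. A simulator failure (integrator breakdown or
parabolicity loss) turns into a large finite residual penalty, so such
regions repel the search instead of crashing it.

Bounds are set about one decade either side of literature-plausible
magnitudes (e.g. K in [10, 1000], q_sat in [5, 500] mg/mL, S_a in [1, 30]);
polynomial coefficient boxes shrink with order (a_2 in +/-20 ... a_5 in
+/-1), reflecting the decay of series coefficients within the radius of
convergence.

The chi-square verdict uses DoF = N*N_y - N_theta and a single-tailed 95%
test; equality with the critical value counts as a pass. Printed chi-square
magnitudes depend on N_y and hence on the reporting grid; with the grid
rule above they are comparable across models within a case but not to
other grids, which is why the case-study checks assert orderings and
pass/fail flips rather than absolute chi-square values.

## Lagrange-multiplier diagnostics

For each fitted parameter theta_k the score test relaxes it into N
per-experiment copies while freezing everything else at the MLE. Because
the constrained optimum of the relaxed problem is the MLE itself, no refit
is needed: with per-experiment output sensitivities s_i = d(yhat_i)/d(theta_k)
(central finite differences, relative step 1e-4, absolute floor 1e-7), the
score elements are s_i^T r_i / sigma_i^2 and the expected Fisher information
of the relaxed vector is diagonal, H_ii = s_i^T s_i / sigma_i^2. The
statistic xi = score^T H^{-1} score is asymptotically chi-square with N-1
degrees of freedom under the constant-parameter null, and the Model
Modification Index MMI = xi / chi2_{N-1}(95%) flags a parameter above 1.
Near-singular information (a parameter locally unidentifiable in some
experiment) triggers a pseudo-inverse with a warning rather than a failure.
At N = 5 the null calibration is only asymptotic; Monte-Carlo replicates of
a linear-Gaussian analogue put the empirical 95th percentile of xi within
[7.8, 11.2] against the nominal 9.49.

## Diagnostic loop

fit -> chi-square test -> (on failure) MMI scan -> modify the largest-MMI
parameter (if above 1) with the first untried rule from an ordered library
-> refit, for at most n_max modifications (default 5). Termination on a
chi-square pass is immediate even if some MMI remain above 1. Ties at the
maximal MMI resolve to the earliest parameter in the report's stable order
and are flagged in the trace. If the test fails but no MMI exceeds 1 the
loop stops with status `no_candidate` (a terminal outcome the binary
pass/exhaust dichotomy cannot express). Each refit's start set includes the
warm-nested parent estimate, so the best log-likelihood is non-decreasing
and chi-square non-increasing along every trace.

The default rule library attaches the exponential capacity laws to q_sat
(when a retention factor K is present), the linear-in-phi rule to S_b, and
degree growth to polynomial coefficients (with tanh damping as the second
option on a_3). Selecting a parameter for which no untried rule exists
raises a `LoopError` listing the library -- candidate invention beyond the
declared rules is deliberately out of scope.

## Known limitations

* The first-order upwind scheme dominates physical dispersion at the
  100-cell study grid (see above); apex times carry an O(dx) bias common to
  generation and fitting.
* Quantities that depend on the absolute number of measurement points
  (chi-square magnitudes, misspecified-model parameter biases) are specific
  to the reporting-grid rule; only their orderings and test verdicts are
  grid-robust.
* MMI values of a correctly specified model are draws from (approximately)
  a scaled chi-square; their exact values vary seed to seed, and individual
  values may approach 1 even when the model is correct.
* The score test's chi-square null is asymptotic in N; at N = 5 it is a
  usable but rough calibration.
* Fitting flat or multimodal likelihoods (high-degree polynomials) can
  strand multistarts; the warm-nested ladder (fit degree n, extend to n+1)
  is markedly more reliable than cold Sobol starts alone.
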