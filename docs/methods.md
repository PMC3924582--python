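# Methods

## Models and assumptions

Both models are deterministic linear compartment ODEs for thymocyte numbers
after the DN stage. All cells within a compartment are kinetically
identical (exponential dwell times, no age structure or "conveyor belt"
progression), rates are constant in time (steady-state thymus), and there is
no feedback from mature T cells. Proliferation is allowed only in the SP
compartment(s), consistent with the absence of detectable post-DP division
in labeling experiments. The pooled model tracks pre-DP → post-DP → SP;
the lineage model resolves the SP pool into CD4 and CD8 branches fed in
parallel from the post-DP pool, with the pooled SP count always the exact
sum `n3 = n4 + n8`.

The Jacobians are lower triangular, so the eigenvalues are minus the
per-compartment net decay rates, and the steady state exists and is stable
exactly when every net SP decay rate (egress + death − proliferation) is
positive. The analytic solution is the standard cascade sum of
exponentials; it is re-derived from the ODEs rather than transcribed (the
coefficients used here are validated against RK4 in the test-suite, which is
the arbiter of correctness for the closed form). The confluent case of
equal decay rates is deliberately not handled analytically — it is
measure-zero, never produced by the estimation identities, and the numerical
integrator covers it; `analytic_solution` raises an explicit error there.

## Parameters

| symbol | meaning | unit | default |
| --- | --- | --- | --- |
| τ1, τ2 | pre-/post-DP residence times | d | 2.5, 0.67 |
| τ3, τ4, τ8 | SP residence times | d | 4.0 |
| φ_out | thymic export flux | cells/d | 2.5×10⁶ |
| μ4, μ8 | CD4/CD8 medullary death rates | 1/d | 0.04, 0.11 |
| λ_min | minimum proliferation rate | 1/d | 1/7 |
| t_acc | acceptance horizon | d | 21 |
| n_λ3, n_φ4 | sweep grid sizes | – | 100 |
| dt | RK4 step | d | 0.01 |

τ2 uses the two-decimal convention 0.67 d (1/τ2 = 1.4925/d), not 2/3 d;
the accepted-interval endpoints for μ2 are sensitive to this choice. The
grid sizes are a density choice ("equally spaced" sampling with unspecified
density in the source procedure); reported intervals are over accepted grid
points and converge quickly with grid refinement. dt = 0.01 d gives ≥100
RK4 steps per fastest timescale (1/1.49 d); the classical fourth-order
convergence is verified in the tests. Days are the universal time unit;
cells/hour figures are a presentation-layer division by 24.

## Estimation conventions

* Cohort summary statistics use population SDs (ddof = 0), the convention of
  the bundled reference table's printed summary rows; the one-SD acceptance
  band depends on it.
* Regression orientation: a1 regresses n2 on n1; a2: n3 on n2; a3: n2 on n4;
  a4: n4 on n8; a5: n3 on n8 (the numerator of each steady-state ratio is
  the response). Slopes are least-squares through the origin,
  `a = Σxy/Σx²`. The `RegressionResult.p_value` is the through-origin
  slope t-test with n−1 df; `p_pearson` (the Pearson-correlation test) is
  also reported, since published analyses of this design commonly quote that
  test.
* The acceptance filter integrates from zero cells in all compartments (the
  same empty-thymus initial condition used for trajectory ensembles) and
  accepts a candidate iff every compartment is within one SD of the cohort
  mean at t = 21 d. The integration uses the exact cascade solution with an
  RK4 fallback for near-degenerate spectra — mathematically identical to
  direct integration and cheap enough for the 2⁸-corner sensitivity sweeps.
* "Proliferation time larger than 7 days" is read as 1/λ > 7 d, so both λ4
  and λ8 candidates are rejected outside [1/7, 1/τ). The upper end
  coincides with the stability/existence boundary. Note that the published
  lineage-model mean λ8 lies *below* 1/7; this package applies the stated
  rejection rule uniformly, so its accepted lineage sweep differs from the
  published means (which are internally inconsistent with the per-row
  defining identities in any case — see Limitations).
* Point estimates of swept rates are means over the accepted grid; intervals
  are accepted min–max.
* Duplicate mice in the reference table are kept as printed.

## Sensitivity analysis

Perturbations are applied to the summary *inputs* of the estimation chain —
θ = (τ1, τ2, τ3, φ_out, a1, a2, n̄3, n̄1) for the pooled model and
θ = (τ4, τ8, μ4, μ8, a3, a4, a5) for the lineage model (pooled-stage means
held at baseline) — and all downstream rates are recomputed per corner, not
perturbed directly. All 2ᵏ sign corners of ±10% are enumerated; the
acceptance rule is the same one-SD-at-21-days criterion, always referenced
to the unperturbed cohort statistics (it is the only acceptance rule the
workflow defines). Corners whose accepted set is empty contribute no
samples. The "95% trimmed interval" is the empirical central-95% interval
(2.5th/97.5th percentiles, linear interpolation) — a convention of this
package, chosen because the source's defining footnote is not available.

First-order variability propagation converts parameter half-widths (by
default the min–max half-widths of the sensitivity sweep) into worst-case
half-widths of the fate probabilities by summing absolute delta-method
terms; each term is validated against central finite differences in the
tests.

## Synthetic cohorts

The generator draws, per mouse, a shared mean-one lognormal size factor
(log-SD `size_dispersion`, default 0.6 — the log-scale spread of the
reference cohort, whose largest mouse is big in every column) and
independent mean-one lognormal measurement noise per compartment (CV
`noise_cv`, default 0.1), multiplying the steady state of a known lineage
truth; `n3` is formed as `n4 + n8` after noise so the a5 = a4 + 1 slope
identity holds exactly. The default truth is the published wild-type point
estimate set.

What passing recovery tests show — and what they do not: the generative
model matches the estimator's own assumptions (proportional compartments,
multiplicative noise), so recovery there demonstrates internal consistency
and correct algebra, not robustness to gating error structure, lineage-
specific covariation, or age trends, none of which are simulated. Two
structural facts surfaced by the recovery experiments are worth noting:
(i) the one-SD 21-day filter is only satisfiable when the cohort's relative
SD is ≳ e^(−(1/τ3 − λ)·21), so cohorts much tighter than the reference
table's ~65% spread reject every candidate — the filter is calibrated to
real-cohort dispersion; (ii) the influx φ is the only scale-bearing
estimate, so its error tracks the sampling error of the mean size factor
(recovery tests use cohorts of a few hundred mice to separate algorithmic
bias from that sampling noise; rate ratios recover well already at n = 8).

## Numerical choices and degenerate inputs

* Sweep grids are `numpy.linspace` (inclusive endpoints for λ3 ∈ [1/7, 1/τ3];
  the unstable right endpoint is rejected by the filter; the φ4 grid is the
  open interval (0, φ2) via interior points).
* The closed-form trajectory clips negative rounding dust to zero; counts
  are analytically nonnegative for nonnegative initial conditions.
* Spectrum degeneracy is declared at pairwise decay-rate gaps below 10⁻⁹
  of the largest rate.
* Empty accepted sets raise a dedicated error carrying per-cause rejection
  counts (λ-window, stability, 21-day filter) so filter behavior is
  auditable.
* Cohort validation enforces `n3 = n4 + n8` to 0.5% (count tables are
  typically printed rounded to 10⁴ cells).

## Known limitations

* The pooled-model stringency `φ3 n̄3 / φ_out`-style ratio evaluates to
  ~7.1% at the experimental means (and ~6.4% at model-consistent counts);
  published values between these are not reproducible from the documented
  definitions, so the package reports its own computed value.
* The published lineage sweep means (φ4, λ4, λ8) do not satisfy the per-row
  defining identities jointly; this package reports means over its own
  accepted set, which therefore differ.
* Measurement error in the regressors biases through-origin slopes downward
  by ≈CV² (attenuation); no errors-in-variables correction is applied.
* Branching-process expected-yield computations (cells surviving to export
  per 10³ pre-DP, accounting for proliferation) are out of scope.
* No confidence intervals from regression theory, no Bayesian posterior, no
  time-course fitting: the workflow is the steady-state sweep-and-filter
  design throughout.
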