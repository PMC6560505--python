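# Methods

## Models

**Structural models.** Two PK structures are implemented. The
one-compartment model with first-order oral absorption uses the closed
form `C(t) = Σ_d D_d·ka/(V·(ka−ke))·(e^{−ke·(t−t_d)} − e^{−ka·(t−t_d)})`,
`ke = CL/V`, superposed over doses; when `|ka−ke| < 1e−8·ka` the analytic
limit `D·ka·(t−t_d)·e^{−ka(t−t_d)}/V` replaces the cancelling difference.
The two-compartment model eliminates drug from the central compartment
through parallel first-order (`CLlin`) and Michaelis–Menten (`Vmax`, `Km`)
pathways, with intercompartmental clearance `Q` and volumes `V1`/`V2`;
doses are intravenous boluses and the system is integrated piecewise
between dose instants with LSODA at rtol 1e−8 / atol 1e−10. Disposition
parameters (`CLlin`, `Vmax`, `V1`, `V2`) scale linearly with body weight
relative to 70 kg; allometric exponents are deliberately not used. The
dosing route for the parallel-elimination scenario is bolus because its
parameter set contains no absorption constant.

**Mixture population model.** Each subject belongs to one of K = 2 latent
subpopulations drawn with proportions `pmix`; the mixture parameter (CL or
CLlin) has one typical value per subpopulation while the remaining typical
values, the diagonal random-effect covariance Ω and the residual variance
are shared across subpopulations. Random effects act multiplicatively,
`param_i = typical_k · e^{η_i}`, `η ~ N(0, Ω)`. Residual error is
proportional (`var = σ²·f²`), additive, or combined. The data structures
are K-ary but fitting more than two components is unsupported.

## Likelihood

Per subject and component, the marginal likelihood is approximated by
Laplace around the conditional mode `η̂` of
`g(η) = Σ_j [log v_j + (y_j − f_j)²/v_j] + log|Ω| + η'Ω⁻¹η`:

    IOFV = g(η̂) + log det(∇²g(η̂)/2)

with the `N·log 2π` constant excluded so that OFV differences, not
absolute values, are the comparison currency (the convention of the major
NLME estimation software). Adaptive Gauss–Hermite quadrature (default 21
nodes, tensor product, mode-centered and curvature-scaled) is available
for problems with at most two random effects and serves as the
verification route in the test suite; on one-random-effect problems it
agrees with direct numerical integration to ~1e−3 and Laplace agrees with
it to better than 0.1. Note that under proportional residual error the
Laplace approximation itself carries a small systematic offset (~0.05 per
six-observation subject) from the skewness of the integrand; this cancels
in all comparisons between components or models and is invisible to
IP_mix, which depends only on IOFV differences.

The printed form of the individual-likelihood transformation in the
literature, `IL = e^{+IOFV/2}`, would make worse-fitting components more
probable; since IOFV is −2·log likelihood, the implementation uses
`IL = e^{−IOFV/2}`, and `IP_mix,k ∝ pmix_k·e^{−IOFV_k/2}` is evaluated by
log-sum-exp after centering so any shared additive constant cancels
exactly. MIXEST is the argmax of IP_mix (ties break to the lowest index),
equivalently the argmin of `IOFV_k − 2·log pmix_k`.

**Inner optimization.** Subjects sharing a design (dose schedule and
sampling times) are processed as one vectorized batch. For the analytic
model the conditional modes come from a damped Newton iteration with
central-difference gradients and Hessians over η (step 1e−4), per-subject
step halving and a trust-region-style cap of 3 on the step norm. For the
ODE model, Newton on finite differences of the objective sits at the
solver noise floor, so modes come instead from Fisher scoring: prediction
sensitivities ∂f/∂η by central differences (step 1e−3) with all stencil
variants stacked into a single LSODA solve (the solver cost is dominated
by per-step overhead, not state count), the exact gradient assembled from
the sensitivities, and the expected information `J'WJ + 2Ω⁻¹`
(`W = 2/v + (v'/v)²`) as the step matrix. Reported IOFVs use the exact
central-difference Hessian at the mode; during fitting the
expected-information determinant stands in for speed, and the reported
parameters, records and OFV are always recomputed with the exact form.

**Outer optimization.** Parameters are transformed (log for typical
values and variances, multinomial logit for `pmix`) and maximized by
L-BFGS-B with central finite-difference gradients (relative step 1e−5) for
the analytic models. For the ODE model a bounded Powell search (box:
100-fold around the start) replaces the quasi-Newton pass: its FD
gradients are at the ODE-noise floor, and unit-scale quasi-Newton trial
steps visit extreme parameter regions where integration becomes very
expensive. Convergence is a relative OFV change of 1e−9 (1e−6 for
Powell). Because the per-component IOFVs do not depend on `pmix`, the
mixing proportions are afterwards polished to their exact conditional MLE,
the EM fixed point `pmix = mean(IP_mix)`; this makes the randomized
allocation exactly unbiased against the displayed PMIX. Components of a
fitted mixture are canonically ordered by ascending mixture-parameter
value. Default starts: the supplied initial estimates plus mixture-θ
splits at 0.5×/2× and 0.33×/3× of their geometric mean (`pmix` reset to
uniform); when no initial estimates are given, a naive pooled
least-squares fit of the median concentration profile seeds the
one-compartment model (ODE fits require explicit initial estimates, as is
usual practice). A fit whose `pmix` reaches the 1e−6 boundary is flagged,
not failed.

## Simulation scenarios

Three presets define the exercised study conditions:

| preset | model | mixture split | proportions | n | design |
|---|---|---|---|---|---|
| linear-70-30 | 1-cmt oral | CL 20/80 L/h | 0.70/0.30 | 1000 | 100 mg at 0 h; samples 0.5–12 h (6) |
| linear-85-15 | 1-cmt oral | CL 20/60 L/h | 0.85/0.15 | 1000 | same |
| parallel-40-60 | 2-cmt parallel | CLlin 0.03/0.12 L/h | 0.40/0.60 | 36 | 4×50 mg q168h; 22 samples over 672 h |

Shared values: ka 1 h⁻¹, V 100 L (linear); Vmax 1.2 mg/h, Km 10 mg/L,
V1 3 L, V2 2 L, Q 0.075 L/h (parallel); proportional residual variance
0.04 everywhere. Interindividual variances of 0.09 are placed on ka, CL
and V for the linear scenarios — the design statement names no specific
parameters, so all structural parameters carry IIV, and the choice is
configurable — and on CLlin, Vmax and V1 for the parallel scenario, whose
source example states IIV existed without printing magnitudes. Body
weights for the parallel scenario are lognormal with median 70 kg and 20%
CV (none are printed in the source design). The 22 sampling times are this
package's own rich design, about six per dosing interval. Membership is
per-subject and constant; each subject's true component is also emitted as
a binary covariate `COV` so the covariate-model comparator can use it.
Replicate simulation re-draws membership, η and residuals per subject per
replicate from independent seed streams while preserving the template
design.

What the generator does not emulate: dropout or missingness, time-varying
covariates, dose individualization, assay limits of quantification, and
model misspecification beyond what a scenario explicitly encodes. Passing
tests therefore demonstrate correctness of the machinery under the stated
generating model, not robustness to real-data pathologies.

## VPC construction

Defaults: percentiles 5/50/95, 95% confidence bands, 200 replicates,
binning on nominal design times (quantile binning with equal counts is
available for irregular designs). None of these display choices are fixed
by the methodology; they follow common VPC practice and are configurable.
For each (bin, percentile) the band is the empirical 2.5–97.5% interval of
that percentile across replicates; a bin left empty by any replicate has
its band marked unavailable and is excluded from outside-cell counts. The
mixture VPC simulates replicates from the fitted parameters over the
original design, evaluates original data and every replicate at those
parameters, allocates each replicate independently (one dedicated seed
stream per run, split into observed + per-replicate substreams so adding
replicates never perturbs the observed-data allocation), and builds one
panel per subpopulation with the PMIX/ORIGID/SIMID annotation; SIMID is
the across-replicate mean percentage. The observed-data randomized
allocation is drawn once per run — a single observed line per panel.
Allocation bias is measured against the estimated PMIX (the number
displayed on the same panel), since true proportions are unknown for real
data; a truth-referenced variant exists for simulation studies. Rendering
is strictly separated from computation: every VPC operation returns a
plain data product.

## Desk-scale choices in the test suite

The end-to-end tests run the linear-scenario pipeline at n = 250 (with the
correspondingly widened recovery interval for the 70/30 scenario) and the
misspecification-sensitivity experiment at n = 120 with 100 replicates per
VPC across 10 independent studies; the acceptance script runs the
reduced-separation experiment at its full design scale of n = 1000. The
misspecification construct inflates the second subpopulation's volume of
distribution by 50% in the generating model while the fitted mixture
shares one volume across subpopulations.

## Known limitations

* Exactly two mixture components are supported in estimation.
* No FOCE-with-interaction equivalence to any specific software is
  claimed; OFV values agree in differences, not absolute level, with
  implementations using other inner approximations.
* Standard errors of estimates are not reported.
* The MIXEST allocation bias observed under the reduced-separation
  scenario is small (≈0.5 percentage points at n = 1000) because the
  stated design values separate the subpopulations strongly; populations
  with flatter IP_mix distributions show proportionally larger shrinkage
  bias, and the randomized strategy remains unbiased in all cases.
* Laplace accuracy degrades for subjects with very few observations under
  proportional error; the quadrature mode exists for such checks but is
  limited to two random effects.
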