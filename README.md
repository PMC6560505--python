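# mixvpc

Visual predictive checks (VPCs) that account for multimodal parameter
distributions in population pharmacokinetic mixture models.

## The problem

Population PK analyses assume interindividual variability is unimodal. When
the population is heterogeneous — classically a genetic polymorphism that
splits clearance into slow and fast metabolizers — a finite-mixture
nonlinear mixed-effects (NLME) model describes each individual as belonging
to one of several latent subpopulations, each with its own typical
parameter values, mixed with an estimated proportion. The standard VPC,
which pools all individuals into one panel, can hide exactly the
misspecification a mixture model is meant to capture: over-prediction in
one subpopulation can cancel under-prediction in the other.

`mixvpc` is a self-contained toolkit for pharmacometricians that

* simulates mixture populations for one-compartment oral and
  two-compartment parallel linear/Michaelis–Menten elimination models,
* fits two-component mixture, non-mixture and covariate NLME variants by
  Laplace-approximated maximum likelihood,
* derives each individual's posterior subpopulation probability
  (`IP_mix`) and most likely subpopulation (`MIXEST`), and
* builds mixture-specific VPCs with one panel per allocated subpopulation,
  annotated with the population mixture estimate (PMIX) and the allocation
  percentages of original (ORIGID) and simulated (SIMID) individuals.

## The statistics

For subject *i* and subpopulation *k*, the individual objective function
value is the Laplace-approximated marginal likelihood on the −2·log scale
(`N·log 2π` excluded, the NONMEM reporting convention):

```
IOFV_ik = −2 log ∫ p(y_i | η, θ_k) p(η; Ω) dη
IP_mix,ik = P_mix,k · exp(−IOFV_ik / 2) / Σ_j P_mix,j · exp(−IOFV_ij / 2)
MIXEST_i  = argmax_k IP_mix,ik
```

Two allocation strategies stratify observed and simulated individuals into
subpopulation panels: deterministic `MIXEST` assignment, which — like any
empirical-Bayes classifier — shrinks toward the dominant subpopulation
when individual data are uninformative, and `randomized` assignment, which
draws each individual's panel from its `IP_mix` vector and is unbiased in
expectation. Every simulated replicate is re-evaluated at the final
parameter estimates (the MAXEVAL=0 analog) so that observed and simulated
data are post-processed identically. The gap between the MIXEST ORIGID
percentage and the displayed PMIX percentage is the *allocation bias* in
percentage points.

## Worked example

Simulate a fourfold-clearance mixture population (CL 20 vs 80 L/h, 70/30%
proportions, one 100 mg oral dose, six samples over 12 h), fit the
two-component mixture, and build the mixture VPC:

```
$ mixvpc simulate --scenario linear-70-30 --seed 1 --n-subjects 200 --outdir run
simulated 200 subjects, 1200 observations; true component counts: [139, 61]

$ mixvpc fit --dataset run/linear-70-30.csv --scenario linear-70-30 \
    --variant mixture --n-starts 1 --outdir run
OFV = -5196.213 (converged: True)
estimated dominant P_mix = 69.6%

$ mixvpc vpc --dataset run/linear-70-30.csv --fit-file run/fit.yaml \
    --scenario linear-70-30 --mix --strategy mixest -r 100 --seed 1 --outdir run
PMIX [69.6, 30.4] | ORIGID [70.0, 30.0] | SIMID [69.8, 30.2] | bias +0.4 pp
traditional VPC cells outside CI: 1/18

$ mixvpc separation-plot --phm run/fit_phm.csv --outdir run
separation index = 0.985
```

Reading the output: the fitted mixture proportion (69.6%) recovers the
simulation truth (70%, realized 139/200 = 69.5%); MIXEST allocates 70.0%
of individuals to the dominant subpopulation, within half a percentage
point of PMIX, so allocation bias is negligible here — the fourfold
clearance difference separates the subpopulations almost perfectly
(separation index 0.985 = fraction of individuals whose maximum `IP_mix`
exceeds 0.8). The traditional VPC shows 1 of 18 percentile cells outside
its 95% confidence band, consistent with a correctly specified model.
`run/vpc_mixture.png` holds the per-subpopulation panels;
`run/fit_phm.csv` is the phm-like per-individual table (ID, SUBPOP, IOFV,
IL, IPmix, MIXEST).

The same workflow applies to the harder 85/15% scenario with a threefold
clearance difference (`--scenario linear-85-15`), where MIXEST allocation
visibly over-represents the dominant subpopulation, and to the 36-subject
two-compartment scenario with parallel linear and saturable elimination
(`--scenario parallel-40-60`).

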