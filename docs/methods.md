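# Methods

## Problem setting

Relative (alchemical) free-energy calculations predict how a chemical
modification changes a ligand's binding free energy to one target. In
selectivity optimization, the quantity of interest is the *difference* of
such changes between two targets,

    S_i   = dG_i(target2) - dG_i(target1)
    dS_ij = S_j - S_i = ddG_ij(target2) - ddG_ij(target1),

so errors made for the two targets partially cancel. If the systematic
(reproducible) per-target errors sigma_sys,1 and sigma_sys,2 are correlated
with coefficient rho, and the statistical (sampling) errors sigma_stat are
independent between targets, the standard error of a predicted dS is

    sigma_selectivity
      = sqrt(sigma_sys,1^2 + sigma_sys,2^2 - 2 rho sigma_sys,1 sigma_sys,2
             + sigma_stat,1^2 + sigma_stat,2^2).

The package provides (i) this propagation and Monte-Carlo models of the
synthesis *speedup* that triage with such predictions delivers, (ii) a
hierarchical Bayesian model that infers rho (and the error decomposition)
from paired perturbation maps plus experimental affinities, and (iii) a
ground-truthed synthetic generator that makes the whole chain testable.

## Speedup models

**Proposal distribution.** True changes in selectivity proposed by a
chemist are modeled as dS ~ Normal(0, 1 kcal/mol): most R-group edits do
not move selectivity much. Predictions are the truth plus
Normal(0, sigma_selectivity^2) noise. Experimental follow-up is treated as
error-free.

**Unlimited resources.** Every compound predicted at or above a threshold
theta is synthesized; the speedup is the enrichment of truly selective
compounds among them relative to the base rate. The default Monte-Carlo
size is 10^7 proposals (configurable; the estimate's standard error is
reported via the delta method on the conditional fraction, with the base
rate computed from the analytic normal tail). A closed-form oracle
evaluates the same quantity exactly as a bivariate-normal orthant ratio:
with T ~ N(0,1), P = T + E, corr(T,P) = 1/sqrt(1+sigma_sel^2),

    speedup = Pr(T>=theta, P>=theta) / [Pr(T>=theta) Pr(P>=theta)].

**Thresholds in kcal/mol.** The package adopts the rounded field convention
1 log10 unit = 1.4 kcal/mol (rather than kB*T*ln10 = 1.372 at 300 K), so
10x = 1.4, 100x = 2.8, 500x ~ 3.78, 1000x = 4.2 kcal/mol.

**Constrained resources.** Per replicate, ``n_scored`` proposals are drawn
and ranked by prediction; those meeting the synthesis rule are made, at
most ``max_synthesized`` (default 10). The replicate speedup is the number
of true successes divided by the expected number under random selection,
``Pr(dS >= theta) * n_synthesized``; that probability is computed
analytically rather than by a large Monte-Carlo sample. If nothing
qualifies, the replicate scores exactly 1 (triage neither helped nor
hurt). The estimate is the mean over replicates (default 1000) with a
2.5/97.5-percentile interval. Ranking ties are broken by draw order, a
measure-zero event for continuous predictions.

**Statistical effort.** Statistical error follows
sigma_stat(N) = 0.2/sqrt(N) kcal/mol, where N is relative sampling effort:
0.2 kcal/mol at baseline, halved at 4x effort, zero at infinite effort.
The effort sweep evaluates the unlimited model with both error components.

**Posterior-marginal speedup.** Given a posterior mean and sd for rho,
replicates draw rho from a normal *truncated to [-1, 1]* (an unbounded
draw can yield an invalid error model), form sigma_selectivity with zero
statistical error, and evaluate the unlimited model (Monte Carlo by
default, or the exact orthant formula).

## Bayesian error decomposition

Per target and phase (ligand-in-complex, ligand-in-solvent), ligand
absolute free energies G carry Normal(0, 25^2) priors, with one reference
ligand pinned at Normal(0, 1^2) per phase — the pinning replaces the broad
prior and only fixes the arbitrary per-phase additive constant. Each edge
(i -> j) has a dummy-atom term c_ij ~ Normal(0, 25^2), shared between the
two phases so it cancels exactly in the binding free energy (dummy-atom
endpoint contributions are phase-independent). Calculated edge values are
observations

    ddG_calc(phase,ij) ~ Normal(G_j - G_i + c_ij, (alpha * delta_BAR)^2),

with one scaling factor alpha per target shared by all of that target's
edges; alpha absorbs the tendency of BAR standard errors to under-report
the sampling error evident in cycle hysteresis. Its prior is
Lognormal(0, 1) (positive support, median 1). Experimental affinities
enter as dG_obs ~ Normal(dG_true, 0.3^2) with dG_true ~ Normal(0, 50^2);
the 0.3 kcal/mol experimental uncertainty is fixed, not inferred.

Per draw, dG_FEP = G_complex - G_solvent per ligand; ddG_FEP and ddG_true
are formed over **all unordered distinct ligand pairs** (self-pairs and
reversed duplicates excluded); the pair error is
eps = ddG_FEP - ddG_true, and

    rho = cov(eps_1, eps_2) / (sd(eps_1) sd(eps_2))

with the population (n-denominator) convention in both numerator and
denominator, so the convention cancels. The per-target systematic error is
summarized as the mean over draws and ligands of |eps_{i,ref}| (pairs
containing the reference), and the per-pair statistical error as the
posterior standard deviation of ddG_FEP.

### Sampling

Conditional on alpha, the model is linear-Gaussian: the node/edge block
has a conjugate multivariate-normal posterior and a closed-form marginal
likelihood. The default sampler therefore:

1. evaluates the marginal posterior of log(alpha) per target on a fine
   log-spaced grid (default 241 points over alpha in [0.05, 20]);
2. draws alpha values from that discretized marginal;
3. draws the node/edge block exactly from the conditional multivariate
   normal for each sampled alpha (one Cholesky factorization per unique
   grid value);
4. draws dG_true from its independent conjugate posterior.

Draws are independent and exact up to the alpha grid resolution, so no
warmup is needed and the effective sample size equals the number of
draws; split-R-hat and ESS are still computed (via arviz on pseudo-chains)
and attached for interface completeness. An affine-invariant ensemble MCMC
backend over the identical log-posterior serves as an independent
cross-check in the test suite and carries the optional Student-t
likelihood variant (heavier-tailed edge errors; not conjugate). Default
draw counts are 20 000 for analyses and 1000-2000 in tests; because draws
are iid, far fewer draws suffice than an autocorrelated MCMC chain would
need.

### What the rho posterior estimates — and what it does not

The correlation is defined *per draw over the finite set of noisy pair
errors*. That estimand differs from the population correlation of the
underlying systematic offsets in two ways:

- **Attenuation.** eps contains, besides the systematic offset difference,
  statistical edge noise, experimental noise (through dG_true), and
  posterior draw scatter — all independent between targets. These inflate
  the per-target eps variance without contributing covariance, biasing the
  per-draw correlation toward zero. At the default study conditions
  (sigma_sys = 1, exp_sd = 0.3, edge delta = 0.2 kcal/mol, 16 ligands) the
  attenuation factor is roughly 0.8.
- **Finite-sample scatter.** With n ligands there are only n-1 independent
  offsets; the realized offset correlation fluctuates around the
  population value with sd ~ (1-rho^2)/sqrt(n-1) (~0.26 at rho=0, n=16).

Calibration experiments in the test suite show the posterior interval
brackets the *realized* pair-error correlation essentially always, i.e.
the sampler is well calibrated for the estimand the procedure defines,
while nominal-rate coverage of the population rho_true is not achieved at
high rho_true (attenuation) or at rho_true = 0 (finite-sample scatter
exceeds the interval width). This is a property of the published
estimator, not of the sampler; de-attenuated population inference would
require a different (hierarchical-population) model, which is out of
scope.

## Synthetic data generator

The generator emulates a paired two-target campaign on one congeneric
series:

- True binding free energies are uniform over a 3 kcal/mol window centered
  at -9 kcal/mol (matching the narrow 2-3 kcal/mol dynamic ranges typical
  of published selectivity series), reference pinned at the center.
  Arbitrary per-ligand solvent free energies define the two phases.
- Per-ligand systematic offsets (e_1, e_2) are bivariate normal with
  per-target sds sigma_sys_true (default 1 kcal/mol each) and correlation
  rho_true; the reference's offsets are 0. Injecting error at the *node*
  level keeps maps cycle-consistent and makes pair errors e_j - e_i
  inherit the correlation; the offset is placed in the complex phase only
  (the split between phases is unidentifiable from binding data — this
  choice is arbitrary and documented).
- Edges (topologies: star, ring, or the default star-plus-ring so cycle
  diagnostics are exercised) see truth plus offsets plus
  Normal(0, (alpha_true * delta)^2) noise per phase, with reported BAR
  uncertainty delta = sigma_edge_stat (default 0.2 kcal/mol, the baseline
  statistical error). alpha_true > 1 emulates BAR under-reporting. When
  sigma_edge_stat = 0 the injected noise is exactly zero but the
  *reported* uncertainty is floored at 0.01 kcal/mol so maps remain valid.
- Experimental observations are truth plus Normal(0, 0.3^2) noise.

All randomness flows from one seed through four independent sub-streams
(free energies, offsets, edge noise, experimental noise), so switching one
noise source off never perturbs the others.

What the generator does **not** emulate: real force-field error structure
(offsets here are exchangeable Gaussians, not chemically clustered),
edge-specific BAR uncertainties, inter-ligand assay correlations, or any
molecular detail. Passing recovery tests therefore demonstrates
statistical correctness of the inference machinery under the model's own
assumptions, not accuracy on real campaigns.

## Bundled affinity tables

The two bundled series (`cdk2_cdk9_shao_synthetic.csv`,
`cdk2_erk2_blake_synthetic.csv`) are *synthetic stand-ins*: per-ligand
potencies were constructed and calibrated so that the derived selectivity
summaries reproduce the published series statistics (CDK2/CDK9: mean
S(CDK9-CDK2) -0.65, sd 0.88, range 2.8 kcal/mol over 12 ligands;
CDK2/ERK2: mean S(ERK2-CDK2) -1.74, sd 0.56, range 2.2 kcal/mol over 11
ligands, with the charged compound 9 flagged `exclude_from_analysis`).
The original per-compound tables exist only as figure panels in the
source publications and are not redistributed here. Summary statistics
use the sample (n-1) standard deviation. The CDK2/CDK9 table carries Ki
values (Cheng-Prusoff already applied by the original authors, per-kinase
Km); the CDK2/ERK2 table carries IC50 values used directly as Ki under
the Km(ATP) >> [S0] assumption.

## Numerical choices

- kB = 0.0019872 kcal/(mol K); default temperature 300 K. Free energies
  from inhibition constants use dG = kB T ln(Ki in molar), i.e. potent
  binders are negative (1 nM ~ -12.4 kcal/mol at 300 K).
- Unit conversion to molar happens in exactly one place
  (``affinity.to_free_energy``) to avoid silent nM/µM mistakes.
- Cycle enumeration defaults to a fundamental cycle basis (all simple
  cycles is exponential); full enumeration is available for small maps.
- MUE/RMSE bootstrap resamples (prediction, observation) pairs jointly,
  with percentile intervals (default 10 000 resamples).
- Monte-Carlo sizes are configurable; defaults (10^7 proposals for the
  unlimited model, 1000 replicates for the constrained model) keep a
  desk-scale run under a minute while reporting standard errors.
- The bivariate-normal orthant probability uses scipy's multivariate
  normal CDF; central symmetry maps the upper orthant to a CDF call.

## Known limitations

- Two targets only; no multi-target generalization.
- The alpha grid bounds [0.05, 20] cap detectable BAR mis-reporting; data
  implying alpha outside the grid would pile posterior mass at the edge
  (none of the tested regimes approach the bounds).
- The Student-t likelihood path relies on ensemble MCMC and is orders of
  magnitude slower than the exact sampler; it is provided for sensitivity
  analysis, not routine use.
- The rho posterior quantifies the finite-set error correlation (see
  above); it is not a de-attenuated estimate of the population
  correlation of systematic errors.
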