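# selekt

Can relative free-energy calculations accelerate *selectivity* optimization?

Alchemical free-energy methods predict relative binding free energies
(ΔΔG) with roughly 1 kcal/mol per-target accuracy. When the goal is
selectivity between two related targets — say sparing CDK2 while potently
inhibiting CDK9 — the quantity that matters is the change in selectivity

    ΔS_ij = ΔΔG_ij(target 2) − ΔΔG_ij(target 1),

and the *systematic* parts of the two per-target errors may cancel. If
they are correlated with coefficient ρ, the standard error of a predicted
ΔS is

    σ_selectivity = sqrt(σ²_sys,1 + σ²_sys,2 − 2 ρ σ_sys,1 σ_sys,2
                         + σ²_stat,1 + σ²_stat,2),

which reaches zero at ρ = 1 with equal per-target errors even though each
potency prediction is wrong by ~1 kcal/mol. `selekt` quantifies what that
means for medicinal chemistry throughput:

- **Error propagation and triage speedup** (`selekt.speedup`): Monte-Carlo
  and closed-form (bivariate-normal orthant) models of the fold reduction
  in compounds that must be synthesized to reach a selectivity goal when
  proposals are triaged by prediction — with unlimited resources, under
  scoring/synthesis budgets, and as a function of sampling effort
  (σ_stat(N) = 0.2/√N kcal/mol).
- **Bayesian error decomposition** (`selekt.bayes`): a hierarchical model
  over two targets' perturbation maps (per-edge, per-phase ΔΔG with BAR
  uncertainties, scaled by an inferred per-target factor α) plus
  experimental affinities, yielding posterior draws of the per-pair
  prediction errors and their inter-target correlation ρ.
- **Perturbation-map and affinity handling** (`selekt.fepmap`,
  `selekt.affinity`): validated map I/O, cycle-closure (hysteresis)
  diagnostics, Cheng–Prusoff IC50→Ki conversion and ΔG = k_B T ln Ki,
  selectivity series summaries.
- **Ground-truthed synthetic campaigns** (`selekt.synthetic`): two-target
  congeneric series with controllable offset correlation ρ_true,
  statistical noise, BAR under-reporting (α_true) and experimental noise,
  so the whole inference chain is testable end to end.
- **Accuracy metrics** (`selekt.metrics`): MUE/RMSE with joint-pair
  bootstrap confidence intervals.

See `docs/methods.md` for the models, priors, sampler design and known
limitations.

## Worked example

Simulate a 16-ligand two-target campaign with correlated systematic
errors, infer ρ from the maps plus noisy experimental affinities, and ask
what speedup that correlation buys:

```sh
$ selekt simulate --n-ligands 16 --rho 0.7 --sigma-sys 1 1 --seed 7 --out demo/
$ selekt fit-rho --map1 demo/map_target1.csv --map2 demo/map_target2.csv \
    --exp1 demo/affinity_target1.csv --exp2 demo/affinity_target2.csv \
    --draws 4000 --seed 1
{
 "rho_mean": 0.8757419171007459,
 "rho_sd": 0.038009090934068054,
 "rho_ci": [0.7912866542136858, 0.9403029548610683],
 "sigma_sys": {"target1": 1.2962036523381255, "target2": 1.231138093987054},
 "alpha_mean": {"target1": 0.8268076921972838, "target2": 1.107459615168148},
 ...
}
$ selekt speedup --rho 0.88 --sigma-sys 1.30 1.23 --threshold-log10 1 --analytic
sigma_selectivity=0.6234
rho,sigma_sys_1,sigma_sys_2,...,speedup,...
0.88,1.3,1.23,...,6.186844832370803,...
```

Read: the posterior puts the inter-target error correlation near 0.88
(95% CI 0.79–0.94; this realization of the 16-ligand series happens to
carry a high sample correlation — the posterior tracks the realized,
noise-attenuated error correlation, see the methods note), the per-target
systematic errors near 1.2–1.3 kcal/mol, and triaging proposals with such
a method would let a team synthesize ~6× fewer compounds to find a
tenfold (1.4 kcal/mol) selectivity improvement.

The bundled example tables reproduce published selectivity summaries:

```sh
$ selekt summary --affinity src/selekt/data/cdk2_cdk9_shao_synthetic.csv --pair CDK2 CDK9
n=12 mean_S=-0.65 std_S=0.88 range_S=2.80 kcal/mol  (S = dG[CDK9] - dG[CDK2])
```

(These per-ligand tables are constructed stand-ins calibrated to the
published series statistics; see `docs/methods.md`.)

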