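# metajac

Reconstruction of the biochemical Jacobian of a metabolic network from the
covariance of replicate metabolomics measurements, with the multivariate
statistics of a targeted-metabolomics study (Pareto scaling, PCA, OPLS-DA
with VIP scores, permutation validation, differential-metabolite
screening).

## The problem

Replicate metabolite measurements within one biological condition are not
identical: metabolite pools fluctuate around a steady state, and those
fluctuations are *correlated* because the metabolites are coupled through
the reaction network. For a system near a stable steady state driven by
Gaussian noise, the fluctuation–dissipation relation takes the form of a
Lyapunov equation

```
J · COV + COV · Jᵀ = −2 · FLU
```

where `J` is the Jacobian of the reaction dynamics (∂(dCᵢ/dt)/∂Cⱼ,
evaluated at the steady state), `COV` the stationary covariance of the
metabolite pools, and `FLU` the fluctuation (diffusion) matrix of the
noise. Measuring `COV` from replicates and inverting this relation yields
the local dynamics `J` — which metabolite's balance responds to which
pool, and how strongly — from purely observational snapshot data.

The inversion is underdetermined: `J` has n² entries but `COV` only
n(n+1)/2 independent equations. The network's stoichiometry closes the
gap: `J = S · ∂r/∂C`, so an entry `J[i, j]` can only be nonzero if some
reaction that produces or consumes species `i` has species `j` among its
substrates or modifiers. Restricting the unknowns to that sparsity
pattern makes the linear system (generically) solvable.

On top of the reconstruction, the package compares conditions: bootstrap
resampling of replicates gives per-entry standard errors, entry-wise
z-scores quantify Jacobian changes between conditions, and pathway-level
aggregation (mean |z| over entries whose row species carries a pathway
tag) points to the part of the network that rewired.

A built-in fixture, `mannose_core`, encodes the mannose /
glycolysis / glycosylation branch point (Man → M6P → {F6P → FBP,
M1P → GDP-mannose}, plus a parallel Glc → G6P → F6P branch), and a
stochastic mass-action simulator (Euler–Maruyama) generates replicate
tables for a four-arm diet study (`WT+SD`, `AD+SD`, `AD+NMD`,
`AD+NMD+M`, differing in the mannose inflow), so the whole pipeline is
testable end to end with no external data.

## Worked example

```yaml
# demo.yaml
seed: 11
network: mannose_core
simulation:
  n_replicates: 200
  noise_sd: 0.15
  measurement_cv: 0.05
bootstrap_B: 200
n_perm: 200
comparisons:
  - [WT+SD, AD+SD]
```

```
$ metajac run --config demo.yaml --outdir demo_out
{
 "WT+SD_vs_AD+SD": {
  "pathway_scores": {
   "glycosylation": 2.0477565301914904,
   "glycolysis": 1.0256772452937257
  },
  "top_entry": ["Man", "Man"],
  "R2Y": 0.9865388924752478,
  "Q2": 0.9860986172846407,
  "permutation_valid": true,
  "selected_metabolites": ["Man", "M6P", "F6P", "FBP", "GDPMan"]
 }
}
```

Reading the output: the elevated-mannose condition triples the mannose
inflow, which shifts the steady state and — through the regulatory
coupling in the glycosylation branch — changes the Jacobian entries in
the rows of M1P and GDP-mannose. The pathway score (mean |z| of
Jacobian changes over each pathway's rows) is accordingly about twice as
high for glycosylation (2.05) as for glycolysis (1.03). The OPLS-DA
model separating the two conditions is essentially perfect (R2Y ≈ Q2 ≈
0.99), survives the 200-permutation overfitting test, and the screen
(VIP > 1 and p < 0.05) selects the mannose-pathway metabolites whose
means moved. Per-condition covariances, Jacobian edge lists with
bootstrap SEs, the differential report, the OPLS summary and the screen
table are written to `demo_out/`; rerunning with the same config and
seed reproduces every file byte for byte.

Library use mirrors the CLI: `load_builtin`, `generate_study`,
`condition_covariance`, `solve_inverse` / `bootstrap_jacobian`,
`differential_jacobian`, `fit_oplsda`, `screen_metabolites`.

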