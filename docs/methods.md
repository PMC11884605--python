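# Methods

## Model

Metabolite dynamics are mass action on a reaction network: for
concentrations C and reactions with rates r(C), dC/dt = S·r(C), where S
is the net stoichiometric matrix with inflow (constant) and outflow
(first-order) pseudo-reactions appended as extra columns. A reaction's
rate is its rate constant times the product of substrate concentrations
(raised to their stoichiometric coefficients) and modifier
concentrations. Modifiers model regulation without consumption: they
enter the rate law and therefore the Jacobian sparsity, but not S.

Biological replicate variation is modeled as Langevin noise around the
deterministic steady state C*:

    dC = S·r(C) dt + diag(noise_sd) dW.

Linearizing at C* gives an Ornstein–Uhlenbeck process with drift
J = S·(∂r/∂C)|_{C*}, whose stationary covariance COV satisfies the
Lyapunov equation

    J·COV + COV·Jᵀ = −2·FLU,   FLU = diag(noise_sd²) / 2.

The factor of one half is the package's single noise convention; it is
pinned by the scalar closed form (a pool with first-order decay k and
noise σ has stationary variance σ²/(2k)) and asserted by tests at every
level that touches it. When nothing is known about the noise, the
inverse solver defaults to FLU = I; rescaling FLU by a constant rescales
the reconstructed J by the same constant, so signs, z-scores and
rankings do not depend on the unknown noise magnitude (asserted as a
test).

## Forward and inverse solvers

The forward problem (J, FLU → COV) uses the standard Schur-based
Lyapunov solver after an explicit Hurwitz check; the residual
‖J·COV + COV·Jᵀ + 2·FLU‖ is verified below 1e-10·‖FLU‖. An independent
Kronecker-vectorization solve serves as the oracle in tests, never as
the implementation.

The inverse problem enumerates one linear equation per unordered index
pair (i ≤ j) — exactly n(n+1)/2 rows, which resolves the symmetric
redundancy of the matrix equation — over the free entries of the
stoichiometry-derived sparsity pattern: J[i, j] may be nonzero iff some
reaction with net stoichiometry on species i depends structurally on
species j (substrate or modifier), or i = j carries an outflow. The
system is solved by least squares; ridge > 0 adds Tikhonov
regularization, ridge = 0 returns the minimum-norm solution when rank
deficient (strict mode raises instead). The estimate is never forced
stable: an unstable reconstruction from noisy covariance is a
diagnostic the user should see.

Identifiability. Entry count ≤ n(n+1)/2 is necessary but not
sufficient: if the pattern decomposes into decoupled diagonal blocks,
the cross-block covariances vanish and the cross-block equations
degenerate to 0 = 0, so e.g. an isolated full 2×2 block (4 unknowns, 3
informative equations) cannot be recovered. The property tests
therefore draw irreducible patterns (diagonal + coupling chain + random
extras up to the count cap), for which exact recovery held in 500/500
random instances at 1e-8. Real metabolic networks are connected through
shared intermediates, so the caveat rarely binds in practice, but the
`rank_deficient` flag reports it when it does.

## Uncertainty and differential analysis

Per-entry standard errors come from bootstrap resampling of a
condition's replicates (default B = 200; degenerate resamples with a
zero-variance metabolite are redrawn up to a cap). Between two
conditions, each shared pattern entry gets delta = value_b − value_a and
z = delta / sqrt(se_a² + se_b²) with a Gaussian reference. No
multiple-testing correction is applied across entries; the unit of
inference is the pathway aggregate: for each pathway tag, the mean |z|
over entries whose row species carries the tag (the row is the species
whose balance the entry perturbs). Rankings sort by |z| descending with
lexicographic (row id, col id) tie-break for determinism.

## The mannose_core fixture

Eight species, nine reactions: mannose inflow → Man; hexokinase
Man → M6P; reversible phosphomannose isomerase M6P ⇌ F6P;
phosphofructokinase F6P → FBP (glycolysis sink); reversible
phosphomannomutase M6P ⇌ M1P; GDP-mannose pyrophosphorylase
M1P → GDP-mannose (glycosylation sink); and a parallel glucose branch
Glc → G6P → F6P with its own inflow. GTP is not in the measured panel
and is folded into the GPP rate constant. Pathway tags: Man, M6P, M1P,
GDP-mannose → "glycosylation"; F6P, FBP, Glc, G6P → "glycolysis".

GPP carries a regulatory activation by M6P (a modifier), representing
metabolite-level regulation without consumption. This is also what
makes the fixture scientifically useful for differential analysis: a
purely first-order network has a concentration-independent Jacobian, so
no inflow perturbation could ever change it. With the bilinear GPP
term, raising the mannose inflow shifts C* and changes the Jacobian
entries in the M1P and GDP-mannose rows, giving the four-arm study a
ground-truth pathway signal.

Rate constants are order-one per-time fixture values (0.2–1.0) chosen
so all pools equilibrate on comparable timescales; none are measured.
The steady state at defaults is strictly positive with all eigenvalues
in [−1.8, −0.5].

## Synthetic study design

The default study has four arms differing only in the mannose inflow:
baseline ×1 (`WT+SD`), elevated ×3 (`AD+SD`), restricted ×0.5
(`AD+NMD`), re-supplemented ×2 (`AD+NMD+M`). These multipliers are
fixture choices — no kinetic parameters exist to calibrate against —
but they reproduce the qualitative contrast the analysis is meant to
detect: the glycosylation-branch pools (M6P, F6P, FBP, M1P) rise under
elevated mannose, fall under restriction, and rise again on
re-supplementation.

Simulation defaults: Euler–Maruyama step 0.05 time units; 400 burn-in
steps; retained samples spaced 150 steps (7.5 time units, several
relaxation times, so consecutive replicates are effectively
decorrelated); 12 replicates per arm, matching common rodent-study
group sizes; noise_sd 0.15, putting stationary biological fluctuations
at roughly 5–15 % of the steady-state pools while keeping zero-clipping
rare (negative excursions are clipped to zero, counted, and warned
about above 1 % of visited states — the restricted-mannose arm, with
its small GDP-mannose pool, occasionally grazes this threshold);
multiplicative log-normal measurement noise with CV 5 %, the typical
technical variability of targeted MS panels (set it to 0 for theory
tests). Measurement noise has unit mean, so condition means are
unbiased; it inflates covariance diagonals slightly, which is one
reason the Jacobian-inference branch prefers raw covariance from
well-replicated conditions.

What the simulator does not emulate: batch/drift structure and QC
injections, missing values below quantification limits (the reader
imputes half-minimum when given such data, but the simulator never
produces it), heavy-tailed or correlated measurement error, and slow
regulation (transcriptional adaptation) that would violate the
steady-state assumption. Passing tests therefore show the inference is
correct *given* the fluctuation–dissipation regime, not that real
tissue data satisfy that regime.

Replicate counts matter: with n = 200 replicates per arm the pathway
contrast is reliably detected, while at realistic animal-study sizes
(n ≈ 12–20) the covariance estimate is too noisy for stable Jacobian
contrasts even though the multivariate screen still separates the arms
cleanly. The acceptance checks use 200–500 replicates accordingly, and
the package reports bootstrap SEs precisely so that underpowered
reconstructions are visibly uncertain.

## Preprocessing

Pareto scaling divides each mean-centered column by the square root of
its sample standard deviation (n−1 denominator); constant columns are
centered only and flagged. It is the default on the multivariate
branch. The covariance for Jacobian inference defaults to raw
(unscaled) concentrations, because the Lyapunov relation links physical
fluctuations to the physical Jacobian; both choices are exposed in the
config. Missing values are imputed as half the column minimum (standard
for below-quantification values in targeted panels) with a report.
When a condition has fewer samples than metabolites, the covariance is
shrunk toward its diagonal with the analytic (Schäfer–Strimmer-style)
intensity, which is recorded on the model.

## OPLS-DA, VIP, permutation test, screening

OPLS-DA removes class-orthogonal variation (default one component,
NIPALS-style deflation) before fitting a single predictive component on
the dummy-coded response. R2Y is the explained response fraction; Q2 is
its cross-validated counterpart from stratified 7-fold CV (seeded; 7 is
the de facto standard of the commercial software lineage; folds are
reduced with a warning for small classes). Scaling is refit inside each
training fold so Q2 never leaks test information.

VIP uses the predictive component only — orthogonal components carry no
class information by construction — giving VIP_j = sqrt(p)·|w_j|/‖w‖,
whose squares average to exactly 1.

The permutation check refits the model under n = 200 random label
permutations and regresses R2Y and Q2 on the absolute label correlation
(anchored by the unpermuted model at correlation 1), evaluating the
lines at correlation 0. The validity flag requires (a) both intercepts
below the unpermuted R2Y and Q2 and (b) the permutation test on Q2 to
reject at α = 0.05, i.e. p = (#{permuted Q2 ≥ model Q2}+1)/(n+1) <
0.05. Condition (b) is needed for the flag to mean anything: for an
uninformative model the unpermuted fit is exchangeable with the
permuted refits, so the intercept comparison alone is a coin flip; with
(b) the flag is true on clearly separated synthetic data and false on
pure noise in ≥ 9/10 seeds.

Screening marks a metabolite differential iff VIP > 1.0 and p < 0.05,
with p from a two-tailed two-sample t test (two groups) or one-way
ANOVA (more groups; for two groups the two paths agree exactly via
F = t²) on the unscaled data. Fold change is log₂ of the group-mean
ratio (base configurable); a zero group mean is replaced by half the
smallest positive table value and flagged. No multiple-testing
correction by default, mirroring the stated rule; `fdr=True` adds a
Benjamini–Hochberg column. Cohen's d (mean difference / SD) is provided
for power bookkeeping.

## Pipeline determinism

The run seed is split via SeedSequence into independent substreams for
simulation, bootstrap, cross-validation and permutation, so stages can
be rerun independently with identical results; outputs are written with
fixed float formatting, making a rerun with the same config and seed
byte-identical. Every run writes a report JSON with the config hash,
package version, per-comparison summaries and accumulated warnings; any
stage failure is re-raised with the stage name and halts the run.

## Known limitations

- The Lyapunov inversion assumes a *linear* fluctuation regime; strongly
  nonlinear kinetics or large fluctuations bias the reconstruction.
- FLU is assumed diagonal. Correlated noise sources would require a
  full FLU, which the inverse problem cannot infer jointly with J.
- The estimate is condition-local: it cannot see regulation that only
  manifests on slower-than-sampling timescales.
- Reconstruction quality degrades quickly below ~100 replicates; the
  bootstrap SEs quantify, but do not remove, that limitation.
- Pathway scores aggregate by row tag only; an entry whose row and
  column straddle two pathways contributes only to its row's pathway.
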