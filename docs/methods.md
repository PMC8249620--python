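# Methods

## Model family

A gene is a continuous-time Markov chain on 2 or 3 activity states arranged
as a birth–death chain, with switching rates k₀₁, k₁₀, k₁₂, k₂₁ (s⁻¹),
state-dependent transcription rates α₀..α₂ (molecules·s⁻¹) and first-order
mRNA degradation with rate constant δ.  δ is treated as a first-order
constant (s⁻¹, propensity δ·x) throughout: a zeroth-order loss in
molecules·s⁻¹ cannot reproduce the observed stationary behaviour.

The nuclear NF-κB signal is phenomenological:
s(t) = e^{−r₁t}(1 − e^{−r₂t}), with s(0) = 0, a single maximum at
t* = ln(1 + r₂/r₁)/r₂ and decay to zero.  Its amplitude is left
unnormalised (max < 1, arbitrary units).  Exactly one switching edge per
gene is signal-modulated:

- **enhance**: k(t) = k + b·s(t), b in s⁻¹;
- **suppress**: k(t) = k / (1 + b·s(t)), b dimensionless.

The saturating suppress form is the default because it is positive for any
b ≥ 0 and reduces to the basal rate at s = 0; the clipped-linear alternative
k·max(0, 1 − b·s) is available via `suppress_form="linear"`.  With the
packaged CM2 values (b₁₀ = 6.60, s* ≈ 0.107) both forms are well behaved.

C/EBP is not modelled as a dynamic species: it exerts a constant influence
on G₀→G₁ and is absorbed into k₀₁.  Consequently U0126 (which blocks C/EBP)
acts by substituting k₀₁ → k₀₁^U0126 in every phase of the experiment, and
MG132 (which blocks NF-κB signalling) substitutes b → b^MG.  The combined
condition applies both substitutions; the sets are disjoint, so order is
irrelevant.  Six single-gene mechanisms are screened: 2-state with
enhanced G₀→G₁ or suppressed G₁→G₀, and 3-state with enhanced G₀→G₁ or
G₁→G₂, or suppressed G₁→G₀ or G₂→G₁.  The exact mechanism set follows the
two activation modes (faster activation, slower deactivation) applied to
each eligible chain edge; a two-gene model is any pair of mechanisms with a
shared signal (3 kept per gene → 9 combinations; all 6 → 36).

## FSP solution

The state space is (gene state) × (mRNA count 0..max_count), dimension
n·(M+1).  Reactions: switching, transcription (x → x+1), degradation
(x → x−1).  Transcription flux leaving x = M enters a single absorbing sink
state, so total probability is conserved exactly and the sink mass is a
running certificate of truncation error.  If the final sink mass exceeds
the requested tolerance (default 10⁻⁴), M is doubled and the solve
restarted, up to a ceiling (default 8192).  The default M = 1500 suits the
full-scale models (means up to ~325 with long tails).

Because exactly one edge is time-varying, the generator splits as
A(t) = A₀ + g(t)·E with constant sparse A₀, E.  The linear ODE is
integrated by an adaptive Dormand–Prince RK45 kernel (compiled with numba,
CSR matvecs, default rtol 10⁻⁸ / atol 10⁻¹², no freezing of A(t)).  The
kernel is cross-checked in the tests against dense Kolmogorov integration
with SciPy's LSODA on independently assembled matrices (agreement to total
variation ≤ 10⁻⁶) and against the closed-form immigration–death law.

**Initial condition.** Every condition starts from the signal-free (s ≡ 0)
stationary distribution computed with that condition's substituted
constants, i.e. cells have equilibrated under inhibitor pre-treatment
before stimulation.  This is deterministic and matches the pre-treatment
protocol; passing `init=` overrides it (e.g. the drug-free stationary law).
The stationary law is obtained by a sparse solve of A·p = 0 on the
reflecting truncated space.

## Exact simulation

The time-inhomogeneous chain is sampled exactly by thinning: between
events all propensities are constant except the signal edge, whose future
supremum is closed-form (k + b·s(t*) before the peak and the current value
after it in enhance mode; the basal k in suppress mode), so candidate
events drawn against that bound and accepted with ratio probability
reproduce the exact law — no discretisation error, no per-interval
recomputation needed.  Initial states are drawn from the same stationary
law the FSP solver uses.  Synthetic datasets replicate the study design:
four conditions × five times (0, 30, 60, 120, 240 min) × four i.i.d.
replicates (the study pools replicates and reports no replicate variance
model) × 500 cells per replicate by default (the study reports "hundreds to
thousands" per condition without exact counts).  Cells at different
measurement times are independent, as smFISH is destructive.  Counting is
treated as exact (no detection-efficiency parameter).  All sub-seeds derive
from one design seed via `numpy.random.SeedSequence`, making tables
bit-for-bit reproducible.

What the generator does *not* emulate: segmentation/spot-detection error,
replicate-level batch effects, cell-cycle or cell-size covariates, and any
gene–gene dependence beyond the shared signal.  Passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to these real-data effects.

## Likelihood and fitting

For each (gene, condition, time), the sample contributes
n · Σₓ p̂(x)·ln q(x), where p̂ is the empirical histogram and q the FSP
marginal with the sink mass assigned to the top bin; counts above the
truncation are censored into the top bin on both sides.  Weighting each
KL term by its cell count makes the objective exactly the multinomial
log-likelihood, so the two formulations differ only by the data entropy
(asserted numerically in the tests).  q is floored at 10⁻¹² so isolated
counts in zero-probability regions cannot produce infinite objectives.

Free parameters (all rates, signal coefficients, r₁, r₂ and inhibitor
substitutions — any subset selectable) are optimised in log₁₀ space with
bounds 10⁻⁷..10 by multistart Nelder–Mead (default 20 starts: the template
values plus log-uniform perturbations, default ±0.5 decades; every start's
endpoint is recorded).  r₁ and r₂ are shared across genes and conditions;
substitutions are shared across time points.  The held-out combined
condition is excluded from training by construction and refusing it is
enforced in both the estimator and the CLI.

BIC uses n_obs = total number of (cell, gene) observations across the
training samples; k = number of free parameters.  Model ranking sorts by
training + held-out log-likelihood, breaking ties by lower BIC and then
name.  The default pipeline screens the six mechanisms per gene on the
drug-free data by BIC, keeps the top three, and fits the nine combinations
jointly; `--full-screen` fits all 36.

## Problem sizes used in the validation suite

Repeated FSP solves inside an optimiser are the cost driver, so the
recovery experiments run on *count-scaled* variants of the packaged models:
all αᵢ divided by 20, switching kinetics, signal and δ unchanged.  This
shrinks copy numbers (and the FSP dimension ~25-fold) while leaving the
gene-state dynamics, time scales and every kinetic ratio identical.

- FSP–SSA equivalence: full-scale CM1 TNF-α, 10,000 cells at each of the
  five design times.  TV is compared on 20 equal-model-mass bins because
  the raw unit-bin TV of a 10⁴-cell histogram against a distribution
  spread over hundreds of support points has an irreducible multinomial
  sampling floor of ~0.08–0.09 (measured by resampling from the FSP
  marginal itself) — larger than any implementation signal.  The suite
  additionally asserts that the raw TV is within 30% of that resampled
  sampling-only expectation, a stricter equivalence certificate.
- Parameter recovery: single-gene 3-state (IL-1β mechanism), 2,000 cells
  per (condition, time) across the three training conditions; 11 free
  parameters started from truth perturbed by up to ±0.2 decades; two
  starts, 1,200 objective evaluations each.  Recovery thresholds: δ and α₂
  within 25%.
- Selection recovery: ten seeded datasets (300 cells per condition and
  time, all four conditions); the generating enhanced-G₁→G₂ mechanism
  competes against the suppressed-G₂→G₁ variant with identical shared
  components and balanced generic starting values.  Because the TNF-α
  component is the same in both candidate pairs, it cancels from the
  combined-score comparison and only the differing gene is fitted.

## Known limitations

- Joint FSP of both genes in one state space is out of scope (the shared
  signal makes the genes conditionally, not marginally, independent; a
  correlated treatment would require the product space).
- No identifiability analysis beyond the recovery tests; several
  parameters (e.g. α₀, α₁ when far below α₂, or substitutions pinned near
  bounds) are weakly informed by count histograms.
- The optimiser is a local multistart search; with few starts on rugged
  likelihoods it returns the best local optimum found, not a certified
  global one.
- Krylov/exponential integrators are not used; very stiff parameter
  corners fall back on small RK45 steps.
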