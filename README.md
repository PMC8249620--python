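# fspburst

Signal-activated stochastic bursting models of gene expression, fitted to
single-cell mRNA count data by Finite State Projection (FSP) of the chemical
master equation.

The package is built around the transcriptional response of the inflammatory
cytokines IL-1β and TNF-α in THP-1 monocytes after LPS stimulation, measured
by smFISH as exact mRNA copy numbers per cell under four inhibitor conditions
(no drug, MG132, U0126, both).  It is aimed at quantitative biologists who
want to screen mechanistic bursting models against count distributions and
predict drug-combination effects from single-drug calibrations.

## Model

Each gene switches among 2 or 3 discrete activity states on a birth–death
chain G₀ ⇌ G₁ ⇌ G₂, transcribes mRNA at a state-dependent rate αᵢ, and
degrades mRNA with first-order rate constant δ.  A shared nuclear NF-κB
signal

    s(t) = e^{−r₁ t}(1 − e^{−r₂ t})

modulates exactly one switching edge per gene, either additively
(k → k + b·s(t)) or by repression (k → k / (1 + b·s(t))).  Inhibitors act as
parameter substitutions: MG132 replaces the signal coefficient b by b^MG,
U0126 replaces the basal activation rate k₀₁ by k₀₁^U0126; the combined
condition applies both.  The two genes are conditionally independent given
the signal, so a two-gene "combinatorial" model is a pair of single-gene
models sharing one (r₁, r₂).

The probability vector over (gene state, mRNA count) obeys the chemical
master equation dp/dt = A(t) p(t).  It is solved by FSP: the count axis is
truncated, transcription flux leaving the boundary is routed into an
absorbing sink whose mass certifies the truncation error, and the space is
doubled automatically until the certificate meets tolerance.  Fitting
maximises the multinomial log-likelihood of the observed count histograms
(equivalently, minimises the cell-count-weighted sum of KL divergences from
the empirical to the model marginals) over log-transformed parameters, with
multistart Nelder–Mead.  Models are compared by training log-likelihood,
BIC = k·ln(n) − 2·logL, and the log-likelihood of the held-out combined
condition, predicted without refitting.

Two fitted parameter sets (models CM1 and CM2) ship as packaged configs:
in CM1, NF-κB enhances G₁→G₂ for IL-1β; in CM2 it suppresses G₁→G₀; TNF-α
uses the enhanced-G₀→G₁ mechanism in both.

## Worked example

```python
import numpy as np
from fspburst import load_model, solve_gene, moments, summarize

cm1 = load_model("cm1")
print(f"signal peak: {cm1.signal.peak_time/60:.2f} min")

times = np.array([0, 1800, 3600, 7200, 14400], dtype=float)
for cond in ("none", "mg132"):
    sol = solve_gene(cm1, "tnfa", cond, times)
    mean, sd = moments(sol)
    print(cond, np.round(mean, 1))

ratios = summarize(cm1)["genes"]["tnfa"]
print(f"k10/k01 = {ratios['k10_over_k01']:.1f}, "
      f"b01/b01_MG = {ratios['b_over_b_mg132']:.2f}")
```

prints

```
signal peak: 15.93 min
none [ 19.6 104.9 138.8  89.2  33.4]
mg132 [19.6 51.2 63.5 44.9 24.6]
k10/k01 = 386.0, b01/b01_MG = 2.91
```

The NF-κB signal peaks ~16 min after stimulation; the predicted mean TNF-α
copy number rises from its stationary value (~20) to a peak near 1 h and
decays by 4 h, and MG132 roughly halves the response.  The TNF-α gene is
strongly biased toward its silent state (deactivation ≈ 386× activation),
and MG132 weakens the NF-κB coupling about 2.9-fold.

A command-line pipeline (`fspburst simulate|fit|select|predict|report`)
orchestrates synthetic-data generation, fitting, model ranking,
combined-condition prediction and report tables from a single YAML config;
see `fspburst --help`.

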