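# markertime

Bayesian pseudotime inference from **small panels of marker genes** for
single-cell (and bulk) RNA-seq, with interpretable, parametric models of
gene behaviour.

## The problem

Most pseudotime methods are unsupervised: they reduce the whole
transcriptome to a low-dimensional embedding and order cells along it, then
check a handful of known marker genes afterwards to confirm the trajectory
makes biological sense.  `markertime` inverts this workflow.  If an
investigator already knows that, say, *NANOG* switches off and *CDX1* peaks
transiently during differentiation, those few genes carry enough signal to
infer the trajectory directly — and the fit is then *explained* by
interpretable quantities: when each gene switches on or off, when it peaks,
and how sharply.

## The model

For cells n = 1..N and marker genes g = 1..G, observed log-scale expression
y_ng (each gene rescaled so the mean of its positive values is 1) is modelled
as a one-dimensional nonlinear factor analysis with latent pseudotimes
t_n ∈ [0, 1):

* **switch-like genes**  μ_g(t) = 2η_g / (1 + exp(−k_g (t − t0_g))) — half-peak
  expression η_g, activation strength/direction k_g, switch time t0_g;
* **transient genes**  μ_g(t) = 2η_g exp(−λ b_g (t − p_g)²), λ = 10 — peak
  time p_g and bandwidth b_g;
* **noise**: a zero-inflated, dispersed Student-t law.  Dropout fires with
  probability π_ng = logit⁻¹(β0 + β1 μ_ng) and yields an exact zero;
  otherwise y_ng ~ T_ν(μ_ng, σ²_ng) with σ²_ng = (1 + φ) μ_ng + ε, ε = 0.01.

Inference targets the full joint posterior p(t, Θ | Y) via either an
adaptive Metropolis-within-Gibbs sampler (`fit_mcmc`, hand-derived
blockwise updates, exact in the long run) or stochastic-gradient
variational Bayes (`fit_vi`, mean-field Gaussian with analytic gradients,
fast and accurate for point estimates).  Built on the posterior draws:

* **regulation-order tests** — gene A is declared regulated before gene B
  when the 95% credible interval of t0_A − t0_B excludes 0;
* **metastable states** — discrete cell states along the continuous
  trajectory, found by clustering the first principal component of the
  cell-by-cell ordering-consistency matrix with a BIC-selected Gaussian
  mixture;
* **behaviour diagnostics** — a pre-fit check that the declared
  switch/transient split matches the panel's absolute-correlation structure;
* **a simulation module** reproducing the behaviour-misspecification
  robustness study.

## Worked example

```bash
python examples/01_fit_pseudotime.py
```

simulates a 60-cell, 6-gene panel (4 switch-like, 2 transient), fits it with
the variational backend and prints:

```
|Pearson r| between inferred and true pseudotimes: 0.826

Per-gene regulation times (posterior mean and 95% HPD):
  gene_00 (t0): 0.78  [0.72, 0.84]
  gene_01 (t0): 0.08  [0.04, 0.13]
  gene_02 (t0): 0.46  [0.36, 0.57]
  gene_03 (t0): 0.21  [0.16, 0.26]
  gene_04 (p): 0.49  [0.46, 0.52]
  gene_05 (p): 0.67  [0.64, 0.69]
```

The correlation says the latent ordering was recovered well despite ~25%
dropout and heavy-tailed noise; the regulation times order the genes along
the trajectory — gene_01 switches first and gene_00 last, with the two
transient genes peaking mid-trajectory.  The other scripts in `examples/`
demonstrate the pairwise regulation-order test, metastable-state detection,
the behaviour diagnostic, and the robustness study; a thin CLI
(`markertime simulate|fit|test|cluster|diagnose|robustness`) wraps the same
functions for shell pipelines, writing a reproducibility manifest per run.

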