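# pesnet — pooled-effect-size informed neural networks

Epidemiological datasets are small, noisy, and incompletely measured, and
purely data-driven neural networks trained on them happily learn
confounded or attenuated exposure–outcome relationships. What the field
*does* have in abundance is meta-analytic consensus: pooled effect sizes
(PES) — standardized regression coefficients (SRC), odds ratios (OR) and
risk ratios (RR) — summarizing an exposure's association with an outcome
across many studies.

`pesnet` trains feed-forward networks whose objective blends the usual
prediction loss with soft constraints derived from such effect sizes, and
provides the simulation scenarios and the Shapley-based fidelity metric
used to validate the approach. It is aimed at quantitative
epidemiologists and ML researchers studying informed learning on tabular
exposome-style data.

## The model

For inputs $X$ (n × p) and $q$ effect-size constraints with values
$v_i$, perturbation steps $h_i$ and weights $\lambda$:

$$\mathcal{L} = \lambda_0\,\mathcal{L}_{pred}(X,\theta) + \sum_{i=1}^{q} \lambda_i\,\mathcal{L}_{meta}(X,\theta,v_i,h_i)$$

Each constraint compares the model's response to a single-column
perturbation of the batch against the response a generalized linear model
with coefficient $v_i$ would show:

* **SRC** (linear scale, step $+h$): $\frac1n\sum_k \big(f_\theta(X_k^{x_i+h}) - v_i h_i - f_\theta(X_k)\big)^2$
* **OR** (probability scale, step $-h$): $\frac1n\sum_k \big(\sigma(\mathrm{logit}\,p_\theta(X_k^{x_i-h}) + v_i h_i) - p_\theta(X_k)\big)^2$
* **RR** (rate scale, step $+h$): $\frac1n\sum_k \big(e^{-v_i h_i} f_\theta(X_k^{x_i+h}) - f_\theta(X_k)\big)^2$

Each penalty is exactly zero when the model *is* the matching GLM, for
every step $h \ne 0$. Default steps are $h=1$ for SRCs and $1/v$
($-1/v$ for RRs) otherwise, keeping $v h$ of order one inside the
exponentials. Weights may be set by hand or derived from confidence
scores — meta-analysis sample sizes $c_i$, and $c_0 = n\times p$ for the
data term — via $\lambda_i = \ln c_i / \sum_j \ln c_j$.

Explanation fidelity is scored by comparing interventional Shapley
attributions of the trained network against those of the generative
(reference) function, estimated with *shared* sampling draws on the same
background set; the per-variable score is the mean absolute attribution
difference (lower = more faithful).

## Worked example

Noise (sd 0.75) is added to fish intake in the training and validation
splits of the linear scenario (mercury and fish intake correlated 0.8,
opposite true effects +1 / −2), and a single SRC prior (−2) is
integrated for fish intake alone:

```bash
$ python examples/03_noisy_confounder_recovery.py
   model    r2  dshap_fish_intake  dshap_mercury  dshap_stress  dshap_bmi
agnostic 0.973              1.048          0.875         0.187      0.432
informed 0.992              0.036          0.156         0.074      0.407
```

The agnostic network's fish-intake relationship is attenuated by the
measurement error (fidelity gap 1.05 in outcome units) and the bias
propagates to correlated mercury (0.88). The informed network recovers
the constrained fish-intake effect almost exactly (0.04) and — through
the correlation — mercury too (0.16), without a prior on mercury. The
uncorrelated variables (stress, BMI) are unaffected, and test R² does
not suffer.

The other scripts in `examples/` walk through the loss primitives, the
data-vs-literature tradeoff as a function of $\lambda_0$, the
missing-data comparison table, and the hidden-confounder design with a
duplicated exposure. A thin CLI wraps the experiment runner:

```bash
pesnet run exp1_logistic --replicates 10 --seed 1 --out runs/exp1
pesnet table1 runs/exp1
pesnet demo
```

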