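# genecircuits

Data-driven **gene circuit** modeling of the erythrocyte–neutrophil
cell-fate decision, for systems biologists who want to infer the genetic
architecture of a small gene regulatory network (GRN) from two-condition
expression time series — and then interrogate the fitted models:
simulate knockouts, knockdowns and overexpression, decompose each gene's
regulatory input over time, and validate the inferred activation order
in potential-ordered single-cell data.

## The model

A gene circuit describes the mRNA concentration $x_i^l(t)$ of gene $i$
in condition $l$ with coupled ODEs

$$\frac{dx_i^l}{dt} = R_i\, S\!\Big(\sum_{j=1}^{N} T_{ij} x_j^l + b_i c^l + h_i\Big) - \lambda_i x_i^l ,
\qquad S(u) = \tfrac12\Big(\frac{u}{\sqrt{u^2+1}} + 1\Big),$$

where $T_{ij}$ is the genetic interconnectivity (positive = activation,
negative = repression of target $i$ by regulator $j$), $b_i$ couples the
gene to condition-specific cytokine signaling through the condition code
$c^l \in \{-1, 0, +1\}$ (neutrophil, progenitor, erythrocyte), $h_i$ is
a threshold, $R_i$ the maximum synthesis rate, and $\lambda_i$ the mRNA
degradation rate. All $N^2 + 4N$ parameters are inferred by seeded
stochastic global optimization (adaptive simulated annealing plus a
bounded least-squares polish) of the penalized least-squares cost

$$E = \sum_{i,m,l} \big(x_i^l(t_m) - \hat x_i^l(t_m)\big)^2 + \text{Penalty},$$

with a soft regularization cap on the magnitude of $T$, $b$ and $h$.
Fits are summarized by $\mathrm{RMS} = \sqrt{E/N_d}$ and ensembles keep
circuits with RMS < 0.06. Downstream analyses include:

* **significance** — chimeric null datasets that swap the two
  conditions' values at late time points for gene subsets, refit, and a
  Wilcoxon rank-sum comparison of RMS distributions;
* **perturbation** — knockout ($R_i = x_i(0) = 0$), knockdown ($R_i$
  calibrated to an observed fold change), and activity overexpression (a
  bias $B_i = T_{i\leftarrow g}\,\beta$ added to every regulatory input);
* **regulation dynamics** — exact additive decomposition of each gene's
  total regulatory input into per-regulator contributions
  $T_{ij} x_j(t)$, half-max activation times (first zero-crossing of
  $u$), quartile-rule edge classification over ensembles, and
  time-evolving GRN export;
* **lineage ordering** — equal-count potential binning of fate-selected
  single cells with Welch one-sided tests of peak order.

A seeded synthetic-data generator emulates the two-lineage study design
(12 genes, 30 time points over 0–168 h with 2-hourly early sampling, two
antagonistic modules, 3 replicates with multiplicative noise, per-gene
dynamic ranges from a few-fold to >100-fold), so every stage can be
exercised against a known ground truth.

## Worked example

```python
import numpy as np
import genecircuits as gc
from genecircuits.dynamics import (classify_edges, select_representative,
                                   decompose, half_max_ordering)

# 1. a seeded 4-gene two-module circuit and its noiseless dataset
spec = gc.SynthesisSpec(n_genes=4, seed=0, noise_cv=0.0)
truth, data = gc.make_synthetic_dataset(spec)
print(gc.count_datapoints(data), gc.count_free_parameters(data.n_genes))
# -> 240 data points, 32 free parameters

# 2. fit an ensemble of gene circuits
config = gc.FitConfig(n_steps=1500, polish_max_nfev=150)
ensemble = gc.fit_ensemble(data, config, n_fits=5, base_seed=0)
print(np.round(ensemble.rms_values(), 4))
# -> [0.0208 0.3964 0.0132 0.018  0.0048]   (4 of 5 below the 0.06 bar)

# 3. ensemble edge classification and representative model
edges = classify_edges(ensemble.selected)
print(edges[edges.label != "unconstrained"].head(4))
#  target regulator      q1  median      q3      label
# gene_01   gene_01  0.0046  0.0563  0.1130 activation
# gene_01   gene_02  0.4177  0.4564  0.5207 activation
# gene_01   gene_03 -0.7357 -0.6657 -0.5808 repression
# gene_01   gene_04 -0.8070 -0.7360 -0.7287 repression
rep = ensemble.selected[select_representative(gc.Ensemble(ensemble.selected))]

# 4. order gene activation during neutrophil differentiation
traj = gc.simulate(rep.params, data.x0, gc.Condition.NEUTROPHIL, data.times)
print(half_max_ordering(decompose(rep.params, traj)))
#     gene  half_max_time_h
#  gene_04        21.276086
#  gene_01              NaN   (input never crosses zero: the gene stays
#  gene_02              NaN    repressed in this condition)
#  gene_03              NaN
```

The quartile rule reads an edge as activation when the first quartile of
its ensemble distribution is positive and repression when the third
quartile is negative; here the fits recover the ground truth's
within-module activation and cross-module repression. The half-max time
is when a gene's total regulatory input crosses zero, i.e. when it is
synthesized at half its maximum rate — the marker used to order gene
activation during differentiation.

The same workflow is available from the shell via the `genecircuits`
CLI (`simulate-data`, `fit`, `swap`, `significance`, `perturb`,
`decompose`, `grn-export`, `order-cells`).

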