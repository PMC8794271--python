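# Methods

## Model and assumptions

The dynamical core is a deterministic mRNA-level gene circuit: each
gene's synthesis rate is its maximum rate $R_i$ scaled by the sigmoid
$S(u) = \tfrac12(u/\sqrt{u^2+1}+1)$ of the total regulatory input
$u_i = \sum_j T_{ij} x_j + b_i c^l + h_i$, opposed by first-order decay
$\lambda_i x_i$. The model coarse-grains biochemistry deliberately: an
interconnection $T_{ij}$ may stand for direct or indirect regulation,
there is no protein/mRNA distinction, no delays, no higher-order
(complex-mediated) terms, and no stochasticity. Cytokine conditions act
only through the signed code $c^l$ (−1 neutrophil, 0 progenitor/self-
renewal, +1 erythrocyte), so condition effects on each gene are
symmetric about the progenitor state by construction.

Concentrations are relative expression: the training convention
normalizes each gene by the maximum of its mean expression over all
conditions and time points, so data lie in [0, 1] and parameters are in
those units. Model trajectories start from the progenitor state (the
t = 0 mean, shared between conditions).

## Integration and equilibria

Systems are integrated with LSODA (adaptive step, automatic stiff/
non-stiff switching) at relative tolerance 1e-3 — the package's working
accuracy for fitting and reporting — with an absolute floor of 1e-6;
the tolerance is an argument everywhere for oracle tests that need
tighter solutions. The interpretation of the accuracy as relative with
an absolute floor is a package choice. Equilibria use the fixed-horizon
protocol (1000 h of relaxation); afterwards the derivative norm is
checked (default 1e-6/h) and a warning, not an error, is raised if the
state is still drifting, since the horizon itself is the protocol.
Solver undershoot below zero is never clipped in memory, only in
exported tables.

## Cost, penalty, and fit selection

The cost is the sum over genes, conditions and time points of squared
deviations between model output and the replicate **means** (replicate
standard deviations are carried for reporting only), plus the penalty
$\exp(\Pi) - e$ applied when
$\Pi = \sum_i \Lambda_i(\sum_j (T_{ij}\hat x_j^{max})^2 + (b_i c^{max})^2 + h_i^2)$
exceeds 1. $\Lambda_i$ defaults to 0.1 with per-gene overrides (0.01
for a wide-dynamic-range gene, letting its regulatory parameters grow
large enough to span two orders of magnitude of expression). The
middle penalty term uses $(b_i c^{max})^2$ — the form that actually
constrains the external-signal coefficients; a config switch
(`penalty_scaled_b=False`) selects the parameter-free literal variant
$(c^{max})^2$ instead. Goodness of fit is
$\mathrm{RMS} = \sqrt{\text{residual}/N_d}$, computed from the residual
term only (for selected fits the penalty is expected to vanish, and an
"average error in expression" reading is only meaningful for
residuals); `rms_from_cost=True` switches to the literal total cost.
Ensembles select fits with RMS strictly below 0.06.

## Optimization

Each fit is a seeded run of a coordinate-wise Metropolis annealer with
an acceptance-targeted adaptive schedule: per-parameter proposal scales
are adapted each batch toward the classic 0.44 acceptance target while
the temperature follows a geometric profile from an automatically
probed starting value down to a fixed fraction (1e-4) of it. The
annealed candidate is then polished by bounded trust-region least
squares on the residual vector extended with $\sqrt{\text{penalty}}$,
so the polish minimizes the same penalized cost; the polish integrates
at rtol 1e-5 (finite-difference Jacobians need smoother cost surfaces
than the 1e-3 working tolerance provides) with relative steps of 1e-4.
The better of the annealed and polished candidates is returned. The
annealer is pluggable by design — the contract is determinism under a
seed and global stochastic search, not a specific schedule, because
recovery quality is what the acceptance suite checks. Default bounds:
$T, b, h \in [-30, 30]$, $R \in (0, 50]$, half-lives 0.5–500 h; initial
points are sampled well inside the bounds ($|T|,|b|,|h| \le 1.5$).

Default budgets (4000 annealing moves, 300 polish iterations) fit a
4-gene circuit in ~20–30 s on one CPU; the test suite uses reduced
budgets (1500 moves, 150 iterations) chosen as the package's desk-scale
setting. Ensemble seeds are spawned from a master seed via
`SeedSequence` and kept below 2^31.

## Synthetic study design

The generator emulates the training design: two differentiation
conditions plus a shared progenitor state, 30 sampling times over
0–168 h (2-hourly through the first day — the published grid's exact
late-phase times are not recoverable from its inconsistent ellipsis, so
the late grid 30–96 h 6-hourly then 108/120/132/144/168 h is a package
choice, configurable, with only the count, endpoints and early spacing
treated as normative), 3 replicates, and multiplicative lognormal noise
with mean 1 and CV 0.1 (microarray replicate error scales with
expression; reported error bars are sd over replicates).

Ground-truth circuits have two antagonistic lineage modules:
within-module activation (strength 0.25), cross-module repression
(0.45), autoactivation (0.5), opposite-signed condition coupling
(|b| ≈ 0.8) and negative thresholds (h ∈ [−1.3, −0.6]) that leave every
gene partially repressed in progenitors (lineage priming). Degradation
rates span half-lives of ~5–23 h and expression ceilings $R/\lambda$
are ~0.7–1.5 relative units, keeping dynamics on the normalized scale.
One wide-range gene (h and b ×5, $\Lambda$ = 0.01) mirrors a cytokine
receptor spanning >100-fold; one narrow gene (b ×0.22, h ×0.35) mirrors
a weakly responsive receptor (~4-fold). After drawing, T, b and h are
uniformly rescaled into the penalty budget ($\Pi \le 0.9$) so the truth
lies inside the unpenalized search region. These defaults were fixed
once, during generator construction, to reproduce the qualitative
study features: with them, all 12 genes diverge ≥2-fold between
conditions at 168 h and dynamic ranges span ~4–110-fold.

What the generator does **not** emulate: probe-level microarray error
structure, batch effects, the real network's dense empirically
validated wiring, cross-gene noise correlations, or population
heterogeneity. Passing recovery tests therefore demonstrates that the
inference machinery recovers circuits of this family under the study's
sampling design and noise scale — not that it would recover the true
biological network from real measurements.

The single-cell stand-in table is likewise synthetic: potentials are
uniform, fate probability rises logistically as potential falls, and
per-gene counts are Poisson around Gaussian bumps over potential, so
peak order is known by construction. Real potentials and fate
probabilities come from an external population-balance analysis and
are consumed as input, never computed.

## Numerical and procedural choices

* **Chimeric swapping** follows the branch "keep if t < cut, else
  swap": the cut time (default 96 h) itself is swapped. The swap is an
  involution and cannot change per-gene maxima, so chimeric data remain
  normalized.
* **Rank-sum comparison** uses the asymptotic Mann–Whitney U with
  continuity correction and midrank ties; identical constant samples
  short-circuit to p = 1 with a log message.
* **Calibration** of knockdown (on $R \in [0, R_0]$) and overexpression
  (on $\beta \in [0, \beta_{max}]$) uses bracketing root finding on the
  equilibrium fold change; an unreachable request raises an error
  reporting the achievable range. Bracketing assumes the empirically
  monotone response; under multistability the bracketed solver still
  returns *a* matching value. Knockdown/overexpression equilibria use
  c = 0 and 1000 h; knockouts are simulated as full differentiation
  time courses in each condition, and both endpoint and trajectory
  comparisons are available since the perturbed-trajectory distance
  measure is not uniquely fixed.
* **Quartiles** for edge classification use linear interpolation
  between order statistics (numpy's default, the "type 7" convention),
  fixed so labels are deterministic; the same interquartile rule is
  applied to the external-signal coefficients.
* **Representative-model selection** scores each model by the number of
  interconnectivity signs matching the ensemble majority; parameters
  with an exact 50/50 sign split are excluded from every score, and
  residual score ties break by lowest RMS then lowest index.
* **Half-max times** report the first zero-crossing of the total input
  (linear interpolation between samples; an exactly-zero sample reports
  its own time); all crossings are retained on the decomposition.
* **Binning** sorts by decreasing potential and assigns remainder cells
  to the earliest (highest-potential) bins; Welch tests run on per-cell
  values within bins, not on bin means, with Satterthwaite degrees of
  freedom; two constant equal bins return the one-sided convention
  p = 0.5. Both raw and normalized expression are accepted.

## Limitations

Fits are local-search products: individual restarts can land in poor
optima (visible as rejected ensemble members), and identifiability of
weak interconnections from two conditions is limited — only parameter
signs robust across the ensemble should be interpreted. The RMS bar,
penalty weights and bounds are inherited settings, sensible on the
normalized scale but not universal. The deterministic model cannot
speak to single-cell stochasticity or population structure; the
lineage-ordering stage depends entirely on the quality of the upstream
potential and fate-probability assignments it consumes.
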