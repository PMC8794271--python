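"""Synthetic ground-truth circuits and noisy datasets.

This module is the analysis's stand-in for the FDCP-mix microarray series:
it generates gene circuits with a known two-module antagonistic
architecture (an erythroid-like module and a neutrophil-like module with
within-module activation, cross-module repression, autoactivation, and
opposite-signed external-signal coupling), simulates differentiation time
courses in both conditions from a progenitor equilibrium, and adds
multiplicative replicate noise.  It also emits per-cell tables emulating
the structure of a potential-ordered single-cell validation dataset.

Everything is fully determined by the seed in the :class:`SynthesisSpec`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .dataio import ExpressionDataset, default_time_grid, normalize_dataset
from .model import (Condition, GeneCircuitParams, regulation_expression,
                    simulate, solve_equilibrium)

__all__ = [
    "SynthesisSpec",
    "make_ground_truth_circuit",
    "progenitor_state",
    "simulate_dataset",
    "make_synthetic_dataset",
    "make_cell_table",
]

#: The 12 modeled genes: lineage-specifying TFs plus cytokine receptors.
DEFAULT_GENES = ("Gata1", "Zfpm1", "Klf1", "Tal1", "Epor",
                 "Spi1", "Cebpa", "Gfi1", "Stat3", "Gata2", "Il3ra", "Csf3r")
#: Erythroid-module members of the default gene list.
DEFAULT_ERYTHROID_MODULE = ("Gata1", "Zfpm1", "Klf1", "Tal1", "Epor")


@dataclass
class SynthesisSpec:
    """Recipe for a seeded two-module ground-truth circuit and dataset.

    The defaults emulate the training-study design: 12 genes, 30 time
    points over 0-168 h (2-hourly during the first day), two
    differentiation conditions plus a progenitor state, 3 replicates with
    multiplicative measurement noise, and either-or divergent lineage
    expression driven by opposite-signed external-signal coupling.
    """

    n_genes: int = 12
    gene_names: Optional[Sequence[str]] = None
    #: indices of the erythroid-like module; remaining genes form the
    #: neutrophil-like module.  None -> default split (first half for
    #: generic circuits; the named erythroid genes for the 12-gene default).
    module_a: Optional[Sequence[int]] = None
    within_strength: float = 0.25
    cross_strength: float = 0.45
    auto_strength: float = 0.5
    b_strength: float = 0.8
    h_range: tuple = (-1.3, -0.6)
    #: degradation rates (1/h; half-lives ~5-23 h) and expression ceilings
    #: R/lam in relative units; synthesis rates are R = ceiling * lam.
    lam_range: tuple = (0.03, 0.15)
    ceiling_range: tuple = (0.7, 1.5)
    #: gene name given a wide dynamic range (stronger h/b swing); mirrors a
    #: receptor whose expression spans ~2 orders of magnitude.
    wide_gene: Optional[str] = "auto"
    wide_boost: float = 5.0
    #: gene with damped condition coupling (a ~2-4x dynamic-range gene).
    narrow_gene: Optional[str] = "auto"
    narrow_b_factor: float = 0.22
    narrow_h_factor: float = 0.35
    #: regularization budget the circuit is rescaled into (see
    #: :func:`make_ground_truth_circuit`).
    pi_target: float = 0.9
    Lambda: float = 0.1
    wide_Lambda: float = 0.01
    noise_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0
    times: Optional[np.ndarray] = None

    def resolved_genes(self) -> tuple:
        if self.gene_names is not None:
            names = tuple(str(g) for g in self.gene_names)
            if len(names) != self.n_genes:
                raise ConfigurationError("gene_names length != n_genes")
            return names
        if self.n_genes == 12:
            return DEFAULT_GENES
        return tuple(f"gene_{i + 1:02d}" for i in range(self.n_genes))

    def resolved_modules(self) -> tuple:
        genes = self.resolved_genes()
        if self.module_a is not None:
            a = tuple(int(i) for i in self.module_a)
        elif genes == DEFAULT_GENES:
            a = tuple(genes.index(g) for g in DEFAULT_ERYTHROID_MODULE)
        else:
            a = tuple(range(self.n_genes // 2))
        b = tuple(i for i in range(self.n_genes) if i not in a)
        if not a or not b:
            raise ConfigurationError("both lineage modules must be non-empty")
        return a, b

    def resolved_wide_gene(self) -> Optional[str]:
        if self.wide_gene == "auto":
            return "Csf3r" if self.resolved_genes() == DEFAULT_GENES else None
        return self.wide_gene

    def resolved_narrow_gene(self) -> Optional[str]:
        if self.narrow_gene == "auto":
            return "Il3ra" if self.resolved_genes() == DEFAULT_GENES else None
        return self.narrow_gene

    def lambda_vector(self) -> np.ndarray:
        genes = self.resolved_genes()
        lam = np.full(len(genes), self.Lambda)
        wide = self.resolved_wide_gene()
        if wide is not None:
            lam[genes.index(wide)] = self.wide_Lambda
        return lam


def _penalty_pi(T, b, h, Lambda, xhat_max, c_max=1.0):
    return float(np.sum(Lambda * (np.sum((T * xhat_max) ** 2, axis=1)
                                  + (b * c_max) ** 2 + h ** 2)))


def make_ground_truth_circuit(spec: SynthesisSpec) -> GeneCircuitParams:
    """Draw a seeded two-module antagonistic circuit.

    Within-module interconnections are non-negative, cross-module
    interconnections non-positive, the diagonal (autoregulation)
    non-negative, and the external-signal coefficients ``b`` are positive
    for the erythroid-like module and negative for the neutrophil-like
    module, so that the condition code pulls the two modules apart.
    Thresholds are negative, leaving every gene partially repressed in the
    progenitor state (lineage priming).

    After drawing, ``T``, ``b`` and ``h`` are uniformly rescaled (if
    needed) so that the regularization functional the inference stage
    penalizes stays below ``spec.pi_target`` — the ground truth then lives
    inside the region the fitting procedure searches without penalty.
    """
    if spec.n_genes < 2:
        raise ConfigurationError("need at least 2 genes for two modules")
    genes = spec.resolved_genes()
    mod_a, mod_b = spec.resolved_modules()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes

    module = np.zeros(n, dtype=int)
    module[list(mod_b)] = 1
    same = module[:, None] == module[None, :]
    mag = rng.uniform(0.5, 1.0, size=(n, n))
    T = np.where(same, spec.within_strength, -spec.cross_strength) * mag
    np.fill_diagonal(T, spec.auto_strength * rng.uniform(0.75, 1.25, size=n))
    b = np.where(module == 0, 1.0, -1.0) * spec.b_strength \
        * rng.uniform(0.8, 1.2, size=n)
    h = rng.uniform(*spec.h_range, size=n)
    lam = rng.uniform(*spec.lam_range, size=n)
    R = rng.uniform(*spec.ceiling_range, size=n) * lam

    wide = spec.resolved_wide_gene()
    if wide is not None:
        i = genes.index(wide)
        h[i] *= spec.wide_boost
        b[i] *= spec.wide_boost
    narrow = spec.resolved_narrow_gene()
    if narrow is not None:
        i = genes.index(narrow)
        b[i] *= spec.narrow_b_factor
        h[i] *= spec.narrow_h_factor

    pi = _penalty_pi(T, b, h, spec.lambda_vector(), xhat_max=1.0)
    if pi > spec.pi_target:
        s = np.sqrt(spec.pi_target / pi)
        T, b, h = T * s, b * s, h * s
    return GeneCircuitParams(genes, T, b, h, R, lam)


def progenitor_state(params: GeneCircuitParams,
                     horizon_hours: float = 1000.0) -> np.ndarray:
    """Progenitor initial state: circuit equilibrium at condition code 0.

    Started from the decoupled-gene guess ``R * S(h) / lam`` and relaxed
    for ``horizon_hours``.
    """
    guess = params.R * regulation_expression(params.h) / params.lam
    return solve_equilibrium(params, guess, Condition.PROGENITOR,
                             horizon_hours=horizon_hours, deriv_tol=1e-5)


def simulate_dataset(params: GeneCircuitParams, x0=None, times=None,
                     noise_cv: float = 0.1, n_replicates: int = 3,
                     seed: int = 0,
                     conditions=(Condition.ERYTHROCYTE,
                                 Condition.NEUTROPHIL)) -> ExpressionDataset:
    """Simulate a replicate dataset from a circuit and normalize it.

    Replicate values are the simulated trajectory multiplied by i.i.d.
    lognormal factors with mean 1 and coefficient of variation
    ``noise_cv`` (microarray replicate error scales with expression), then
    max-normalized per gene as in the training-data convention.  With
    ``noise_cv=0`` the replicates equal the trajectory exactly.  Fixed
    seeds give bit-identical datasets.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if times is None:
        times = default_time_grid()
    times = np.asarray(times, dtype=float)
    if x0 is None:
        x0 = progenitor_state(params)
    conditions = tuple(
        c if isinstance(c, Condition) else Condition.from_label(c)
        for c in conditions)
    traj = np.stack([
        simulate(params, x0, cond, times).values for cond in conditions
    ])  # (C, G, T)
    clean = np.clip(np.moveaxis(traj, 0, 1), 0.0, None)  # (G, C, T)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        mu = -sigma ** 2 / 2.0  # mean-1 multiplicative factors
        factors = rng.lognormal(mu, sigma,
                                size=clean.shape + (n_replicates,))
        replicates = clean[..., None] * factors
    else:
        replicates = np.repeat(clean[..., None], n_replicates, axis=3)
    raw = ExpressionDataset.from_replicates(params.gene_names, conditions,
                                            times, replicates)
    return normalize_dataset(raw)


def make_synthetic_dataset(spec: SynthesisSpec):
    """Convenience: ground-truth circuit plus its simulated dataset.

    Returns ``(params, dataset)``; the dataset noise/replicates/grid come
    from the spec and the whole product is determined by ``spec.seed``.
    """
    params = make_ground_truth_circuit(spec)
    times = spec.times if spec.times is not None else default_time_grid()
    dataset = simulate_dataset(params, times=times, noise_cv=spec.noise_cv,
                               n_replicates=spec.n_replicates,
                               seed=spec.seed + 1)
    return params, dataset


# ---------------------------------------------------------------------------
# Synthetic per-cell table for the lineage-ordering stage
# ---------------------------------------------------------------------------

def make_cell_table(n_cells: int = 1551, lineage: str = "neutrophil",
                    gene_peaks: Optional[dict] = None,
                    peak_width: float = 0.15, base_rate: float = 0.5,
                    amplitude: float = 20.0, seed: int = 0) -> pd.DataFrame:
    """Emulate a potential-ordered single-cell table (synthetic stand-in
    for a published scRNA-Seq fate-probability table; the real potentials
    and probabilities come from an external population-balance analysis
    and are consumed, never computed, by this package).

    Each cell gets a scalar potential (higher = earlier in development), a
    fate probability for ``lineage`` that rises as potential falls, and
    per-gene expression counts drawn from a Poisson law whose mean is a
    Gaussian bump over potential centred at the gene's ``gene_peaks``
    location (in units of potential).  Genes with higher peak positions
    therefore turn on earlier.

    Returns a long-format DataFrame with columns ``cell_id``,
    ``potential``, ``p_<lineage>``, and one column per gene.
    """
    if gene_peaks is None:
        # early / middle / late activation, mirroring an early TF pair
        # driving a late-rising master regulator
        gene_peaks = {"Cebpa": 0.75, "Gfi1": 0.55, "Spi1": 0.25}
    rng = np.random.default_rng(seed)
    potential = rng.uniform(0.0, 1.0, size=n_cells)
    # fate probability rises as the potential decreases
    prob = 1.0 / (1.0 + np.exp((potential - 0.6) / 0.12))
    prob = np.clip(prob + rng.normal(0.0, 0.02, size=n_cells), 0.0, 1.0)
    data = {
        "cell_id": [f"cell_{i + 1:05d}" for i in range(n_cells)],
        "potential": potential,
        f"p_{lineage}": prob,
    }
    for gene, peak in gene_peaks.items():
        mean = base_rate + amplitude * np.exp(
            -0.5 * ((potential - peak) / peak_width) ** 2)
        data[gene] = rng.poisson(mean).astype(float)
    return pd.DataFrame(data)
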