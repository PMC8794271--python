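"""Fit-significance testing against chimeric (condition-swapped) data.

To check that good fits reflect temporal structure in the data rather
than an excess of degrees of freedom, the training data are randomized in
a way that preserves each gene's dynamic range but destroys its
biological temporal pattern: for a chosen subset of genes, the
erythrocyte and neutrophil expression values are exchanged at late time
points (t >= 96 h by default), creating chimeric "either-then-other"
trajectories.  One chimeric dataset is built per combination of swapped
genes (C(12, 10) = 66 for the full design), several circuits are fitted
to each, and the RMS scores of chimeric fits are compared with those of
fits to the real data by a rank-sum test.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dataio import ExpressionDataset
from .exceptions import ConfigurationError
from .inference import Ensemble, FitConfig, ensemble_seeds, fit

logger = logging.getLogger(__name__)

__all__ = [
    "ChimericMember",
    "ChimericDatasetSet",
    "make_chimeric_datasets",
    "campaign_plan",
    "permuted_fit_campaign",
    "RmsComparison",
    "compare_rms",
]


@dataclass
class ChimericMember:
    """One chimeric dataset tagged with the swapped-gene combination."""

    swapped_genes: tuple
    dataset: ExpressionDataset


@dataclass
class ChimericDatasetSet:
    source: ExpressionDataset
    members: list
    t_cut: float

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def _swap_member(dataset: ExpressionDataset, combo: Sequence[int],
                 t_cut: float) -> ExpressionDataset:
    if dataset.n_conditions != 2:
        raise ConfigurationError("swapping requires exactly two conditions")
    late = dataset.times >= t_cut
    replicates = dataset.replicates.copy()
    idx = np.asarray(combo, dtype=int)
    block = replicates[np.ix_(idx, [0, 1], np.flatnonzero(late))]
    replicates[np.ix_(idx, [0, 1], np.flatnonzero(late))] = block[:, ::-1]
    return ExpressionDataset.from_replicates(
        dataset.gene_names, dataset.conditions, dataset.times, replicates)


def make_chimeric_datasets(dataset: ExpressionDataset, k_swapped: int = 10,
                           t_cut: float = 96.0) -> ChimericDatasetSet:
    """Build one chimeric dataset per combination of ``k_swapped`` genes.

    For swapped genes, values at times t < ``t_cut`` are kept and values
    at t >= ``t_cut`` are exchanged between the two conditions (so the
    cut time itself is swapped); the remaining genes carry the original
    data at every time point.  The per-gene maximum over the union of
    conditions — and hence the normalization — is unchanged by the swap.
    """
    if not (1 <= k_swapped <= dataset.n_genes):
        raise ConfigurationError(
            f"k_swapped must be in [1, {dataset.n_genes}]")
    if not (dataset.times.min() < t_cut <= dataset.times.max()):
        raise ConfigurationError(
            f"t_cut = {t_cut} outside the time grid "
            f"[{dataset.times.min()}, {dataset.times.max()}]")
    members = [
        ChimericMember(tuple(dataset.gene_names[i] for i in combo),
                       _swap_member(dataset, combo, t_cut))
        for combo in itertools.combinations(range(dataset.n_genes), k_swapped)
    ]
    return ChimericDatasetSet(dataset, members, t_cut)


def campaign_plan(chimeric_set: ChimericDatasetSet, fits_per_dataset: int,
                  base_seed: int = 0) -> list:
    """The (member, seed) schedule of a permuted-fit campaign.

    Total length = |chimeric set| x fits_per_dataset, with distinct,
    reproducible seeds.
    """
    if fits_per_dataset < 1:
        raise ConfigurationError("fits_per_dataset must be >= 1")
    seeds = ensemble_seeds(base_seed,
                           len(chimeric_set) * fits_per_dataset)
    plan = []
    k = 0
    for member in chimeric_set:
        for _ in range(fits_per_dataset):
            plan.append((member, seeds[k]))
            k += 1
    return plan


def permuted_fit_campaign(chimeric_set: ChimericDatasetSet,
                          config: Optional[FitConfig] = None,
                          fits_per_dataset: int = 10,
                          base_seed: int = 0) -> list:
    """Fit circuits to every chimeric dataset; returns one Ensemble per
    member, in member order."""
    config = config or FitConfig()
    plan = campaign_plan(chimeric_set, fits_per_dataset, base_seed)
    ensembles = []
    for i, member in enumerate(chimeric_set):
        chunk = plan[i * fits_per_dataset:(i + 1) * fits_per_dataset]
        fits = [fit(member.dataset, config, seed=s) for _, s in chunk]
        ensembles.append(Ensemble(fits, rms_threshold=config.rms_threshold))
    return ensembles


@dataclass
class RmsComparison:
    statistic: float
    pvalue: float
    median_real: float
    median_permuted: float
    alternative: str


def compare_rms(real_rms, permuted_rms,
                alternative: str = "two-sided") -> RmsComparison:
    """Rank-sum comparison of real-fit vs permuted-fit RMS distributions.

    Wilcoxon rank-sum (Mann-Whitney U) with continuity correction and
    midrank tie handling.  ``alternative`` follows the scipy convention
    for the first sample (the real fits); use "less" to test that real
    fits have smaller RMS than permuted fits.
    """
    real = np.asarray(real_rms, dtype=float)
    perm = np.asarray(permuted_rms, dtype=float)
    if real.size == 0 or perm.size == 0:
        raise ValueError("both RMS samples must be non-empty")
    med_r, med_p = float(np.median(real)), float(np.median(perm))
    pooled = np.concatenate([real, perm])
    if np.all(pooled == pooled[0]):
        logger.warning("degenerate rank-sum comparison: all values identical")
        u = real.size * perm.size / 2.0
        return RmsComparison(u, 1.0, med_r, med_p, alternative)
    res = stats.mannwhitneyu(real, perm, alternative=alternative,
                             use_continuity=True, method="asymptotic")
    return RmsComparison(float(res.statistic), float(res.pvalue),
                         med_r, med_p, alternative)
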