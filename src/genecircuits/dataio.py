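"""Expression datasets: container, normalization, and TSV round-trip.

An :class:`ExpressionDataset` holds replicate time-series measurements of
relative gene expression for one or two differentiation conditions plus the
shared progenitor initial state.  The study-design conventions are:

* expression is normalized per gene to its maximum *mean* expression across
  all conditions and time points (so the per-gene max of means is 1);
* the progenitor initial state ``x0`` is the mean expression at t = 0,
  which the conditions share;
* the default sampling grid has 30 points over 0-168 h, denser (2-hourly)
  during the first day.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import NormalizationError
from .model import Condition

__all__ = [
    "ExpressionDataset",
    "normalize_dataset",
    "default_time_grid",
    "read_dataset_tsv",
    "write_dataset_tsv",
]


def default_time_grid() -> np.ndarray:
    """30-point sampling grid over 0-168 h.

    2-hourly through the first day, 6-hourly through day 4, then sparser
    (12-24 h) to day 7.  The exact late-phase times are a package choice;
    the grid size (30), endpoints (0 and 168 h), and 2-h early spacing are
    treated as fixed by the study design.
    """
    grid = np.concatenate([
        np.arange(0.0, 25.0, 2.0),       # 13 points: 0, 2, ..., 24
        np.arange(30.0, 97.0, 6.0),      # 12 points: 30, 36, ..., 96
        np.array([108.0, 120.0, 132.0, 144.0, 168.0]),
    ])
    assert grid.size == 30
    return grid


@dataclass
class ExpressionDataset:
    """Replicate time-series expression measurements.

    Attributes
    ----------
    gene_names : tuple of str
    conditions : tuple of Condition
        The differentiation conditions present (usually erythrocyte and
        neutrophil).
    times : ndarray
        Strictly increasing sampling times in hours.
    replicates : ndarray, shape (n_genes, n_conditions, n_times, n_replicates)
    means, sds : ndarray, shape (n_genes, n_conditions, n_times)
        Mean and standard deviation (ddof=1) over replicates.
    x0 : ndarray, shape (n_genes,)
        Progenitor initial state: mean expression at the first time point,
        averaged over conditions.
    xhat_max : ndarray, shape (n_genes,)
        Per-gene maximum of mean expression over conditions and times
        (exactly 1 after normalization).
    """

    gene_names: tuple
    conditions: tuple
    times: np.ndarray
    replicates: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    x0: np.ndarray
    xhat_max: np.ndarray

    @classmethod
    def from_replicates(cls, gene_names, conditions, times, replicates):
        gene_names = tuple(str(g) for g in gene_names)
        conditions = tuple(
            c if isinstance(c, Condition) else Condition.from_label(c)
            for c in conditions)
        times = np.asarray(times, dtype=float)
        replicates = np.asarray(replicates, dtype=float)
        n_g, n_c, n_t = len(gene_names), len(conditions), times.size
        if replicates.ndim != 4 or replicates.shape[:3] != (n_g, n_c, n_t):
            raise ValueError(
                "replicates must be (n_genes, n_conditions, n_times, n_rep), "
                f"got {replicates.shape}")
        if replicates.shape[3] < 1:
            raise ValueError("at least one replicate is required")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(replicates < 0):
            raise ValueError("expression values must be >= 0")
        means = replicates.mean(axis=3)
        if replicates.shape[3] > 1:
            sds = replicates.std(axis=3, ddof=1)
        else:
            sds = np.zeros_like(means)
        x0 = means[:, :, 0].mean(axis=1)
        xhat_max = means.max(axis=(1, 2))
        return cls(gene_names, conditions, times, replicates, means, sds,
                   x0, xhat_max)

    # -- basic shape helpers -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    @property
    def n_replicates(self) -> int:
        return int(self.replicates.shape[3])

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.gene_names, self.conditions,
                                 self.times.copy(), self.replicates.copy(),
                                 self.means.copy(), self.sds.copy(),
                                 self.x0.copy(), self.xhat_max.copy())

    # -- long-format frame ---------------------------------------------------
    def to_frame(self, include_mean: bool = False) -> pd.DataFrame:
        """Long format: gene, condition, time_h, replicate, value.

        With ``include_mean=True`` a "mean" pseudo-replicate row set is
        appended for each gene/condition/time.
        """
        rows = []
        for g, gene in enumerate(self.gene_names):
            for ci, cond in enumerate(self.conditions):
                for ti, t in enumerate(self.times):
                    for r in range(self.n_replicates):
                        rows.append((gene, cond.label, t, str(r + 1),
                                     self.replicates[g, ci, ti, r]))
                    if include_mean:
                        rows.append((gene, cond.label, t, "mean",
                                     self.means[g, ci, ti]))
        return pd.DataFrame(
            rows, columns=["gene", "condition", "time_h", "replicate", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionDataset":
        df = df[df["replicate"].astype(str) != "mean"]
        genes = tuple(pd.unique(df["gene"]))
        conds = tuple(Condition.from_label(c)
                      for c in pd.unique(df["condition"]))
        times = np.array(sorted(pd.unique(df["time_h"].astype(float))))
        reps = sorted(pd.unique(df["replicate"].astype(str)), key=str)
        shape = (len(genes), len(conds), times.size, len(reps))
        values = np.full(shape, np.nan)
        gidx = {g: i for i, g in enumerate(genes)}
        cidx = {c.label: i for i, c in enumerate(conds)}
        tidx = {t: i for i, t in enumerate(times)}
        ridx = {r: i for i, r in enumerate(reps)}
        for row in df.itertuples(index=False):
            values[gidx[row.gene], cidx[Condition.from_label(row.condition).label],
                   tidx[float(row.time_h)], ridx[str(row.replicate)]] = row.value
        if np.any(np.isnan(values)):
            raise ValueError("incomplete dataset table: missing combinations")
        return cls.from_replicates(genes, conds, times, values)


def write_dataset_tsv(path, dataset: ExpressionDataset,
                      include_mean: bool = True) -> None:
    dataset.to_frame(include_mean=include_mean).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_dataset_tsv(path) -> ExpressionDataset:
    return ExpressionDataset.from_frame(
        pd.read_csv(path, sep="\t", float_precision="round_trip"))


def normalize_dataset(raw: ExpressionDataset) -> ExpressionDataset:
    """Normalize each gene against its maximum mean expression in either
    condition.

    Every replicate value of a gene is divided by the same per-gene factor:
    the maximum of the gene's mean expression over all conditions and time
    points.  Idempotent on already-normalized data.
    """
    factors = raw.means.max(axis=(1, 2))
    zero = np.flatnonzero(factors <= 0)
    if zero.size:
        names = ", ".join(raw.gene_names[i] for i in zero)
        raise NormalizationError(
            f"cannot normalize all-zero gene(s): {names}")
    replicates = raw.replicates / factors[:, None, None, None]
    return ExpressionDataset.from_replicates(
        raw.gene_names, raw.conditions, raw.times, replicates)
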