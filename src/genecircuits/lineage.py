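"""Ordering gene activation along a single-cell differentiation axis.

Validation stage for model-inferred activation order: given a per-cell
table carrying a scalar developmental potential (higher = earlier), fate
probabilities per lineage, and normalized expression counts — all
produced upstream by a population-balance analysis and consumed here as
input — the procedure is:

1. keep cells whose probability of the lineage of interest is strictly
   greater than a threshold (default 0.5);
2. order them by decreasing potential and split into equal-count bins
   (default 11);
3. per gene, average expression within bins, attach standard errors, and
   normalize to the per-gene maximum over bins;
4. compare expression between two bins with Welch's one-sided two-sample
   t-test on the per-cell values.

Peak (argmax) bins of the resulting trends order gene activation in
developmental time.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "select_fated_cells",
    "bin_by_potential",
    "BinnedTrend",
    "bin_trends",
    "compare_bins",
    "read_cell_table",
    "write_cell_table",
]

logger = logging.getLogger(__name__)

POTENTIAL_COL = "potential"


def _prob_column(cells: pd.DataFrame, lineage: str) -> str:
    col = f"p_{lineage}"
    if col not in cells.columns:
        raise KeyError(
            f"no fate-probability column {col!r} in the cell table")
    return col


def select_fated_cells(cells: pd.DataFrame, lineage: str,
                       threshold: float = 0.5) -> pd.DataFrame:
    """Cells whose probability of ``lineage`` is strictly > threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    col = _prob_column(cells, lineage)
    return cells[cells[col] > threshold].reset_index(drop=True)


def bin_by_potential(cells: pd.DataFrame, n_bins: int = 11) -> list:
    """Partition cells into contiguous equal-count bins of decreasing
    potential (bin 1 = highest potential = earliest development).

    When the cell count does not divide evenly, the remainder cells go to
    the earliest (highest-potential) bins.  Returns a list of DataFrames.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(cells)
    if n < n_bins:
        raise ValueError(f"{n} cells cannot fill {n_bins} bins")
    ordered = cells.sort_values(POTENTIAL_COL, ascending=False,
                                kind="mergesort").reset_index(drop=True)
    base, rem = divmod(n, n_bins)
    counts = [base + 1 if i < rem else base for i in range(n_bins)]
    bins, start = [], 0
    for c in counts:
        bins.append(ordered.iloc[start:start + c].reset_index(drop=True))
        start += c
    return bins


@dataclass
class BinnedTrend:
    """Per-bin normalized mean expression of one gene.

    Bins are ordered by decreasing potential; ``means`` are normalized to
    the per-gene maximum over bins (so max(means) = 1), ``sems`` are
    sd/sqrt(n) scaled by the same factor.
    """

    gene: str
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray

    @property
    def peak_bin(self) -> int:
        """0-based index of the maximum-expression bin."""
        return int(np.argmax(self.means))


def bin_trends(bins: Sequence[pd.DataFrame], genes: Sequence[str]) -> dict:
    """Binned mean-expression trends, normalized per gene to the max bin.

    Returns ``{gene: BinnedTrend}``.
    """
    if not bins:
        raise ValueError("no bins supplied")
    out = {}
    for gene in genes:
        means = np.array([b[gene].mean() for b in bins], dtype=float)
        sds = np.array([b[gene].std(ddof=1) if len(b) > 1 else 0.0
                        for b in bins], dtype=float)
        counts = np.array([len(b) for b in bins])
        sems = sds / np.sqrt(counts)
        top = means.max()
        if top > 0:
            means, sems = means / top, sems / top
        out[gene] = BinnedTrend(gene, means, sems, counts)
    return out


def compare_bins(bins: Sequence[pd.DataFrame], gene: str, bin_a: int,
                 bin_b: int, one_sided: bool = True) -> float:
    """Welch's two-sample t-test of gene expression between two bins.

    Tests mean(bin_a) > mean(bin_b) when ``one_sided`` (the default),
    using per-cell expression values and the Satterthwaite degrees of
    freedom.  Two zero-variance bins with equal means return p = 0.5
    (one-sided convention) and are logged.
    """
    a = np.asarray(bins[bin_a][gene], dtype=float)
    b = np.asarray(bins[bin_b][gene], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each bin needs >= 2 cells")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            logger.warning("degenerate bin comparison: both bins constant "
                           "and equal")
            return 0.5 if one_sided else 1.0
        # constant but different: direction is certain
        if one_sided:
            return 0.0 if a.mean() > b.mean() else 1.0
        return 0.0
    alternative = "greater" if one_sided else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def write_cell_table(path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cell_table(path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t")
    if POTENTIAL_COL not in cells.columns:
        raise ValueError("cell table must carry a 'potential' column")
    return cells
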