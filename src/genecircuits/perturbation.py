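"""In-silico genetic perturbations.

Three perturbation protocols are implemented on a fitted circuit:

* **knockout** — the gene's initial concentration and maximum synthesis
  rate are set to zero and the full differentiation time course is
  simulated in each condition;
* **knockdown** — the gene's synthesis rate R is reduced; because the
  efficiency of an experimental knockdown is unknown, R is calibrated so
  that the target gene's equilibrium fold change (progenitor condition,
  c = 0, 1000 h) matches the observed value, and the remaining genes'
  fold changes are the prediction;
* **overexpression** — raising a factor's *activity* (e.g. an ERT fusion
  induced post-translationally) leaves its mRNA equation unchanged but
  adds a constant bias B_i = T_{i<-g} * beta to every gene's regulatory
  input; beta is calibrated against the observed fold change of one
  reference gene, and the overexpressed gene's own mRNA fold change is
  flagged non-predictive.

Fold changes are ratios of perturbed to unperturbed equilibrium
expression; an initial-condition sensitivity sweep (one gene at a time,
+-10..70%) quantifies robustness of the fit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dataio import ExpressionDataset
from .exceptions import CalibrationError
from .inference import count_datapoints, residual_ss, rms_score
from .model import Condition, GeneCircuitParams, simulate, solve_equilibrium

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationSpec",
    "FoldChangeTable",
    "knockout",
    "knockdown_calibrated",
    "overexpression_calibrated",
    "sensitivity_sweep",
    "fold_change",
    "classify_quadrant",
]

SENSITIVITY_LEVELS = (-0.7, -0.5, -0.3, -0.2, -0.1, 0.1, 0.2, 0.3, 0.5, 0.7)


@dataclass
class PerturbationSpec:
    """A resolved perturbation: what was done and with which calibrated
    parameter value."""

    kind: str  # knockout | knockdown | overexpression
    target_gene: str
    condition: Condition = Condition.PROGENITOR
    R_target: Optional[float] = None      # knockdown: calibrated rate
    beta: Optional[float] = None          # overexpression: active factor
    reference_gene: Optional[str] = None  # overexpression calibration gene
    observed_fold_change: Optional[float] = None


@dataclass
class FoldChangeTable:
    """Per-gene perturbed / unperturbed expression ratios.

    ``non_predictive`` marks calibration genes whose fold change was
    matched to data rather than predicted; ``undefined`` marks genes with
    zero baseline (ratio not defined, reported as NaN).
    """

    gene_names: tuple
    ratios: np.ndarray
    non_predictive: tuple = ()
    undefined: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": list(self.gene_names),
            "fold_change": self.ratios,
            "predictive": [g not in self.non_predictive
                           for g in self.gene_names],
        })


def fold_change(perturbed_state, baseline_state, gene_names,
                non_predictive: Sequence[str] = ()) -> FoldChangeTable:
    """Elementwise perturbed/baseline ratio with zero-baseline flagging."""
    perturbed = np.asarray(perturbed_state, dtype=float)
    baseline = np.asarray(baseline_state, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = perturbed / baseline
    undefined = tuple(np.asarray(gene_names)[baseline <= 0.0])
    ratios = np.where(baseline > 0.0, ratios, np.nan)
    return FoldChangeTable(tuple(gene_names), ratios,
                           tuple(non_predictive), undefined)


def classify_quadrant(predicted: float, observed: float) -> str:
    """Qualitative agreement of a (predicted, observed) fold-change pair.

    Both above 1 or both below 1 -> "agreement" (green quadrant); opposite
    sides of 1 -> "disagreement" (red quadrant); either exactly 1 ->
    "boundary".
    """
    sp, so = np.sign(np.log(predicted)), np.sign(np.log(observed))
    if sp == 0 or so == 0:
        return "boundary"
    return "agreement" if sp == so else "disagreement"


# ---------------------------------------------------------------------------
# Knockout
# ---------------------------------------------------------------------------

def knockout(params: GeneCircuitParams, x0, gene: str):
    """Zero the gene's synthesis rate and initial concentration.

    Returns ``(perturbed_params, perturbed_x0)`` ready to simulate in any
    condition; idempotent (knocking out twice is a no-op).
    """
    i = params.index(gene)
    new = params.copy()
    new.R[i] = 0.0
    new_x0 = np.asarray(x0, dtype=float).copy()
    new_x0[i] = 0.0
    return new, new_x0


# ---------------------------------------------------------------------------
# Calibrated knockdown / overexpression
# ---------------------------------------------------------------------------

def _equilibrium(params, x0, horizon, bias=None):
    return solve_equilibrium(params, x0, Condition.PROGENITOR,
                             horizon_hours=horizon, bias=bias,
                             deriv_tol=np.inf)


def knockdown_calibrated(params: GeneCircuitParams, gene: str,
                         observed_fold_change: float, x0,
                         horizon: float = 1000.0, rel_tol: float = 1e-3):
    """Calibrate a synthesis-rate knockdown to an observed fold change.

    Finds R_gene in [0, R_original] such that the target gene's
    equilibrium fold change (progenitor condition, ``horizon`` hours)
    matches ``observed_fold_change`` within ``rel_tol``, by bracketing
    root finding.  If the response is non-monotone (multistability) the
    bracketed solver still returns a matching value; if no value in the
    bracket achieves the requested fold change a CalibrationError reports
    the achievable range.

    Returns ``(PerturbationSpec, FoldChangeTable)``; the targeted gene is
    marked non-predictive (the prediction covers the other genes only).
    """
    i = params.index(gene)
    if not (0.0 < observed_fold_change <= 1.0):
        raise CalibrationError(
            "knockdown fold change must be in (0, 1]")
    x0 = np.asarray(x0, dtype=float)
    baseline = _equilibrium(params, x0, horizon)
    if baseline[i] <= 0:
        raise CalibrationError(f"baseline expression of {gene} is zero")

    def achieved(r_value: float) -> float:
        trial = params.copy()
        trial.R[i] = r_value
        return _equilibrium(trial, x0, horizon)[i] / baseline[i]

    r_orig = params.R[i]
    if observed_fold_change == 1.0:
        r_new = r_orig
    else:
        f_lo, f_hi = achieved(0.0), 1.0
        lo, hi = min(f_lo, f_hi), max(f_lo, f_hi)
        if not (lo <= observed_fold_change <= hi):
            raise CalibrationError(
                f"fold change {observed_fold_change} for {gene} outside the "
                f"achievable range [{lo:.4g}, {hi:.4g}]")
        r_new = brentq(lambda r: achieved(r) - observed_fold_change,
                       0.0, r_orig, xtol=1e-10 * max(r_orig, 1.0),
                       rtol=1e-12)
    trial = params.copy()
    trial.R[i] = r_new
    perturbed = _equilibrium(trial, x0, horizon)
    got = perturbed[i] / baseline[i]
    if abs(got - observed_fold_change) > rel_tol * observed_fold_change:
        logger.warning("knockdown calibration residual %.3g for %s",
                       abs(got - observed_fold_change), gene)
    spec = PerturbationSpec("knockdown", gene, R_target=float(r_new),
                            observed_fold_change=observed_fold_change)
    return spec, fold_change(perturbed, baseline, params.gene_names,
                             non_predictive=(gene,))


def overexpression_calibrated(params: GeneCircuitParams, gene: str,
                              reference_gene: str,
                              observed_ref_fold_change: float, x0,
                              horizon: float = 1000.0,
                              beta_max: float = 20.0,
                              rel_tol: float = 1e-3):
    """Calibrate an activity-overexpression bias to a reference gene.

    The bias ``B_i = T_{i<-gene} * beta`` is added to every gene's
    regulatory input; ``beta >= 0`` (the amount of additional active
    factor) is found on ``[0, beta_max]`` so that the *reference* gene's
    equilibrium fold change matches ``observed_ref_fold_change``.  The
    overexpressed gene's own mRNA fold change is flagged non-predictive
    (in an ERT-style experiment the measured mRNA includes the transgene).
    """
    g = params.index(gene)
    r = params.index(reference_gene)
    if r == g:
        raise CalibrationError(
            "reference gene must differ from the overexpressed gene")
    x0 = np.asarray(x0, dtype=float)
    baseline = _equilibrium(params, x0, horizon)
    if baseline[r] <= 0:
        raise CalibrationError(
            f"baseline expression of {reference_gene} is zero")
    column = params.T[:, g]

    def achieved(beta: float) -> float:
        return _equilibrium(params, x0, horizon,
                            bias=column * beta)[r] / baseline[r]

    f0, fmax = 1.0, achieved(beta_max)
    lo, hi = min(f0, fmax), max(f0, fmax)
    if observed_ref_fold_change == 1.0:
        beta = 0.0
    elif not (lo <= observed_ref_fold_change <= hi):
        raise CalibrationError(
            f"fold change {observed_ref_fold_change} for {reference_gene} "
            f"outside the achievable range [{lo:.4g}, {hi:.4g}] at "
            f"beta <= {beta_max}")
    else:
        beta = brentq(lambda be: achieved(be) - observed_ref_fold_change,
                      0.0, beta_max, xtol=1e-10, rtol=1e-12)
    perturbed = _equilibrium(params, x0, horizon, bias=column * beta)
    got = perturbed[r] / baseline[r]
    if abs(got - observed_ref_fold_change) > \
            rel_tol * observed_ref_fold_change:
        logger.warning("overexpression calibration residual %.3g",
                       abs(got - observed_ref_fold_change))
    spec = PerturbationSpec("overexpression", gene, beta=float(beta),
                            reference_gene=reference_gene,
                            observed_fold_change=observed_ref_fold_change)
    return spec, fold_change(perturbed, baseline, params.gene_names,
                             non_predictive=(gene, reference_gene))


# ---------------------------------------------------------------------------
# Initial-condition sensitivity
# ---------------------------------------------------------------------------

def sensitivity_sweep(params: GeneCircuitParams, dataset: ExpressionDataset,
                      levels: Sequence[float] = SENSITIVITY_LEVELS,
                      rel_accuracy: float = 1e-3) -> pd.DataFrame:
    """Perturb each gene's initial concentration by each level, one gene
    at a time, and record the RMS of the re-simulated model against the
    dataset.

    With the default +-10/20/30/50/70% levels and 12 genes this is 120
    simulations.  Returns a DataFrame with columns gene, level, rms.
    """
    n_d = count_datapoints(dataset)
    rows = []
    for gi, gene in enumerate(params.gene_names):
        for level in levels:
            x0 = dataset.x0.copy()
            x0[gi] = max(x0[gi] * (1.0 + level), 0.0)
            perturbed_ds = dataset.copy()
            perturbed_ds.x0 = x0
            res = residual_ss(params, perturbed_ds, rel_accuracy)
            rows.append((gene, level, rms_score(res, n_d)))
    return pd.DataFrame(rows, columns=["gene", "level", "rms"])
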