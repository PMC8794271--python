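"""Time-resolved analysis of gene regulation in a fitted circuit.

The total regulatory input of a target gene,
``u_i(t) = sum_j T_ij x_j(t) + b_i c + h_i``, is an exact sum of
per-regulator contributions ``T_ij x_j(t)``, the external-signal term
``b_i c`` and the threshold ``h_i``; decomposing it attributes the up- or
down-regulation of each gene to individual regulators as their
concentrations evolve.  Because synthesis runs at half its maximum rate
when ``u = 0``, the first zero-crossing of ``u(t)`` ("half-max activation
time") orders gene activation during differentiation.

The module also classifies ensemble edges by the quartile rule
(activation if Q1 > 0, repression if Q3 < 0, otherwise unconstrained),
selects a representative model by consensus parameter signs, and exports
the time-evolving network as weighted edge-list snapshots.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .inference import Ensemble
from .model import Condition, GeneCircuitParams, Trajectory

__all__ = [
    "RegulatoryDecomposition",
    "decompose",
    "half_max_time",
    "half_max_ordering",
    "classify_edges",
    "select_representative",
    "export_dynamic_grn",
    "grn_snapshot_graph",
]


@dataclass
class RegulatoryDecomposition:
    """Additive decomposition of one target's regulatory input over time.

    ``contributions[j]`` is the series ``T_ij x_j(t)`` for regulator j;
    ``external`` is the constant series ``b_i c``; ``threshold`` is
    ``h_i``.  Their sum (plus any bias) equals ``total`` exactly at every
    time point.  ``half_max_time`` is the first zero-crossing of the
    total input (None if it never crosses); ``crossings`` retains all of
    them.
    """

    target: str
    condition: Condition
    gene_names: tuple
    times: np.ndarray
    t_row: np.ndarray          # interconnectivity row T_i. of this target
    contributions: np.ndarray  # (n_regulators, n_times)
    external: float
    threshold: float
    bias: float
    total: np.ndarray
    half_max_time: Optional[float]
    crossings: tuple

    def activators(self) -> tuple:
        """Regulators with positive interconnectivity onto this target."""
        return tuple(g for g, t in zip(self.gene_names, self.t_row) if t > 0)

    def repressors(self) -> tuple:
        return tuple(g for g, t in zip(self.gene_names, self.t_row) if t < 0)


def half_max_time(u_series, times):
    """First zero-crossing of the total regulatory input.

    A sample where ``u`` is exactly 0 reports that sample's time;
    otherwise the crossing is located by linear interpolation between the
    bracketing samples.  Returns None when ``u`` never changes sign.
    """
    u = np.asarray(u_series, dtype=float)
    times = np.asarray(times, dtype=float)
    crossings = _all_crossings(u, times)
    return crossings[0] if crossings else None


def _all_crossings(u: np.ndarray, times: np.ndarray) -> list:
    out = []
    for k in range(u.size):
        if u[k] == 0.0:
            out.append(float(times[k]))
        elif k + 1 < u.size and u[k] * u[k + 1] < 0:
            frac = u[k] / (u[k] - u[k + 1])
            out.append(float(times[k] + frac * (times[k + 1] - times[k])))
    # an exact-zero sample also triggers no sign product; dedupe, keep order
    seen, dedup = set(), []
    for t in out:
        if t not in seen:
            seen.add(t)
            dedup.append(t)
    return dedup


def decompose(params: GeneCircuitParams, trajectory: Trajectory,
              cond: Optional[Condition] = None, bias=None) -> dict:
    """Decompose every gene's total regulatory input along a trajectory.

    Returns ``{target_gene: RegulatoryDecomposition}``.  The trajectory
    must have been simulated from ``params`` under ``cond`` (defaults to
    the trajectory's own condition) for the decomposition to describe the
    model's actual regulation.
    """
    cond = cond or trajectory.condition
    if trajectory.gene_names != params.gene_names:
        raise ValueError("trajectory and params gene order differ")
    c = cond.c
    bias = np.zeros(params.n_genes) if bias is None \
        else np.asarray(bias, dtype=float).ravel()
    out = {}
    for i, target in enumerate(params.gene_names):
        contributions = params.T[i][:, None] * trajectory.values
        total = contributions.sum(axis=0) + params.b[i] * c + params.h[i] \
            + bias[i]
        crossings = tuple(_all_crossings(total, trajectory.times))
        out[target] = RegulatoryDecomposition(
            target=target, condition=cond, gene_names=params.gene_names,
            times=trajectory.times, t_row=params.T[i].copy(),
            contributions=contributions,
            external=float(params.b[i] * c), threshold=float(params.h[i]),
            bias=float(bias[i]), total=total,
            half_max_time=crossings[0] if crossings else None,
            crossings=crossings)
    return out


def half_max_ordering(decompositions: dict) -> pd.DataFrame:
    """Table of half-max activation times, earliest first (genes whose
    input never crosses zero sort last with NaN)."""
    rows = [(gene, d.half_max_time)
            for gene, d in decompositions.items()]
    df = pd.DataFrame(rows, columns=["gene", "half_max_time_h"])
    return df.sort_values("half_max_time_h", na_position="last",
                          ignore_index=True)


# ---------------------------------------------------------------------------
# Ensemble edge classification and representative selection
# ---------------------------------------------------------------------------

def _ensemble_params(ensemble) -> list:
    if isinstance(ensemble, Ensemble):
        return [f.params for f in ensemble.fits]
    return [p.params if hasattr(p, "params") else p for p in ensemble]


def classify_edges(ensemble) -> pd.DataFrame:
    """Quartile-rule classification of every interconnection and of the
    external-signal coefficients.

    For each (target, regulator) pair the ensemble distribution of T_ij
    is summarized by quartiles (linear interpolation between order
    statistics): activation if the first quartile is positive, repression
    if the third quartile is negative, unconstrained if the interquartile
    range spans zero.  The same rule is applied to each b_i, reported
    with regulator label "Ext. Sig." (positive values mean activation in
    the erythrocyte condition and repression in the neutrophil one).
    """
    models = _ensemble_params(ensemble)
    if len(models) < 4:
        raise ValueError("edge classification needs an ensemble of >= 4")
    genes = models[0].gene_names
    T_stack = np.stack([m.T for m in models])      # (M, N, N)
    b_stack = np.stack([m.b for m in models])      # (M, N)
    rows = []

    def label(q1, q3):
        if q1 > 0:
            return "activation"
        if q3 < 0:
            return "repression"
        return "unconstrained"

    for i, target in enumerate(genes):
        for j, regulator in enumerate(genes):
            vals = T_stack[:, i, j]
            q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append((target, regulator, q1, q2, q3, label(q1, q3)))
        vals = b_stack[:, i]
        q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        rows.append((target, "Ext. Sig.", q1, q2, q3, label(q1, q3)))
    return pd.DataFrame(rows, columns=["target", "regulator", "q1", "median",
                                       "q3", "label"])


def select_representative(ensemble) -> int:
    """Index of the model whose interconnectivity signs best match the
    ensemble consensus.

    For each T_ij the majority sign over the ensemble is computed
    (parameters with an exact sign tie are excluded from scoring); each
    model scores one point per parameter whose sign matches the majority,
    and a maximal-score model is returned.  Residual ties are broken by
    lowest RMS when fit metadata is available, then by lowest index.
    """
    models = _ensemble_params(ensemble)
    if not models:
        raise ValueError("empty ensemble")
    T_stack = np.stack([m.T for m in models])
    signs = np.sign(T_stack)
    pos = (signs > 0).sum(axis=0)
    neg = (signs < 0).sum(axis=0)
    majority = np.where(pos > neg, 1.0, np.where(neg > pos, -1.0, np.nan))
    valid = ~np.isnan(majority)
    scores = np.array([(signs[m][valid] == majority[valid]).sum()
                       for m in range(len(models))])
    best = np.flatnonzero(scores == scores.max())
    if len(best) > 1 and isinstance(ensemble, Ensemble):
        rms = np.array([ensemble.fits[i].rms for i in best])
        return int(best[np.argmin(rms)])
    fits = getattr(ensemble, "fits", None)
    if len(best) > 1 and fits is None:
        items = list(ensemble)
        if all(hasattr(x, "rms") for x in items):
            rms = np.array([items[i].rms for i in best])
            return int(best[np.argmin(rms)])
    return int(best[0])


# ---------------------------------------------------------------------------
# Time-evolving GRN export
# ---------------------------------------------------------------------------

def export_dynamic_grn(decompositions: dict,
                       timepoints: Sequence[float]) -> pd.DataFrame:
    """Edge-list snapshots of the time-evolving network.

    For each requested time point, each (regulator, target) pair
    contributes an edge carrying the signed contribution ``T_ij x_j(t)``
    (interpolated onto the requested time) and a normalized magnitude:
    activation and repression magnitudes are each scaled so their maximum
    over the whole export is 1.

    Columns: time_h, regulator, target, sign, contribution, weight.
    """
    rows = []
    for target, d in decompositions.items():
        for j, regulator in enumerate(d.gene_names):
            series = d.contributions[j]
            for t in timepoints:
                cval = float(np.interp(t, d.times, series))
                rows.append((float(t), regulator, target, cval))
    df = pd.DataFrame(rows, columns=["time_h", "regulator", "target",
                                     "contribution"])
    df["sign"] = np.sign(df["contribution"]).astype(int)
    max_act = df.loc[df["contribution"] > 0, "contribution"].max()
    max_rep = (-df.loc[df["contribution"] < 0, "contribution"]).max()
    weight = np.zeros(len(df))
    if np.isfinite(max_act) and max_act > 0:
        pos = df["contribution"] > 0
        weight[pos] = df.loc[pos, "contribution"] / max_act
    if np.isfinite(max_rep) and max_rep > 0:
        negm = df["contribution"] < 0
        weight[negm] = -df.loc[negm, "contribution"] / max_rep
    df["weight"] = weight
    return df[["time_h", "regulator", "target", "sign", "contribution",
               "weight"]]


def grn_snapshot_graph(edges: pd.DataFrame, time_h: float):
    """A networkx DiGraph of one snapshot (edges with nonzero weight)."""
    import networkx as nx

    snap = edges[(edges["time_h"] == time_h) & (edges["weight"] != 0)]
    g = nx.DiGraph()
    for row in snap.itertuples(index=False):
        g.add_edge(row.regulator, row.target, sign=int(row.sign),
                   weight=float(row.weight))
    return g
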