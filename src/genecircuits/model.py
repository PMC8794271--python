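"""Core gene-circuit dynamical system.

A gene circuit models the mRNA concentration ``x_i(t)`` of each gene in an
N-gene regulatory network with the coupled ODEs

    dx_i/dt = R_i * S(u_i) - lam_i * x_i,
    u_i     = sum_j T_ij x_j + b_i c + h_i (+ B_i),

where ``S(u) = (u / sqrt(u^2 + 1) + 1) / 2`` is the sigmoidal
regulation-expression function mapping the total regulatory input ``u`` to
the fraction of the maximum synthesis rate ``R_i`` that is realised.
``T_ij`` is the genetic interconnectivity (positive = activation of target
``i`` by regulator ``j``, negative = repression), ``b_i`` couples the gene
to condition-specific external signals (cytokines) through the condition
code ``c``, ``h_i`` is a threshold setting the basal input, and ``lam_i``
is the first-order mRNA degradation rate.  The optional constant bias
``B_i`` is used to emulate overexpression of a transcription factor whose
activity (not mRNA) is raised.

Concentrations are in relative-expression units (per-gene max-normalized,
so roughly in [0, 1]); rates are per hour.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .exceptions import IntegrationError

__all__ = [
    "Condition",
    "GeneCircuitParams",
    "Trajectory",
    "regulation_expression",
    "total_regulatory_input",
    "rhs",
    "simulate",
    "solve_equilibrium",
    "read_params_table",
    "write_params_table",
    "write_trajectories",
]


class Condition(enum.Enum):
    """Differentiation condition with its signed code ``c``.

    The external-signal term of the regulatory input is ``b_i * c`` with
    ``c = -1`` in neutrophil conditions (GCSF + SCF), ``0`` in the
    progenitor / self-renewal condition (IL3), and ``+1`` in erythrocyte
    conditions (low IL3 + Epo + hemin).
    """

    NEUTROPHIL = -1
    PROGENITOR = 0
    ERYTHROCYTE = 1

    @property
    def c(self) -> float:
        return float(self.value)

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        key = str(label).strip().lower()
        aliases = {
            "erythrocyte": cls.ERYTHROCYTE,
            "erythroid": cls.ERYTHROCYTE,
            "ery": cls.ERYTHROCYTE,
            "neutrophil": cls.NEUTROPHIL,
            "neu": cls.NEUTROPHIL,
            "progenitor": cls.PROGENITOR,
        }
        if key not in aliases:
            raise KeyError(f"unknown condition label {label!r}")
        return aliases[key]


def _condition_code(cond) -> float:
    """Accept a Condition, a label string, or a bare numeric code."""
    if isinstance(cond, Condition):
        return cond.c
    if isinstance(cond, str):
        return Condition.from_label(cond).c
    return float(cond)


@dataclass
class GeneCircuitParams:
    """All free parameters of an N-gene circuit.

    Attributes
    ----------
    gene_names
        Ordered gene labels; rows and columns of ``T`` and all vectors
        follow this order.
    T
        N x N genetic interconnectivity matrix; row = target, column =
        regulator.
    b
        External-signal coefficients (one per gene).
    h
        Thresholds (basal-input offsets).
    R
        Maximum synthesis rates (concentration / hour), >= 0.
    lam
        mRNA degradation rates (1 / hour), > 0.
    """

    gene_names: tuple
    T: np.ndarray
    b: np.ndarray
    h: np.ndarray
    R: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        self.gene_names = tuple(str(g) for g in self.gene_names)
        n = len(self.gene_names)
        if n == 0:
            raise ValueError("circuit needs at least one gene")
        self.T = np.asarray(self.T, dtype=float)
        for name in ("b", "h", "R", "lam"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if self.T.shape != (n, n):
            raise ValueError(f"T must be {n}x{n}, got {self.T.shape}")
        for name in ("b", "h", "R", "lam"):
            v = getattr(self, name)
            if v.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got {v.shape}")
        if not (np.all(np.isfinite(self.T)) and all(
                np.all(np.isfinite(getattr(self, v))) for v in ("b", "h", "R", "lam"))):
            raise ValueError("circuit parameters must be finite")
        if np.any(self.R < 0):
            raise ValueError("synthesis rates R must be >= 0")
        if np.any(self.lam <= 0):
            raise ValueError("degradation rates lam must be > 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(
                f"gene {gene!r} not in circuit {self.gene_names}") from None

    def copy(self) -> "GeneCircuitParams":
        return GeneCircuitParams(self.gene_names, self.T.copy(), self.b.copy(),
                                 self.h.copy(), self.R.copy(), self.lam.copy())


@dataclass
class Trajectory:
    """Model solution on a time grid for one condition.

    ``values`` has shape (n_genes, n_times) in relative-expression units.
    """

    gene_names: tuple
    condition: Condition
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.gene_names = tuple(self.gene_names)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.values.shape != (len(self.gene_names), self.times.size):
            raise ValueError("values must be (n_genes, n_times)")

    def gene(self, name: str) -> np.ndarray:
        return self.values[self.gene_names.index(name)]

    def at(self, t: float) -> np.ndarray:
        """Linearly interpolated state at time ``t``."""
        return np.array([np.interp(t, self.times, row) for row in self.values])


def regulation_expression(u):
    """Sigmoidal regulation-expression function ``S(u)``.

    ``S(u) = (u / sqrt(u^2 + 1) + 1) / 2``: strictly increasing, S(0) = 1/2,
    with limits 0 and 1 at -inf / +inf.  Accepts scalars or arrays.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("regulatory input u must be finite")
    out = 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)
    return out if out.ndim else float(out)


def total_regulatory_input(params: GeneCircuitParams, x, cond, bias=None):
    """Total regulatory input ``u_i = sum_j T_ij x_j + b_i c + h_i + B_i``."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != params.n_genes:
        raise ValueError(
            f"state has length {x.size}, circuit has {params.n_genes} genes")
    c = _condition_code(cond)
    u = params.T @ x + params.b * c + params.h
    if bias is not None:
        bias = np.asarray(bias, dtype=float).ravel()
        if bias.size != params.n_genes:
            raise ValueError("bias length does not match circuit size")
        u = u + bias
    return u


def rhs(params: GeneCircuitParams, x, cond, bias=None):
    """Time derivative ``dx_i/dt = R_i S(u_i) - lam_i x_i``."""
    x = np.asarray(x, dtype=float).ravel()
    u = total_regulatory_input(params, x, cond, bias)
    return params.R * regulation_expression(u) - params.lam * x


def _integrate(params: GeneCircuitParams, x0: np.ndarray, c: float,
               t_grid: np.ndarray, rtol: float, atol: float,
               bias=None) -> np.ndarray:
    """Fast path: adaptive-step integration, returns (n_genes, n_times)."""
    T = params.T
    offs = params.b * c + params.h
    if bias is not None:
        offs = offs + np.asarray(bias, dtype=float).ravel()
    R, lam = params.R, params.lam

    def f(t, x):
        u = T @ x + offs
        return R * (0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)) - lam * x

    out, info = odeint(f, x0, t_grid, rtol=rtol, atol=atol, tfirst=True,
                       full_output=True, mxstep=100000)
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"solver failed near t = {float(info['tcur'][-1]):.3g} h: "
            f"{info['message']}")
    return out.T


def simulate(params: GeneCircuitParams, x0, cond, t_grid,
             rel_accuracy: float = 1e-3, abs_accuracy: float = 1e-6,
             bias=None) -> Trajectory:
    """Integrate the circuit forward in time for one condition.

    Uses an adaptive step-size solver with relative local error control at
    ``rel_accuracy`` (default 1e-3) and an absolute floor ``abs_accuracy``.
    Deterministic for fixed inputs.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != params.n_genes:
        raise ValueError("x0 length does not match circuit size")
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    cond_obj = cond if isinstance(cond, Condition) else (
        Condition.from_label(cond) if isinstance(cond, str)
        else Condition(int(cond)))
    values = _integrate(params, x0, cond_obj.c, t_grid,
                        rel_accuracy, abs_accuracy, bias)
    return Trajectory(params.gene_names, cond_obj, t_grid, values)


def solve_equilibrium(params: GeneCircuitParams, x0, cond,
                      horizon_hours: float = 1000.0, bias=None,
                      deriv_tol: float = 1e-6,
                      rel_accuracy: float = 1e-3) -> np.ndarray:
    """Relax the circuit for ``horizon_hours`` (default 1000 h) and return
    the final state.

    A fixed-horizon protocol is used; afterwards the derivative norm is
    checked against ``deriv_tol`` (per hour) and a warning is emitted if the
    solution has not settled.
    """
    grid = np.array([0.0, horizon_hours / 2.0, horizon_hours])
    traj = simulate(params, x0, cond, grid, rel_accuracy=rel_accuracy,
                    bias=bias)
    x_end = traj.values[:, -1]
    d = rhs(params, x_end, cond, bias)
    if np.max(np.abs(d)) > deriv_tol:
        warnings.warn(
            f"equilibrium not reached at {horizon_hours} h: "
            f"max |dx/dt| = {np.max(np.abs(d)):.3g} > {deriv_tol:.3g}",
            RuntimeWarning, stacklevel=2)
    return x_end


# ---------------------------------------------------------------------------
# Parameter-table I/O.  Column convention: "T_Genei_Genej" (target, regulator),
# "b_Genei", "h_Genei", "R_Genei", "lambda_Genei"; one row per model; TSV.
# ---------------------------------------------------------------------------

def _param_columns(gene_names: Sequence[str]):
    cols = [f"T_{gi}_{gj}" for gi in gene_names for gj in gene_names]
    for prefix in ("b", "h", "R", "lambda"):
        cols.extend(f"{prefix}_{g}" for g in gene_names)
    return cols


def params_to_row(params: GeneCircuitParams) -> dict:
    row = {}
    g = params.gene_names
    for i, gi in enumerate(g):
        for j, gj in enumerate(g):
            row[f"T_{gi}_{gj}"] = params.T[i, j]
    for i, gi in enumerate(g):
        row[f"b_{gi}"] = params.b[i]
        row[f"h_{gi}"] = params.h[i]
        row[f"R_{gi}"] = params.R[i]
        row[f"lambda_{gi}"] = params.lam[i]
    return row


def write_params_table(path, params_list: Iterable[GeneCircuitParams]) -> None:
    params_list = list(params_list)
    if not params_list:
        raise ValueError("no parameter sets to write")
    genes = params_list[0].gene_names
    for p in params_list:
        if p.gene_names != genes:
            raise ValueError("all parameter sets must share one gene order")
    df = pd.DataFrame([params_to_row(p) for p in params_list],
                      columns=_param_columns(genes))
    df.to_csv(path, sep="\t", index=False)


def read_params_table(path) -> list:
    """Read one or more parameter sets from a TSV in the table convention."""
    df = pd.read_csv(path, sep="\t")
    genes = [c[2:] for c in df.columns if c.startswith("b_")]
    if not genes:
        raise ValueError("no 'b_<gene>' columns found; not a parameter table")
    out = []
    for _, row in df.iterrows():
        n = len(genes)
        T = np.array([[row[f"T_{gi}_{gj}"] for gj in genes] for gi in genes])
        vecs = {p: np.array([row[f"{p}_{g}"] for g in genes])
                for p in ("b", "h", "R", "lambda")}
        out.append(GeneCircuitParams(tuple(genes), T, vecs["b"], vecs["h"],
                                     vecs["R"], vecs["lambda"]))
    return out


def write_trajectories(path, trajectories: Iterable[Trajectory]) -> None:
    """Write trajectories as TSV: time_h, condition, one column per gene.

    Values are clipped at 0 in the export (solver undershoot is never
    clipped inside the integrator state, only in tables).
    """
    frames = []
    for traj in trajectories:
        df = pd.DataFrame(np.clip(traj.values.T, 0.0, None),
                          columns=list(traj.gene_names))
        df.insert(0, "condition", traj.condition.label)
        df.insert(0, "time_h", traj.times)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
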