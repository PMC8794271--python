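"""Adaptive simulated annealing.

A coordinate-wise Metropolis annealer with an acceptance-targeted adaptive
schedule: per-parameter move scales are adjusted every batch toward a
target acceptance ratio (0.44, the classic single-variable target used by
Lam-style statistically adaptive schedules), while the temperature follows
a geometric profile from an automatically estimated starting temperature
down to a fixed fraction of it.  Deterministic under a seeded Generator.

The annealer is deliberately pluggable: the inference layer only requires
a seeded global stochastic minimizer, not a specific schedule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnnealResult", "anneal"]


@dataclass
class AnnealResult:
    best_x: np.ndarray
    best_energy: float
    n_evaluations: int
    n_accepted: int
    final_temperature: float


def anneal(energy, x0, lower, upper, scales, rng, n_steps: int = 6000,
           target_accept: float = 0.44, t_final_frac: float = 1e-4,
           batch: int = 0) -> AnnealResult:
    """Minimize ``energy`` over a box by adaptive simulated annealing.

    Parameters
    ----------
    energy : callable(ndarray) -> float
        Evaluations that raise or return non-finite values are treated as
        infinitely bad moves (rejected).
    x0, lower, upper : ndarray
        Start point and box bounds.
    scales : ndarray
        Initial per-coordinate proposal standard deviations; adapted
        during the run.
    rng : numpy.random.Generator
    n_steps : int
        Total number of proposal moves (cost evaluations, excluding the
        temperature probe).
    """
    x = np.asarray(x0, dtype=float).copy()
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    scales = np.asarray(scales, dtype=float).copy()
    n = x.size
    n_evals = 0

    def safe_energy(p):
        nonlocal n_evals
        n_evals += 1
        try:
            e = float(energy(p))
        except Exception:
            return np.inf
        return e if np.isfinite(e) else np.inf

    e_cur = safe_energy(x)
    best_x, best_e = x.copy(), e_cur

    # probe: estimate an initial temperature giving ~80% uphill acceptance
    deltas = []
    for _ in range(min(40, max(10, n))):
        k = rng.integers(n)
        trial = x.copy()
        trial[k] = np.clip(trial[k] + scales[k] * rng.standard_normal(),
                           lower[k], upper[k])
        e_t = safe_energy(trial)
        if np.isfinite(e_t):
            deltas.append(abs(e_t - e_cur))
            if e_t < best_e:
                best_x, best_e = trial.copy(), e_t
    t0 = max(float(np.median(deltas)) if deltas else 1.0, 1e-12) / np.log(5.0)

    if batch <= 0:
        batch = max(10 * n, 100)
    n_batches = max(int(np.ceil(n_steps / batch)), 1)
    alpha = t_final_frac ** (1.0 / n_batches)

    temp = t0
    accepted_total = 0
    steps_done = 0
    while steps_done < n_steps:
        acc = np.zeros(n)
        tried = np.zeros(n)
        for _ in range(min(batch, n_steps - steps_done)):
            k = rng.integers(n)
            trial = x.copy()
            trial[k] = np.clip(trial[k] + scales[k] * rng.standard_normal(),
                               lower[k], upper[k])
            e_t = safe_energy(trial)
            d = e_t - e_cur
            tried[k] += 1
            if d <= 0 or rng.random() < np.exp(-d / temp):
                x, e_cur = trial, e_t
                acc[k] += 1
                accepted_total += 1
                if e_cur < best_e:
                    best_x, best_e = x.copy(), e_cur
            steps_done += 1
        # move-scale adaptation toward the target acceptance ratio
        mask = tried > 0
        ratio = np.where(mask, acc / np.maximum(tried, 1), target_accept)
        scales[mask] *= np.exp(ratio[mask] - target_accept)
        scales = np.clip(scales, 1e-6 * (upper - lower), 0.5 * (upper - lower))
        temp *= alpha

    return AnnealResult(best_x, best_e, n_evals, accepted_total, temp)
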