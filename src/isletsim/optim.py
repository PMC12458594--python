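"""Compact CMA-ES (covariance matrix adaptation evolution strategy).

A self-contained implementation of the standard (mu/mu_w, lambda)
strategy with rank-one and rank-mu covariance updates and cumulative
step-size adaptation, following Hansen's canonical parameterisation.
It is written for low-dimensional, noisy, gradient-free objectives such
as the simulation-based calibration loss (dimension 4), where the full
machinery of a dedicated optimisation package is unnecessary.

The objective is called as ``f(x, generation)`` so that simulation-based
objectives can fix their replicate seeds per generation (common random
numbers across the candidates of one generation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CMAESResult", "cmaes_minimize"]


@dataclass
class CMAESResult:
    best_x: np.ndarray
    best_f: float
    trace: list[dict]  # per generation: generation, best_f, mean_f, sigma
    evaluations: int


def cmaes_minimize(
    f: Callable[[np.ndarray, int], float],
    x0: np.ndarray,
    sigma0: float,
    popsize: int = 16,
    generations: int = 9,
    seed: int = 0,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> CMAESResult:
    """Minimise ``f`` starting from mean ``x0`` with initial step ``sigma0``.

    Optional box bounds are enforced by coordinate-wise clipping of the
    sampled candidates (the evaluated point is the clipped one).  The
    best candidate ever evaluated is returned; with one generation this
    is the best of the initial population.

    Raises
    ------
    RuntimeError
        If the objective returns a non-finite value.
    """
    x0 = np.asarray(x0, float)
    n = x0.size
    lam = int(popsize)
    if lam < 2:
        raise ValueError("popsize must be >= 2")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    csig = (mueff + 2.0) / (n + mueff + 5.0)
    dsig = 1.0 + 2.0 * max(0.0, np.sqrt((mueff - 1.0) / (n + 1.0)) - 1.0) + csig
    cc = (4.0 + mueff / n) / (n + 4.0 + 2.0 * mueff / n)
    c1 = 2.0 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1.0 - c1, 2.0 * (mueff - 2.0 + 1.0 / mueff) / ((n + 2.0) ** 2 + mueff))
    chi_n = np.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n**2))

    rng = np.random.default_rng(seed)
    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    p_sig = np.zeros(n)
    p_c = np.zeros(n)

    best_x = mean.copy()
    best_f = np.inf
    trace: list[dict] = []
    n_eval = 0

    for gen in range(generations):
        evals, eigvec = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        sqrt_c = eigvec @ np.diag(np.sqrt(evals)) @ eigvec.T
        inv_sqrt_c = eigvec @ np.diag(1.0 / np.sqrt(evals)) @ eigvec.T

        zs = rng.standard_normal((lam, n))
        xs = mean + sigma * zs @ sqrt_c.T
        if lower is not None:
            xs = np.maximum(xs, lower)
        if upper is not None:
            xs = np.minimum(xs, upper)
        fs = np.empty(lam)
        for k in range(lam):
            fs[k] = f(xs[k], gen)
            n_eval += 1
            if not np.isfinite(fs[k]):
                raise RuntimeError(
                    f"objective returned non-finite value {fs[k]} at x={xs[k]}"
                )
        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = xs[order[0]].copy()

        sel = xs[order[:mu]]
        old_mean = mean
        mean = w @ sel
        y = (mean - old_mean) / sigma

        p_sig = (1.0 - csig) * p_sig + np.sqrt(csig * (2.0 - csig) * mueff) * (
            inv_sqrt_c @ y
        )
        h_sig = float(
            np.linalg.norm(p_sig)
            / np.sqrt(1.0 - (1.0 - csig) ** (2.0 * (gen + 1)))
            < (1.4 + 2.0 / (n + 1.0)) * chi_n
        )
        p_c = (1.0 - cc) * p_c + h_sig * np.sqrt(cc * (2.0 - cc) * mueff) * y

        arts = (sel - old_mean) / sigma
        C = (
            (1.0 - c1 - cmu) * C
            + c1 * (np.outer(p_c, p_c) + (1.0 - h_sig) * cc * (2.0 - cc) * C)
            + cmu * arts.T @ np.diag(w) @ arts
        )
        sigma *= float(np.exp((csig / dsig) * (np.linalg.norm(p_sig) / chi_n - 1.0)))

        trace.append(
            {
                "generation": gen,
                "best_f": float(fs[order[0]]),
                "best_f_ever": best_f,
                "mean_f": float(fs.mean()),
                "sigma": sigma,
            }
        )
    return CMAESResult(best_x=best_x, best_f=best_f, trace=trace, evaluations=n_eval)
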