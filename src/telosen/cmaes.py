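"""Covariance-matrix-adaptation evolution strategy (CMA-ES).

A compact (mu/mu_w, lambda)-CMA-ES with cumulative step-size adaptation
and rank-one plus rank-mu covariance updates, following the standard
formulation (Hansen's tutorial parameterization).  Box constraints are
handled by clipping candidates into the feasible box before evaluation;
the distribution mean is updated from the clipped candidates so it stays
feasible.  Sufficient for the low-dimensional (10-parameter), noisy,
derivative-free objective it is used on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.random import Generator


@dataclass
class CmaResult:
    x_best: np.ndarray
    f_best: float
    n_evals: int
    trace: list[float] = field(default_factory=list)  # best-so-far per generation
    converged: bool = False


def cma_es_minimize(
    f: Callable[[np.ndarray], float],
    x0: Sequence[float],
    sigma0: float,
    rng: Generator,
    bounds: Optional[tuple[Sequence[float], Sequence[float]]] = None,
    max_evals: int = 3000,
    popsize: Optional[int] = None,
    ftol: float = 0.0,
) -> CmaResult:
    """Minimize ``f`` starting from ``x0`` with initial step ``sigma0``."""
    mean = np.asarray(x0, dtype=float).copy()
    n = mean.size
    lo = hi = None
    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        mean = np.clip(mean, lo, hi)

    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)

    c_sigma = (mu_eff + 2) / (n + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    c_1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    sigma = float(sigma0)
    C = np.eye(n)
    p_sigma = np.zeros(n)
    p_c = np.zeros(n)

    x_best = mean.copy()
    f_best = np.inf
    n_evals = 0
    trace: list[float] = []
    gen = 0

    while n_evals < max_evals:
        # eigendecomposition each generation (n is small)
        C = (C + C.T) / 2
        eigvals, B = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-20)
        D = np.sqrt(eigvals)
        inv_sqrt_C = (B / D) @ B.T

        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T
        x = mean + sigma * y
        if lo is not None:
            x = np.clip(x, lo, hi)
            y = (x - mean) / sigma  # keep updates consistent with clipping

        fvals = np.empty(lam)
        for i in range(lam):
            fvals[i] = f(x[i])
        n_evals += lam

        order = np.argsort(fvals)
        if fvals[order[0]] < f_best:
            f_best = float(fvals[order[0]])
            x_best = x[order[0]].copy()
        trace.append(f_best)

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w
        if lo is not None:
            mean = np.clip(mean, lo, hi)

        p_sigma = (1 - c_sigma) * p_sigma + np.sqrt(
            c_sigma * (2 - c_sigma) * mu_eff
        ) * (inv_sqrt_C @ y_w)
        h_sigma = float(
            np.linalg.norm(p_sigma)
            / np.sqrt(1 - (1 - c_sigma) ** (2 * (gen + 1)))
            < (1.4 + 2 / (n + 1)) * chi_n
        )
        p_c = (1 - c_c) * p_c + h_sigma * np.sqrt(c_c * (2 - c_c) * mu_eff) * y_w

        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1 - c_1 - c_mu) * C
            + c_1 * (np.outer(p_c, p_c) + (1 - h_sigma) * c_c * (2 - c_c) * C)
            + c_mu * rank_mu
        )
        sigma *= float(
            np.exp((c_sigma / d_sigma) * (np.linalg.norm(p_sigma) / chi_n - 1))
        )
        sigma = min(sigma, 1e6)
        gen += 1

        if ftol > 0 and len(trace) > 20 and trace[-20] - trace[-1] < ftol:
            return CmaResult(x_best, f_best, n_evals, trace, converged=True)

    return CmaResult(x_best, f_best, n_evals, trace, converged=False)
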