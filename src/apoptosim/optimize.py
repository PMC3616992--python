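"""Shared evolution-strategy minimization engine.

Both the network calibration and the therapy search minimize penalized
least-squares costs with flat penalty plateaus (1000 per violated
constraint), for which population-based evolution strategies are the
standard tool.  This wraps scipy's differential evolution with optional
initial-point seeding and a Nelder-Mead polish, and records a convergence
trace so callers can report optimizer diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

__all__ = ["EvolveResult", "evolve"]


@dataclass
class EvolveResult:
    x: np.ndarray
    fun: float
    success: bool
    n_evals: int
    trace: list = field(default_factory=list)


def evolve(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    seed: int,
    x0: np.ndarray | None = None,
    init_points: Sequence[np.ndarray] | None = None,
    maxiter: int = 60,
    popsize: int = 12,
    polish: bool = True,
    tol: float = 1e-10,
) -> EvolveResult:
    """Minimize ``objective`` over box ``bounds``.

    ``x0`` and ``init_points`` seed the initial population (the rest is
    Latin-hypercube sampled), which matters on flat penalty plateaus where
    an unseeded population may never find the feasible basin.  Deterministic
    given ``seed``.
    """
    bounds = [tuple(b) for b in bounds]
    ndim = len(bounds)
    rng = np.random.default_rng(seed)
    npop = max(popsize, 5)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    pop = lo + (hi - lo) * _lhs(rng, npop, ndim)
    seeds = []
    if x0 is not None:
        seeds.append(np.clip(np.asarray(x0, float), lo, hi))
    if init_points is not None:
        seeds.extend(np.clip(np.asarray(p, float), lo, hi) for p in init_points)
    for i, s in enumerate(seeds[:npop]):
        pop[i] = s

    trace: list[float] = []

    def cb(intermediate_result):
        trace.append(float(intermediate_result.fun))

    res = differential_evolution(
        objective,
        bounds=bounds,
        init=pop,
        maxiter=maxiter,
        tol=tol,
        seed=int(rng.integers(0, 2**31 - 1)),
        polish=False,
        callback=cb,
        updating="immediate",
    )
    x, fun, nfev = res.x, float(res.fun), res.nfev
    if polish:
        local = minimize(objective, x, method="Nelder-Mead",
                         options={"maxfev": 400 * ndim, "xatol": 1e-9, "fatol": 1e-9})
        nfev += local.nfev
        if local.fun < fun:
            x, fun = np.clip(local.x, lo, hi), float(objective(np.clip(local.x, lo, hi)))
        trace.append(fun)
    return EvolveResult(x=np.asarray(x), fun=fun, success=True, n_evals=nfev, trace=trace)


def _lhs(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """Latin-hypercube sample in the unit cube."""
    u = (rng.random((n, d)) + np.arange(n)[:, None]) / n
    for j in range(d):
        rng.shuffle(u[:, j])
    return u
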