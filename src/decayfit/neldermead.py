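"""Nelder-Mead simplex minimizer with relative function-value termination.

The fitting protocol terminates when the simplex function values agree to a
*relative* tolerance::

    f_worst - f_best <= reltol * (|f_best| + reltol)

with an iteration cap, mirroring the convergence control of the classic
implementations used for lifetime fitting (R's ``optim``).  scipy's
Nelder-Mead offers only absolute ``xatol``/``fatol`` criteria, which behave
very differently when lifetimes span many orders of magnitude, so the loop
is implemented here: a generic Python version for arbitrary objectives and
a numba-compiled twin specialized to the biexponential likelihood (the
25-start direct fit is the hot path of the simulation study).  Simplex
construction and move coefficients follow the standard choices (reflection
1, expansion 2, contraction 0.5, shrink 0.5; initial simplex by 5%
coordinate perturbation).

Out-of-domain parameters are handled by objectives returning ``+inf``; the
simplex simply never accepts such points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NMResult", "nelder_mead"]

# move coefficients and initial-simplex perturbations (scipy's defaults)
RHO, CHI, PSI, SIGMA = 1.0, 2.0, 0.5, 0.5
NONZDELT, ZDELT = 0.05, 0.00025


@dataclass(frozen=True)
class NMResult:
    x: np.ndarray
    fun: float
    nit: int
    nfev: int
    converged: bool


def _initial_simplex(x0: np.ndarray) -> np.ndarray:
    n = x0.size
    sim = np.repeat(x0[None, :], n + 1, axis=0)
    for k in range(n):
        if sim[k + 1, k] != 0.0:
            sim[k + 1, k] *= 1.0 + NONZDELT
        else:
            sim[k + 1, k] = ZDELT
    return sim


def nelder_mead(
    fn: Callable[[np.ndarray], float],
    x0,
    max_iter: int = 10_000,
    reltol: float = 1e-8,
) -> NMResult:
    """Minimize ``fn`` from ``x0``; see module docstring for the protocol."""
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    sim = _initial_simplex(x0)
    fsim = np.array([fn(sim[i]) for i in range(n + 1)])
    nfev = n + 1
    order = np.argsort(fsim, kind="stable")
    sim, fsim = sim[order], fsim[order]

    nit = 0
    converged = False
    while nit < max_iter:
        if fsim[-1] - fsim[0] <= reltol * (abs(fsim[0]) + reltol):
            converged = True
            break
        nit += 1
        centroid = np.mean(sim[:-1], axis=0)
        xr = centroid + RHO * (centroid - sim[-1])
        fxr = fn(xr)
        nfev += 1
        if fxr < fsim[0]:
            xe = centroid + RHO * CHI * (centroid - sim[-1])
            fxe = fn(xe)
            nfev += 1
            if fxe < fxr:
                sim[-1], fsim[-1] = xe, fxe
            else:
                sim[-1], fsim[-1] = xr, fxr
        elif fxr < fsim[-2]:
            sim[-1], fsim[-1] = xr, fxr
        else:
            if fxr < fsim[-1]:  # outside contraction
                xc = centroid + PSI * RHO * (centroid - sim[-1])
                fxc = fn(xc)
                nfev += 1
                if fxc <= fxr:
                    sim[-1], fsim[-1] = xc, fxc
                else:
                    sim, fsim, nfev = _shrink(fn, sim, fsim, nfev)
            else:  # inside contraction
                xcc = centroid - PSI * (centroid - sim[-1])
                fxcc = fn(xcc)
                nfev += 1
                if fxcc < fsim[-1]:
                    sim[-1], fsim[-1] = xcc, fxcc
                else:
                    sim, fsim, nfev = _shrink(fn, sim, fsim, nfev)
        order = np.argsort(fsim, kind="stable")
        sim, fsim = sim[order], fsim[order]

    if not math.isfinite(fsim[0]):
        converged = False
    return NMResult(x=sim[0].copy(), fun=float(fsim[0]), nit=nit, nfev=nfev,
                    converged=converged)


def _shrink(fn, sim, fsim, nfev):
    for i in range(1, sim.shape[0]):
        sim[i] = sim[0] + SIGMA * (sim[i] - sim[0])
        fsim[i] = fn(sim[i])
        nfev += 1
    return sim, fsim, nfev
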