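"""numba-compiled Nelder-Mead specialized to the biexponential likelihood.

The direct biexponential fit runs 25 Nelder-Mead starts per dataset and
dominates the simulation-study runtime, so its objective and simplex loop
are compiled here.  The algorithm is line-for-line the one in
:mod:`decayfit.neldermead` (the generic Python implementation is the
reference; the test suite asserts agreement between the two).
"""

from __future__ import annotations

import numpy as np
from numba import njit

RHO, CHI, PSI, SIGMA = 1.0, 2.0, 0.5, 0.5
NONZDELT, ZDELT = 0.05, 0.00025


@njit(cache=True)
def _biexp_negll(theta, tau1_known, pts, y, n):
    """Binned multinomial -loglik of the biexponential; +inf outside domain.

    ``theta`` is (c, tau2) when tau1_known > 0, else (c, tau1, tau2); ``pts``
    holds the lower edges of the k occupied bins, then their upper edges,
    then the window edge.
    """
    c = theta[0]
    if tau1_known > 0.0:
        tau1 = tau1_known
        tau2 = theta[1]
    else:
        tau1 = theta[1]
        tau2 = theta[2]
    if not (0.0 <= c <= 1.0) or tau1 <= 0.0 or tau2 <= 0.0:
        return np.inf
    for v in theta:
        if not np.isfinite(v):
            return np.inf
    k = y.size
    total = -c * np.expm1(-pts[2 * k] / tau1) - (1.0 - c) * np.expm1(
        -pts[2 * k] / tau2
    )
    if not (total > 0.0) or not np.isfinite(total):
        return np.inf
    out = n * np.log(total)
    for i in range(k):
        lo = -c * np.expm1(-pts[i] / tau1) - (1.0 - c) * np.expm1(-pts[i] / tau2)
        hi = -c * np.expm1(-pts[k + i] / tau1) - (1.0 - c) * np.expm1(
            -pts[k + i] / tau2
        )
        d = hi - lo
        if d <= 0.0:
            return np.inf
        out -= y[i] * np.log(d)
    return out


@njit(cache=True)
def nm_biexp(x0, tau1_known, pts, y, n, max_iter, reltol):
    """Nelder-Mead on the biexponential likelihood; see neldermead module.

    Returns (x_best, f_best, nit, nfev, converged).
    """
    d = x0.size
    sim = np.empty((d + 1, d))
    for i in range(d + 1):
        for j in range(d):
            sim[i, j] = x0[j]
    for k in range(d):
        if sim[k + 1, k] != 0.0:
            sim[k + 1, k] *= 1.0 + NONZDELT
        else:
            sim[k + 1, k] = ZDELT
    fsim = np.empty(d + 1)
    for i in range(d + 1):
        fsim[i] = _biexp_negll(sim[i], tau1_known, pts, y, n)
    nfev = d + 1
    order = np.argsort(fsim, kind="mergesort")
    sim, fsim = sim[order], fsim[order]

    nit = 0
    converged = False
    while nit < max_iter:
        if fsim[-1] - fsim[0] <= reltol * (abs(fsim[0]) + reltol):
            converged = True
            break
        nit += 1
        centroid = np.zeros(d)
        for i in range(d):
            for j in range(d):
                centroid[j] += sim[i, j]
        centroid /= d
        xr = centroid + RHO * (centroid - sim[-1])
        fxr = _biexp_negll(xr, tau1_known, pts, y, n)
        nfev += 1
        if fxr < fsim[0]:
            xe = centroid + RHO * CHI * (centroid - sim[-1])
            fxe = _biexp_negll(xe, tau1_known, pts, y, n)
            nfev += 1
            if fxe < fxr:
                sim[-1], fsim[-1] = xe, fxe
            else:
                sim[-1], fsim[-1] = xr, fxr
        elif fxr < fsim[-2]:
            sim[-1], fsim[-1] = xr, fxr
        else:
            if fxr < fsim[-1]:
                xc = centroid + PSI * RHO * (centroid - sim[-1])
                fxc = _biexp_negll(xc, tau1_known, pts, y, n)
                nfev += 1
                if fxc <= fxr:
                    sim[-1], fsim[-1] = xc, fxc
                else:
                    for i in range(1, d + 1):
                        sim[i] = sim[0] + SIGMA * (sim[i] - sim[0])
                        fsim[i] = _biexp_negll(sim[i], tau1_known, pts, y, n)
                        nfev += 1
            else:
                xcc = centroid - PSI * (centroid - sim[-1])
                fxcc = _biexp_negll(xcc, tau1_known, pts, y, n)
                nfev += 1
                if fxcc < fsim[-1]:
                    sim[-1], fsim[-1] = xcc, fxcc
                else:
                    for i in range(1, d + 1):
                        sim[i] = sim[0] + SIGMA * (sim[i] - sim[0])
                        fsim[i] = _biexp_negll(sim[i], tau1_known, pts, y, n)
                        nfev += 1
        order = np.argsort(fsim, kind="mergesort")
        sim, fsim = sim[order], fsim[order]

    if not np.isfinite(fsim[0]):
        converged = False
    return sim[0].copy(), fsim[0], nit, nfev, converged
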