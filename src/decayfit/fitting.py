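"""Maximum-likelihood fitting and gamma-to-biexponential conversion.

The binned counts are multinomial with window-normalized bin probabilities,
so up to an additive constant the negative log-likelihood of a model with
cdf ``F`` is::

    n log F(delta*m) - sum_j y_j log[F(delta*j) - F(delta*(j-1))]

Both the gamma fit (the first stage of the gamma-conversion estimator) and
the direct biexponential fit minimize this objective with Nelder-Mead in
the models' natural parameterization, terminating on a relative
function-value tolerance (see :mod:`decayfit.neldermead`).  Domain
constraints (``0 <= c <= 1``, ``0 < alpha <= 1``, positive lifetimes) are
enforced by the objective returning ``+inf`` outside the domain, so the
simplex never accepts an infeasible point and no penalty terms distort the
likelihood values.

The second stage converts fitted gamma parameters ``(alpha, tau_gamma)``
into biexponential ones by matching raw moments (equivalently, derivatives
of the moment generating functions at zero): two moments when ``tau1`` is
known, three when it is not.  Conversions that land outside the physical
parameter space (``c`` outside [0, 1], non-positive lifetimes) are returned
with ``valid=False`` and the raw values preserved, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special

from ._fastpath import nm_biexp
from .exceptions import EmptyHistogramError, NoSolutionError, ParameterDomainError
from .models import BiexpParams, GammaParams, Histogram, gamma_moments
from .neldermead import nelder_mead

__all__ = [
    "OptimizerOptions",
    "FitResult",
    "ConversionResult",
    "neg_loglik",
    "fit_gamma",
    "fit_biexp_direct",
    "convert_two_moment",
    "convert_three_moment",
    "moment_match_numeric",
]

N_DIRECT_STARTS = 25  # c starts at i/26, i = 1..25


@dataclass(frozen=True)
class OptimizerOptions:
    """Nelder-Mead settings: iteration cap and relative convergence tolerance.

    The search stops when the simplex function values agree to
    ``reltol * (|f_best| + reltol)`` or after ``max_iter`` iterations.
    """

    max_iter: int = 10_000
    reltol: float = 1e-8


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: GammaParams | BiexpParams | None
    converged: bool
    neg_loglik: float
    n_iterations: int
    n_starts_tried: int = 1
    start_index_of_best: int = 0


@dataclass(frozen=True)
class ConversionResult:
    """Gamma-to-biexponential moment-matching output.

    ``raw_tau2``/``raw_c`` (and ``raw_tau1`` for the three-moment path) hold
    the unclipped solution; ``biexp`` is populated only when it is physical.
    ``degenerate`` marks the tau_gamma == tau1 monoexponential branch.
    """

    biexp: BiexpParams | None
    valid: bool
    raw_tau2: float
    raw_c: float
    raw_tau1: float | None = None
    degenerate: bool = False


def neg_loglik(model_cdf: Callable[[np.ndarray], np.ndarray], h: Histogram) -> float:
    """Binned multinomial negative log-likelihood (additive constant taken as 0).

    Returns ``+inf`` (not an exception) when any occupied bin has zero model
    probability, so optimizers treat such parameters as infeasible.
    """
    b = h.binspec
    cdf_vals = np.asarray(model_cdf(b.edges), dtype=float)
    total = cdf_vals[-1]
    if not (total > 0) or not np.all(np.isfinite(cdf_vals)):
        return math.inf
    diffs = np.diff(cdf_vals)
    occupied = h.counts > 0
    d_occ = diffs[occupied]
    if np.any(d_occ <= 0):
        return math.inf
    return float(h.n * math.log(total) - np.dot(h.counts[occupied], np.log(d_occ)))


# ---------------------------------------------------------------------------
# fast objective evaluators (precompute occupied-bin edges once per histogram)


class _BinnedData:
    """Histogram unpacked for repeated likelihood evaluation."""

    def __init__(self, h: Histogram):
        b = h.binspec
        j = h.nonzero_bins()
        self.n = h.n
        self.window = b.window
        self.y = h.counts[j - 1].astype(float)
        # cdf evaluation points: lower edges, upper edges, window
        self.pts = np.concatenate((b.delta * (j - 1), b.delta * j, [self.window]))
        self.k = j.size
        self.mean_bin_index = float(np.dot(j, self.y) / self.n)
        self.delta = b.delta

    def negloglik_from_cdf_values(self, f: np.ndarray) -> float:
        total = f[-1]
        if not (total > 0):
            return math.inf
        diffs = f[self.k : 2 * self.k] - f[: self.k]
        if np.any(diffs <= 0) or not np.isfinite(total):
            return math.inf
        return float(self.n * math.log(total) - np.dot(self.y, np.log(diffs)))


def _gamma_objective(data: _BinnedData) -> Callable[[np.ndarray], float]:
    pts = data.pts

    def obj(theta: np.ndarray) -> float:
        alpha, tau_gamma = theta
        if not (0.0 < alpha <= 1.0) or tau_gamma <= 0.0 or not np.all(
            np.isfinite(theta)
        ):
            return math.inf
        f = special.gammainc(alpha, pts * (alpha / tau_gamma))
        return data.negloglik_from_cdf_values(f)

    return obj


def _biexp_objective(
    data: _BinnedData, tau1_known: float | None
) -> Callable[[np.ndarray], float]:
    """Pure-Python twin of the compiled objective (reference and tests)."""
    pts = data.pts

    def obj(theta: np.ndarray) -> float:
        if tau1_known is None:
            c, tau1, tau2 = theta
        else:
            c, tau2 = theta
            tau1 = tau1_known
        if (
            not (0.0 <= c <= 1.0)
            or tau1 <= 0.0
            or tau2 <= 0.0
            or not np.all(np.isfinite(np.asarray(theta)))
        ):
            return math.inf
        f = -c * np.expm1(-pts / tau1) - (1.0 - c) * np.expm1(-pts / tau2)
        return data.negloglik_from_cdf_values(f)

    return obj


def _check_fittable(h: Histogram) -> _BinnedData:
    data = _BinnedData(h)
    if data.n < 2 or data.k < 2:
        raise EmptyHistogramError(
            "fitting requires at least 2 photons spread over at least 2 bins"
        )
    return data


def fit_gamma(h: Histogram, opts: OptimizerOptions | None = None) -> FitResult:
    """Fit the gamma decay model by Nelder-Mead from a single start.

    Initialization follows the simulation protocol: ``alpha = 0.5`` and
    ``tau_gamma`` equal to the mean occupied bin index scaled by the bin
    width.
    """
    opts = opts or OptimizerOptions()
    data = _check_fittable(h)
    tau0 = data.delta * data.mean_bin_index
    res = nelder_mead(
        _gamma_objective(data), (0.5, tau0),
        max_iter=opts.max_iter, reltol=opts.reltol,
    )
    params = None
    converged = res.converged
    alpha, tau_gamma = (float(v) for v in res.x)
    if converged and 0.0 < alpha <= 1.0 and tau_gamma > 0:
        params = GammaParams(alpha=alpha, tau_gamma=tau_gamma)
    else:
        converged = False
    return FitResult(
        params=params,
        converged=converged,
        neg_loglik=float(res.fun),
        n_iterations=int(res.nit),
    )


def fit_biexp_direct(
    h: Histogram,
    tau1_known: float | None = None,
    opts: OptimizerOptions | None = None,
) -> FitResult:
    """Fit the biexponential directly by multi-start Nelder-Mead.

    Runs 25 starts with ``c`` on the even grid i/26 (i = 1..25) and every
    lifetime initialized to the mean occupied bin index times the bin width.
    The best converged start (by objective; ties to the lowest start index)
    wins; the fit counts as failed only when all starts fail.
    """
    opts = opts or OptimizerOptions()
    if tau1_known is not None and not (
        math.isfinite(tau1_known) and tau1_known > 0
    ):
        raise ParameterDomainError("tau1_known must be finite and > 0")
    data = _check_fittable(h)
    tau0 = data.delta * data.mean_bin_index
    tau1_flag = tau1_known if tau1_known is not None else -1.0

    best: tuple[float, int, np.ndarray] | None = None
    best_any: tuple[float, int, np.ndarray] | None = None
    total_iter = 0
    for i in range(1, N_DIRECT_STARTS + 1):
        c0 = i / (N_DIRECT_STARTS + 1)
        if tau1_known is None:
            theta0 = np.array([c0, tau0, tau0])
        else:
            theta0 = np.array([c0, tau0])
        x, fun, nit, _, converged = nm_biexp(
            theta0, tau1_flag, data.pts, data.y, float(data.n),
            opts.max_iter, opts.reltol,
        )
        total_iter += int(nit)
        if converged and (best is None or fun < best[0]):
            best = (float(fun), i - 1, x)
        if math.isfinite(fun) and (best_any is None or fun < best_any[0]):
            best_any = (float(fun), i - 1, x)

    chosen = best if best is not None else best_any
    if chosen is None:
        return FitResult(
            params=None,
            converged=False,
            neg_loglik=math.inf,
            n_iterations=total_iter,
            n_starts_tried=N_DIRECT_STARTS,
            start_index_of_best=-1,
        )
    fun, idx, x = chosen
    if tau1_known is None:
        params = BiexpParams(c=float(x[0]), tau1=float(x[1]), tau2=float(x[2]))
    else:
        params = BiexpParams(c=float(x[0]), tau1=float(tau1_known), tau2=float(x[1]))
    return FitResult(
        params=params,
        converged=best is not None,
        neg_loglik=fun,
        n_iterations=total_iter,
        n_starts_tried=N_DIRECT_STARTS,
        start_index_of_best=idx,
    )


# ---------------------------------------------------------------------------
# moment-matching conversions

#: relative |tau_gamma - tau1| below which the two-moment system is singular
DEGENERACY_RTOL = 1e-9


def convert_two_moment(g: GammaParams, tau1: float) -> ConversionResult:
    """Convert gamma estimates to ``(c, tau2)`` with ``tau1`` known.

    Matches the first two raw moments.  Closed form::

        tau2 = (2 a tg t1 - (1+a) tg^2) / (2 a t1 - 2 a tg)
        c    = (1-a) tg^2 / (2 a t1^2 - 4 a tg t1 + (1+a) tg^2)

    With ``alpha = 1`` (the gamma is monoexponential) this collapses to
    ``c = 0, tau2 = tau_gamma`` exactly, which is returned analytically.
    """
    if not (math.isfinite(tau1) and tau1 > 0):
        raise ParameterDomainError("tau1 must be finite and > 0")
    a, tg = g.alpha, g.tau_gamma
    if abs(tg - tau1) < DEGENERACY_RTOL * tau1:
        # moment system is singular: the gamma mean sits on the known lifetime
        return ConversionResult(
            biexp=BiexpParams(c=1.0, tau1=tau1, tau2=tau1),
            valid=False,
            raw_tau2=math.nan,
            raw_c=1.0,
            degenerate=True,
        )
    if a == 1.0:
        return ConversionResult(
            biexp=BiexpParams(c=0.0, tau1=tau1, tau2=tg),
            valid=True,
            raw_tau2=tg,
            raw_c=0.0,
        )
    tau2 = (2 * a * tg * tau1 - (1 + a) * tg**2) / (2 * a * tau1 - 2 * a * tg)
    c = (1 - a) * tg**2 / (2 * a * tau1**2 - 4 * a * tg * tau1 + (1 + a) * tg**2)
    valid = (
        math.isfinite(tau2)
        and math.isfinite(c)
        and tau2 > 0
        and 0.0 <= c <= 1.0
    )
    biexp = BiexpParams(c=c, tau1=tau1, tau2=tau2) if valid else None
    return ConversionResult(biexp=biexp, valid=valid, raw_tau2=tau2, raw_c=c)


def convert_three_moment(g: GammaParams) -> ConversionResult:
    """Convert gamma estimates to ``(c, tau1, tau2)`` by matching three moments.

    Solves the k = 1, 2, 3 raw-moment system numerically (Hankel/Prony
    reduction; see :func:`moment_match_numeric`).  Requires ``alpha < 1``
    strictly — at ``alpha = 1`` the gamma is monoexponential and the
    two-component system is degenerate.  Components are labelled so that
    ``tau2 >= tau1``.
    """
    if g.alpha >= 1.0:
        raise ParameterDomainError(
            "three-moment conversion requires alpha < 1 strictly"
        )
    targets = [gamma_moments(g, k) for k in (1, 2, 3)]
    try:
        weights, lifetimes = moment_match_numeric(targets, n_components=2)
    except NoSolutionError:
        return ConversionResult(
            biexp=None, valid=False, raw_tau2=math.nan, raw_c=math.nan,
            raw_tau1=math.nan,
        )
    order = np.argsort(lifetimes)
    tau1, tau2 = (float(lifetimes[i]) for i in order)
    c = float(weights[order[0]])
    valid = (
        all(map(math.isfinite, (tau1, tau2, c)))
        and tau1 > 0
        and tau2 > 0
        and 0.0 <= c <= 1.0
    )
    biexp = BiexpParams(c=c, tau1=tau1, tau2=tau2) if valid else None
    return ConversionResult(
        biexp=biexp, valid=valid, raw_tau2=tau2, raw_c=c, raw_tau1=tau1
    )


def _moment_system_with_known(
    e: np.ndarray, n_components: int, known: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the reduced-moment system when some lifetimes are fixed."""
    m_free = n_components - known.size
    n_w = n_components - 1  # weights minus the sum-to-one constraint

    def residual(z: np.ndarray) -> np.ndarray:
        w_free = z[:n_w]
        lifetimes = np.concatenate((known, z[n_w:]))
        weights = np.concatenate((w_free, [1.0 - w_free.sum()]))
        # relative residuals: the raw power moments span many decades
        return np.array(
            [np.dot(weights, lifetimes ** (k + 1)) / e[k] - 1.0
             for k in range(e.size)]
        )

    sol = None
    # Newton-type solvers are start-sensitive here; sweep a small grid of
    # weight/lifetime initializations until the residual check passes
    for w0 in (0.5, 0.1, 0.9):
        for scale0 in (1.0, 0.25, 0.5, 2.0, 4.0):
            z0 = np.concatenate(
                (np.full(n_w, w0), np.full(m_free, scale0 * e[0]))
            )
            cand = optimize.root(residual, z0, method="hybr")
            if (
                cand.success
                and np.all(np.isfinite(cand.x))
                and np.max(np.abs(residual(cand.x))) <= 1e-9
            ):
                sol = cand
                break
        if sol is not None:
            break
    if sol is None:
        raise NoSolutionError("moment system root-finding failed from all starts")
    w_free = sol.x[:n_w]
    weights = np.concatenate((w_free, [1.0 - w_free.sum()]))
    lifetimes = np.concatenate((known, sol.x[n_w:]))
    return weights, lifetimes


def moment_match_numeric(
    target_moments: Sequence[float],
    n_components: int,
    known_lifetimes: Sequence[float] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Find an M-component exponential mixture matching raw moments.

    ``target_moments`` are raw moments ``E[X^k]`` for k = 1..K with
    ``K = 2M - 1``, reduced by one per known lifetime.  Dividing by ``k!``
    turns them into power moments ``e_k = sum_i w_i tau_i^k`` of the
    discrete mixing measure over lifetimes; with no lifetimes known, the
    lifetimes are the roots of the Hankel (Prony) recurrence and the weights
    follow from a Vandermonde solve — the standard two-point Gauss
    quadrature construction.  With known lifetimes the reduced system is
    solved by a Newton-type root finder.

    Returns ``(weights, lifetimes)``; known lifetimes occupy the leading
    positions.  Raises :class:`NoSolutionError` when no real solution
    exists or the root finder fails.
    """
    m = int(n_components)
    if m < 1:
        raise ValueError("n_components must be >= 1")
    known = np.asarray(known_lifetimes, dtype=float)
    expected_k = 2 * m - 1 - known.size
    moments = np.asarray(target_moments, dtype=float)
    if moments.size != expected_k:
        raise ValueError(
            f"need K = {expected_k} moments for M = {m} components with "
            f"{known.size} known lifetime(s), got {moments.size}"
        )
    e = moments / special.factorial(np.arange(1, moments.size + 1))

    if m == 1:
        return np.array([1.0]), np.array([e[0]])
    if known.size:
        return _moment_system_with_known(e, m, known)

    # Prony: power moments e_0..e_{2M-1} of the mixing measure determine a
    # recurrence e_k = sum_i a_i e_{k-i}; the lifetimes are the roots of the
    # associated monic polynomial.
    e_full = np.concatenate(([1.0], e))
    hankel = np.array([[e_full[k - i] for i in range(1, m + 1)] for k in range(m, 2 * m)])
    rhs = e_full[m : 2 * m]
    try:
        a = np.linalg.solve(hankel, rhs)
    except np.linalg.LinAlgError as exc:
        raise NoSolutionError(f"singular moment system: {exc}") from exc
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly)
    if np.any(np.abs(roots.imag) > 1e-9 * np.max(np.abs(roots.real))):
        raise NoSolutionError("moment system has complex lifetimes")
    lifetimes = np.sort(roots.real)
    vander = np.vander(lifetimes, m, increasing=True).T  # rows k=0..M-1
    try:
        weights = np.linalg.solve(vander, e_full[:m])
    except np.linalg.LinAlgError as exc:
        raise NoSolutionError(f"coincident lifetimes: {exc}") from exc
    return weights, lifetimes
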