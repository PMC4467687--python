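"""Decay-curve models for binned single-photon (TCSPC) data.

Two models for the photon delay time X (picoseconds):

* the **biexponential** mixture with weight ``c`` on lifetime ``tau1`` and
  weight ``1 - c`` on ``tau2``,

  ``f(x) = (c/tau1) exp(-x/tau1) + ((1-c)/tau2) exp(-x/tau2)``;

* the **gamma** decay model with shape ``alpha`` and *mean lifetime*
  ``tau_gamma`` (scale = ``tau_gamma/alpha``),

  ``g(x) = x^(alpha-1) exp(-alpha x / tau_gamma) / ((tau_gamma/alpha)^alpha
  Gamma(alpha))``.

With ``alpha = 1`` the gamma model is exactly the monoexponential with
lifetime ``tau_gamma``; the shape is restricted to ``0 < alpha <= 1`` so the
density is completely monotone (a continuous mixture of exponentials), the
regime relevant to fluorescence decay.

Counts in ``m`` bins of width ``delta`` are multinomial with bin
probabilities obtained from the model cdf, conditioned on the observation
window ``[0, delta*m)``::

    p_j = [F(delta*j) - F(delta*(j-1))] / F(delta*m),   j = 1..m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special

from .exceptions import (
    DegenerateWindowError,
    EmptyHistogramError,
    ParameterDomainError,
)

__all__ = [
    "BiexpParams",
    "GammaParams",
    "BinSpec",
    "Histogram",
    "biexp_pdf",
    "biexp_cdf",
    "gamma_pdf",
    "gamma_cdf",
    "bin_probabilities",
    "biexp_moments",
    "gamma_moments",
]


def _require_finite_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ParameterDomainError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class BiexpParams:
    """Two-component exponential mixture: weight ``c`` on ``tau1`` (ps)."""

    c: float
    tau1: float
    tau2: float

    def __post_init__(self):
        if not (math.isfinite(self.c) and 0.0 <= self.c <= 1.0):
            raise ParameterDomainError(f"c must lie in [0, 1], got {self.c!r}")
        _require_finite_positive("tau1", self.tau1)
        _require_finite_positive("tau2", self.tau2)

    @property
    def mean(self) -> float:
        return self.c * self.tau1 + (1.0 - self.c) * self.tau2


@dataclass(frozen=True)
class GammaParams:
    """Gamma decay model: shape ``alpha`` in (0, 1], mean lifetime ``tau_gamma`` (ps)."""

    alpha: float
    tau_gamma: float

    def __post_init__(self):
        if not (math.isfinite(self.alpha) and 0.0 < self.alpha <= 1.0):
            raise ParameterDomainError(f"alpha must lie in (0, 1], got {self.alpha!r}")
        _require_finite_positive("tau_gamma", self.tau_gamma)

    @property
    def scale(self) -> float:
        """Gamma scale parameter tau_gamma / alpha (ps)."""
        return self.tau_gamma / self.alpha


@dataclass(frozen=True)
class BinSpec:
    """Uniform binning: ``m`` bins of width ``delta`` ps covering [0, delta*m)."""

    delta: float
    m: int

    def __post_init__(self):
        _require_finite_positive("delta", self.delta)
        if int(self.m) != self.m or self.m < 1:
            raise ParameterDomainError(f"m must be an integer >= 1, got {self.m!r}")
        object.__setattr__(self, "m", int(self.m))

    @property
    def window(self) -> float:
        """Right edge of the observation window, delta*m (ps)."""
        return self.delta * self.m

    @property
    def edges(self) -> np.ndarray:
        """Bin edges 0, delta, ..., delta*m (length m + 1)."""
        return self.delta * np.arange(self.m + 1)


@dataclass(frozen=True, eq=False)
class Histogram:
    """Photon counts per bin. ``counts[j-1]`` is the count in bin j (1-based)."""

    counts: np.ndarray
    binspec: BinSpec
    n: int = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.shape[0] != self.binspec.m:
            raise ParameterDomainError(
                f"counts must be a 1-d array of length m={self.binspec.m}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise ParameterDomainError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ParameterDomainError("counts must be non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n", int(counts.sum()))
        if self.n == 0:
            raise EmptyHistogramError("histogram contains no photons")

    def __eq__(self, other):
        if not isinstance(other, Histogram):
            return NotImplemented
        return self.binspec == other.binspec and np.array_equal(
            self.counts, other.counts
        )

    def nonzero_bins(self) -> np.ndarray:
        """1-based indices of bins with at least one photon."""
        return np.flatnonzero(self.counts) + 1


def _as_float_array(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def biexp_pdf(x, p: BiexpParams):
    """Biexponential density at delay time(s) ``x`` >= 0 (units 1/ps)."""
    arr, scalar = _as_float_array(x)
    if np.any(arr < 0):
        raise ValueError("delay times must be >= 0")
    out = (p.c / p.tau1) * np.exp(-arr / p.tau1) + ((1.0 - p.c) / p.tau2) * np.exp(
        -arr / p.tau2
    )
    return float(out) if scalar else out


def biexp_cdf(x, p: BiexpParams):
    """Biexponential cdf ``c(1-e^(-x/tau1)) + (1-c)(1-e^(-x/tau2))``."""
    arr, scalar = _as_float_array(x)
    if np.any(arr < 0):
        raise ValueError("delay times must be >= 0")
    out = -p.c * np.expm1(-arr / p.tau1) - (1.0 - p.c) * np.expm1(-arr / p.tau2)
    return float(out) if scalar else out


def gamma_pdf(x, g: GammaParams):
    """Gamma-decay density at ``x``; diverges (returns ``inf``) at x=0 for alpha<1."""
    arr, scalar = _as_float_array(x)
    if np.any(arr < 0):
        raise ValueError("delay times must be >= 0")
    scale = g.scale
    with np.errstate(divide="ignore"):
        out = (
            arr ** (g.alpha - 1.0)
            * np.exp(-arr / scale)
            / (scale**g.alpha * special.gamma(g.alpha))
        )
    return float(out) if scalar else out


def gamma_cdf(x, g: GammaParams):
    """Gamma-decay cdf: regularized lower incomplete gamma of alpha*x/tau_gamma."""
    arr, scalar = _as_float_array(x)
    if np.any(arr < 0):
        raise ValueError("delay times must be >= 0")
    out = special.gammainc(g.alpha, arr / g.scale)
    return float(out) if scalar else out


def bin_probabilities(dist_cdf: Callable[[np.ndarray], np.ndarray], b: BinSpec):
    """Window-normalized bin probabilities from a cdf.

    ``p_j = [F(delta*j) - F(delta*(j-1))] / F(delta*m)``; the vector is
    renormalized to sum to one exactly, so floating-point conservation holds
    by construction.
    """
    cdf_vals = np.asarray(dist_cdf(b.edges), dtype=float)
    total = cdf_vals[-1]
    if not (total > 0):
        raise DegenerateWindowError(
            "model assigns zero probability to the observation window"
        )
    diffs = np.diff(cdf_vals)
    if np.any(diffs < -1e-12 * total):
        raise ValueError("cdf is not monotone non-decreasing on the bin edges")
    diffs = np.maximum(diffs, 0.0)
    return diffs / diffs.sum()


def biexp_moments(p: BiexpParams, k: int) -> float:
    """Raw moment E[X^k] = k! (c tau1^k + (1-c) tau2^k) for k in {1, 2, 3}."""
    if k not in (1, 2, 3):
        raise ValueError(f"moment order must be 1, 2 or 3, got {k!r}")
    return math.factorial(k) * (p.c * p.tau1**k + (1.0 - p.c) * p.tau2**k)


def gamma_moments(g: GammaParams, k: int) -> float:
    """Raw moment E[X^k] = tau_gamma^k * prod_{i=0}^{k-1}(alpha+i) / alpha^k."""
    if k not in (1, 2, 3):
        raise ValueError(f"moment order must be 1, 2 or 3, got {k!r}")
    prod = 1.0
    for i in range(k):
        prod *= g.alpha + i
    return g.tau_gamma**k * prod / g.alpha**k
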