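"""Truncated Grunwald-Letnikov (GL) fractional-derivative kernel.

The GL derivative of order :math:`\\nu` is the limit of a weighted backward
sum,

.. math::

    D^{\\nu} f(t) = \\lim_{\\Delta t \\to 0} \\frac{1}{\\Delta t^{\\nu}}
        \\sum_{k=0}^{N} (-1)^k \\binom{\\nu}{k} f(t - k \\Delta t),

which becomes directly implementable on sampled signals once the sum is
truncated at a finite memory depth ``N``.  The binomial weights
:math:`w_k = (-1)^k \\binom{\\nu}{k}` carry the hereditary character of the
operator: for non-integer order they decay only algebraically
(:math:`|w_k| \\sim k^{-\\nu-1}`), so the operator genuinely remembers the
signal's past, while for integer order the weights truncate to the familiar
finite-difference stencil.

Only the left-sided (causal) derivative is provided: the value at the newest
sample depends on present and past samples alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["GLWeights", "SampledSignal", "gl_weights", "gl_derivative"]


@dataclass(frozen=True)
class GLWeights:
    """Truncated GL binomial weight table for one fractional order.

    Attributes
    ----------
    order : float
        The (real, non-negative) order of the derivative.
    n_terms : int
        Truncation depth ``N``; the table holds ``N + 1`` weights.
    weights : numpy.ndarray
        ``w_0 .. w_N`` with ``w_0 = 1`` and
        ``w_k = w_{k-1} * (1 - (order + 1) / k)``.
    """

    order: float
    n_terms: int
    weights: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.n_terms + 1


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled signal, newest sample last."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("signal must be a non-empty 1-D sequence")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be finite and positive, got {self.dt}")
        object.__setattr__(self, "values", values)


@lru_cache(maxsize=256)
def _weight_table(order: float, n_terms: int) -> np.ndarray:
    w = np.empty(n_terms + 1)
    w[0] = 1.0
    for k in range(1, n_terms + 1):
        w[k] = w[k - 1] * (1.0 - (order + 1.0) / k)
    w.setflags(write=False)
    return w


def gl_weights(order: float, n_terms: int) -> GLWeights:
    """Compute the truncated GL weight table for ``order``.

    The weights equal :math:`(-1)^k \\Gamma(\\nu+1) / (\\Gamma(k+1)
    \\Gamma(\\nu-k+1))` but are evaluated by the multiplicative recurrence
    ``w_k = w_{k-1} (1 - (order+1)/k)``, which is exact where the Gamma form
    is defined and remains well-defined at integer order where the Gamma form
    hits poles.  Tables are cached per ``(order, n_terms)`` pair: the
    coefficients need to be computed only once for a given medium.

    Parameters
    ----------
    order : float
        Fractional order (finite; negative orders are out of scope).
    n_terms : int
        Truncation depth ``N >= 0``.

    Returns
    -------
    GLWeights
    """
    if not np.isfinite(order):
        raise ValueError(f"order must be finite, got {order}")
    if order < 0:
        raise ValueError("negative orders are not supported")
    n_terms = int(n_terms)
    if n_terms < 0:
        raise ValueError(f"n_terms must be >= 0, got {n_terms}")
    return GLWeights(order=float(order), n_terms=n_terms,
                     weights=_weight_table(float(order), n_terms))


def gl_derivative(signal: SampledSignal | np.ndarray, order: float,
                  weights: GLWeights | None = None,
                  dt: float | None = None):
    """Left-sided truncated GL derivative at the newest sample.

    Returns ``(1/dt**order) * sum_k w_k * f(t - k*dt)``.  Histories shorter
    than ``n_terms + 1`` are implicitly zero-padded on the old end (the
    signal is assumed at rest before recording started, matching FDTD
    initialization).

    Parameters
    ----------
    signal : SampledSignal or array_like
        Samples, newest last.  If an array is passed, ``dt`` must be given.
    order : float
        Fractional order; must match ``weights.order`` when a table is
        supplied.
    weights : GLWeights, optional
        Precomputed table.  By default a table spanning the whole available
        history is computed (and cached).
    dt : float, optional
        Sample spacing when ``signal`` is a bare array.
    """
    if not isinstance(signal, SampledSignal):
        if dt is None:
            raise ValueError("dt is required when passing a bare array")
        signal = SampledSignal(np.asarray(signal), float(dt))
    values = signal.values
    if weights is None:
        weights = gl_weights(order, len(values) - 1)
    elif weights.order != order:
        raise ValueError(
            f"weight table is for order {weights.order}, requested {order}")
    w = weights.weights
    n_avail = min(len(w), len(values))
    # newest sample pairs with w_0; older samples beyond the history are zero
    tail = values[::-1][:n_avail]
    return np.dot(w[:n_avail], tail) / signal.dt ** order
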