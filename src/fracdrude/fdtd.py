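"""1-D Yee-grid FDTD with the fractional Drude medium as an ADE.

The electric and magnetic fields leapfrog on a staggered grid in normalized
units ``c = dx = eps0 = 1`` (the time step then equals the Courant number,
and the nondispersive 1-D stability limit sits at ``dt = 1``).  The medium
polarization ``P`` evolves by an auxiliary difference equation obtained by
discretizing

    gamma_alpha * D^(alpha+1) P + gamma_beta * D^beta P = omega_p^2 * E

with truncated Grunwald-Letnikov sums: the order-(alpha+1) operator as a
first difference of order-alpha sums, and the order-beta operator as the
two-sample average of order-beta sums.  Solving for the newest value yields
a recursion

    P_{t+1} = coef_P_t * P_t + coef_P_tm1 * P_{t-1}
              + (memory terms over P_{t-2} .. P_{t-N}) + coef_E * E

whose ``N`` retained past values implement the hereditary character of the
fractional derivative.  At ``alpha = beta = 1`` every memory weight beyond
``P_{t-1}`` vanishes and the recursion reduces exactly to the standard
Drude ADE.

Two field couplings are provided.  The default, ``"trapezoidal"``, drives
the polarization with the time-centred average ``(E^n + E^{n+1})/2`` and
solves the P and E updates jointly (a scalar linear solve per cell); it is
stable through ``dt = 1.0`` with this medium.  The literal ``"explicit"``
coupling drives with ``E^n``; it is simpler but loses stability slightly
below the vacuum Courant limit, because the Drude permittivity is below one
at high frequency.  Both reduce to classic Drude ADE forms at integer
orders.

Boundaries are first-order Mur (absorbing); sources are soft (additive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dispersion import FractionalDrudeMedium
from .gl import gl_weights

__all__ = [
    "ADECoefficients", "Grid1D", "SourceSpec", "ProbeRecord", "RunResult",
    "ade_coefficients", "step", "run",
]

COUPLINGS = ("trapezoidal", "explicit")


@dataclass(frozen=True)
class ADECoefficients:
    """Precomputed polarization-update coefficients and memory weights.

    ``history_coefs[j]`` multiplies ``P_{t-j}`` (j = 0 .. N) in the update;
    ``history_coefs[0]`` is ``coef_P_t`` and ``history_coefs[1]`` is
    ``coef_P_tm1``.  ``mem_alpha``/``mem_beta`` expose the per-k weights of
    the two k >= 2 memory sums separately for inspection.
    """

    n_terms: int
    dt: float
    denom: float
    coef_P_t: float
    coef_P_tm1: float
    mem_alpha: np.ndarray = field(repr=False)
    mem_beta: np.ndarray = field(repr=False)
    coef_E: float
    history_coefs: np.ndarray = field(repr=False)
    coupling: str = "trapezoidal"


def ade_coefficients(medium: FractionalDrudeMedium, dt: float, n_terms: int,
                     coupling: str = "trapezoidal") -> ADECoefficients:
    """Derive the polarization-recursion coefficients for one medium.

    The recursion is obtained from the discrete equation of motion

        A * sum_k a_k (P_{t-k+1} - P_{t-k})
          + B * sum_k b_k (P_{t-k+1} + P_{t-k}) = omega_p^2 E_t,

    with ``A = gamma_alpha / (dt * dt**alpha)``,
    ``B = gamma_beta / (2 * dt**beta)`` and ``a_k``/``b_k`` the truncated GL
    weight tables of orders alpha and beta.  Collecting the coefficient of
    each ``P_{t-j}`` and dividing by the ``P_{t+1}`` coefficient
    ``denom = A*a_0 + B*b_0`` gives the update used at run time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if coupling not in COUPLINGS:
        raise ValueError(f"coupling must be one of {COUPLINGS}")
    aw = gl_weights(medium.alpha, n_terms).weights
    bw = gl_weights(medium.beta, n_terms).weights
    A = medium.gamma_alpha / (dt * dt ** medium.alpha)
    B = medium.gamma_beta / (2.0 * dt ** medium.beta)
    denom = A * aw[0] + B * bw[0]
    if denom == 0 or not np.isfinite(denom):
        raise ZeroDivisionError("degenerate medium: update denominator is "
                                f"{denom}")
    # coefficient of P_{t-j} on the equation's left-hand side
    c = np.zeros(n_terms + 1)
    for j in range(n_terms + 1):
        if j + 1 <= n_terms:
            c[j] += A * aw[j + 1] + B * bw[j + 1]
        c[j] += -A * aw[j] + B * bw[j]
    history_coefs = -c / denom
    history_coefs.setflags(write=False)
    mem_alpha = A * aw[2:] / denom
    mem_beta = B * bw[2:] / denom
    mem_alpha.setflags(write=False)
    mem_beta.setflags(write=False)
    return ADECoefficients(
        n_terms=n_terms, dt=float(dt), denom=float(denom),
        coef_P_t=float(history_coefs[0]), coef_P_tm1=float(history_coefs[1]),
        mem_alpha=mem_alpha, mem_beta=mem_beta,
        coef_E=float(medium.omega_p_sq / denom),
        history_coefs=history_coefs, coupling=coupling)


@dataclass
class SourceSpec:
    """Soft (additive) source at one cell.

    ``ramp_cycles`` raised-cosine periods suppress turn-on transients of the
    monochromatic source.  The Gaussian pulse is for broadband/vacuum tests:
    ``amplitude * exp(-((t - center_time)/width)^2)``.
    """

    position: int
    omega: float = 0.0
    amplitude: float = 1.0
    ramp_cycles: float = 10.0
    kind: str = "monochromatic_soft"
    center_time: float = 30.0
    width: float = 10.0

    def __post_init__(self):
        if self.kind not in ("monochromatic_soft", "gaussian_pulse"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.kind == "monochromatic_soft" and self.omega <= 0:
            raise ValueError("monochromatic source needs omega > 0")
        if self.ramp_cycles < 0:
            raise ValueError("ramp_cycles must be >= 0")

    def waveform(self, t: float) -> float:
        if self.kind == "gaussian_pulse":
            return self.amplitude * np.exp(
                -((t - self.center_time) / self.width) ** 2)
        ramp_time = self.ramp_cycles * 2.0 * np.pi / self.omega
        env = 1.0
        if ramp_time > 0 and t < ramp_time:
            env = 0.5 * (1.0 - np.cos(np.pi * t / ramp_time))
        return self.amplitude * env * np.sin(self.omega * t)


@dataclass
class Grid1D:
    """1-D Yee field state plus per-cell polarization history.

    ``p_history[j]`` holds ``P_{t-j}`` for every cell (vacuum cells stay
    identically zero).  ``courant`` equals ``dt`` in the normalized units.
    """

    n_cells: int
    dt: float
    E: np.ndarray
    H: np.ndarray
    medium_mask: np.ndarray
    p_history: np.ndarray
    time_index: int = 0
    _mur_prev: tuple = (0.0, 0.0)

    @property
    def courant(self) -> float:
        return self.dt

    @classmethod
    def at_rest(cls, n_cells: int, dt: float, n_terms: int,
                medium_mask: np.ndarray | None = None) -> "Grid1D":
        """All-zero fields and history (the medium starts at rest)."""
        if n_cells < 3:
            raise ValueError("grid needs at least 3 cells")
        if medium_mask is None:
            medium_mask = np.ones(n_cells, dtype=bool)
        else:
            medium_mask = np.asarray(medium_mask, dtype=bool)
            if medium_mask.shape != (n_cells,):
                raise ValueError("medium_mask must have one entry per cell")
        return cls(n_cells=n_cells, dt=float(dt),
                   E=np.zeros(n_cells), H=np.zeros(n_cells - 1),
                   medium_mask=medium_mask,
                   p_history=np.zeros((n_terms + 1, n_cells)))


@dataclass(frozen=True)
class ProbeRecord:
    """E and P time series recorded at one cell."""

    cell: int
    e_series: np.ndarray
    p_series: np.ndarray
    dt: float


@dataclass(frozen=True)
class RunResult:
    records: tuple
    diverged: bool
    n_steps_run: int

    def probe(self, cell: int) -> ProbeRecord:
        for rec in self.records:
            if rec.cell == cell:
                return rec
        raise KeyError(f"no probe at cell {cell}")


def _advance(grid: Grid1D, coeffs: ADECoefficients, source: SourceSpec | None):
    """Advance the grid by one step in place (shared by step() and run())."""
    dt = grid.dt
    E, H, hist = grid.E, grid.H, grid.p_history
    mask = grid.medium_mask
    t = grid.time_index * dt

    H += dt * (E[1:] - E[:-1])
    recall = coeffs.history_coefs @ hist      # memory contribution, all cells
    recall[~mask] = 0.0
    e_star = E.copy()
    e_star[1:-1] += dt * (H[1:] - H[:-1])
    if coeffs.coupling == "trapezoidal":
        s = np.where(mask, 0.5 * coeffs.coef_E, 0.0)
        e_new = (e_star - s * E - recall + hist[0]) / (1.0 + s)
        e_new[~mask] = e_star[~mask]
        p_new = s * (E + e_new) + recall
    else:                                     # explicit drive E^n
        p_new = np.where(mask, coeffs.coef_E * E + recall, 0.0)
        e_new = e_star - (p_new - hist[0])
    prev_left, prev_right = grid._mur_prev
    E[:] = e_new
    if source is not None:
        E[source.position] += source.waveform(t)
    k_mur = (dt - 1.0) / (dt + 1.0)
    E[0] = prev_left + k_mur * (E[1] - E[0])
    E[-1] = prev_right + k_mur * (E[-2] - E[-1])
    grid._mur_prev = (E[1], E[-2])
    hist[1:] = hist[:-1]
    hist[0] = p_new
    grid.time_index += 1


def step(grid: Grid1D, coeffs: ADECoefficients,
         source: SourceSpec | None = None) -> Grid1D:
    """Advance the simulation by one time step (in place; returns the grid)."""
    if source is not None and not 0 <= source.position < grid.n_cells:
        raise IndexError("source position outside grid")
    _advance(grid, coeffs, source)
    return grid


def run(grid: Grid1D, coeffs: ADECoefficients, source: SourceSpec | None,
        n_steps: int, probes: Sequence[int] = (),
        divergence_factor: float = 1e6,
        check_every: int = 100) -> RunResult:
    """Run ``n_steps`` steps, recording E and P at the probe cells.

    The divergence flag is set (and the run stopped) when ``max |E|``
    exceeds ``divergence_factor`` times the source amplitude, checked every
    ``check_every`` steps — the cheap, unambiguous signature of an unstable
    parameter set.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    for p in probes:
        if not 0 <= p < grid.n_cells:
            raise IndexError(f"probe cell {p} outside grid")
    if source is not None and not 0 <= source.position < grid.n_cells:
        raise IndexError("source position outside grid")
    amp = abs(source.amplitude) if source is not None else 1.0
    threshold = divergence_factor * max(amp, np.abs(grid.E).max(), 1e-300)
    probes = tuple(probes)
    e_out = {p: np.empty(n_steps) for p in probes}
    p_out = {p: np.empty(n_steps) for p in probes}
    diverged = False
    n_run = 0
    for n in range(n_steps):
        _advance(grid, coeffs, source)
        for p in probes:
            e_out[p][n] = grid.E[p]
            p_out[p][n] = grid.p_history[0][p]
        n_run = n + 1
        if n % check_every == 0:
            m = np.abs(grid.E).max()
            if not np.isfinite(m) or m > threshold:
                diverged = True
                break
    if not diverged:
        m = np.abs(grid.E).max()
        diverged = bool(not np.isfinite(m) or m > threshold)
    records = tuple(
        ProbeRecord(cell=p, e_series=e_out[p][:n_run],
                    p_series=p_out[p][:n_run], dt=grid.dt)
        for p in probes)
    return RunResult(records=records, diverged=diverged, n_steps_run=n_run)
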