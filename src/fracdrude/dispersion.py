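"""Closed-form frequency-domain material functions.

The central object is the two-parameter fractional Drude medium.  The
classical Drude equation of motion for the polarization,
:math:`\\ddot P + \\gamma \\dot P = \\omega_p^2 E`, is generalized by
replacing both time derivatives with fractional (Grunwald-Letnikov) ones,

.. math::

    \\gamma_\\alpha D^{\\alpha+1} P + \\gamma_\\beta D^{\\beta} P
        = \\omega_p^2 E,

which for a harmonic field :math:`E \\propto e^{-i\\omega t}` gives the
susceptibility

.. math::

    \\chi(\\omega) = \\frac{\\omega_p^2}
        {\\gamma_\\alpha (-i\\omega)^{\\alpha+1}
         + \\gamma_\\beta (-i\\omega)^{\\beta}} .

The two independent orders ``alpha`` and ``beta`` let the model interpolate
between metallic (Drude, ``alpha = beta = 1``), resonant (``beta = 0``) and
relaxational (Debye/Cole-Cole-like) behaviour, and produce power-law wave
absorption with a tunable exponent — the phenomenology observed for
electromagnetic and acoustic propagation in soft biological tissue.

The dimensional constants ``gamma_alpha`` and ``gamma_beta`` carry the
left-over units of the fractional operators so that chi stays dimensionless.
Only ``omega > 0`` is modelled (no electrostatics).

Conventions: the physics time convention ``e^{-i omega t}`` is canonical
internally, with the principal branch ``(-i omega)^x = omega^x e^{-i pi x/2}``.
The engineering convention (``e^{+i omega t}``, as in the usual Debye form
``delta_eps / (1 + i omega tau)``) is obtained by complex conjugation via
:class:`UnitSystem`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FractionalDrudeMedium", "DebyeParams", "ColeColeParams",
    "HavriliakNegamiParams", "UnitSystem", "susceptibility", "permittivity",
    "reference_permittivity", "wavevector", "imk_asymptotic_exponent",
    "conductivity_spectrum",
]


@dataclass(frozen=True)
class FractionalDrudeMedium:
    """Seven-parameter fractional Drude dielectric.

    ``omega_p_sq`` may be negative: anomalous-dispersion fits to tissue
    spectra use a negative oscillator strength.
    """

    omega_p_sq: float
    gamma_alpha: float = 1.0
    gamma_beta: float = 0.1
    alpha: float = 1.0
    beta: float = 1.0
    eps_inf: float = 1.0
    sigma_dc: float = 0.0

    def __post_init__(self):
        for name in ("omega_p_sq", "gamma_alpha", "gamma_beta", "alpha",
                     "beta", "eps_inf", "sigma_dc"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be > 0")
        if self.gamma_beta < 0:
            raise ValueError("gamma_beta must be >= 0")
        if self.sigma_dc < 0:
            raise ValueError("sigma_dc must be >= 0")


@dataclass(frozen=True)
class DebyeParams:
    """Single-term Debye relaxation ``eps_inf + delta_eps/(1 + i omega tau)``."""

    eps_inf: float
    delta_eps: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class ColeColeParams:
    """Cole-Cole relaxation with broadening exponent ``alpha_cc`` in [0, 1)."""

    eps_inf: float
    delta_eps: float
    tau: float
    alpha_cc: float = 0.0
    sigma_dc: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0 <= self.alpha_cc < 1:
            raise ValueError("alpha_cc must lie in [0, 1)")
        if self.sigma_dc < 0:
            raise ValueError("sigma_dc must be >= 0")


@dataclass(frozen=True)
class HavriliakNegamiParams:
    """Havriliak-Negami relaxation ``eps_inf + delta_eps/(1+(i omega tau)^a)^b``."""

    eps_inf: float
    delta_eps: float
    tau: float
    alpha_hn: float = 1.0
    beta_hn: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0 < self.alpha_hn <= 1:
            raise ValueError("alpha_hn must lie in (0, 1]")
        if not 0 < self.beta_hn <= 1:
            raise ValueError("beta_hn must lie in (0, 1]")


@dataclass(frozen=True)
class UnitSystem:
    """Wave speed, vacuum permittivity and time-harmonic sign convention.

    The default is the normalized system ``c = eps0 = 1`` used for the
    accuracy and stability experiments; SI values support tissue fitting.
    """

    c: float = 1.0
    eps0: float = 1.0
    convention: str = "physics_e_minus_iwt"

    _CONVENTIONS = ("physics_e_minus_iwt", "engineering_e_plus_iwt")

    def __post_init__(self):
        if self.c <= 0 or self.eps0 <= 0:
            raise ValueError("c and eps0 must be positive")
        if self.convention not in self._CONVENTIONS:
            raise ValueError(f"convention must be one of {self._CONVENTIONS}")

    @property
    def engineering(self) -> bool:
        return self.convention == "engineering_e_plus_iwt"


NORMALIZED = UnitSystem()
SI = UnitSystem(c=299792458.0, eps0=8.8541878128e-12)


def _check_omega(omega) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0) or not np.all(np.isfinite(omega)):
        raise ValueError("omega must be positive and finite (omega > 0)")
    return omega


def _minus_i_omega_pow(omega: np.ndarray, x: float) -> np.ndarray:
    """Principal branch of (-i*omega)**x for omega > 0."""
    return omega ** x * np.exp(-0.5j * np.pi * x)


def susceptibility(medium: FractionalDrudeMedium, omega,
                   units: UnitSystem = NORMALIZED):
    """Fractional Drude susceptibility chi(omega).

    chi = omega_p^2 / (gamma_alpha (-i w)^(alpha+1) + gamma_beta (-i w)^beta)
    under the physics convention; the engineering convention returns the
    conjugate.  ``omega`` may be a scalar or array of positive frequencies.
    """
    omega = _check_omega(omega)
    den = (medium.gamma_alpha * _minus_i_omega_pow(omega, medium.alpha + 1.0)
           + medium.gamma_beta * _minus_i_omega_pow(omega, medium.beta))
    if np.any(den == 0):
        raise ZeroDivisionError("susceptibility denominator vanished")
    chi = medium.omega_p_sq / den
    if units.engineering:
        chi = np.conj(chi)
    return chi if chi.ndim else complex(chi)


def permittivity(medium: FractionalDrudeMedium, omega,
                 units: UnitSystem = NORMALIZED):
    """Complex relative permittivity eps_inf + chi + i sigma/(omega eps0)."""
    omega = _check_omega(omega)
    chi = susceptibility(medium, omega, units)
    cond = medium.sigma_dc / (omega * units.eps0)
    cond = -1j * cond if units.engineering else 1j * cond
    eps = medium.eps_inf + chi + cond
    return eps if np.ndim(eps) else complex(eps)


def reference_permittivity(params, omega, units: UnitSystem = NORMALIZED):
    """Debye, Cole-Cole or Havriliak-Negami permittivity.

    The textbook forms are written for the engineering convention
    (``+ i omega tau``); under the canonical physics convention the signs are
    conjugated so that the loss part keeps the passive sign.
    """
    omega = _check_omega(omega)
    # evaluate in the engineering convention, then conjugate if needed
    iwt = 1j * omega
    if isinstance(params, DebyeParams):
        eps = params.eps_inf + params.delta_eps / (1.0 + iwt * params.tau)
    elif isinstance(params, ColeColeParams):
        eps = (params.eps_inf
               + params.delta_eps / (1.0 + (iwt * params.tau) ** (1.0 - params.alpha_cc))
               + params.sigma_dc / (iwt * units.eps0))
    elif isinstance(params, HavriliakNegamiParams):
        eps = (params.eps_inf
               + params.delta_eps
               / (1.0 + (iwt * params.tau) ** params.alpha_hn) ** params.beta_hn)
    else:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    if not units.engineering:
        eps = np.conj(eps)
    return eps if np.ndim(eps) else complex(eps)


def wavevector(medium: FractionalDrudeMedium, omega,
               units: UnitSystem = NORMALIZED):
    """Complex wave vector k = (omega/c) sqrt(eps), decaying-wave root.

    The root with ``Im k >= 0`` is returned (physics convention: a forward
    wave ``e^{i k x}`` decays).  Under the engineering convention the
    conjugate root (``Im k <= 0``) is returned.
    """
    omega = _check_omega(omega)
    eps = permittivity(medium, omega, UnitSystem(units.c, units.eps0))
    k = omega / units.c * np.sqrt(np.asarray(eps, dtype=complex))
    k = np.where(np.imag(k) < 0, -k, k)
    if units.engineering:
        k = np.conj(k)
    return k if k.ndim else complex(k)


def imk_asymptotic_exponent(medium: FractionalDrudeMedium) -> float:
    """High-frequency power-law exponent of Im k: returns beta - 3.

    Valid for a small modification of the Drude model (alpha = 1, beta near
    1), where expanding k to first order in chi at high frequency gives
    ``Im k ~ omega^(beta-3)``.  Outside that regime a warning is raised; in
    the opposite limit alpha -> 0 the absorption becomes frequency-flat
    (exponent ~ 0), which this closed form does not describe.
    """
    if abs(medium.alpha - 1.0) > 0.2 or abs(medium.beta - 1.0) > 0.6:
        warnings.warn(
            "Im k ~ omega^(beta-3) holds for alpha = 1 and beta near 1; "
            f"alpha={medium.alpha}, beta={medium.beta} is outside the regime",
            stacklevel=2)
    return medium.beta - 3.0


def conductivity_spectrum(medium: FractionalDrudeMedium, omega,
                          units: UnitSystem = NORMALIZED):
    """Dynamic conductivity sigma(omega) = eps0 * omega * Im chi(omega)."""
    omega = _check_omega(omega)
    chi = susceptibility(medium, omega, UnitSystem(units.c, units.eps0))
    sigma = units.eps0 * omega * np.imag(chi)
    return sigma if np.ndim(sigma) else float(sigma)
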