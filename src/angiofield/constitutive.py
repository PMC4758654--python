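"""Pointwise constitutive functions of the tumor–angiogenesis model.

The model couples two phase fields — tumor ``phi`` in [0, 1] and capillary
``c`` in [-1, 1] — with two reaction–diffusion species, nutrient ``sigma`` and
tumor angiogenic factor (TAF) ``f``, both in [0, 1].  Everything in this
module is a pure, vectorized function of field values; no grid or time enters
here.

Tumor dynamics derives from the free energy

    Psi_phi = 0.5 * lambda_phi**2 * |grad phi|**2 + g(phi) + m(sigma) * h(phi)

where ``g`` is a symmetric double well with minima at phi = 0 (host) and
phi = 1 (tumor) and ``m`` tilts the well depths with the local nutrient
level: below the hypoxic–viable threshold the host state is energetically
preferred and the tumor regresses; above it the tumor grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "double_well_g",
    "tilt_shape_h",
    "tilting_m",
    "mu_phi",
    "mu_c",
    "proliferation_Bp",
    "secretion_G",
    "smoothed_heaviside_H",
    "migration_J",
    "chemo_velocity",
    "tec_template",
]

#: Below this gradient magnitude a chemotactic cue is considered absent and
#: the migration velocity is the zero vector (a tip cell with no cue rests).
GRAD_TOL = 1e-12

#: Default amplitude of the TAF secretion rate G.  The secretion rate is a
#: Gaussian bump of sigma centered mid-hypoxia; the amplitude is read as a
#: Gaussian-normalization remnant, 0.02/sqrt(2*pi).
G_AMP_DEFAULT = 0.02 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ModelParameters:
    """All nondimensional model constants plus the physical scales.

    Defaults are the reference in-silico values used throughout; lengths are
    measured in units of ``L_scale`` micrometres and times in units of
    ``T_scale`` seconds.
    """

    M_phi: float = 0.3        # tumor mobility
    lambda_phi: float = 22.0  # tumor interface-width constant
    D_sigma: float = 30.0     # nutrient diffusivity
    V_pc: float = 1.0         # nutrient production rate at capillaries
    V_uT: float = 6e-3        # nutrient uptake rate, tumor
    V_uH: float = 6e-4        # nutrient uptake rate, host tissue
    sigma_nh: float = 0.2     # necrotic-hypoxic nutrient threshold
    sigma_hv: float = 0.4     # hypoxic-viable nutrient threshold
    f_p: float = 0.3          # TAF level at which endothelial proliferation saturates
    M_c: float = 1.0          # capillary mobility
    lambda_c: float = 1.0     # capillary interface-width constant
    B_p: float = 1.401        # endothelial proliferation rate
    R: float = 4.0            # tip-cell radius
    c_act: float = 0.9        # tip-cell activation threshold on c
    f_act: float = 0.001      # tip-cell activation threshold on f
    chi: float = 7.28         # chemotactic constant (tip-cell speed scale)
    delta4: float = 80.0      # Dll4 effective exclusion distance
    D_f: float = 100.0        # TAF diffusivity
    B_u: float = 6.25         # TAF uptake rate by capillaries
    L_scale: float = 1.25     # micrometres per nondimensional length unit
    T_scale: float = 1562.5   # seconds per nondimensional time unit
    eps_H: float = 0.1        # half-width of the smoothed Heaviside step
    G_amp: float = G_AMP_DEFAULT  # TAF secretion prefactor
    eps_template: float = 1.0     # tip-cell template interface width
    # Numerical regularization: denominator of the arctan tilt; must exceed
    # 3*pi so that |m| < 1/3 and both wells persist for every sigma.
    m_denominator: float = 3.01 * np.pi

    def __post_init__(self) -> None:
        positive = (
            "M_phi", "lambda_phi", "D_sigma", "V_pc", "V_uT", "V_uH",
            "f_p", "M_c", "lambda_c", "B_p", "R", "c_act", "f_act",
            "chi", "delta4", "D_f", "B_u", "L_scale", "T_scale",
            "eps_H", "G_amp", "eps_template",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if not 0.0 < self.sigma_nh < self.sigma_hv < 1.0:
            raise ValueError("thresholds must satisfy 0 < sigma_nh < sigma_hv < 1")
        if not self.m_denominator > 3.0 * np.pi:
            raise ValueError("m_denominator must exceed 3*pi to keep |m| < 1/3")

    def with_overrides(self, overrides: Mapping[str, float]) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **dict(overrides))


# ---------------------------------------------------------------------------
# Tumor free energy
# ---------------------------------------------------------------------------

def double_well_g(phi):
    """Symmetric double-well potential g(phi) = phi^2 (1 - phi)^2."""
    phi = np.asarray(phi, dtype=float)
    return phi * phi * (1.0 - phi) ** 2


def tilt_shape_h(phi):
    """Interpolant h(phi) = phi^2 (3 - 2 phi), with h(0)=0, h(1)=1, h' = 6 g^(1/2)-like."""
    phi = np.asarray(phi, dtype=float)
    return phi * phi * (3.0 - 2.0 * phi)


def tilting_m(sigma, p: ModelParameters):
    """Nutrient-dependent tilt m(sigma) = -(2/denom) * arctan(15 (sigma - sigma_hv)).

    Positive (host preferred, tumor shrinks) below the hypoxic-viable
    threshold, negative (tumor grows) above it; |m| < 1/3 for all sigma
    because the denominator exceeds 3*pi.
    """
    sigma = np.asarray(sigma, dtype=float)
    return -(2.0 / p.m_denominator) * np.arctan(15.0 * (sigma - p.sigma_hv))


def mu_phi(phi, sigma, p: ModelParameters):
    """Tumor chemical potential d/dphi [g + m(sigma) h] .

    Equals 2 phi (1-phi)(1-2 phi) + 6 m(sigma) phi (1-phi); vanishes at the
    two bulk states phi = 0, 1 for every sigma.
    """
    phi = np.asarray(phi, dtype=float)
    one_m = 1.0 - phi
    return 2.0 * phi * one_m * (1.0 - 2.0 * phi) + 6.0 * tilting_m(sigma, p) * phi * one_m


def mu_c(c):
    """Capillary chemical potential c^3 - c (wells of c^4/4 - c^2/2 at +-1)."""
    c = np.asarray(c, dtype=float)
    return c * c * c - c


# ---------------------------------------------------------------------------
# Reaction rates
# ---------------------------------------------------------------------------

def proliferation_Bp(f, p: ModelParameters):
    """Endothelial proliferation rate: B_p * f, saturating at B_p * f_p."""
    f = np.asarray(f, dtype=float)
    return p.B_p * np.minimum(f, p.f_p)


def secretion_G(sigma, p: ModelParameters):
    """TAF secretion rate: Gaussian bump of sigma centered mid-hypoxia.

    G(sigma) = G_amp * exp(-125 (sigma - (sigma_nh + sigma_hv)/2)^2), maximal
    where tumor cells are hypoxic (between the two thresholds).
    """
    sigma = np.asarray(sigma, dtype=float)
    center = 0.5 * (p.sigma_nh + p.sigma_hv)
    return p.G_amp * np.exp(-125.0 * (sigma - center) ** 2)


def smoothed_heaviside_H(x, p: ModelParameters):
    """Smoothed Heaviside step H(x) = 0.5 (1 + tanh(x / eps_H))."""
    x = np.asarray(x, dtype=float)
    return 0.5 * (1.0 + np.tanh(x / p.eps_H))


# ---------------------------------------------------------------------------
# Tip-cell migration
# ---------------------------------------------------------------------------

def migration_J(phi):
    """Velocity modulation J(phi) = 0.45 [tanh(50 (0.5 - phi)) + 1] + 0.1.

    Close to 1 in host tissue (phi ~ 0) and to 0.1 deep inside the tumor:
    sprouts can penetrate the lesion, but much more slowly.
    """
    phi = np.asarray(phi, dtype=float)
    return 0.45 * (np.tanh(50.0 * (0.5 - phi)) + 1.0) + 0.1


def chemo_velocity(grad_f, phi, p: ModelParameters):
    """Tip-cell velocity chi * (grad f / |grad f|) * J(phi).

    With no appreciable TAF gradient (|grad f| below ``GRAD_TOL``) the cell
    has no cue and the velocity is the zero vector.
    """
    grad_f = np.asarray(grad_f, dtype=float)
    norm = float(np.hypot(grad_f[0], grad_f[1]))
    if norm < GRAD_TOL:
        return np.zeros(2)
    return (p.chi * float(migration_J(phi)) / norm) * grad_f


def tec_template(r, p: ModelParameters):
    """Radial template of one circular tip cell: tanh((R - r) / eps_template).

    Approximately +1 inside the cell (r << R), -1 outside (r >> R), crossing
    zero at the cell boundary r = R.
    """
    r = np.asarray(r, dtype=float)
    return np.tanh((p.R - r) / p.eps_template)
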