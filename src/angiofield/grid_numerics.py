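"""Rectangular-grid storage and semi-implicit steppers for the four PDEs.

All fields live on a cell-centered uniform grid with zero-flux (mirror)
boundaries on every edge: the two inner edges of the quarter domain are
symmetry planes of the full tissue, the outer edges isolate it.  The mirror
5-point Laplacian is diagonalized exactly by the type-II discrete cosine
transform, so every implicit solve below is a pointwise division in DCT
space.

Time integration is first-order IMEX:

* tumor (Allen-Cahn): implicit diffusion + linear stabilization, explicit
  tilted-potential derivative;
* capillaries (Cahn-Hilliard + reaction): implicit biharmonic + linear
  stabilization, explicit chemical potential and proliferation;
* nutrient and TAF: exact pointwise exponential update of the (locally
  linear-in-the-unknown) reaction, then implicit diffusion.  Both stages
  satisfy a discrete maximum principle, which keeps sigma and f in [0, 1].

The linear stabilization constants make the phase-field schemes gradient
stable at any step size; accuracy is controlled by the adaptive step-size
rule `adapt_dt`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn

from .constitutive import (
    ModelParameters,
    double_well_g,
    mu_c,
    mu_phi,
    proliferation_Bp,
    secretion_G,
    smoothed_heaviside_H,
    tilt_shape_h,
    tilting_m,
)

__all__ = [
    "Grid",
    "FieldState",
    "SpectralOperators",
    "StepDiagnostics",
    "laplacian",
    "gradient",
    "step_tumor",
    "step_nutrient",
    "step_capillary",
    "step_taf",
    "adapt_dt",
    "tumor_free_energy",
    "DT_MIN",
    "DT_MAX",
    "TOL_UP",
    "TOL_DOWN",
]

# Adaptive step-size bounds and per-step max-norm change tolerances
# (nondimensional time / field units).
DT_MIN = 1e-4
DT_MAX = 5.0
TOL_UP = 5e-2
TOL_DOWN = 5e-3

# Linear stabilization constants; at least half the Lipschitz constant of the
# explicit potential derivative on the physically visited range.
_STAB_PHI = 2.0
_STAB_C = 2.0


class NumericsError(RuntimeError):
    """A field left its admissible range or a solve produced non-finite values."""


@dataclass(frozen=True)
class Grid:
    """Cell-centered uniform rectangular grid for the quarter domain."""

    nx: int
    ny: int
    width: float = 1050.0
    height: float = 810.0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 nodes per direction")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid extents must be positive")

    @property
    def dx(self) -> float:
        return self.width / self.nx

    @property
    def dy(self) -> float:
        return self.height / self.ny

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx): fields are indexed [row = y, column = x]."""
        return (self.ny, self.nx)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """X, Y coordinate arrays of shape (ny, nx)."""
        return np.meshgrid(self.x_centers(), self.y_centers())


@dataclass
class FieldState:
    """The four coupled fields and the current nondimensional time."""

    phi: np.ndarray    # tumor phase field, ~[0, 1]
    sigma: np.ndarray  # nutrient, [0, 1]
    c: np.ndarray      # capillary phase field, ~[-1, 1]
    f: np.ndarray      # tumor angiogenic factor, [0, 1]
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.phi.copy(), self.sigma.copy(),
                          self.c.copy(), self.f.copy(), self.t)

    def validate(self, grid: Grid) -> None:
        for name, arr in (("phi", self.phi), ("sigma", self.sigma),
                          ("c", self.c), ("f", self.f)):
            if arr.shape != grid.shape:
                raise NumericsError(f"field {name} not congruent with grid")
            if not np.all(np.isfinite(arr)):
                raise NumericsError(f"non-finite values in field {name}")
        _check_range(self.phi, -0.05, 1.05, "phi")
        _check_range(self.c, -1.05, 1.05, "c")
        _check_unit_range(self.sigma, "sigma")
        _check_unit_range(self.f, "f")


def _check_range(arr: np.ndarray, lo: float, hi: float, name: str) -> None:
    if arr.min() < lo or arr.max() > hi:
        raise NumericsError(
            f"field {name} out of [{lo}, {hi}]: [{arr.min():.4g}, {arr.max():.4g}]")


#: Overshoot of sigma/f beyond [0, 1] larger than this is a hard error;
#: anything smaller is silently clipped (floating-point residue of the
#: maximum-principle-preserving solves).
_CLIP_TOL = 1e-9


def _check_unit_range(arr: np.ndarray, name: str) -> None:
    lo, hi = arr.min(), arr.max()
    if lo < -_CLIP_TOL or hi > 1.0 + _CLIP_TOL:
        raise NumericsError(f"field {name} out of [0, 1]: [{lo:.4g}, {hi:.4g}]")
    np.clip(arr, 0.0, 1.0, out=arr)


# ---------------------------------------------------------------------------
# Differential operators
# ---------------------------------------------------------------------------

def laplacian(arr: np.ndarray, grid: Grid) -> np.ndarray:
    """5-point Laplacian with mirror (zero-flux) boundaries on all edges."""
    if arr.shape != grid.shape:
        raise ValueError(f"shape {arr.shape} does not match grid {grid.shape}")
    padded = np.pad(arr, 1, mode="edge")
    return ((padded[1:-1, 2:] - 2.0 * arr + padded[1:-1, :-2]) / grid.dx ** 2
            + (padded[2:, 1:-1] - 2.0 * arr + padded[:-2, 1:-1]) / grid.dy ** 2)


def gradient(arr: np.ndarray, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (gx, gy) with mirror boundaries."""
    padded = np.pad(arr, 1, mode="edge")
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / (2.0 * grid.dx)
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / (2.0 * grid.dy)
    return gx, gy


class SpectralOperators:
    """DCT-II diagonalization of the mirror-boundary 5-point Laplacian.

    The eigenvalues are those of the discrete operator itself, so implicit
    solves are exact solves of the finite-difference system, not a spectral
    approximation.
    """

    def __init__(self, grid: Grid):
        self.grid = grid
        lam_x = (2.0 * np.cos(np.pi * np.arange(grid.nx) / grid.nx) - 2.0) / grid.dx ** 2
        lam_y = (2.0 * np.cos(np.pi * np.arange(grid.ny) / grid.ny) - 2.0) / grid.dy ** 2
        #: eigenvalues of the Laplacian, shape (ny, nx); all <= 0
        self.lap_eig = lam_y[:, None] + lam_x[None, :]

    def to_modes(self, arr: np.ndarray) -> np.ndarray:
        return dctn(arr, type=2, norm="ortho")

    def from_modes(self, modes: np.ndarray) -> np.ndarray:
        return idctn(modes, type=2, norm="ortho")

    def solve_diffusion(self, rhs: np.ndarray, coef: float) -> np.ndarray:
        """Solve (I - coef * Lap) u = rhs."""
        return self.from_modes(self.to_modes(rhs) / (1.0 - coef * self.lap_eig))


_ops_cache: dict[Grid, SpectralOperators] = {}


def get_operators(grid: Grid) -> SpectralOperators:
    ops = _ops_cache.get(grid)
    if ops is None:
        ops = _ops_cache[grid] = SpectralOperators(grid)
    return ops


# ---------------------------------------------------------------------------
# Steppers (each returns the updated field array; the caller owns the state)
# ---------------------------------------------------------------------------

def step_tumor(state: FieldState, dt: float, p: ModelParameters,
               grid: Grid, ops: SpectralOperators | None = None) -> np.ndarray:
    """One stabilized IMEX step of the tilted Allen-Cahn tumor equation.

    d(phi)/dt = M_phi (lambda_phi^2 Lap(phi) - mu_phi(phi, sigma))
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ops = ops or get_operators(grid)
    rhs = state.phi + dt * p.M_phi * (_STAB_PHI * state.phi
                                      - mu_phi(state.phi, state.sigma, p))
    denom = 1.0 - dt * p.M_phi * (p.lambda_phi ** 2 * ops.lap_eig - _STAB_PHI)
    phi_new = ops.from_modes(ops.to_modes(rhs) / denom)
    if not np.all(np.isfinite(phi_new)):
        raise NumericsError("NaN in tumor step")
    return phi_new


def _capillary_indicator(c: np.ndarray, p: ModelParameters) -> np.ndarray:
    """c H(c), clamped at zero.

    The product approximates the positive part of c; the smoothed step gives
    it a tiny negative lobe for c < 0 (magnitude ~0.01 at the vessel wall)
    that would act as a spurious source/sink, so it is cut off.
    """
    return np.maximum(c * smoothed_heaviside_H(c, p), 0.0)


def _phi1(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, stable near x = 0."""
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


def _reaction_exact(u: np.ndarray, a: np.ndarray, b: np.ndarray,
                    dt: float) -> np.ndarray:
    """Exact step of du/dt = a (1 - u) - b u = a - (a + b) u."""
    k = a + b
    return u + (a - k * u) * dt * _phi1(k * dt)


def step_nutrient(state: FieldState, dt: float, S: float, p: ModelParameters,
                  grid: Grid, ops: SpectralOperators | None = None) -> np.ndarray:
    """One step of the nutrient equation.

    d(sigma)/dt = div(D_sigma grad sigma) + V_pc (1-sigma) c H(c) S
                  - V_uT sigma phi - V_uH sigma H(1-phi)

    Reaction handled by an exact pointwise exponential update (the capillary
    production is linear in sigma), then implicit diffusion.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0.0 < S <= 1.0:
        raise ValueError("S must lie in (0, 1]")
    ops = ops or get_operators(grid)
    prod = p.V_pc * _capillary_indicator(state.c, p) * S
    uptake = p.V_uT * state.phi + p.V_uH * smoothed_heaviside_H(1.0 - state.phi, p)
    sigma_new = _reaction_exact(state.sigma, prod, uptake, dt)
    sigma_new = ops.solve_diffusion(sigma_new, dt * p.D_sigma)
    if not np.all(np.isfinite(sigma_new)):
        raise NumericsError("NaN in nutrient step")
    return sigma_new


def step_capillary(state: FieldState, dt: float, p: ModelParameters,
                   grid: Grid, ops: SpectralOperators | None = None) -> np.ndarray:
    """One stabilized IMEX step of the capillary Cahn-Hilliard equation.

    dc/dt = div(M_c grad(mu_c(c) - lambda_c^2 Lap c)) + B_p(f) c H(c)

    Biharmonic term implicit, chemical potential and proliferation explicit,
    with a linear Laplacian stabilization.  With the proliferation switched
    off the scheme conserves the mean of c exactly (the zero mode of the flux
    part is untouched).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ops = ops or get_operators(grid)
    lam = ops.lap_eig
    reaction = proliferation_Bp(state.f, p) * _capillary_indicator(state.c, p)
    explicit_hat = ops.to_modes(mu_c(state.c) - _STAB_C * state.c)
    rhs_hat = (ops.to_modes(state.c + dt * reaction)
               + dt * p.M_c * lam * explicit_hat)
    denom = 1.0 + dt * p.M_c * (p.lambda_c ** 2 * lam ** 2 - _STAB_C * lam)
    c_new = ops.from_modes(rhs_hat / denom)
    if not np.all(np.isfinite(c_new)):
        raise NumericsError("NaN in capillary step")
    return c_new


def step_taf(state: FieldState, dt: float, p: ModelParameters,
             grid: Grid, ops: SpectralOperators | None = None) -> np.ndarray:
    """One step of the TAF equation.

    df/dt = div(D_f grad f) + phi (1 - f) G(sigma) - B_u f c H(c)

    Same exact-reaction / implicit-diffusion splitting as the nutrient.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ops = ops or get_operators(grid)
    source = state.phi * secretion_G(state.sigma, p)
    uptake = p.B_u * _capillary_indicator(state.c, p)
    f_new = _reaction_exact(state.f, source, uptake, dt)
    f_new = ops.solve_diffusion(f_new, dt * p.D_f)
    if not np.all(np.isfinite(f_new)):
        raise NumericsError("NaN in TAF step")
    return f_new


# ---------------------------------------------------------------------------
# Adaptive step-size control
# ---------------------------------------------------------------------------

@dataclass
class StepDiagnostics:
    """What the controller needs to know about the step just taken."""

    max_change: float            # max-norm change over all evolved fields
    solver_failed: bool = False  # non-finite values / solve breakdown
    max_tec_speed: float = 0.0   # fastest active tip cell, for displacement cap


def adapt_dt(prev_dt: float, diag: StepDiagnostics, p: ModelParameters,
             dt_min: float = DT_MIN, dt_max: float = DT_MAX,
             tol_up: float = TOL_UP, tol_down: float = TOL_DOWN) -> float:
    """Next step size: halve on failure or too-large change, grow when quiet.

    The step is additionally capped so that no tip cell moves more than half
    its radius per step.
    """
    if prev_dt <= 0:
        raise ValueError("prev_dt must be positive")
    if diag.solver_failed or diag.max_change > tol_up:
        dt = 0.5 * prev_dt
    elif diag.max_change < tol_down:
        dt = 1.2 * prev_dt
    else:
        dt = prev_dt
    if diag.max_tec_speed > 0.0:
        dt = min(dt, p.R / (2.0 * diag.max_tec_speed))
    dt = min(dt, dt_max)
    if dt < dt_min:
        raise NumericsError(f"adaptive step size underflow: dt = {dt:.3e} < {dt_min:.3e}")
    return dt


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def tumor_free_energy(phi: np.ndarray, sigma: np.ndarray,
                      grid: Grid, p: ModelParameters) -> float:
    """Discrete tumor free energy; non-increasing under `step_tumor` at frozen sigma.

    The surface term uses forward differences, the discretization whose
    variational derivative is exactly the mirror-boundary 5-point Laplacian
    of the stepper.
    """
    dfx = np.diff(phi, axis=1) / grid.dx
    dfy = np.diff(phi, axis=0) / grid.dy
    surface = 0.5 * p.lambda_phi ** 2 * ((dfx ** 2).sum() + (dfy ** 2).sum())
    chemical = (double_well_g(phi) + tilting_m(sigma, p) * tilt_shape_h(phi)).sum()
    return float((surface + chemical) * grid.cell_area)
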