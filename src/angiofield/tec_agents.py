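"""Discrete tip-endothelial-cell (TEC) agents.

TECs are circular, mesh-free agents of radius ``R`` that lead new capillary
sprouts.  They are activated on capillary points where enough TAF is present
and no other active tip cell lies within the Dll4 exclusion distance
``delta4`` (a minimal model of Delta/Notch lateral inhibition); they migrate
up the TAF gradient at speed ``chi * J(phi)``, probe their surroundings with
filopodia once they have left their parent vessel behind, redirect toward any
capillary they detect, and anastomose with it, which deactivates them.  Each
agent is stamped into the capillary phase field every step through a radial
template function, leaving a contiguous trail that the endothelial
proliferation term of the capillary equation then sustains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import ModelParameters, chemo_velocity, migration_J, tec_template
from .grid_numerics import FieldState, Grid

__all__ = [
    "TipCell",
    "TecEvent",
    "sample_field",
    "scan_activation",
    "update_tec",
    "detect_filopodia",
    "try_anastomose",
    "imprint_template",
]

# Filopodia geometry: probes on rays every 45 degrees at radii {2R, 4R},
# skipping the trailing half-cone (+-60 degrees around minus-velocity).
_N_RAYS = 8
_PROBE_RADII = (2.0, 4.0)          # in units of R
_TRAIL_CONE_DEG = 60.0
# Points within this multiple of R of the stored recent path (last 8R of
# arc) count as the cell's own trail and are never "detected".
_TRAIL_EXCLUSION = 1.5
_TRAIL_ARC = 8.0                   # in units of R
# Steps of f < f_act at the center before a cell fades out (hysteresis).
_FADE_STEPS = 10
# Anastomosis probes: forward cone around the redirect direction, placed just
# beyond the trail-exclusion radius so a capillary dead ahead is seen while
# the cell's own sprout is not.
_ANA_CONE_DEG = 75.0
_ANA_RADIUS = 1.6                  # in units of R


@dataclass
class TecEvent:
    """One row of the TEC event log."""

    t: float
    tec_id: int
    event: str  # activation | redirect | anastomosis | deactivation
    x: float
    y: float
    # distance to the nearest other active cell at the time of the event
    # (recorded for activations; the lateral-inhibition audit checks it)
    nearest_active: float = float("nan")


@dataclass
class TipCell:
    """One migrating tip endothelial cell."""

    id: int
    pos: np.ndarray                  # (x, y), nondim
    radius: float
    parent_pos: np.ndarray
    sprout_id: int = -1
    active: bool = True
    path_length: float = 0.0
    redirect_dir: np.ndarray | None = None
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    fade_count: int = 0
    # recent path: list of (x, y, cumulative arc length at that point)
    trail: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.parent_pos = np.asarray(self.parent_pos, dtype=float)
        if not self.trail:
            self.trail = [(float(self.pos[0]), float(self.pos[1]), 0.0)]

    def trail_points(self) -> np.ndarray:
        """Recent path positions (last ``_TRAIL_ARC * R`` of arc), shape (n, 2)."""
        pts = [(x, y) for x, y, s in self.trail
               if self.path_length - s <= _TRAIL_ARC * self.radius]
        return np.asarray(pts)

    def _record_position(self) -> None:
        self.trail.append((float(self.pos[0]), float(self.pos[1]), self.path_length))
        cutoff = self.path_length - _TRAIL_ARC * self.radius
        while len(self.trail) > 2 and self.trail[1][2] < cutoff:
            self.trail.pop(0)


# ---------------------------------------------------------------------------
# Field sampling at agent positions
# ---------------------------------------------------------------------------

def sample_field(arr: np.ndarray, grid: Grid, pos: np.ndarray) -> float:
    """Bilinear sample of a cell-centered field at an (x, y) position.

    Positions outside the grid are clamped to the boundary cells, which is
    the mirror-boundary-consistent extension.
    """
    fx = pos[0] / grid.dx - 0.5
    fy = pos[1] / grid.dy - 0.5
    ix = int(np.clip(np.floor(fx), 0, grid.nx - 2))
    iy = int(np.clip(np.floor(fy), 0, grid.ny - 2))
    tx = float(np.clip(fx - ix, 0.0, 1.0))
    ty = float(np.clip(fy - iy, 0.0, 1.0))
    return float((1 - ty) * ((1 - tx) * arr[iy, ix] + tx * arr[iy, ix + 1])
                 + ty * ((1 - tx) * arr[iy + 1, ix] + tx * arr[iy + 1, ix + 1]))


def _sample_gradient(arr: np.ndarray, grid: Grid, pos: np.ndarray) -> np.ndarray:
    """Centered finite-difference gradient sampled at an off-grid position."""
    hx, hy = grid.dx, grid.dy
    gx = (sample_field(arr, grid, pos + (hx, 0.0)) -
          sample_field(arr, grid, pos - (hx, 0.0))) / (2.0 * hx)
    gy = (sample_field(arr, grid, pos + (0.0, hy)) -
          sample_field(arr, grid, pos - (0.0, hy))) / (2.0 * hy)
    return np.array([gx, gy])


def _mirror_images(pos: np.ndarray, grid: Grid) -> np.ndarray:
    """The position plus its reflections across the two symmetry edges.

    The quarter domain is the bottom-right quadrant of the full tissue: the
    left edge (x = 0) and the top edge (y = height) are symmetry planes.
    """
    x, y = pos
    return np.array([
        (x, y),
        (-x, y),
        (x, 2.0 * grid.height - y),
        (-x, 2.0 * grid.height - y),
    ])


# ---------------------------------------------------------------------------
# Activation (Dll4 lateral inhibition)
# ---------------------------------------------------------------------------

def scan_activation(state: FieldState, tecs: list[TipCell], p: ModelParameters,
                    grid: Grid, rng: np.random.Generator,
                    delta4: float | None = None) -> TipCell | None:
    """Activate at most one new tip cell this step.

    Eligible grid nodes satisfy c >= c_act (inside a capillary), f >= f_act
    (enough TAF), and lie farther than ``delta4`` from every active tip cell,
    including the mirror images of the cells across the symmetry edges.  If
    several nodes are eligible one is chosen uniformly at random.
    """
    delta4 = p.delta4 if delta4 is None else delta4
    mask = (state.c >= p.c_act) & (state.f >= p.f_act)
    if not mask.any():
        return None
    iy, ix = np.nonzero(mask)
    nodes = np.column_stack(((ix + 0.5) * grid.dx, (iy + 0.5) * grid.dy))
    actives = [t for t in tecs if t.active]
    if actives:
        images = np.concatenate([_mirror_images(t.pos, grid) for t in actives])
        d2 = ((nodes[:, None, :] - images[None, :, :]) ** 2).sum(axis=2)
        nodes = nodes[d2.min(axis=1) > delta4 ** 2]
    if len(nodes) == 0:
        return None
    choice = nodes[rng.integers(len(nodes))]
    new_id = max((t.id for t in tecs), default=-1) + 1
    return TipCell(id=new_id, pos=choice.copy(), radius=p.R, parent_pos=choice.copy())


# ---------------------------------------------------------------------------
# Migration, filopodia, anastomosis
# ---------------------------------------------------------------------------

def update_tec(tec: TipCell, state: FieldState, dt: float, p: ModelParameters,
               grid: Grid) -> TipCell:
    """Advance one active tip cell by one step (mutates and returns it).

    The cell moves along the stored redirect direction if a capillary has
    been detected, otherwise up the TAF gradient; speed is modulated by
    J(phi).  After the move it probes with filopodia (once it is more than 4R
    of arc away from its parent vessel) and fades out if the TAF condition at
    its center fails for ``_FADE_STEPS`` consecutive steps or it reaches the
    domain boundary.
    """
    if not tec.active:
        raise ValueError("update_tec requires an active cell")
    phi_here = sample_field(state.phi, grid, tec.pos)
    if tec.redirect_dir is not None:
        v = p.chi * float(migration_J(phi_here)) * tec.redirect_dir
    else:
        v = chemo_velocity(_sample_gradient(state.f, grid, tec.pos), phi_here, p)
    tec.velocity = v
    new_pos = tec.pos + v * dt
    clamped = np.clip(new_pos, [0.0, 0.0], [grid.width, grid.height])
    hit_edge = bool(np.any(clamped != new_pos))
    tec.path_length += float(np.hypot(*(clamped - tec.pos)))
    tec.pos = clamped
    tec._record_position()
    if hit_edge:
        tec.active = False
        return tec
    if sample_field(state.f, grid, tec.pos) < p.f_act:
        tec.fade_count += 1
        if tec.fade_count >= _FADE_STEPS:
            tec.active = False
            return tec
    else:
        tec.fade_count = 0
    if tec.redirect_dir is None and tec.path_length > 4.0 * tec.radius:
        direction = detect_filopodia(tec, state, p, grid)
        if direction is not None:
            tec.redirect_dir = direction
    return tec


def _away_from_trail(points: np.ndarray, trail: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of probe points farther than the exclusion radius from the trail."""
    if len(trail) == 0:
        return np.ones(len(points), dtype=bool)
    d2 = ((points[:, None, :] - trail[None, :, :]) ** 2).sum(axis=2)
    return d2.min(axis=1) > (_TRAIL_EXCLUSION * radius) ** 2


def detect_filopodia(tec: TipCell, state: FieldState, p: ModelParameters,
                     grid: Grid) -> np.ndarray | None:
    """Probe the capillary field around the cell; return a unit direction.

    Samples c at probe points on rays around the cell, excluding the
    trailing half-cone and any point close to the cell's own recent path
    (so a sprout never "detects" itself).  If any sampled value is positive a
    capillary is there and the direction toward the most capillary-like
    sample is returned; otherwise None.
    """
    angles = np.arange(_N_RAYS) * (2.0 * np.pi / _N_RAYS)
    dirs = np.column_stack((np.cos(angles), np.sin(angles)))
    speed = float(np.hypot(*tec.velocity))
    if speed > 0.0:
        back = -tec.velocity / speed
        keep = dirs @ back < np.cos(np.deg2rad(_TRAIL_CONE_DEG))
        dirs = dirs[keep]
    probes = np.concatenate([tec.pos + r * tec.radius * dirs for r in _PROBE_RADII])
    probes = probes[_away_from_trail(probes, tec.trail_points(), tec.radius)]
    inside = ((probes[:, 0] >= 0) & (probes[:, 0] <= grid.width)
              & (probes[:, 1] >= 0) & (probes[:, 1] <= grid.height))
    probes = probes[inside]
    if len(probes) == 0:
        return None
    values = np.array([sample_field(state.c, grid, q) for q in probes])
    if values.max() <= 0.0:
        return None
    target = probes[int(values.argmax())]
    direction = target - tec.pos
    return direction / np.linalg.norm(direction)


def try_anastomose(tec: TipCell, state: FieldState, p: ModelParameters,
                   grid: Grid) -> bool:
    """Deactivate the cell if it has reached a foreign capillary.

    A redirected cell fuses when a probe just ahead of it (forward cone
    around the redirect direction, radius ``_ANA_RADIUS * R``) samples
    c >= c_act at a point away from its own trail.  The caller closes the
    sprout and performs the final template imprint.
    """
    if not (tec.active and tec.redirect_dir is not None):
        return False
    angles = np.deg2rad(np.linspace(-_ANA_CONE_DEG, _ANA_CONE_DEG, 7))
    base = np.arctan2(tec.redirect_dir[1], tec.redirect_dir[0])
    dirs = np.column_stack((np.cos(base + angles), np.sin(base + angles)))
    probes = tec.pos + _ANA_RADIUS * tec.radius * dirs
    probes = probes[_away_from_trail(probes, tec.trail_points(), tec.radius)]
    if len(probes) == 0:
        return False
    values = np.array([sample_field(state.c, grid, q) for q in probes])
    if values.max() >= p.c_act:
        tec.active = False
        return True
    return False


def imprint_template(c_field: np.ndarray, tec: TipCell, p: ModelParameters,
                     grid: Grid) -> np.ndarray:
    """Stamp the cell template into c (in place): c <- max(c, template).

    Only a window of half-width 3R around the cell is touched; the template
    is +1-like inside the cell and -1-like outside, so the max never lowers
    c anywhere and repeated imprints at one position are idempotent.

    On grids coarser than the cell the stamped radius and transition width
    are floored at roughly one grid spacing, so a sprout is always at least
    one cell wide regardless of resolution.
    """
    h = max(grid.dx, grid.dy)
    r_eff = max(p.R, 1.5 * h)
    eps_eff = max(p.eps_template, 0.5 * h)
    half = 3.0 * r_eff
    x0 = max(int((tec.pos[0] - half) / grid.dx - 0.5), 0)
    x1 = min(int((tec.pos[0] + half) / grid.dx + 1.5), grid.nx)
    y0 = max(int((tec.pos[1] - half) / grid.dy - 0.5), 0)
    y1 = min(int((tec.pos[1] + half) / grid.dy + 1.5), grid.ny)
    if x0 >= x1 or y0 >= y1:
        return c_field
    xs = (np.arange(x0, x1) + 0.5) * grid.dx
    ys = (np.arange(y0, y1) + 0.5) * grid.dy
    r = np.hypot(xs[None, :] - tec.pos[0], ys[:, None] - tec.pos[1])
    if r_eff == p.R and eps_eff == p.eps_template:
        stamp = tec_template(r, p)
    else:
        stamp = np.tanh((r_eff - r) / eps_eff)
    window = c_field[y0:y1, x0:x1]
    np.maximum(window, stamp, out=window)
    return c_field
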