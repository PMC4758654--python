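"""Experiment definitions: initial state, unit conversion, and the run loop.

The reference setup is a rectangular tissue of 2625 um x 2025 um with a
circular tumor (radius 625 um, concentric necrotic core of radius
0.45 * 625 um) at its center and one straight capillary of width 25 um along
the bottom and top edges.  By symmetry only the bottom-right quadrant is
simulated: the tumor center sits at the top-left corner of the quarter
domain and the bottom strip carries the capillary.

Four scenario modes are provided:

* ``avascular`` — capillary and TAF dynamics frozen, no tip-cell activation,
  S = 1: the tumor first grows on the nutrient present in the tissue, then
  regresses slowly, limited by diffusion from the single vessel.
* ``vascular`` — the full coupled model: hypoxic tumor cells secrete TAF,
  tip cells sprout from the parent vessel and the angiogenic switch rescues
  tumor growth.
* ``dll4_blockade`` — same, with the Dll4 exclusion distance reduced
  (default 55 instead of 80), emulating down-regulated Delta/Notch
  signaling: a denser but less functional network.
* ``small_spheroid`` — a tumor three times smaller, for studying the
  disappearance of central necrosis after vascularization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .constitutive import ModelParameters
from .grid_numerics import (
    DT_MAX,
    DT_MIN,
    TOL_UP,
    FieldState,
    Grid,
    NumericsError,
    StepDiagnostics,
    adapt_dt,
    get_operators,
    step_capillary,
    step_nutrient,
    step_taf,
    step_tumor,
)
from .observables_io import ObservableRecord, collect_record
from .tec_agents import (
    TecEvent,
    TipCell,
    imprint_template,
    scan_activation,
    try_anastomose,
    update_tec,
)
from .vasculature import VascularNetwork, grow_sprout

__all__ = ["ScenarioConfig", "ScenarioResult", "days_to_sim_time",
           "build_initial_state", "run_scenario"]

MODES = ("avascular", "vascular", "dll4_blockade", "small_spheroid")

SECONDS_PER_DAY = 86400.0


def days_to_sim_time(days: float, T_scale: float = 1562.5) -> float:
    """Convert days to nondimensional simulation time (T_scale seconds per unit)."""
    if days < 0:
        raise ValueError("days must be nonnegative")
    return days * SECONDS_PER_DAY / T_scale


@dataclass
class ScenarioConfig:
    """Complete description of one simulation experiment."""

    mode: str = "vascular"
    R_t: float = 625.0              # initial tumor radius, um
    necrotic_fraction: float = 0.45  # R_n / R_t
    capillary_width: float = 25.0   # um
    sigma_background: float = 0.45
    sigma_capillary: float = 1.0
    sigma_necrotic: float = 0.0
    delta4_override: float | None = None  # defaults to 55 in dll4_blockade mode
    t_end_days: float | None = None  # per-mode default if None
    seed: int = 0
    nx: int = 512
    ny: int = 396
    output_every_days: float = 0.25  # observable cadence
    snapshot_every_days: float | None = None  # None: first and last only
    param_overrides: dict[str, float] = field(default_factory=dict)

    # Per-mode defaults for the simulated horizon (days).
    _T_END = {"avascular": 1054.0, "vascular": 5.1,
              "dll4_blockade": 5.1, "small_spheroid": 5.1}

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.t_end_days is None:
            self.t_end_days = self._T_END[self.mode]
        if self.delta4_override is None and self.mode == "dll4_blockade":
            self.delta4_override = 55.0

    @property
    def delta4(self) -> float | None:
        return self.delta4_override

    def parameters(self) -> ModelParameters:
        p = ModelParameters().with_overrides(self.param_overrides)
        if self.delta4_override is not None:
            p = p.with_overrides({"delta4": self.delta4_override})
        return p

    def grid(self) -> Grid:
        return Grid(nx=self.nx, ny=self.ny)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls) if f.init}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Initial state
# ---------------------------------------------------------------------------

def build_initial_state(config: ScenarioConfig, grid: Grid,
                        p: ModelParameters) -> tuple[FieldState, VascularNetwork,
                                                     list[TipCell]]:
    """The reference initial condition on the quarter domain.

    Tumor: quarter disc around the top-left corner, phase 1 inside, smoothed
    with a tanh edge.  Capillary: bottom strip, c = +1 inside, -1 elsewhere,
    with an equilibrium-profile tanh edge.  Nutrient: 1 in the capillary, 0
    in the necrotic core, the background level elsewhere.  TAF: 0.  The
    network starts as the single parent vessel spanning the quarter-domain
    width.
    """
    R_t = config.R_t / p.L_scale
    if config.mode == "small_spheroid":
        R_t /= 3.0
    R_n = config.necrotic_fraction * R_t
    strip = config.capillary_width / p.L_scale
    if grid.height - R_t <= strip:
        raise ValueError("initial tumor overlaps the capillary strip")

    X, Y = grid.meshgrid()
    r = np.hypot(X, Y - grid.height)  # distance to tumor center (corner)
    phi = 0.5 * (1.0 + np.tanh((R_t - r) / (p.lambda_phi / 10.0)))
    c = np.tanh((strip - Y) / (np.sqrt(2.0) * p.lambda_c))
    sigma = np.full(grid.shape, config.sigma_background)
    sigma[Y < strip] = config.sigma_capillary
    sigma[r < R_n] = config.sigma_necrotic
    f = np.zeros(grid.shape)

    state = FieldState(phi=phi, sigma=sigma, c=c, f=f, t=0.0)
    state.validate(grid)
    network = VascularNetwork.with_parent(grid.width)
    return state, network, []


# ---------------------------------------------------------------------------
# Run loop
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Everything a finished run produced."""

    config: ScenarioConfig
    records: list[ObservableRecord]
    snapshots: list[FieldState]
    snapshot_times: list[float]
    tecs: list[TipCell]
    network: VascularNetwork
    events: list[TecEvent]
    final_state: FieldState

    @property
    def g_re_final(self) -> float:
        return self.records[-1].g_re


def run_scenario(config: ScenarioConfig,
                 progress: bool = False) -> ScenarioResult:
    """Run one scenario to its configured horizon.

    Step order: nutrient -> tumor -> (unless avascular) TAF -> capillaries ->
    tip-cell moves/imprints -> anastomosis -> activation scan -> network/S
    update, under adaptive step-size control with step rejection.  Avascular
    mode freezes c and f, never activates tip cells and holds S = 1.  Given
    the seed, the run is fully deterministic.
    """
    p = config.parameters()
    grid = config.grid()
    ops = get_operators(grid)
    rng = np.random.default_rng(config.seed)
    avascular = config.mode == "avascular"

    state, network, tecs = build_initial_state(config, grid, p)
    events: list[TecEvent] = []
    n_anastomoses = 0

    t_end = days_to_sim_time(config.t_end_days, p.T_scale)
    out_every = days_to_sim_time(config.output_every_days, p.T_scale)
    snap_every = (days_to_sim_time(config.snapshot_every_days, p.T_scale)
                  if config.snapshot_every_days else None)

    records: list[ObservableRecord] = []
    snapshots: list[FieldState] = []
    snapshot_times: list[float] = []

    A0 = None
    rec0 = collect_record(state, grid, p, network, tecs, n_anastomoses, A0=None)
    A0 = rec0.A_t
    records.append(rec0)
    snapshots.append(state.copy())
    snapshot_times.append(0.0)
    next_output = out_every
    next_snapshot = snap_every

    dt = min(0.01, DT_MAX)
    while state.t < t_end - 1e-12:
        dt = min(dt, t_end - state.t)
        # --- continuum steps with rejection on too-fast change -------------
        while True:
            S = 1.0 if avascular else network.S
            sigma_new = step_nutrient(state, dt, S, p, grid, ops)
            phi_new = step_tumor(state, dt, p, grid, ops)
            if avascular:
                f_new, c_new = state.f, state.c
            else:
                f_new = step_taf(state, dt, p, grid, ops)
                c_new = step_capillary(state, dt, p, grid, ops)
            max_change = max(np.abs(phi_new - state.phi).max(),
                             np.abs(sigma_new - state.sigma).max(),
                             np.abs(f_new - state.f).max(),
                             np.abs(c_new - state.c).max())
            if max_change <= TOL_UP or dt <= 2.0 * DT_MIN:
                break
            dt *= 0.5  # reject and retry with a smaller step
        state.phi, state.sigma = phi_new, sigma_new
        state.f, state.c = f_new, c_new
        state.t += dt

        # --- discrete agents ------------------------------------------------
        max_tec_speed = 0.0
        if not avascular:
            for tec in tecs:
                if not tec.active:
                    continue
                before = tec.path_length
                update_tec(tec, state, dt, p, grid)
                moved = tec.path_length - before
                if moved > 0.0:
                    grow_sprout(network, tec.sprout_id, moved)
                imprint_template(state.c, tec, p, grid)
                max_tec_speed = max(max_tec_speed, float(np.hypot(*tec.velocity)))
                if tec.redirect_dir is not None and tec.active:
                    if not any(e.tec_id == tec.id and e.event == "redirect"
                               for e in events):
                        events.append(TecEvent(state.t, tec.id, "redirect",
                                               *tec.pos))
                if try_anastomose(tec, state, p, grid):
                    n_anastomoses += 1
                    network.close_sprout(tec.sprout_id)
                    imprint_template(state.c, tec, p, grid)
                    events.append(TecEvent(state.t, tec.id, "anastomosis",
                                           *tec.pos))
                elif not tec.active:
                    network.close_sprout(tec.sprout_id)
                    events.append(TecEvent(state.t, tec.id, "deactivation",
                                           *tec.pos))
            new_tec = scan_activation(state, tecs, p, grid, rng)
            if new_tec is not None:
                new_tec.sprout_id = network.open_sprout(initial_length=1e-3)
                dists = [float(np.hypot(*(t_.pos - new_tec.pos)))
                         for t_ in tecs if t_.active]
                imprint_template(state.c, new_tec, p, grid)
                tecs.append(new_tec)
                events.append(TecEvent(state.t, new_tec.id, "activation",
                                       *new_tec.pos,
                                       nearest_active=min(dists, default=float("nan"))))
            # proliferation plus imprinting can push c marginally past the
            # bulk value; fold the overshoot back into the admissible band
            np.clip(state.c, -1.05, 1.05, out=state.c)
        state.validate(grid)

        # --- output ---------------------------------------------------------
        if state.t >= next_output - 1e-9 or state.t >= t_end - 1e-12:
            S_now = 1.0 if avascular else network.S
            records.append(collect_record(state, grid, p, network, tecs,
                                          n_anastomoses, A0=A0,
                                          S_override=S_now))
            while next_output <= state.t + 1e-9:
                next_output += out_every
        if snap_every and state.t >= next_snapshot - 1e-9:
            snapshots.append(state.copy())
            snapshot_times.append(state.t)
            while next_snapshot <= state.t + 1e-9:
                next_snapshot += snap_every
        if progress:  # pragma: no cover - cosmetic
            print(f"\rt = {state.t:10.1f} / {t_end:.1f}  dt = {dt:8.4f}  "
                  f"tecs = {sum(t_.active for t_ in tecs)}", end="")

        dt = adapt_dt(dt, StepDiagnostics(max_change=max_change,
                                          max_tec_speed=max_tec_speed), p)

    if snapshots[-1] is not state and snapshot_times[-1] != state.t:
        snapshots.append(state.copy())
        snapshot_times.append(state.t)
    if progress:  # pragma: no cover
        print()
    return ScenarioResult(config=config, records=records, snapshots=snapshots,
                          snapshot_times=snapshot_times, tecs=tecs,
                          network=network, events=events, final_state=state)
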