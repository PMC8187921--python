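"""Monodomain simulation driver: grids, scenarios, cross-field initiation.

Two AF scenarios are supported.  Scenario A models early-stage AF:
healthy diffusion 0.1 mm^2/ms (conduction velocity 0.7 m/s) with the
second cross-field stimulus at 28 ms anchored at the LSPV.  Scenario B
models persistent AF: diffusion 0.05 mm^2/ms (0.5 m/s), S2 at 58 ms
anchored at the disk centre.  Fibrotic tissue conducts slowly
(0.15 x healthy D); PV/LAA openings and everything outside the disk are
non-conducting with zero-flux borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .fenton_karma import FKParams, PARAM_SETS, advance, face_coefficients
from .geometry import DiskTemplate
from .tissue import TissueImage, HEALTHY, FIBROTIC

logger = logging.getLogger(__name__)

FIBROSIS_D_FACTOR = 0.15  # diffusion scaling in fibrotic tissue (slow conduction)


@dataclass(frozen=True)
class ScenarioConfig:
    """Numerical and protocol settings for one AF scenario."""

    name: str                   # "A" or "B"
    healthy_D: float            # mm^2/ms in healthy myocardium
    s2_time: float              # ms after start for the S2 stimulus
    s2_anchor: str              # "LSPV" or "centre"
    fibrosis_factor: float = FIBROSIS_D_FACTOR
    duration: float = 2000.0    # ms
    dt: float = 0.01            # ms
    dx: float = 0.3             # mm (must match template pixel size)
    snapshot_every: float = 10.0  # ms, observer/tracking cadence
    s1_width: float = 3.0       # mm, S1 stimulus strip along the left edge
    s2_retry_step: float = 25.0  # ms added to s2_time per retry
    s2_max_retries: int = 5
    params: FKParams = field(default_factory=lambda: PARAM_SETS["ATRIAL_AF"])

    @staticmethod
    def scenario_a(**overrides) -> "ScenarioConfig":
        cfg = ScenarioConfig(name="A", healthy_D=0.1, s2_time=28.0, s2_anchor="LSPV")
        return replace(cfg, **overrides)

    @staticmethod
    def scenario_b(**overrides) -> "ScenarioConfig":
        cfg = ScenarioConfig(name="B", healthy_D=0.05, s2_time=58.0, s2_anchor="centre")
        return replace(cfg, **overrides)


def scenario(name: str, **overrides) -> ScenarioConfig:
    if name.upper() == "A":
        return ScenarioConfig.scenario_a(**overrides)
    if name.upper() == "B":
        return ScenarioConfig.scenario_b(**overrides)
    raise ValueError(f"unknown scenario {name!r}")


@dataclass
class SimGrid:
    """Conduction mask and per-node diffusion on the tissue raster."""

    conduction_mask: np.ndarray   # bool (rows, cols)
    diffusion: np.ndarray         # float, mm^2/ms, 0 off-mask
    dx: float
    template: DiskTemplate | None = None
    _coeffs: tuple | None = None

    def coefficients(self):
        if self._coeffs is None:
            self._coeffs = face_coefficients(self.diffusion, self.conduction_mask, self.dx)
        return self._coeffs

    def invalidate(self):
        """Drop cached face coefficients (after lesions change the mask)."""
        self._coeffs = None

    def n_conducting(self) -> int:
        return int(self.conduction_mask.sum())


@dataclass
class SimState:
    """Fenton-Karma fields on the grid at time t (ms)."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    t: float = 0.0

    @staticmethod
    def resting(grid: SimGrid) -> "SimState":
        shape = grid.conduction_mask.shape
        u = np.zeros(shape, dtype=np.float32)
        v = np.ones(shape, dtype=np.float32)
        w = np.ones(shape, dtype=np.float32)
        return SimState(u=u, v=v, w=w, t=0.0)

    def copy(self) -> "SimState":
        return SimState(self.u.copy(), self.v.copy(), self.w.copy(), self.t)


@dataclass
class SimRecord:
    """Result of one AF-initiation run."""

    scenario: ScenarioConfig
    final_state: SimState
    grid: SimGrid
    snapshot_times: list[float]
    snapshots: list[np.ndarray]          # u at snapshot cadence (float32 copies)
    max_u_trace: list[float]             # max u over conducting nodes per snapshot
    s2_time_used: float = 0.0
    retries: int = 0
    no_af: bool = False


class SimulationDiverged(RuntimeError):
    pass


def build_sim_grid(tissue: TissueImage, scenario: ScenarioConfig) -> SimGrid:
    """Map tissue labels to diffusion: healthy D, 0.15*D in fibrosis, 0 in void."""
    d = np.zeros(tissue.labels.shape, dtype=np.float64)
    d[tissue.labels == HEALTHY] = scenario.healthy_D
    d[tissue.labels == FIBROTIC] = scenario.healthy_D * scenario.fibrosis_factor
    mask = tissue.labels != 0
    return SimGrid(conduction_mask=mask, diffusion=d, dx=scenario.dx,
                   template=tissue.template)


def step(state: SimState, grid: SimGrid, params: FKParams,
         dt: float = 0.01, n_steps: int = 1, diffusion_only: bool = False) -> SimState:
    """Advance ``state`` in place by ``n_steps`` explicit-Euler steps.

    Raises :class:`SimulationDiverged` on non-finite or runaway voltage.
    """
    umax = advance(state.u, state.v, state.w, grid.coefficients(),
                   grid.conduction_mask, params, dt, n_steps,
                   diffusion_only=diffusion_only)
    state.t += dt * n_steps
    if not np.isfinite(umax) or umax > 3.0:
        raise SimulationDiverged(f"|u| reached {umax:.3g} at t={state.t:.2f} ms")
    return state


def _anchor_point(template: DiskTemplate, anchor: str) -> tuple[float, float]:
    if anchor.upper() == "LSPV":
        return template.pv_centres["LSPV"]
    if anchor.lower() in ("centre", "center"):
        return template.centre
    raise ValueError(f"unknown S2 anchor {anchor!r}")


def apply_cross_field(state: SimState, grid: SimGrid, scenario: ScenarioConfig,
                      stage: str) -> SimState:
    """Apply one stage of the cross-field protocol.

    S1: a vertical strip (scenario.s1_width mm) along the left edge of
    the conducting tissue is set to u = 1, launching a planar wave in
    +x.  S2 cuts that wave: u is reset to 0 (gates untouched) in the
    axis-aligned quadrant up-and-left of the anchor point (one corner
    at the anchor).  The surviving wavefront ends at the cut line; the
    free end curls into the resetting region as its gates recover,
    forming a rotor anchored near the cut corner.  Only conducting
    nodes are touched.
    """
    template = grid.template
    ny, nx = state.u.shape
    dxmm = grid.dx
    x = (np.arange(nx) + 0.5) * dxmm
    y = (np.arange(ny) + 0.5) * dxmm
    xx, yy = np.meshgrid(x, y)
    if stage.upper() == "S1":
        cols = np.where(grid.conduction_mask.any(axis=0))[0]
        x_min = (cols[0] + 0.5) * dxmm if cols.size else 0.0
        region = xx <= x_min + scenario.s1_width
        state.u[region & grid.conduction_mask] = 1.0
    elif stage.upper() == "S2":
        if template is None:
            raise ValueError("S2 needs a template for its anchor")
        ax, ay = _anchor_point(template, scenario.s2_anchor)
        region = (xx <= ax) & (yy <= ay)
        state.u[region & grid.conduction_mask] = 0.0
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return state


def _max_u(state: SimState, grid: SimGrid) -> float:
    if grid.n_conducting() == 0:
        return 0.0
    return float(state.u[grid.conduction_mask].max())


def run_protocol(grid: SimGrid, scenario: ScenarioConfig, s2_time: float,
                 duration: float, observers=(),
                 early_stop_quiescent_after: float | None = None) -> SimRecord:
    """One S1-S2 run from rest to ``duration`` ms at snapshot cadence.

    With ``early_stop_quiescent_after`` set (used by the S2 retry
    probes), the run ends as soon as the tissue has been quiescent for
    100 ms at any time past that point — a dead probe needs no further
    integration.
    """
    params = scenario.params
    state = SimState.resting(grid)
    apply_cross_field(state, grid, scenario, "S1")
    cadence = scenario.snapshot_every
    steps_per_snap = max(1, int(round(cadence / scenario.dt)))
    record = SimRecord(scenario=scenario, final_state=state, grid=grid,
                       snapshot_times=[], snapshots=[], max_u_trace=[],
                       s2_time_used=s2_time)

    def snap():
        record.snapshot_times.append(state.t)
        record.snapshots.append(state.u.copy())
        record.max_u_trace.append(_max_u(state, grid))
        for obs in observers:
            obs(state.t, state.u)

    snap()
    s2_done = False
    n_snaps = int(round(duration / cadence))
    for _ in range(n_snaps):
        # apply S2 mid-interval when its time falls inside this chunk
        t_next = state.t + cadence
        if not s2_done and s2_time < t_next - 1e-9:
            n1 = max(0, int(round((s2_time - state.t) / scenario.dt)))
            if n1:
                step(state, grid, params, scenario.dt, n1)
            apply_cross_field(state, grid, scenario, "S2")
            s2_done = True
            n2 = int(round((t_next - state.t) / scenario.dt))
            if n2:
                step(state, grid, params, scenario.dt, n2)
        else:
            step(state, grid, params, scenario.dt, steps_per_snap)
        snap()
        if (early_stop_quiescent_after is not None
                and s2_done and state.t > early_stop_quiescent_after
                and is_quiescent(record.max_u_trace, record.snapshot_times)):
            break
    record.final_state = state
    return record


def _reentry_sustained(record: SimRecord, scenario: ScenarioConfig) -> bool:
    """Not quiescent 500 ms after S2 and a tip is detectable near the end."""
    from .tracking import find_tips, tracking_mask

    t_check = record.s2_time_used + 500.0
    times = np.asarray(record.snapshot_times)
    alive = any(m >= 0.1 for t, m in zip(record.snapshot_times, record.max_u_trace)
                if t >= t_check)
    if not alive:
        return False
    idx = np.where(times >= t_check)[0]
    px = scenario.dx
    mask = tracking_mask(record.grid.template) \
        if record.grid.template is not None else None
    for i in idx[-8:]:
        if i + 1 < len(record.snapshots):
            tips = find_tips(record.snapshots[i], record.snapshots[i + 1],
                             pixel_size=px, mask=mask)
            if tips:
                return True
    return False


def _extend(record: SimRecord, scenario: ScenarioConfig, grid: SimGrid,
            duration: float, observers=(),
            early_stop_quiescent: bool = False) -> SimRecord:
    """Continue an existing record (S2 already applied) to ``duration``."""
    state = record.final_state
    params = scenario.params
    cadence = scenario.snapshot_every
    steps_per_snap = max(1, int(round(cadence / scenario.dt)))
    while state.t < duration - 1e-9:
        step(state, grid, params, scenario.dt, steps_per_snap)
        record.snapshot_times.append(state.t)
        record.snapshots.append(state.u.copy())
        record.max_u_trace.append(_max_u(state, grid))
        for obs in observers:
            obs(state.t, state.u)
        if early_stop_quiescent and is_quiescent(record.max_u_trace,
                                                 record.snapshot_times):
            break
    record.final_state = state
    return record


def simulate(tissue: TissueImage, scenario: ScenarioConfig,
             observers=()) -> SimRecord:
    """Initiate AF on a tissue, retrying with a delayed S2 if needed.

    Each attempt runs the S1-S2 protocol to S2 + 600 ms (stopping early
    if the tissue dies out) and checks for sustained re-entry: not
    quiescent 500 ms past S2 and a detectable tip.  Failed attempts
    delay S2 by ``s2_retry_step`` ms, up to ``s2_max_retries`` times —
    with the wave cut at the anchor, re-entry needs the front to have
    passed it, so the step is sized to move the front a few cm.  On
    success the same run is continued to the scenario duration (bit-
    identical to an uninterrupted run).  Observers implementing
    ``reset()`` are cleared before each attempt.  The record is flagged
    ``no_af`` when every retry fails.
    """
    grid = build_sim_grid(tissue, scenario)
    s2 = scenario.s2_time
    retries = 0
    while True:
        for obs in observers:
            if hasattr(obs, "reset"):
                obs.reset()
        probe_end = min(scenario.duration, s2 + 600.0)
        record = run_protocol(grid, scenario, s2, probe_end, observers,
                              early_stop_quiescent_after=s2 + 100.0)
        record.retries = retries
        if _reentry_sustained(record, scenario):
            if record.final_state.t < scenario.duration - 1e-9:
                _extend(record, scenario, grid, scenario.duration, observers,
                        early_stop_quiescent=True)
            # a rotor that passed the 500 ms probe can still extinguish
            # (e.g. drift into an opening); that too means re-entry was
            # not sustained for this S2 timing
            if not is_quiescent(record.max_u_trace, record.snapshot_times):
                return record
        if retries >= scenario.s2_max_retries:
            logger.warning("no sustained re-entry after %d retries", retries)
            record.no_af = True
            return record
        retries += 1
        s2 += scenario.s2_retry_step


def is_quiescent(max_u_trace, times, u_threshold: float = 0.1,
                 hold_ms: float = 100.0) -> bool:
    """True iff max u over conducting nodes stayed below ``u_threshold``
    for the final ``hold_ms`` of the trace."""
    times = np.asarray(times, dtype=float)
    trace = np.asarray(max_u_trace, dtype=float)
    if times.size == 0:
        return True
    t_end = times[-1]
    tail = trace[times >= t_end - hold_ms + 1e-9]
    if times[0] > t_end - hold_ms + 1e-9 and times[0] > 0:
        return False  # trace does not cover the hold window
    return bool((tail < u_threshold).all())


def measure_cv(params: FKParams, D: float, dx: float = 0.3, dt: float = 0.01,
               strip_rows: int = 20, strip_cols: int = 200,
               probe_sep_mm: float = 36.0) -> float:
    """Conduction velocity (m/s) of a planar wave in a homogeneous strip.

    A thin rectangle is stimulated at its left end; activation times
    (u upward-crossing 0.5) are measured at two probes at least 30 mm
    apart on the mid row, and CV = separation / delay (mm/ms = m/s).
    Raises RuntimeError if the wave fails to reach the far probe.
    """
    mask = np.ones((strip_rows, strip_cols), dtype=bool)
    d = np.full(mask.shape, float(D))
    grid = SimGrid(conduction_mask=mask, diffusion=d, dx=dx)
    state = SimState.resting(grid)
    state.u[:, : max(2, int(round(3.0 / dx)))] = 1.0
    row = strip_rows // 2
    x1_mm = 0.25 * strip_cols * dx
    c1 = int(round(x1_mm / dx))
    c2 = c1 + int(round(probe_sep_mm / dx))
    if c2 >= strip_cols - 2:
        raise ValueError("strip too short for the probe separation")
    t1 = t2 = None
    check_every = max(1, int(round(0.1 / dt)))  # 0.1 ms resolution
    max_t = strip_cols * dx / 0.05  # generous bound: slower than 0.05 m/s fails
    prev1 = prev2 = 0.0
    while state.t < max_t:
        step(state, grid, params, dt, check_every)
        u1 = float(state.u[row, c1]); u2 = float(state.u[row, c2])
        if t1 is None and prev1 < 0.5 <= u1:
            t1 = state.t
        if t2 is None and prev2 < 0.5 <= u2:
            t2 = state.t
            break
        prev1, prev2 = u1, u2
    if t1 is None or t2 is None:
        raise RuntimeError("planar wave failed to propagate across the strip")
    return (c2 - c1) * dx / (t2 - t1)
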