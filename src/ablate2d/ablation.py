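"""Catheter-ablation strategies on a running AF simulation.

Three strategy families are simulated: Fibro (ablate the healthy/
fibrotic border), PVI in two variants (rings around each PV, or one
large ring around each left/right PV pair), and Rotor (ablate the
tracked rotor tip, re-targeted at every interval).  Lesions are small
discs in which membrane potential and diffusion are set to zero with
zero-flux borders, mimicking a catheter tip.  Each run is capped at
2000 ms of ablation time and 40% of the initially conducting tissue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import DiskTemplate, PV_NAMES
from .simulator import (
    ScenarioConfig, SimGrid, SimRecord, SimState,
    build_sim_grid, is_quiescent, simulate, step,
)
from .tissue import TissueImage, FIBROTIC, HEALTHY
from .tracking import TipObservation, find_tips, tracking_mask

logger = logging.getLogger(__name__)

LESION_RADIUS_DEFAULT = 2.0     # mm, catheter-tip footprint
LESION_SPACING_FACTOR = 1.5     # centre spacing <= 1.5 x radius -> continuous line
MAX_ABLATED_PERCENT = 40.0
ABLATION_TIME_CAP = 2000.0      # ms of ablation-phase simulation
STRATEGIES = ("FIBRO", "PVI1", "PVI2", "ROTOR")
INTERVALS = (10.0, 30.0)


@dataclass(frozen=True)
class Lesion:
    """One circular catheter lesion (centre in mm)."""

    centre: tuple[float, float]
    radius: float = LESION_RADIUS_DEFAULT

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass
class OutcomeRecord:
    """Result of one (tissue, scenario, strategy, interval) ablation run."""

    tissue_id: str
    scenario: str
    strategy: str
    interval: float
    success: bool
    ablated_percent: float
    termination_time: float | None   # ms from ablation onset, None if AF persisted
    lesions_applied: int = 0
    no_af: bool = False              # AF never initiated -> strategy untestable


# ---------------------------------------------------------------------------
# Lesion planning


def _space_along(path: np.ndarray, spacing: float, radius: float) -> list[Lesion]:
    """Place lesions along a polyline at <= ``spacing`` arc-length steps."""
    if len(path) == 0:
        return []
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total == 0:
        return [Lesion((float(path[0, 0]), float(path[0, 1])), radius)]
    n = max(2, int(math.ceil(total / spacing)) + 1)
    targets = np.linspace(0.0, total, n)
    xs = np.interp(targets, arclen, path[:, 0])
    ys = np.interp(targets, arclen, path[:, 1])
    return [Lesion((float(x), float(y)), radius) for x, y in zip(xs, ys)]


def fibro_plan(tissue: TissueImage,
               radius: float = LESION_RADIUS_DEFAULT) -> list[Lesion]:
    """Lesions tracing the healthy/fibrotic border of every fibrotic patch.

    Each connected fibrotic component contributes one contiguous run of
    lesions ordered along its contour (sub-pixel marching-squares
    contour of the component mask), spaced for a continuous line.  Only
    the border against *healthy* tissue is ablated: stretches of the
    contour facing void (disk edge, PV/LAA rims) are already
    non-conducting and are skipped.  Tissues without fibrosis give an
    empty plan.
    """
    fib = tissue.labels == FIBROTIC
    if not fib.any():
        return []
    px = tissue.template.pixel_size
    spacing = LESION_SPACING_FACTOR * radius
    healthy = tissue.labels == HEALTHY
    # fibrotic pixels 4-adjacent to healthy: the ablatable border
    neigh = np.zeros_like(healthy)
    neigh[1:, :] |= healthy[:-1, :]
    neigh[:-1, :] |= healthy[1:, :]
    neigh[:, 1:] |= healthy[:, :-1]
    neigh[:, :-1] |= healthy[:, 1:]
    border = fib & neigh

    def near_border(x, y):
        j = min(max(int(x / px - 0.5), 0), border.shape[1] - 1)
        i = min(max(int(y / px - 0.5), 0), border.shape[0] - 1)
        i0, i1 = max(0, i - 2), min(border.shape[0], i + 3)
        j0, j1 = max(0, j - 2), min(border.shape[1], j + 3)
        return border[i0:i1, j0:j1].any()

    comp_labels, n_comp = ndimage.label(fib)
    plan: list[Lesion] = []
    for c in range(1, n_comp + 1):
        comp = comp_labels == c
        if comp.sum() < 2:
            rows, cols = np.nonzero(comp)
            lesion = Lesion(((cols[0] + 0.5) * px, (rows[0] + 0.5) * px), radius)
            if near_border(*lesion.centre):
                plan.append(lesion)
            continue
        for contour in measure.find_contours(comp.astype(float), 0.5):
            path = np.empty_like(contour)
            path[:, 0] = (contour[:, 1] + 0.5) * px
            path[:, 1] = (contour[:, 0] + 0.5) * px
            plan.extend(l for l in _space_along(path, spacing, radius)
                        if near_border(*l.centre))
    return plan


def _ring(centre: tuple[float, float], ring_radius: float,
          lesion_radius: float) -> list[Lesion]:
    spacing = LESION_SPACING_FACTOR * lesion_radius
    n = max(4, int(math.ceil(2 * math.pi * ring_radius / spacing)))
    angles = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    cx, cy = centre
    return [Lesion((cx + ring_radius * math.cos(a), cy + ring_radius * math.sin(a)),
                   lesion_radius) for a in angles]


def _clear_ring_radius(template: DiskTemplate, centre: tuple[float, float],
                       base_radius: float, lesion_radius: float,
                       exclude: tuple[str, ...] = ()) -> float:
    """Grow a ring radius until the ring clears every other opening."""
    openings = [(name, c, r) for name, (c, r) in template.openings().items()
                if name not in exclude]
    ring_r = base_radius
    for _ in range(50):
        ok = True
        for _, (ox, oy), orad in openings:
            d = math.hypot(ox - centre[0], oy - centre[1])
            # ring band [ring_r - lesion_r, ring_r + lesion_r] must not
            # cut into the opening disc
            if abs(d - ring_r) < orad + lesion_radius:
                if d > ring_r:   # opening outside the ring: cannot fix by growing
                    ok = False if d - orad - lesion_radius < ring_r else ok
                else:
                    ring_r = d + orad + lesion_radius + 0.5
                    ok = False
                    break
        if ok:
            return ring_r
    return ring_r


def pvi1_plan(template: DiskTemplate, clearance: float = 2.0,
              radius: float = LESION_RADIUS_DEFAULT) -> list[Lesion]:
    """Four closed lesion rings, one encircling each PV opening."""
    plan: list[Lesion] = []
    for name in PV_NAMES:
        centre = template.pv_centres[name]
        ring_r = template.pv_radii[name] + clearance + radius
        ring_r = _clear_ring_radius(template, centre, ring_r, radius,
                                    exclude=(name,))
        plan.extend(_ring(centre, ring_r, radius))
    return plan


def pvi2_plan(template: DiskTemplate, clearance: float = 2.0,
              radius: float = LESION_RADIUS_DEFAULT) -> list[Lesion]:
    """Two large lesion rings, one around each left/right PV pair."""
    plan: list[Lesion] = []
    for pair in (("LSPV", "LIPV"), ("RSPV", "RIPV")):
        centres = [template.pv_centres[n] for n in pair]
        cx = sum(c[0] for c in centres) / 2.0
        cy = sum(c[1] for c in centres) / 2.0
        ring_r = max(
            math.hypot(c[0] - cx, c[1] - cy) + template.pv_radii[n]
            for n, c in zip(pair, centres)
        ) + clearance + radius
        ring_r = _clear_ring_radius(template, (cx, cy), ring_r, radius,
                                    exclude=pair + ("LAA",))
        plan.extend(_ring((cx, cy), ring_r, radius))
    return plan


def rotor_next_lesion(latest_tip: TipObservation | None,
                      radius: float = LESION_RADIUS_DEFAULT) -> Lesion | None:
    """Lesion centred on the most recent tracked tip (None if no tip)."""
    if latest_tip is None:
        return None
    return Lesion((latest_tip.x, latest_tip.y), radius)


# ---------------------------------------------------------------------------
# Lesion application and strategy execution


def lesion_pixels(lesion: Lesion, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean raster of pixels whose centres fall inside the lesion disc."""
    ny, nx = shape
    cx, cy = lesion.centre
    r_px = lesion.radius / pixel_size
    i0 = max(0, int((cy / pixel_size - 0.5) - r_px - 1))
    i1 = min(ny, int((cy / pixel_size - 0.5) + r_px + 2))
    j0 = max(0, int((cx / pixel_size - 0.5) - r_px - 1))
    j1 = min(nx, int((cx / pixel_size - 0.5) + r_px + 2))
    out = np.zeros(shape, dtype=bool)
    if i0 >= i1 or j0 >= j1:
        return out
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    xs = (jj + 0.5) * pixel_size
    ys = (ii + 0.5) * pixel_size
    out[i0:i1, j0:j1] = (xs - cx) ** 2 + (ys - cy) ** 2 <= lesion.radius**2
    return out


def apply_lesion(state: SimState, grid: SimGrid, lesion: Lesion) -> int:
    """Ablate: u = 0, D = 0, remove from the conduction mask.

    Returns the number of newly ablated (previously conducting) nodes;
    a lesion entirely in void is a no-op.
    """
    disc = lesion_pixels(lesion, grid.conduction_mask.shape, grid.dx)
    new = disc & grid.conduction_mask
    n_new = int(new.sum())
    if n_new == 0:
        return 0
    grid.conduction_mask[new] = False
    grid.diffusion[new] = 0.0
    state.u[new] = 0.0
    grid.invalidate()
    return n_new


def _plan_for(strategy: str, tissue: TissueImage,
              radius: float) -> list[Lesion] | None:
    if strategy == "FIBRO":
        return fibro_plan(tissue, radius)
    if strategy == "PVI1":
        return pvi1_plan(tissue.template, radius=radius)
    if strategy == "PVI2":
        return pvi2_plan(tissue.template, radius=radius)
    if strategy == "ROTOR":
        return None   # generated online from the tracker
    raise ValueError(f"unknown strategy {strategy!r}")


def established_af_state(tissue: TissueImage, scenario: ScenarioConfig,
                         margin_ms: float = 100.0):
    """Initiate AF and return (state, grid, record) at the ablation start.

    Ablation begins once AF is established: at the first tracked tip's
    birth plus ``margin_ms``.  Returns None in place of the state when
    no sustained re-entry could be initiated.
    """
    record = simulate(tissue, scenario)
    if record.no_af:
        return None, None, record
    # find first tip time from the snapshot stack
    px = scenario.dx
    tip_mask = tracking_mask(tissue.template)
    first_tip_t = None
    for i in range(len(record.snapshots) - 1):
        tips = find_tips(record.snapshots[i], record.snapshots[i + 1],
                         pixel_size=px, t=record.snapshot_times[i],
                         mask=tip_mask)
        if tips:
            first_tip_t = record.snapshot_times[i]
            break
    if first_tip_t is None:
        record.no_af = True
        return None, None, record
    t_start = first_tip_t + margin_ms
    # re-run the protocol up to t_start to get the exact state there
    from .simulator import run_protocol
    grid = build_sim_grid(tissue, scenario)
    start = run_protocol(grid, scenario, record.s2_time_used, t_start)
    return start.final_state, grid, record


def run_strategy(tissue: TissueImage, scenario: ScenarioConfig, strategy: str,
                 interval: float, lesion_radius: float = LESION_RADIUS_DEFAULT,
                 initial: tuple[SimState, SimGrid] | None = None,
                 time_cap: float = ABLATION_TIME_CAP,
                 quiescence_u: float = 0.1,
                 quiescence_hold: float = 100.0) -> OutcomeRecord:
    """Simulate one ablation strategy at one lesion interval.

    Starting from an established AF state, one lesion is applied every
    ``interval`` ms (plan order for FIBRO/PVI; live tip targeting for
    ROTOR).  The run stops at quiescence, plan exhaustion + one
    quiescence-hold window, the 2000 ms cap, or the 40% ablated-tissue
    cap (a lesion that would cross the cap is not applied and ends the
    run).  Success means the tissue is quiescent at the end.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if initial is None:
        state, grid, record = established_af_state(tissue, scenario)
        if state is None:
            return OutcomeRecord(tissue.id, scenario.name, strategy, interval,
                                 success=False, ablated_percent=0.0,
                                 termination_time=None, no_af=True)
    else:
        state, grid = initial[0].copy(), _copy_grid(initial[1])
    params = scenario.params
    n0 = grid.n_conducting()
    plan = _plan_for(strategy, tissue, lesion_radius)
    plan_iter = iter(plan) if plan is not None else None
    ablated = 0
    lesions_applied = 0
    t0 = state.t
    cadence = scenario.snapshot_every
    steps_per_snap = max(1, int(round(cadence / scenario.dt)))
    steps_per_interval = max(1, int(round(interval / scenario.dt)))
    max_u_trace = [float(state.u[grid.conduction_mask].max())] if n0 else [0.0]
    times = [0.0]
    tip_mask = tracking_mask(tissue.template) if strategy == "ROTOR" else None
    prev_frame = state.u.copy()
    prev_t = 0.0
    latest_tip: TipObservation | None = None
    plan_exhausted_at: float | None = None
    while state.t - t0 < time_cap - 1e-9:
        # --- place the next lesion
        lesion = None
        if plan_iter is not None:
            lesion = next(plan_iter, None)
            if lesion is None and plan_exhausted_at is None:
                plan_exhausted_at = state.t - t0
        elif latest_tip is not None:
            lesion = rotor_next_lesion(latest_tip, lesion_radius)
        if lesion is not None:
            disc = lesion_pixels(lesion, grid.conduction_mask.shape, grid.dx)
            would = int((disc & grid.conduction_mask).sum())
            if 100.0 * (ablated + would) / n0 > MAX_ABLATED_PERCENT:
                break
            applied = apply_lesion(state, grid, lesion)
            if applied:
                ablated += applied
                lesions_applied += 1
        # --- advance one interval, sampling at the snapshot cadence
        steps_left = steps_per_interval
        while steps_left > 0:
            n = min(steps_per_snap, steps_left)
            step(state, grid, params, scenario.dt, n)
            steps_left -= n
            m = float(state.u[grid.conduction_mask].max()) if grid.n_conducting() else 0.0
            max_u_trace.append(m)
            times.append(state.t - t0)
            if strategy == "ROTOR":
                tips = find_tips(prev_frame, state.u, pixel_size=grid.dx,
                                 t=prev_t, mask=tip_mask)
                if tips:
                    latest_tip = tips[0]
                prev_frame = state.u.copy()
                prev_t = state.t - t0
        if is_quiescent(max_u_trace, times, quiescence_u, quiescence_hold) \
                and times[-1] >= quiescence_hold:
            break
        if plan_exhausted_at is not None and \
                state.t - t0 > plan_exhausted_at + quiescence_hold:
            break   # plan done and AF still going: declare failure
    success = is_quiescent(max_u_trace, times, quiescence_u, quiescence_hold) \
        and times[-1] >= quiescence_hold
    termination = None
    if success:
        below = [t for t, m in zip(times, max_u_trace) if m < quiescence_u]
        # first time after which the trace stayed below threshold
        termination = times[-1]
        for t, m in zip(reversed(times), reversed(max_u_trace)):
            if m >= quiescence_u:
                break
            termination = t
    return OutcomeRecord(
        tissue_id=tissue.id, scenario=scenario.name, strategy=strategy,
        interval=interval, success=success,
        ablated_percent=100.0 * ablated / n0 if n0 else 0.0,
        termination_time=termination, lesions_applied=lesions_applied,
    )


def _copy_grid(grid: SimGrid) -> SimGrid:
    return SimGrid(conduction_mask=grid.conduction_mask.copy(),
                   diffusion=grid.diffusion.copy(), dx=grid.dx,
                   template=grid.template)


def evaluate_strategies(tissue: TissueImage, scenario: ScenarioConfig,
                        lesion_radius: float = LESION_RADIUS_DEFAULT,
                        time_cap: float = ABLATION_TIME_CAP) -> list[OutcomeRecord]:
    """Run all four strategies at 10 and 30 ms intervals (8 runs).

    The AF initiation is computed once and every run starts from the
    same established AF state, so records are directly comparable and
    deterministic.
    """
    state, grid, _record = established_af_state(tissue, scenario)
    records = []
    for strategy in STRATEGIES:
        for interval in INTERVALS:
            if state is None:
                records.append(OutcomeRecord(
                    tissue.id, scenario.name, strategy, interval,
                    success=False, ablated_percent=0.0,
                    termination_time=None, no_af=True))
            else:
                records.append(run_strategy(
                    tissue, scenario, strategy, interval, lesion_radius,
                    initial=(state, grid), time_cap=time_cap))
    return records


def class_outcomes(records: list[OutcomeRecord]) -> dict[str, float]:
    """Per-class success with minimum ablated% over successful runs.

    The two PVI variants report a single "PVI" class (success = OR over
    both variants and both intervals); FIBRO and ROTOR aggregate over
    their two intervals.  Returns {class: min ablated% among successful
    runs} with only successful classes present.
    """
    group = {"FIBRO": "FIBRO", "PVI1": "PVI", "PVI2": "PVI", "ROTOR": "ROTOR"}
    out: dict[str, float] = {}
    for rec in records:
        if not rec.success:
            continue
        cls = group[rec.strategy]
        if cls not in out or rec.ablated_percent < out[cls]:
            out[cls] = rec.ablated_percent
    return out
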