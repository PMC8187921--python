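"""Tip detection and trajectory linking against independent oracles."""

import itertools

import numpy as np
import pytest

from ablate2d.tracking import (
    RotorTrajectory, TipObservation,
    find_tips, is_stable_rotor, link_trajectories,
)

PX = 0.5  # mm/pixel used by the synthetic fixtures


def spiral_frame(shape, centre_px, theta0, pitch_px=12.0, sigma_px=2.0,
                 r0_px=0.5, rmax_px=None):
    """u field of a rigidly rotating spiral wave arm.

    The excited arm is a Gaussian ridge along an Archimedean spiral
    (theta = theta0 + r / pitch) whose inner end sits at the pivot
    ``centre_px``.  Unlike a pure phase map — whose rotated isolines
    are parallel spirals that never truly intersect — the ridge's
    u = 0.8 isoline is a closed band whose front and back meet at the
    arm end, so consecutive frames have an exact crossing at the pivot.
    """
    from scipy.spatial import cKDTree

    if rmax_px is None:
        rmax_px = 1.2 * max(shape)
    r = np.linspace(r0_px, rmax_px, 1500)
    th = theta0 + r / pitch_px
    cy, cx = centre_px
    pts = np.stack([cy + r * np.sin(th), cx + r * np.cos(th)], axis=1)
    tree = cKDTree(pts)
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx].astype(float)
    d, _ = tree.query(np.stack([y.ravel(), x.ravel()], axis=1))
    return np.exp(-d.reshape(shape) ** 2 / (2 * sigma_px**2))


def winding_number_tips(frame_a, frame_b, px=PX):
    """Independent phase-singularity detector.

    Builds a two-frame phase angle atan2(u_b - m, u_a - m) per node and
    finds plaquettes whose phase winds by +-2pi — a standard
    phase-singularity criterion needing no isolines.
    """
    phase = np.arctan2(frame_b - 0.5, frame_a - 0.5)

    def dwrap(a, b):
        return np.angle(np.exp(1j * (b - a)))

    w = (
        dwrap(phase[:-1, :-1], phase[:-1, 1:])
        + dwrap(phase[:-1, 1:], phase[1:, 1:])
        + dwrap(phase[1:, 1:], phase[1:, :-1])
        + dwrap(phase[1:, :-1], phase[:-1, :-1])
    )
    rows, cols = np.nonzero(np.abs(w) > 5.0)
    pts = np.stack([(cols + 1.0) * px, (rows + 1.0) * px], axis=1)
    # merge plaquette clusters
    merged = []
    for p in pts:
        for q in merged:
            if np.hypot(*(p - q)) < 6 * px:
                break
        else:
            merged.append(p)
    return np.asarray(merged)


class TestFindTips:
    def test_identical_frames_give_no_tips(self):
        frame = spiral_frame((80, 80), (40, 40), 0.0)
        assert find_tips(frame, frame, pixel_size=PX) == []

    def test_uniform_frames_give_no_tips(self):
        a = np.zeros((40, 40))
        b = np.full((40, 40), 0.95)
        assert find_tips(a, a, pixel_size=PX) == []
        assert find_tips(a, b, pixel_size=PX) == []

    def test_rotating_spiral_tip_near_centre(self):
        centre = (41.3, 38.7)
        a = spiral_frame((80, 80), centre, 0.0)
        b = spiral_frame((80, 80), centre, 0.2)
        tips = find_tips(a, b, pixel_size=PX, cluster_radius_mm=4 * PX)
        assert len(tips) >= 1
        d = min(np.hypot(t.x - (centre[1] + 0.5) * PX,
                         t.y - (centre[0] + 0.5) * PX) for t in tips)
        assert d < 2 * PX   # within 2 pixels of the analytic pivot

    def test_tip_error_below_2px_through_rotation(self):
        centre = (40.0, 40.0)
        for theta in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            a = spiral_frame((80, 80), centre, theta)
            b = spiral_frame((80, 80), centre, theta + 0.2)
            tips = find_tips(a, b, pixel_size=PX, cluster_radius_mm=4 * PX)
            d = min(np.hypot(t.x - (centre[1] + 0.5) * PX,
                             t.y - (centre[0] + 0.5) * PX) for t in tips)
            assert d < 2 * PX

    def test_angular_velocity_recovered(self):
        # rigid rotation: u sampled on a probe ring around the pivot
        # shifts by omega per frame; recover omega by circular
        # cross-correlation and check within 5%
        centre = (40.0, 40.0)
        omega = 0.30  # rad/frame
        n_ang = 720
        angles = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
        r = 20.0

        def ring(theta0):
            fr = spiral_frame((80, 80), centre, theta0)
            yy = centre[0] + r * np.sin(angles)
            xx = centre[1] + r * np.cos(angles)
            return fr[np.round(yy).astype(int), np.round(xx).astype(int)]

        r0 = ring(0.0) - 0.5
        estimates = []
        for k in (1, 2, 3):
            rk = ring(omega * k) - 0.5
            corr = np.fft.ifft(np.fft.fft(rk) * np.conj(np.fft.fft(r0))).real
            shift = np.argmax(corr) * 2 * np.pi / n_ang
            estimates.append(shift / k)
        est = np.median(estimates)
        assert est == pytest.approx(omega, rel=0.05)

    def test_translation_equivariance(self):
        a = spiral_frame((90, 90), (40, 40), 0.0)
        b = spiral_frame((90, 90), (40, 40), 0.35)
        tips0 = find_tips(a[:80, :80], b[:80, :80], pixel_size=PX,
                          cluster_radius_mm=4 * PX)
        shift = 7
        tips1 = find_tips(a[shift:80 + shift, shift:80 + shift],
                          b[shift:80 + shift, shift:80 + shift],
                          pixel_size=PX, cluster_radius_mm=4 * PX)
        assert len(tips0) == len(tips1)
        t0 = sorted((t.x, t.y) for t in tips0)
        t1 = sorted((t.x + shift * PX, t.y + shift * PX) for t in tips1)
        for (x0, y0), (x1, y1) in zip(t0, t1):
            assert np.hypot(x1 - x0, y1 - y0) < 0.5 * PX

    def test_mask_filters_tips(self):
        centre = (40.0, 40.0)
        a = spiral_frame((80, 80), centre, 0.0)
        b = spiral_frame((80, 80), centre, 0.2)
        mask = np.ones((80, 80), dtype=bool)
        mask[30:50, 30:50] = False   # exclude the pivot region
        tips_all = find_tips(a, b, pixel_size=PX, cluster_radius_mm=4 * PX)
        tips_masked = find_tips(a, b, pixel_size=PX, mask=mask,
                                cluster_radius_mm=4 * PX)
        assert len(tips_masked) < max(len(tips_all), 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_agreement_with_winding_number_oracle(self, seed):
        # two-rotor fixtures: both detectors must report the same
        # singularity count and matching positions within 3 px.  Each
        # truncated arm contributes two genuine singularities (the
        # pivot and the free outer end), so both detectors see four.
        rng = np.random.default_rng(seed)
        c1 = rng.uniform(20, 28, size=2)
        c2 = rng.uniform(66, 76, size=2)
        th = rng.uniform(0, 2 * np.pi)

        def field(theta):
            s1 = spiral_frame((96, 96), tuple(c1), theta, rmax_px=16.0)
            s2 = spiral_frame((96, 96), tuple(c2), -theta - th, rmax_px=16.0)
            return np.maximum(s1, s2)

        a, b = field(0.0), field(0.05)
        tips = find_tips(a, b, pixel_size=PX, cluster_radius_mm=3 * PX)
        oracle = winding_number_tips(a, b)
        assert len(tips) == len(oracle) == 4
        for t in tips:
            d = min(np.hypot(t.x - o[0], t.y - o[1]) for o in oracle)
            assert d < 3 * PX
        # both true pivots are among the detections
        for c in (c1, c2):
            d = min(np.hypot(t.x - (c[1] + 0.5) * PX,
                             t.y - (c[0] + 0.5) * PX) for t in tips)
            assert d < 3 * PX


def obs(x, y, t):
    return TipObservation(x=x, y=y, t=t)


class TestLinking:
    def test_single_drifting_tip_one_trajectory(self):
        frames = [[obs(10.0 + k, 20.0, 10.0 * k)] for k in range(30)]
        trajs = link_trajectories(frames, linking_radius=5.0)
        assert len(trajs) == 1
        assert len(trajs[0].observations) == 30

    def test_two_static_far_tips_two_trajectories(self):
        frames = [[obs(10, 10, 10 * k), obs(60, 60, 10 * k)] for k in range(10)]
        trajs = link_trajectories(frames, linking_radius=5.0)
        assert len(trajs) == 2
        assert all(len(t.observations) == 10 for t in trajs)

    def test_gap_of_one_frame_tolerated(self):
        frames = [[obs(10, 10, 0)], [], [obs(10.5, 10, 20)]]
        trajs = link_trajectories(frames, linking_radius=5.0)
        assert len(trajs) == 1
        assert trajs[0].lifetime == 20

    def test_gap_beyond_tolerance_breaks(self):
        # stitching disabled: this exercises the frame-wise gap rule
        frames = [[obs(10, 10, 0)], [], [], [obs(10.5, 10, 30)]]
        trajs = link_trajectories(frames, linking_radius=5.0,
                                  max_gap_frames=1, stitch_gap_ms=0)
        assert len(trajs) == 2

    def test_stitching_merges_identity_break(self):
        # rotor double-detected at t=20: frame-wise linking hands the
        # continuation to the duplicate; gap-closing repairs it
        frames = [[obs(10, 10, 0)], [obs(11, 10, 10)],
                  [obs(11.5, 10, 20), obs(20, 10, 20)],
                  [obs(21, 10, 30)], [obs(22, 10, 40)]]
        unstitched = link_trajectories(frames, linking_radius=9.0,
                                       max_gap_frames=1, stitch_gap_ms=0)
        stitched = link_trajectories(frames, linking_radius=9.0,
                                     max_gap_frames=1)
        assert max(len(t.observations) for t in unstitched) < 5
        assert max(t.lifetime for t in stitched) == 40

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_optimal_matching(self, seed):
        # oracle: exhaustive minimum-total-distance matching per frame
        rng = np.random.default_rng(seed)
        n_frames = 6
        frames = []
        for k in range(n_frames):
            n = rng.integers(1, 5)
            frames.append([obs(float(x), float(y), 10.0 * k)
                           for x, y in rng.uniform(0, 60, size=(n, 2))])
        radius = 25.0

        def brute_force(frames):
            finished, active = [], []
            for tips in frames:
                best, best_cost = None, np.inf
                idx_t = range(len(tips))
                for k in range(min(len(active), len(tips)), -1, -1):
                    for t_sub in itertools.permutations(idx_t, k):
                        for a_sub in itertools.combinations(range(len(active)), k):
                            cost, ok = 0.0, True
                            for ai, ti in zip(a_sub, t_sub):
                                last = active[ai][0].observations[-1]
                                d = np.hypot(tips[ti].x - last.x,
                                             tips[ti].y - last.y)
                                if d > radius:
                                    ok = False
                                    break
                                cost += d
                            if ok and cost < best_cost:
                                best, best_cost = (a_sub, t_sub), cost
                    if best is not None:
                        break
                matched_a, matched_t = (set(), set())
                if best:
                    for ai, ti in zip(*best):
                        active[ai][0].observations.append(tips[ti])
                        matched_a.add(ai)
                        matched_t.add(ti)
                nxt = []
                for i, (traj, gap) in enumerate(active):
                    if i in matched_a:
                        nxt.append((traj, 0))
                    elif gap < 1:
                        nxt.append((traj, gap + 1))
                    else:
                        finished.append(traj)
                for ti in range(len(tips)):
                    if ti not in matched_t:
                        nxt.append((RotorTrajectory([tips[ti]]), 0))
                active = nxt
            finished.extend(t for t, _ in active)
            return finished

        got = link_trajectories(frames, linking_radius=radius,
                                max_gap_frames=1, stitch_gap_ms=0)
        want = brute_force([list(f) for f in frames])
        key = lambda tr: (tr.birth, round(tr.observations[0].x, 6))
        got_sets = sorted([[(o.x, o.y, o.t) for o in tr.observations]
                           for tr in got])
        want_sets = sorted([[(o.x, o.y, o.t) for o in tr.observations]
                            for tr in want])
        assert got_sets == want_sets


class TestStableRotor:
    def test_exactly_2000ms_is_stable(self):
        traj = RotorTrajectory([obs(0, 0, 0.0), obs(1, 0, 2000.0)])
        assert is_stable_rotor(traj)

    def test_just_under_is_not(self):
        traj = RotorTrajectory([obs(0, 0, 0.0), obs(1, 0, 1999.9)])
        assert not is_stable_rotor(traj)

    def test_empty_trajectory_is_not(self):
        assert not is_stable_rotor(RotorTrajectory([]))
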