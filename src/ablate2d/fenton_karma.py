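"""Fenton-Karma three-current ionic model and the monodomain kernel.

The cell model has a normalised membrane voltage u in [0, 1] (specific
capacitance folded to 1) and two gates v, w controlling the fast-inward
(Na+-like), slow-inward (Ca2+-like) and slow-outward (K+-like) currents:

    I_fi = -v * H(u - u_c) * (1 - u) * (u - u_c) / tau_d
    I_so =  u * (1 - H(u - u_c)) / tau_0 + H(u - u_c) / tau_r
    I_si = -w * (1 + tanh(k * (u - u_csi))) / (2 * tau_si)

    dv/dt = (1 - H(u - u_c)) * (1 - v) / tau_v_minus(u) - H(u - u_c) * v / tau_v_plus
    dw/dt = (1 - H(u - u_c)) * (1 - w) / tau_w_minus    - H(u - u_c) * w / tau_w_plus

with tau_v_minus(u) = tau_v1m if u >= u_v else tau_v2m, and the
monodomain PDE  du/dt = div(D grad u) - I_ion  integrated by forward
Euler with a 5-point, divergence-form Laplacian.  Face diffusivities are
arithmetic means of the two node diffusivities and are zero across any
face touching a non-conducting node, which enforces zero-flux boundaries
at the domain edge, around the openings, and around ablation lesions.

Resting state: u = 0, v = 1, w = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
from numba import njit

__all__ = ["FKParams", "PARAM_SETS", "fk_currents", "fk_rhs", "advance", "face_coefficients"]


@dataclass(frozen=True)
class FKParams:
    """Fenton-Karma constants (times in ms, rates in 1/ms)."""

    tau_d: float        # fast-inward depolarisation time (1/g_fi)
    tau_r: float        # slow-outward repolarisation time above threshold
    tau_0: float        # slow-outward time below threshold
    tau_si: float       # slow-inward time
    tau_v_plus: float   # fast gate closing time
    tau_v1_minus: float # fast gate reopening time, u >= u_v
    tau_v2_minus: float # fast gate reopening time, u < u_v
    tau_w_plus: float   # slow gate closing time
    tau_w_minus: float  # slow gate reopening time
    u_c: float          # excitation threshold
    u_v: float          # fast-gate switch threshold
    u_csi: float        # slow-inward activation midpoint
    k: float            # slow-inward activation steepness

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name.startswith("tau") and value <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "FKParams":
        return replace(self, **kw)

    def as_array(self) -> np.ndarray:
        """Parameter vector in the fixed order the kernel expects."""
        return np.array(
            [
                self.tau_d, self.tau_r, self.tau_0, self.tau_si,
                self.tau_v_plus, self.tau_v1_minus, self.tau_v2_minus,
                self.tau_w_plus, self.tau_w_minus,
                self.u_c, self.u_v, self.u_csi, self.k,
            ],
            dtype=np.float64,
        )


# Published parameter sets.  "MBR" is the original modified
# Beeler-Reuter fit of the three-current model; "SET3"/"SET8" are the
# widely used sets 3 and 8 from the spiral-breakup literature.
# "ATRIAL_AF" is this package's default (see its definition below).
PARAM_SETS: dict[str, FKParams] = {
    "MBR": FKParams(
        tau_d=0.25, tau_r=50.0, tau_0=8.3, tau_si=45.0,
        tau_v_plus=3.33, tau_v1_minus=1000.0, tau_v2_minus=19.2,
        tau_w_plus=667.0, tau_w_minus=11.0,
        u_c=0.13, u_v=0.055, u_csi=0.85, k=10.0,
    ),
    "SET3": FKParams(
        tau_d=0.25, tau_r=33.33, tau_0=12.5, tau_si=29.0,
        tau_v_plus=3.33, tau_v1_minus=19.6, tau_v2_minus=1250.0,
        tau_w_plus=870.0, tau_w_minus=41.0,
        u_c=0.13, u_v=0.04, u_csi=0.85, k=10.0,
    ),
    "SET8": FKParams(
        tau_d=0.45, tau_r=33.25, tau_0=12.5, tau_si=29.0,
        tau_v_plus=13.03, tau_v1_minus=19.6, tau_v2_minus=1250.0,
        tau_w_plus=800.0, tau_w_minus=40.0,
        u_c=0.13, u_v=0.04, u_csi=0.85, k=10.0,
    ),
}

# AF-remodelled default: SET8 kinetics with tau_r/tau_si shortened so the
# action potential is ~87 ms (AF-remodelled atrium; the resulting
# wavelength CV x APD ~ 60 mm keeps a rotor stable on the 150 mm disk)
# and tau_d calibrated so a planar wave travels at 0.70 m/s at
# D = 0.1 mm^2/ms on the 0.3 mm / 0.01 ms reference discretisation.
PARAM_SETS["ATRIAL_AF"] = PARAM_SETS["SET8"].with_(
    tau_r=18.0, tau_si=16.0, tau_w_plus=350.0, u_c=0.13, tau_d=0.1062,
)
DEFAULT_PARAMS = PARAM_SETS["ATRIAL_AF"]


def fk_currents(u, v, w, p: FKParams):
    """Vectorised (I_fi, I_so, I_si) — reference implementation used by
    the single-cell oracle tests and by the kernel's derivation."""
    u = np.asarray(u, dtype=np.float64)
    above = (u >= p.u_c).astype(np.float64)
    i_fi = -v * above * (1.0 - u) * (u - p.u_c) / p.tau_d
    i_so = u * (1.0 - above) / p.tau_0 + above / p.tau_r
    i_si = -w * (1.0 + np.tanh(p.k * (u - p.u_csi))) / (2.0 * p.tau_si)
    return i_fi, i_so, i_si


def fk_rhs(u, v, w, p: FKParams):
    """Single-cell right-hand side (du, dv, dw)/dt (no diffusion)."""
    i_fi, i_so, i_si = fk_currents(u, v, w, p)
    above = np.asarray(u) >= p.u_c
    tau_v_minus = np.where(np.asarray(u) >= p.u_v, p.tau_v1_minus, p.tau_v2_minus)
    dv = np.where(above, -v / p.tau_v_plus, (1.0 - v) / tau_v_minus)
    dw = np.where(above, -w / p.tau_w_plus, (1.0 - w) / p.tau_w_minus)
    du = -(i_fi + i_so + i_si)
    return du, dv, dw


def face_coefficients(diffusion: np.ndarray, mask: np.ndarray, dx: float):
    """Per-node Laplacian coefficients toward E/W/S/N neighbours.

    c = 0.5 * (D_i + D_j) / dx^2 when both nodes conduct, else 0.  The
    symmetry c_ij = c_ji makes pure diffusion exactly conservative.
    """
    d = np.where(mask, diffusion, 0.0).astype(np.float64)
    ny, nx = d.shape
    ce = np.zeros((ny, nx)); cw = np.zeros((ny, nx))
    cs = np.zeros((ny, nx)); cn = np.zeros((ny, nx))
    both_x = mask[:, :-1] & mask[:, 1:]
    face_x = 0.5 * (d[:, :-1] + d[:, 1:]) * both_x / dx**2
    ce[:, :-1] = face_x
    cw[:, 1:] = face_x
    both_y = mask[:-1, :] & mask[1:, :]
    face_y = 0.5 * (d[:-1, :] + d[1:, :]) * both_y / dx**2
    cs[:-1, :] = face_y
    cn[1:, :] = face_y
    return (
        ce.astype(np.float32), cw.astype(np.float32),
        cs.astype(np.float32), cn.astype(np.float32),
    )


@njit(cache=True, fastmath=True)
def _advance_kernel(u, v, w, ce, cw, cs, cn, mask, prm, dt, n_steps,
                    tanh_lut, lut_u0, lut_du, diffusion_only):
    """Advance the monodomain system ``n_steps`` forward-Euler steps.

    Arrays are float32 and modified in place.  ``tanh_lut`` tabulates
    tanh(k*(u - u_csi)) on a uniform u grid (linear interpolation);
    ``diffusion_only`` disables I_ion (used by conservation tests).
    Returns the running max of |u| as an overflow diagnostic.
    """
    ny, nx = u.shape
    tau_d, tau_r, tau_0, tau_si = prm[0], prm[1], prm[2], prm[3]
    tau_vp, tau_v1m, tau_v2m = prm[4], prm[5], prm[6]
    tau_wp, tau_wm = prm[7], prm[8]
    u_c, u_v = prm[9], prm[10]
    inv_2tau_si = 1.0 / (2.0 * tau_si)
    n_lut = tanh_lut.shape[0]
    du_new = np.empty_like(u)
    umax = 0.0
    for _ in range(n_steps):
        for i in range(ny):
            for j in range(nx):
                if not mask[i, j]:
                    continue
                uc = u[i, j]
                lap = 0.0
                if j + 1 < nx:
                    lap += ce[i, j] * (u[i, j + 1] - uc)
                if j - 1 >= 0:
                    lap += cw[i, j] * (u[i, j - 1] - uc)
                if i + 1 < ny:
                    lap += cs[i, j] * (u[i + 1, j] - uc)
                if i - 1 >= 0:
                    lap += cn[i, j] * (u[i - 1, j] - uc)
                if diffusion_only:
                    du_new[i, j] = uc + dt * lap
                    continue
                vv = v[i, j]
                ww = w[i, j]
                if uc >= u_c:
                    i_fi = -vv * (1.0 - uc) * (uc - u_c) / tau_d
                    i_so = 1.0 / tau_r
                    v[i, j] = vv - dt * vv / tau_vp
                    w[i, j] = ww - dt * ww / tau_wp
                else:
                    i_fi = 0.0
                    i_so = uc / tau_0
                    tau_vm = tau_v1m if uc >= u_v else tau_v2m
                    v[i, j] = vv + dt * (1.0 - vv) / tau_vm
                    w[i, j] = ww + dt * (1.0 - ww) / tau_wm
                # tanh(k*(u - u_csi)) via LUT + linear interpolation
                pos = (uc - lut_u0) / lut_du
                if pos < 0.0:
                    pos = 0.0
                elif pos > n_lut - 1.001:
                    pos = n_lut - 1.001
                idx = int(pos)
                frac = pos - idx
                th = tanh_lut[idx] * (1.0 - frac) + tanh_lut[idx + 1] * frac
                i_si = -ww * (1.0 + th) * inv_2tau_si
                du_new[i, j] = uc + dt * (lap - (i_fi + i_so + i_si))
        for i in range(ny):
            for j in range(nx):
                if mask[i, j]:
                    un = du_new[i, j]
                    u[i, j] = un
                    if abs(un) > umax:
                        umax = abs(un)
    return umax


_LUT_U0 = -0.5
_LUT_U1 = 1.5
_LUT_N = 4096


_lut_cache: dict[tuple[float, float], np.ndarray] = {}


def _tanh_lut(params: FKParams) -> tuple[np.ndarray, float, float]:
    key = (params.k, params.u_csi)
    lut = _lut_cache.get(key)
    if lut is None:
        grid = np.linspace(_LUT_U0, _LUT_U1, _LUT_N)
        lut = np.tanh(params.k * (grid - params.u_csi)).astype(np.float32)
        _lut_cache[key] = lut
    return lut, _LUT_U0, (_LUT_U1 - _LUT_U0) / (_LUT_N - 1)


def advance(u, v, w, coeffs, mask, params: FKParams, dt: float,
            n_steps: int, diffusion_only: bool = False) -> float:
    """Advance state arrays in place by ``n_steps`` Euler steps of ``dt`` ms.

    ``coeffs`` is the 4-tuple from :func:`face_coefficients`.  Returns
    the running max |u| over the interval; the caller aborts on
    non-finite or runaway values.
    """
    ce, cw, cs, cn = coeffs
    lut, u0, du = _tanh_lut(params)
    return _advance_kernel(
        u, v, w, ce, cw, cs, cn, mask, params.as_array(), np.float64(dt),
        n_steps, lut, u0, du, diffusion_only,
    )
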