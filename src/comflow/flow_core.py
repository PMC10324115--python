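"""Single-level variational optical flow, image warping, and HS/LK baselines.

Conventions
-----------
Images are 2-D float arrays indexed ``(row, col)`` with origin at the top
left.  A :class:`FlowField` stores the dense forward displacement from
frame 1 to frame 2: ``u`` is the horizontal (+column) displacement and
``v`` the vertical (+row) displacement, both in pixels.  Forward flows are
applied by backward sampling ("image correction"): the second frame is
resampled at ``x + w(x)`` so that the warped frame approaches frame 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ComflowError

__all__ = [
    "FlowField",
    "SolverParams",
    "warp_image",
    "gradients",
    "solve_level",
    "flow_energy",
    "refine_level",
    "warping_flow",
    "hs_flow",
    "lk_flow",
]


@dataclass
class FlowField:
    """Dense per-pixel displacement field in pixels.

    Parameters
    ----------
    u : ndarray
        Horizontal (column) displacement.
    v : ndarray
        Vertical (row) displacement, same shape as ``u``.
    valid : ndarray of bool, optional
        Per-pixel reliability flag (used by :func:`lk_flow` to mark
        ill-conditioned pixels).
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise ComflowError("u and v must have the same shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ComflowError("flow components must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @classmethod
    def zeros(cls, shape) -> "FlowField":
        return cls(np.zeros(shape), np.zeros(shape))

    def copy(self) -> "FlowField":
        return FlowField(self.u.copy(), self.v.copy(),
                         None if self.valid is None else self.valid.copy())


@dataclass
class SolverParams:
    """Parameters of the per-level relaxation solver.

    alpha : smoothness weight of the quadratic regularizer (dimensionless,
        relative to squared image gradients of a [0, 1]-ranged image).
    outer_iters : warping (re-linearization) iterations per pyramid level.
    inner_iters : conjugate-gradient iterations of the linear system per warp.
    stop_tol : mean absolute flow update (px) below which iterations stop.
    warp_order : spline order of the image interpolation used when
        warping inside the solver loop (3 = bicubic).
    """

    alpha: float = 0.03
    outer_iters: int = 5
    inner_iters: int = 800
    stop_tol: float = 1e-7
    warp_order: int = 3

    def __post_init__(self):
        if self.alpha <= 0:
            raise ComflowError("alpha must be > 0")
        if self.outer_iters < 1 or self.inner_iters < 1:
            raise ComflowError("iteration counts must be >= 1")
        if self.stop_tol < 0:
            raise ComflowError("stop_tol must be >= 0")
        if self.warp_order not in (1, 3):
            raise ComflowError("warp_order must be 1 or 3")


def _as_float(I: np.ndarray) -> np.ndarray:
    I = np.asarray(I, dtype=np.float64)
    if I.ndim != 2:
        raise ComflowError("images must be 2-D")
    return I


def warp_image(I: np.ndarray, w: FlowField,
               order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Backward-warp ``I`` along ``w``: ``out(x) = I(x + w(x))``.

    Bilinear sampling by default (``order=3`` gives bicubic splines),
    with replicated borders.  Returns ``(warped, oob)`` where ``oob``
    flags pixels whose sample position fell outside the image (their
    value comes from border replication).
    """
    I = _as_float(I)
    if I.shape != w.shape:
        raise ComflowError("image and flow shapes differ")
    rows, cols = np.meshgrid(np.arange(I.shape[0], dtype=np.float64),
                             np.arange(I.shape[1], dtype=np.float64),
                             indexing="ij")
    r = rows + w.v
    c = cols + w.u
    warped = ndimage.map_coordinates(I, [r, c], order=order, mode="nearest")
    oob = (r < 0) | (r > I.shape[0] - 1) | (c < 0) | (c > I.shape[1] - 1)
    return warped, oob


def _central_diff(I: np.ndarray, axis: int) -> np.ndarray:
    # 5-point central difference (fourth-order) with replicated borders
    p = np.pad(I, [(2, 2) if a == axis else (0, 0) for a in range(2)],
               mode="edge")
    if axis == 0:
        return (-p[4:, :] + 8 * p[3:-1, :] - 8 * p[1:-3, :] + p[:-4, :]) / 12.0
    return (-p[:, 4:] + 8 * p[:, 3:-1] - 8 * p[:, 1:-3] + p[:, :-4]) / 12.0


def gradients(I1: np.ndarray, I2: np.ndarray):
    """Spatio-temporal derivatives for the brightness-constancy linearization.

    Spatial derivatives use the fourth-order 5-point central stencil
    ``(-1, 8, 0, -8, 1)/12`` (replicated borders) averaged over both
    frames; ``It = I2 - I1``.
    """
    I1 = _as_float(I1)
    I2 = _as_float(I2)
    if I1.shape != I2.shape:
        raise ComflowError("frame shapes differ")
    Ix = 0.5 * (_central_diff(I1, 1) + _central_diff(I2, 1))
    Iy = 0.5 * (_central_diff(I1, 0) + _central_diff(I2, 0))
    It = I2 - I1
    return Ix, Iy, It


def _neighbor_sums(a: np.ndarray) -> np.ndarray:
    s = np.zeros_like(a)
    s[1:, :] += a[:-1, :]
    s[:-1, :] += a[1:, :]
    s[:, 1:] += a[:, :-1]
    s[:, :-1] += a[:, 1:]
    return s


def _neighbor_count(shape) -> np.ndarray:
    n = np.full(shape, 4.0)
    n[0, :] -= 1
    n[-1, :] -= 1
    n[:, 0] -= 1
    n[:, -1] -= 1
    return n


def flow_energy(Ix, Iy, It, du, dv, alpha) -> float:
    """Discrete energy: data term + alpha * first-difference smoothness."""
    data = np.sum((Ix * du + Iy * dv + It) ** 2)
    sm = (np.sum(np.diff(du, axis=0) ** 2) + np.sum(np.diff(du, axis=1) ** 2)
          + np.sum(np.diff(dv, axis=0) ** 2) + np.sum(np.diff(dv, axis=1) ** 2))
    return float(data + alpha * sm)


def solve_level(I1: np.ndarray, I2: np.ndarray,
                init: FlowField | None = None,
                params: SolverParams | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Solve one linearization of brightness constancy for a flow increment.

    ``I2`` is expected to be already warped by ``init`` (the caller's
    accumulated flow), so the increment is small.  Minimizes

        sum (Ix du + Iy dv + It)^2
            + alpha * |grad (u0 + du)|^2 + alpha * |grad (v0 + dv)|^2

    where ``(u0, v0)`` is ``init`` (zero if omitted) — the quadratic
    regularizer acts on the total flow, so at the fixed point of the
    warping loop the accumulated flow minimizes the level's full energy
    and textureless regions interpolate the total flow, not just the
    last increment.  The SPD normal equations are relaxed by conjugate
    gradients from zero; the energy is non-increasing across iterations.
    Stops after ``inner_iters`` iterations or when the mean absolute
    update drops below ``stop_tol`` px.
    """
    if params is None:
        params = SolverParams()
    I1 = _as_float(I1)
    I2 = _as_float(I2)
    if not (np.isfinite(I1).all() and np.isfinite(I2).all()):
        raise ComflowError("non-finite image values")
    Ix, Iy, It = gradients(I1, I2)
    a = params.alpha
    npix = _neighbor_count(I1.shape)
    Ixx = Ix * Ix
    Iyy = Iy * Iy
    Ixy = Ix * Iy

    def matvec(xu, xv):
        # (data-term block + alpha * graph Laplacian) applied to (xu, xv)
        Lu = npix * xu - _neighbor_sums(xu)
        Lv = npix * xv - _neighbor_sums(xv)
        return (Ixx * xu + Ixy * xv + a * Lu,
                Ixy * xu + Iyy * xv + a * Lv)

    bu = -Ix * It
    bv = -Iy * It
    if init is not None:
        if init.shape != I1.shape:
            raise ComflowError("init flow shape differs from image shape")
        bu -= a * (npix * init.u - _neighbor_sums(init.u))
        bv -= a * (npix * init.v - _neighbor_sums(init.v))
    du = np.zeros_like(I1)
    dv = np.zeros_like(I1)
    ru, rv = bu.copy(), bv.copy()
    pu, pv = ru.copy(), rv.copy()
    rs = np.vdot(ru, ru) + np.vdot(rv, rv)
    if rs == 0:
        return du, dv
    for _ in range(params.inner_iters):
        Apu, Apv = matvec(pu, pv)
        denom = np.vdot(pu, Apu) + np.vdot(pv, Apv)
        if denom <= 0:
            break
        step = rs / denom
        du += step * pu
        dv += step * pv
        ru -= step * Apu
        rv -= step * Apv
        rs_new = np.vdot(ru, ru) + np.vdot(rv, rv)
        mean_update = abs(step) * (np.abs(pu).sum() + np.abs(pv).sum()) \
            / (2 * du.size)
        if mean_update < params.stop_tol or rs_new == 0:
            break
        beta = rs_new / rs
        pu = ru + beta * pu
        pv = rv + beta * pv
        rs = rs_new
    return du, dv


def refine_level(I1: np.ndarray, I2: np.ndarray, flow: FlowField,
                 params: SolverParams,
                 confidence: np.ndarray | None = None) -> FlowField:
    """Warping loop at one resolution: warp, solve increment, accumulate.

    The increment is multiplied pixelwise by ``confidence`` (weights in
    [0, 1]) before accumulation; ``None`` means unit confidence.
    """
    u = flow.u.copy()
    v = flow.v.copy()
    for _ in range(params.outer_iters):
        current = FlowField(u, v)
        warped, _ = warp_image(I2, current, order=params.warp_order)
        du, dv = solve_level(I1, warped, init=current, params=params)
        if confidence is not None:
            du = confidence * du
            dv = confidence * dv
        u = u + du
        v = v + dv
    return FlowField(u, v)


def warping_flow(I1: np.ndarray, I2: np.ndarray,
                 params: SolverParams | None = None) -> FlowField:
    """Full-resolution flow with the warping loop and no pyramid."""
    if params is None:
        params = SolverParams()
    return refine_level(_as_float(I1), _as_float(I2),
                        FlowField.zeros(np.asarray(I1).shape), params)


# Baseline parameters are fixed here (not tuned per experiment): classic
# global smoothing weight for HS at unit image range, 15 px LK window.
HS_PARAMS = SolverParams(alpha=0.08, outer_iters=1, inner_iters=400,
                         stop_tol=1e-5)
LK_WINDOW = 15
LK_EIG_TOL = 1e-6


def hs_flow(I1: np.ndarray, I2: np.ndarray,
            params: SolverParams | None = None) -> FlowField:
    """Classic single-level Horn-Schunck flow (one linearization, no pyramid)."""
    if params is None:
        params = HS_PARAMS
    du, dv = solve_level(I1, I2, params=params)
    return FlowField(du, dv)


def lk_flow(I1: np.ndarray, I2: np.ndarray, window: int = LK_WINDOW,
            eig_tol: float = LK_EIG_TOL) -> FlowField:
    """Single-level Lucas-Kanade flow: windowed least squares per pixel.

    Pixels whose structure tensor has a smallest eigenvalue below
    ``eig_tol`` (per-pixel average over the window) are ill-conditioned:
    they receive zero flow and ``valid=False``.
    """
    if window < 3 or window % 2 == 0:
        raise ComflowError("window must be odd and >= 3")
    I1 = _as_float(I1)
    I2 = _as_float(I2)
    Ix, Iy, It = gradients(I1, I2)

    def wsum(a):
        return ndimage.uniform_filter(a, size=window, mode="constant")

    Sxx = wsum(Ix * Ix)
    Syy = wsum(Iy * Iy)
    Sxy = wsum(Ix * Iy)
    Sxt = wsum(Ix * It)
    Syt = wsum(Iy * It)

    tr = Sxx + Syy
    disc = np.sqrt((Sxx - Syy) ** 2 + 4.0 * Sxy ** 2)
    lam_min = 0.5 * (tr - disc)
    det = Sxx * Syy - Sxy * Sxy

    valid = (lam_min > eig_tol) & (det > 0)
    safe_det = np.where(valid, det, 1.0)
    u = np.where(valid, (-Sxt * Syy + Syt * Sxy) / safe_det, 0.0)
    v = np.where(valid, (-Syt * Sxx + Sxt * Sxy) / safe_det, 0.0)
    return FlowField(u, v, valid=valid)
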