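"""U-shaped ventricular-wall phantoms with known ground-truth motion.

The simulated left-ventricular wall is a binary U (two vertical limbs
joined by a half-annulus) on a black background, optionally Gaussian
smoothed and textured with speckle.  Motion is prescribed analytically —
the limbs translate horizontally toward each other and the whole wall
moves down, emulating systolic contraction in an apical view — so every
generated frame pair comes with its exact dense flow field.  An
elliptical multiplicative shadow emulates rib-induced acoustic dropout.

All generators are pure functions of their parameters (and seed, where
noise is involved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidGeometryError, InvalidMotionError
from .flow_core import FlowField
from .sequence import ImageSequence
from .wall_geometry import WallContour

__all__ = ["Phantom", "GroundTruthPair", "make_u_phantom", "make_u_contour",
           "affine_contract", "add_shadow", "add_speckle", "synth_cycle",
           "reference_affine_pair", "DEFAULT_SHADOW"]


@dataclass
class Phantom:
    """A single U-wall frame plus its exact wall mask and geometry."""

    frame: np.ndarray            # intensities in [0, 1]
    wall_mask: np.ndarray        # bool, True = myocardium
    height: int
    width: int
    wall_thickness: float
    cavity_width: float
    center_col: float            # symmetry axis (col)
    arc_center_row: float        # row of the half-annulus center
    top_row: float               # first wall row of the limbs


@dataclass
class GroundTruthPair:
    """Two frames related by a known dense displacement field.

    ``gt_flow`` maps frame-1 pixel positions to frame 2 (forward flow,
    px); it is zero outside the (dilated) moved wall region.  ``roi`` is
    the region over which flow errors are evaluated: the frame-1 wall.
    """

    frame1: np.ndarray
    frame2: np.ndarray
    gt_flow: FlowField
    roi: np.ndarray


def _u_mask_predicate(height, width, wall_thickness, cavity_width):
    """Returns (geometry tuple, vectorized membership test on (r, c))."""
    t = float(wall_thickness)
    hw = float(cavity_width) / 2.0
    cx = (width - 1) / 2.0
    R = hw + t
    margin = max(4.0, round(0.08 * height))
    top = max(2.0, round(0.1 * height))
    rc = height - 1 - margin - R

    def member(r, c):
        dx = np.abs(c - cx)
        limb = (r >= top) & (r <= rc) & (dx >= hw) & (dx <= R)
        rad = np.hypot(r - rc, c - cx)
        base = (r > rc) & (rad >= hw) & (rad <= R)
        return limb | base

    return (cx, rc, top, hw, R), member


def make_u_phantom(height: int, width: int, wall_thickness: float,
                   cavity_width: float, smooth_sigma: float = 0.0) -> Phantom:
    """Build a U-shaped binary wall phantom on a black background.

    The wall consists of two vertical limbs of width ``wall_thickness``
    separated by ``cavity_width`` and joined at the bottom by a
    half-annulus.  ``smooth_sigma > 0`` Gaussian-smooths the rendered
    frame (the mask stays exact).
    """
    if height < 64 or width < 64:
        raise InvalidGeometryError("image must be at least 64x64")
    if wall_thickness <= 0 or cavity_width <= 0:
        raise InvalidGeometryError("wall_thickness and cavity_width must be > 0")
    (cx, rc, top, hw, R), member = _u_mask_predicate(
        height, width, wall_thickness, cavity_width)
    if cx - R < 1 or rc - top < 8 or rc + R > height - 2:
        raise InvalidGeometryError("U geometry does not fit inside the image")
    rr, cc = np.indices((height, width))
    mask = member(rr, cc)
    frame = mask.astype(np.float64)
    if smooth_sigma > 0:
        frame = ndimage.gaussian_filter(frame, smooth_sigma)
        frame = np.clip(frame, 0.0, 1.0)
    return Phantom(frame=frame, wall_mask=mask, height=height, width=width,
                   wall_thickness=float(wall_thickness),
                   cavity_width=float(cavity_width), center_col=cx,
                   arc_center_row=rc, top_row=top)


def make_u_contour(p: Phantom, step: float = 2.0) -> WallContour:
    """Endo/epi contour of a U phantom, base-left -> apex -> base-right."""

    def trace(radius, col_off):
        left = []
        n_limb = max(3, int(round((p.arc_center_row - p.top_row) / step)))
        rows = np.linspace(p.top_row, p.arc_center_row, n_limb)
        for r in rows:
            left.append((r, p.center_col - col_off))
        n_arc = max(5, int(round(np.pi * radius / step)))
        ang = np.linspace(0, np.pi, n_arc + 1)[1:]
        arc = [(p.arc_center_row + radius * np.sin(a),
                p.center_col - radius * np.cos(a)) for a in ang]
        right = [(r, p.center_col + col_off) for r in rows[::-1][1:]]
        pts = np.array(left + arc + right)
        apex = len(left) + n_arc // 2 - 1
        return pts, apex

    hw = p.cavity_width / 2.0
    endo, apex = trace(hw, hw)
    epi, _ = trace(hw + p.wall_thickness, hw + p.wall_thickness)
    return WallContour(endo_points=endo, epi_points=epi, apex_index=apex,
                       image_shape=(p.height, p.width))


def _displacement_field(p: Phantom, left_dx: float, right_dx: float,
                        global_dy: float):
    """Continuous forward displacement: +-dx on the limbs, linear blend
    of the horizontal component across the cavity/base, dy everywhere."""
    cols = np.arange(p.width, dtype=np.float64)
    hw = p.cavity_width / 2.0
    cl = p.center_col - hw
    cr = p.center_col + hw
    frac = np.clip((cols - cl) / (cr - cl), 0.0, 1.0)
    dx_col = left_dx + frac * (right_dx - left_dx)
    u = np.tile(dx_col, (p.height, 1))
    v = np.full((p.height, p.width), float(global_dy))
    return u, v


def _backward_sample(I: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """First-order inverse warp: out(y) = I(y - d(y)); exact where the
    displacement is locally constant."""
    rr, cc = np.indices(I.shape)
    return ndimage.map_coordinates(I.astype(np.float64), [rr - v, cc - u],
                                   order=1, mode="constant", cval=0.0)


def affine_contract(p: Phantom, left_dx: float, right_dx: float,
                    global_dy: float) -> GroundTruthPair:
    """Apply the affine contraction motion to a phantom.

    The left limb translates by ``(left_dx, global_dy)``, the right limb
    by ``(right_dx, global_dy)``; across the base the horizontal
    component blends linearly with column so the field is continuous.
    """
    limit = p.wall_thickness + p.cavity_width
    for d in (left_dx, right_dx, global_dy):
        if abs(d) >= limit:
            raise InvalidMotionError("motion exceeds wall + cavity size")
    if left_dx - right_dx >= p.cavity_width:
        raise InvalidMotionError("limbs would collide")
    u, v = _displacement_field(p, left_dx, right_dx, global_dy)
    frame2 = _backward_sample(p.frame, u, v)
    mask2 = _backward_sample(p.wall_mask.astype(np.float64), u, v) >= 0.5
    support = ndimage.binary_dilation(p.wall_mask | mask2, iterations=1)
    gt = FlowField(np.where(support, u, 0.0), np.where(support, v, 0.0))
    return GroundTruthPair(frame1=p.frame.copy(), frame2=frame2,
                           gt_flow=gt, roi=p.wall_mask.copy())


def add_shadow(frame: np.ndarray, center: tuple[float, float],
               axes: tuple[float, float], attenuation: float) -> np.ndarray:
    """Multiply intensities inside an ellipse by ``1 - attenuation``."""
    if not (0.0 <= attenuation <= 1.0):
        raise InvalidGeometryError("attenuation must be in [0, 1]")
    frame = np.asarray(frame, dtype=np.float64)
    rr, cc = np.indices(frame.shape)
    inside = (((rr - center[0]) / axes[0]) ** 2
              + ((cc - center[1]) / axes[1]) ** 2) <= 1.0
    if not inside.any():
        raise InvalidGeometryError("shadow ellipse does not intersect image")
    out = frame.copy()
    out[inside] *= (1.0 - attenuation)
    return out


def shadow_mask(shape, center, axes) -> np.ndarray:
    """Boolean raster of the elliptical shadow region."""
    rr, cc = np.indices(shape)
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def add_speckle(frame: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Multiplicative correlated speckle, clipped to [0, 1].

    The noise field is unit-variance Gaussian noise smoothed with a
    1-px Gaussian (echo-like granularity); output is
    ``clip(frame * (1 + sigma * g), 0, 1)``.  Bit-reproducible per seed.
    """
    if sigma < 0:
        raise InvalidGeometryError("sigma must be >= 0")
    frame = np.asarray(frame, dtype=np.float64)
    if sigma == 0:
        return frame.copy()
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(frame.shape)
    g = ndimage.gaussian_filter(g, 1.0)
    g /= g.std()
    return np.clip(frame * (1.0 + sigma * g), 0.0, 1.0)


def synth_cycle(p: Phantom, n_frames: int, peak_left_dx: float,
                peak_right_dx: float, peak_dy: float,
                mm_per_px: float | None = None,
                frame_interval_s: float | None = None
                ) -> tuple[ImageSequence, list[FlowField]]:
    """Simulate one contraction-relaxation cycle with known flows.

    Cumulative displacement follows a half-sine schedule
    ``c_k = sin(pi k / (n_frames - 1))`` scaling the peak displacement
    field, so the wall contracts to its peak mid-cycle and returns to
    the start.  Returns the frame stack and the ``n_frames - 1``
    incremental ground-truth flows between consecutive frames.  With
    ``n_frames = 2`` the cycle degenerates to the single contraction
    step of :func:`affine_contract`.
    """
    if n_frames < 2:
        raise InvalidMotionError("need at least 2 frames")
    if n_frames == 2:
        sched = np.array([0.0, 1.0])
    else:
        sched = np.sin(np.pi * np.arange(n_frames) / (n_frames - 1))
    Du, Dv = _displacement_field(p, peak_left_dx, peak_right_dx, peak_dy)

    frames = []
    for c in sched:
        frames.append(_backward_sample(p.frame, c * Du, c * Dv))
    frames = np.array(frames)

    rr, cc = np.indices(p.frame.shape)
    flows = []
    for k in range(n_frames - 1):
        ck, cn = sched[k], sched[k + 1]
        # evaluate the peak field at the frame-k preimage position
        r0 = rr - ck * Dv
        c0 = cc - ck * Du
        Du_k = ndimage.map_coordinates(Du, [r0, c0], order=1, mode="nearest")
        Dv_k = ndimage.map_coordinates(Dv, [r0, c0], order=1, mode="nearest")
        flows.append(FlowField((cn - ck) * Du_k, (cn - ck) * Dv_k))
    seq = ImageSequence(frames=frames, mm_per_px=mm_per_px,
                        frame_interval_s=frame_interval_s)
    return seq, flows


# Reference simulation-experiment geometry: 256x256 image, 20 px wall,
# 64 px cavity, lightly smoothed; the shadow sits on the right limb with
# attenuation 0.8.
DEFAULT_PHANTOM = dict(height=256, width=256, wall_thickness=20,
                       cavity_width=64, smooth_sigma=1.0)
DEFAULT_SHADOW = dict(center=(100.0, 175.0), axes=(50.0, 15.0),
                      attenuation=0.8)
DEFAULT_MOTION = dict(left_dx=2.0, right_dx=-2.0, global_dy=1.0)


def reference_affine_pair(shadow: str | None = "comoving",
                          speckle_sigma: float = 0.0, seed: int = 0):
    """The standard shadowed affine contraction experiment.

    A 256x256 U phantom moves 2 px right (left limb), 2 px left (right
    limb) and 1 px down, with a 0.8-attenuation elliptical shadow over
    the right limb.  ``shadow`` selects the shadow model:

    - ``"comoving"`` — the shadow is stamped onto the wall image before
      the motion is applied, so it moves with the tissue (the
      shadow-then-warp simulation construction; brightness constancy
      holds, but the shadowed wall has only 20% contrast);
    - ``"static"`` — the shadow darkens both frames at a fixed image
      location while the wall moves beneath it, like a rib shadow
      during acquisition (brightness constancy is violated at the
      shadow border);
    - ``None`` — no shadow.

    Returns ``(pair, phantom, shadow_region)``.
    """
    if shadow not in ("comoving", "static", None):
        raise InvalidGeometryError(f"unknown shadow model {shadow!r}")
    p = make_u_phantom(**DEFAULT_PHANTOM)
    if speckle_sigma > 0:
        p = Phantom(**{**p.__dict__,
                       "frame": add_speckle(p.frame, speckle_sigma, seed)})
    region = np.zeros(p.frame.shape, dtype=bool)
    if shadow is not None:
        region = shadow_mask(p.frame.shape, DEFAULT_SHADOW["center"],
                             DEFAULT_SHADOW["axes"])
    if shadow == "comoving":
        p = Phantom(**{**p.__dict__,
                       "frame": add_shadow(p.frame, **DEFAULT_SHADOW)})
        pair = affine_contract(p, **DEFAULT_MOTION)
    else:
        pair = affine_contract(p, **DEFAULT_MOTION)
        if shadow == "static":
            pair = GroundTruthPair(
                frame1=add_shadow(pair.frame1, **DEFAULT_SHADOW),
                frame2=add_shadow(pair.frame2, **DEFAULT_SHADOW),
                gt_flow=pair.gt_flow, roi=pair.roi)
    return pair, p, region
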