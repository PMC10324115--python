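"""Confidence-optimized multiresolution (COM) optical flow.

The estimator runs a coarse-to-fine warping scheme on an exponentially
scaled resolution pyramid.  At every level a per-pixel confidence weight
``s`` in [0, 1] — by default the min-max-normalized level-1 wavelet
approximation reconstruction of that level's first frame — multiplies the
incremental flow update before it is accumulated:

    u <- u + s * du,    v <- v + s * dv

so that regions with little image information (acoustic shadows, blur)
contribute weakly to high-resolution refinements and mostly retain the
flow interpolated from coarser levels, where the shadow is small relative
to the structure around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from skimage.transform import resize

from .errors import ComflowError, InvalidSpecError
from .flow_core import FlowField, SolverParams, refine_level

__all__ = ["PyramidSpec", "build_pyramid", "level_shapes",
           "confidence_map", "com_flow"]

MIN_LEVEL_SIZE = 16


@dataclass
class PyramidSpec:
    """Exponential (geometric) resolution schedule.

    n_levels levels, coarsest at ``top_fraction`` of the original linear
    size, finest at the original resolution; successive linear sizes have
    a constant ratio.
    """

    n_levels: int = 6
    top_fraction: float = 0.3

    def __post_init__(self):
        if self.n_levels < 1:
            raise InvalidSpecError("n_levels must be >= 1")
        if not (0 < self.top_fraction <= 1):
            raise InvalidSpecError("top_fraction must be in (0, 1]")

    def scales(self) -> np.ndarray:
        """Per-level linear scale factors, coarsest -> finest (last = 1)."""
        if self.n_levels == 1:
            return np.array([1.0])
        k = np.arange(self.n_levels)
        return self.top_fraction ** (1.0 - k / (self.n_levels - 1))


def level_shapes(shape, spec: PyramidSpec) -> list[tuple[int, int]]:
    """Rounded per-level image shapes, coarsest first."""
    shapes = []
    for s in spec.scales():
        h = int(round(shape[0] * s))
        w = int(round(shape[1] * s))
        shapes.append((h, w))
    h0, w0 = shapes[0]
    if min(h0, w0) < MIN_LEVEL_SIZE:
        raise InvalidSpecError(
            f"coarsest level {h0}x{w0} below {MIN_LEVEL_SIZE} px per side")
    return shapes


def _resample(I: np.ndarray, shape) -> np.ndarray:
    if I.shape == tuple(shape):
        return I
    shrinking = shape[0] < I.shape[0] or shape[1] < I.shape[1]
    return resize(I, shape, order=1, mode="edge", anti_aliasing=shrinking,
                  preserve_range=True)


def build_pyramid(I: np.ndarray, spec: PyramidSpec) -> list[np.ndarray]:
    """Anti-alias-filtered resamplings of ``I``, coarsest to finest.

    Every level is resampled directly from the original image; the finest
    level is the original image itself.
    """
    I = np.asarray(I, dtype=np.float64)
    if I.ndim != 2:
        raise ComflowError("image must be 2-D")
    return [_resample(I, shp) for shp in level_shapes(I.shape, spec)]


def confidence_map(I_level: np.ndarray, wavelet_name: str = "db1") -> np.ndarray:
    """Wavelet-approximation confidence weights in [0, 1].

    Level-1 2-D wavelet decomposition of the image, detail bands zeroed,
    reconstruction back to the level's size ("first layer reconstruction
    approximation"), then min-max normalization.  A constant
    reconstruction (zero range) yields all-ones.
    """
    I_level = np.asarray(I_level, dtype=np.float64)
    if min(I_level.shape) < MIN_LEVEL_SIZE:
        raise ComflowError("confidence_map needs at least 16x16 input")
    cA, (cH, cV, cD) = pywt.dwt2(I_level, wavelet_name)
    rec = pywt.idwt2((cA, (np.zeros_like(cH), np.zeros_like(cV),
                           np.zeros_like(cD))), wavelet_name)
    rec = rec[:I_level.shape[0], :I_level.shape[1]]
    lo, hi = rec.min(), rec.max()
    if hi - lo <= 0:
        return np.ones_like(rec)
    return (rec - lo) / (hi - lo)


def _gray_confidence(I_level: np.ndarray) -> np.ndarray:
    lo, hi = I_level.min(), I_level.max()
    if hi - lo <= 0:
        return np.ones_like(I_level)
    return (I_level - lo) / (hi - lo)


def com_flow(I1: np.ndarray, I2: np.ndarray,
             spec: PyramidSpec | None = None,
             params: SolverParams | None = None,
             use_confidence: bool = True,
             confidence_source: str = "wavelet",
             wavelet_name: str = "db1") -> FlowField:
    """Coarse-to-fine flow with confidence-weighted increments.

    At each level the accumulated flow is upsampled (displacements scaled
    by the inter-level size ratio per axis), the second frame is warped
    by it, and the warping loop adds ``s * (du, dv)``.  With
    ``use_confidence=False`` the increments are unweighted (s = 1), which
    makes the single-level case identical to the base warping solver.
    ``confidence_source`` selects the weight: ``"wavelet"`` (default) or
    ``"gray"`` (the min-max-normalized level image itself).
    """
    if spec is None:
        spec = PyramidSpec()
    if params is None:
        params = SolverParams()
    if confidence_source not in ("wavelet", "gray"):
        raise ComflowError(f"unknown confidence_source {confidence_source!r}")
    I1 = np.asarray(I1, dtype=np.float64)
    I2 = np.asarray(I2, dtype=np.float64)
    if I1.shape != I2.shape:
        raise ComflowError("frame shapes differ")

    pyr1 = build_pyramid(I1, spec)
    pyr2 = build_pyramid(I2, spec)

    flow: FlowField | None = None
    prev_shape = None
    for L1, L2 in zip(pyr1, pyr2):
        if flow is None:
            flow = FlowField.zeros(L1.shape)
        elif L1.shape != prev_shape:
            ry = L1.shape[0] / prev_shape[0]
            rx = L1.shape[1] / prev_shape[1]
            u = _resample(flow.u, L1.shape) * rx
            v = _resample(flow.v, L1.shape) * ry
            flow = FlowField(u, v)
        if use_confidence:
            if confidence_source == "wavelet":
                s = confidence_map(L1, wavelet_name)
            else:
                s = _gray_confidence(L1)
        else:
            s = None
        flow = refine_level(L1, L2, flow, params, confidence=s)
        prev_shape = L1.shape
    return flow
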