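"""Flow-accuracy metrics, the method-comparison harness, and file I/O.

Metrics
-------
``rmse`` is the root-mean-square endpoint error in pixels over an ROI.
``angular_error`` is the mean space-time angular error in degrees, using
the standard homogeneous (+1) convention

    AE = arccos( (u_g u_e + v_g v_e + 1)
                 / sqrt((u_g^2 + v_g^2 + 1)(u_e^2 + v_e^2 + 1)) )

which stays defined for zero-length vectors.  Both are evaluated over
the myocardial wall ROI, eroded by one pixel by default to exclude
interpolation boundary pixels.

I/O
---
Image sequences as TIFF/PNG stacks (integer data normalized to [0, 1]);
flow fields in the Middlebury ``.flo`` format (little-endian, magic
202021.25); contours and reports as JSON; curves as tidy CSV.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .com_pyramid import PyramidSpec, com_flow
from .errors import ComflowError, ParseError
from .flow_core import FlowField, SolverParams, hs_flow, lk_flow
from .phantom import GroundTruthPair
from .sequence import ImageSequence
from .tracking_curves import SegmentCurve
from .wall_geometry import WallContour

__all__ = ["ErrorReport", "rmse", "angular_error", "endpoint_error",
           "run_comparison", "METHODS",
           "read_sequence", "write_sequence", "read_flow", "write_flow",
           "read_contour", "write_curves", "write_grading_report",
           "read_dicom_frame", "load_config", "plot_curves"]

FLO_MAGIC = 202021.25


# ---------------------------------------------------------------- metrics

def _check_roi(est: FlowField, gt: FlowField, roi: np.ndarray) -> np.ndarray:
    if est.shape != gt.shape:
        raise ComflowError("flow shapes differ")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != est.shape:
        raise ComflowError("roi shape differs from flow shape")
    if not roi.any():
        raise ComflowError("empty ROI")
    return roi


def rmse(est: FlowField, gt: FlowField, roi: np.ndarray) -> float:
    """Root-mean-square endpoint error (px) over the ROI."""
    roi = _check_roi(est, gt, roi)
    du = gt.u[roi] - est.u[roi]
    dv = gt.v[roi] - est.v[roi]
    return float(np.sqrt(np.mean(du * du + dv * dv)))


def endpoint_error(est: FlowField, gt: FlowField) -> np.ndarray:
    """Per-pixel endpoint error magnitude (px)."""
    if est.shape != gt.shape:
        raise ComflowError("flow shapes differ")
    return np.hypot(gt.u - est.u, gt.v - est.v)


def angular_error(est: FlowField, gt: FlowField, roi: np.ndarray) -> float:
    """Mean space-time angular error (degrees) over the ROI."""
    roi = _check_roi(est, gt, roi)
    ue, ve = est.u[roi], est.v[roi]
    ug, vg = gt.u[roi], gt.v[roi]
    num = ug * ue + vg * ve + 1.0
    den = np.sqrt((ug * ug + vg * vg + 1.0) * (ue * ue + ve * ve + 1.0))
    cosang = np.clip(num / den, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).mean())


# ----------------------------------------------------------- comparison

@dataclass
class ErrorReport:
    method: str
    rmse_px: float
    mean_ae_deg: float
    n_pixels: int
    roi: str = "wall"

    def __post_init__(self):
        if self.rmse_px < 0 or not (0 <= self.mean_ae_deg <= 180):
            raise ComflowError("metric out of range")


def _com(confidence_source=None, use_confidence=True):
    def run(I1, I2, pyramid, solver):
        return com_flow(I1, I2, spec=pyramid, params=solver,
                        use_confidence=use_confidence,
                        confidence_source=confidence_source or "wavelet")
    return run


METHODS = {
    "hs": lambda I1, I2, pyramid, solver: hs_flow(I1, I2),
    "lk": lambda I1, I2, pyramid, solver: lk_flow(I1, I2),
    "pyramid": _com(use_confidence=False),
    "com-gray": _com("gray"),
    "com-wavelet": _com("wavelet"),
}


def run_comparison(pair: GroundTruthPair, methods: list[str],
                   pyramid: PyramidSpec | None = None,
                   solver: SolverParams | None = None,
                   erode_px: int = 1) -> list[ErrorReport]:
    """Evaluate flow methods against ground truth on one frame pair.

    Metrics are computed over the pair's wall ROI eroded by ``erode_px``
    pixels; the report is sorted by RMSE, best first.
    """
    for m in methods:
        if m not in METHODS:
            raise ComflowError(f"unknown method {m!r}; "
                               f"choose from {sorted(METHODS)}")
    pyramid = pyramid or PyramidSpec()
    solver = solver or SolverParams()
    roi = np.asarray(pair.roi, dtype=bool)
    if erode_px > 0:
        roi = ndimage.binary_erosion(roi, iterations=erode_px)
    reports = []
    for m in methods:
        est = METHODS[m](pair.frame1, pair.frame2, pyramid, solver)
        reports.append(ErrorReport(
            method=m,
            rmse_px=rmse(est, pair.gt_flow, roi),
            mean_ae_deg=angular_error(est, pair.gt_flow, roi),
            n_pixels=int(roi.sum()),
            roi=f"wall eroded {erode_px} px"))
    return sorted(reports, key=lambda r: r.rmse_px)


# ------------------------------------------------------------------- I/O

def _normalize_frames(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def read_sequence(path, mm_per_px: float | None = None,
                  frame_interval_s: float | None = None) -> ImageSequence:
    """Read a grayscale sequence from a multipage TIFF or an image directory."""
    import imageio.v3 as iio
    path = Path(path)
    try:
        if path.is_dir():
            files = sorted(f for f in path.iterdir()
                           if f.suffix.lower() in (".png", ".tif", ".tiff"))
            if not files:
                raise ParseError(f"no image files in directory {path}")
            frames = np.stack([_normalize_frames(iio.imread(f))
                               for f in files])
        else:
            arr = iio.imread(path)
            if arr.ndim == 2:
                arr = arr[None]
            frames = _normalize_frames(arr)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read image sequence {path}: {exc}") from exc
    if frames.ndim != 3:
        raise ParseError(f"{path}: expected grayscale frames, got shape "
                         f"{frames.shape}")
    return ImageSequence(frames=frames, mm_per_px=mm_per_px,
                         frame_interval_s=frame_interval_s)


def write_sequence(path, seq: ImageSequence):
    """Write frames as a float32 multipage TIFF."""
    import tifffile
    tifffile.imwrite(os.fspath(path),
                     seq.frames.astype(np.float32), photometric="minisblack")


def write_flow(path, flow: FlowField):
    """Write a flow field in Middlebury .flo format (little-endian)."""
    h, w = flow.shape
    with open(path, "wb") as fh:
        np.array([FLO_MAGIC], dtype="<f4").tofile(fh)
        np.array([w, h], dtype="<i4").tofile(fh)
        inter = np.empty((h, w, 2), dtype="<f4")
        inter[..., 0] = flow.u
        inter[..., 1] = flow.v
        inter.tofile(fh)


def read_flow(path) -> FlowField:
    """Read a Middlebury .flo file; round-trips write_flow bit-exactly."""
    with open(path, "rb") as fh:
        magic = np.fromfile(fh, dtype="<f4", count=1)
        if magic.size != 1 or magic[0] != np.float32(FLO_MAGIC):
            raise ParseError(f"{path}: bad .flo magic at offset 0")
        wh = np.fromfile(fh, dtype="<i4", count=2)
        if wh.size != 2 or (wh <= 0).any():
            raise ParseError(f"{path}: bad dimensions at offset 4")
        w, h = int(wh[0]), int(wh[1])
        data = np.fromfile(fh, dtype="<f4", count=2 * w * h)
        if data.size != 2 * w * h:
            raise ParseError(f"{path}: truncated data at offset 12")
    inter = data.reshape(h, w, 2)
    return FlowField(inter[..., 0].astype(np.float64),
                     inter[..., 1].astype(np.float64))


def read_contour(path) -> WallContour:
    """Read a wall contour JSON (endo/epi point arrays plus landmarks)."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot parse contour {path}: {exc}") from exc
    for key in ("endo_points", "epi_points", "apex_index", "image_shape"):
        if key not in data:
            raise ParseError(f"{path}: missing field {key!r}")
    return WallContour(
        endo_points=np.asarray(data["endo_points"], dtype=np.float64),
        epi_points=np.asarray(data["epi_points"], dtype=np.float64),
        apex_index=int(data["apex_index"]),
        image_shape=tuple(data["image_shape"]),
        base_left_index=int(data.get("base_left_index", 0)),
        base_right_index=int(data.get("base_right_index", -1)))


def write_curves(path, curves: list[SegmentCurve]):
    """Export curves as tidy CSV: frame, segment, incremental, cumulative."""
    rows = []
    for c in curves:
        for k in range(len(c.cumulative_px)):
            rows.append({
                "frame": k,
                "segment": c.label,
                "incremental_px": 0.0 if k == 0 else c.incremental_px[k - 1],
                "cumulative_px": c.cumulative_px[k],
                "cumulative_mm": (np.nan if c.cumulative_mm is None
                                  else c.cumulative_mm[k]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_grading_report(path, curves: list[SegmentCurve]):
    report = {c.label: {"peak_px": c.peak_px, "peak_mm": c.peak_mm,
                        "grade": c.grade} for c in curves}
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def read_dicom_frame(path):
    """Read one DICOM frame; returns (frame in [0,1], mm_per_px or None)."""
    import pydicom
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1) if arr.shape[-1] in (3, 4) else arr[0]
    rng = arr.max() - arr.min()
    frame = (arr - arr.min()) / rng if rng > 0 else np.zeros_like(arr)
    mm = None
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None and len(spacing) >= 1:
        mm = float(spacing[0])
    return frame, mm


def load_config(path):
    """Load pyramid/solver/confidence settings from YAML or JSON.

    Returns ``(PyramidSpec, SolverParams, confidence_dict)`` where the
    confidence dict has keys ``enabled``, ``source`` and ``wavelet_name``.
    """
    import yaml
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ParseError(f"cannot parse config {path}: {exc}") from exc
    pyr = PyramidSpec(**cfg.get("pyramid", {}))
    sol = SolverParams(**cfg.get("solver", {}))
    conf = {"enabled": True, "source": "wavelet", "wavelet_name": "db1"}
    conf.update(cfg.get("confidence", {}))
    return pyr, sol, conf


def plot_curves(curves: list[SegmentCurve], path=None, ncols: int = 3):
    """Plot one panel per segment curve; returns the Figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    n = len(curves)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows),
                             squeeze=False, sharex=True)
    for ax, c in zip(axes.ravel(), curves):
        y = c.cumulative_mm if c.cumulative_mm is not None else c.cumulative_px
        unit = "mm" if c.cumulative_mm is not None else "px"
        ax.plot(np.arange(len(y)), y, marker="o", ms=3)
        ax.axhline(0, color="0.7", lw=0.8)
        ax.set_title(f"segment {c.label}", fontsize=9)
        ax.set_ylabel(f"radial displacement ({unit})", fontsize=7)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def export_report(path, reports: list[ErrorReport]):
    pd.DataFrame([asdict(r) for r in reports]).to_csv(path, index=False)
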