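"""Myocardial wall contours, segments and radial/circumferential decomposition.

The apical two-chamber view contributes six wall segments: each side of
the U-shaped wall (base -> apex) is split into three spans of equal arc
length along the endocardium, and a secondary split halves every segment
into an upper (basal) and lower (apical) half, giving twelve.

Each segment carries one circumferential unit tangent and one radial unit
normal, evaluated at the segment center; the normal points into the
cavity, so positive radial displacement means contraction.  Flow vectors
over a segment's ROI are decomposed by projection onto this orthonormal
pair.

Coordinates are image coordinates ``(row, col)`` with row increasing
downward; "clockwise" traversal means base-left -> apex -> base-right in
these coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import polygon

from .errors import (DegenerateGeometryError, InvalidContourError)
from .flow_core import FlowField

__all__ = ["WallContour", "Segment", "split_six", "subdivide",
           "segment_center", "tangent_normal", "polyline_tangent",
           "decompose"]


@dataclass
class WallContour:
    """Ordered endocardial/epicardial wall traces with landmarks.

    ``endo_points`` runs from the left base endpoint, through the apex,
    to the right base endpoint; ``epi_points`` traces the outer boundary
    in the same direction.  Landmark indices refer to ``endo_points``.
    ``image_shape`` is the raster the contour lives on (used to build
    segment ROI masks).
    """

    endo_points: np.ndarray
    epi_points: np.ndarray
    apex_index: int
    image_shape: tuple[int, int]
    base_left_index: int = 0
    base_right_index: int = field(default=-1)

    def __post_init__(self):
        self.endo_points = np.asarray(self.endo_points, dtype=np.float64)
        self.epi_points = np.asarray(self.epi_points, dtype=np.float64)
        n = len(self.endo_points)
        if self.base_right_index == -1:
            self.base_right_index = n - 1
        if n < 7 or len(self.epi_points) < 3:
            raise InvalidContourError("contour needs at least 7 endo points")
        if self.base_left_index != 0 or self.base_right_index != n - 1:
            raise InvalidContourError(
                "base endpoints must be the first and last endo points")
        if not (0 < self.apex_index < n - 1):
            raise InvalidContourError("apex index must be interior")
        steps = np.linalg.norm(np.diff(self.endo_points, axis=0), axis=1)
        if np.any(steps == 0):
            raise InvalidContourError("coincident consecutive endo points")

    @property
    def cavity_centroid(self) -> np.ndarray:
        """Mean of endo points; lies inside the cavity for a U-shaped wall."""
        return self.endo_points.mean(axis=0)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length along endo_points (first point = 0)."""
        steps = np.linalg.norm(np.diff(self.endo_points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def wall_mask(self) -> np.ndarray:
        """Binary raster of the myocardium between endo and epi."""
        ring = np.vstack([self.epi_points, self.endo_points[::-1]])
        rr, cc = polygon(ring[:, 0], ring[:, 1], shape=self.image_shape)
        mask = np.zeros(self.image_shape, dtype=bool)
        mask[rr, cc] = True
        return mask

    def to_json(self, path):
        data = {
            "endo_points": self.endo_points.tolist(),
            "epi_points": self.epi_points.tolist(),
            "apex_index": int(self.apex_index),
            "base_left_index": int(self.base_left_index),
            "base_right_index": int(self.base_right_index),
            "image_shape": list(self.image_shape),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


@dataclass
class Segment:
    label: str
    endo_span: tuple[int, int]          # [start, stop] inclusive vertex range
    center: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        self.tangent = np.asarray(self.tangent, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)


def _span_boundaries(arc: np.ndarray, i0: int, i1: int, parts: int) -> list[int]:
    """Vertex indices splitting arc[i0..i1] into `parts` equal-length spans."""
    total = arc[i1] - arc[i0]
    bounds = [i0]
    for p in range(1, parts):
        target = arc[i0] + total * p / parts
        j = int(np.searchsorted(arc[i0:i1 + 1], target)) + i0
        j = min(max(j, bounds[-1] + 1), i1 - (parts - p))
        # choose the nearer of the bracketing vertices
        if j > i0 and abs(arc[j - 1] - target) < abs(arc[j] - target) \
                and j - 1 > bounds[-1]:
            j -= 1
        bounds.append(j)
    bounds.append(i1)
    return bounds


def _roi_partition(contour: WallContour, spans: list[tuple[int, int]],
                   wall_mask: np.ndarray | None = None) -> list[np.ndarray]:
    """Assign every wall pixel to the segment of its nearest endo vertex."""
    if wall_mask is None:
        wall_mask = contour.wall_mask()
    pix = np.argwhere(wall_mask)
    tree = cKDTree(contour.endo_points)
    _, idx = tree.query(pix.astype(np.float64))
    masks = []
    for (i0, i1) in spans:
        m = np.zeros_like(wall_mask)
        if len(pix):
            # half-open on the right except the last span, so masks tile
            last = (i1 == len(contour.endo_points) - 1)
            sel = (idx >= i0) & ((idx <= i1) if last else (idx < i1))
            m[pix[sel, 0], pix[sel, 1]] = True
        masks.append(m)
    return masks


def segment_center(span: tuple[int, int], contour: WallContour) -> np.ndarray:
    """Center point of a segment span.

    Chord = line joining the span's two endocardial endpoints; from the
    chord midpoint march horizontally (constant row) to the nearest
    intersection with the span's endocardial polyline.  If no horizontal
    intersection exists (near-horizontal spans), fall back to the
    arc-length midpoint of the span.
    """
    i0, i1 = span
    pts = contour.endo_points[i0:i1 + 1]
    mid = 0.5 * (pts[0] + pts[-1])
    row = mid[0]
    hits = []
    for a, b in zip(pts[:-1], pts[1:]):
        r0, r1 = a[0], b[0]
        if r0 == r1:
            continue  # horizontal edge: no transversal crossing
        t = (row - r0) / (r1 - r0)
        if 0.0 <= t <= 1.0:
            col = a[1] + t * (b[1] - a[1])
            hits.append(np.array([row, col]))
    if hits:
        d = [abs(h[1] - mid[1]) for h in hits]
        return hits[int(np.argmin(d))]
    # fallback: arc-length midpoint
    arc = contour.arc_lengths()
    target = 0.5 * (arc[i0] + arc[i1])
    j = int(np.searchsorted(arc, target))
    j = min(max(j, i0 + 1), i1)
    seg_len = arc[j] - arc[j - 1]
    t = 0.0 if seg_len == 0 else (target - arc[j - 1]) / seg_len
    return contour.endo_points[j - 1] + t * (
        contour.endo_points[j] - contour.endo_points[j - 1])


def polyline_tangent(v_prev: np.ndarray, v_i: np.ndarray,
                     v_next: np.ndarray) -> np.ndarray:
    """Unit circumferential direction at ``v_i`` from its neighbors.

    Sum of the two adjacent unit chord directions, renormalized.
    """
    v_prev = np.asarray(v_prev, float)
    v_i = np.asarray(v_i, float)
    v_next = np.asarray(v_next, float)
    d1 = v_i - v_prev
    d2 = v_next - v_i
    n1 = np.linalg.norm(d1)
    n2 = np.linalg.norm(d2)
    if n1 == 0 or n2 == 0:
        raise DegenerateGeometryError("coincident contour vertices")
    t = d1 / n1 + d2 / n2
    nt = np.linalg.norm(t)
    if nt == 0:
        raise DegenerateGeometryError("cusp: opposite chord directions")
    return t / nt


def tangent_normal(span: tuple[int, int], contour: WallContour,
                   center: np.ndarray | None = None):
    """Unit tangent (circumferential) and unit normal (radial) of a span.

    The tangent at the segment center uses the span's endocardial
    endpoints as the clockwise predecessor/successor vertices.  The
    normal is the tangent rotated by 90 deg, its sign chosen to point
    toward the cavity centroid (the contraction direction).
    """
    i0, i1 = span
    if center is None:
        center = segment_center(span, contour)
    t = polyline_tangent(contour.endo_points[i0], center,
                         contour.endo_points[i1])
    n = np.array([-t[1], t[0]])          # 90 deg rotation in (row, col)
    to_cavity = contour.cavity_centroid - center
    if np.dot(n, to_cavity) < 0:
        n = -n
    return t, n


def _build_segments(contour: WallContour, spans, labels,
                    wall_mask=None) -> list[Segment]:
    rois = _roi_partition(contour, spans, wall_mask)
    out = []
    for (span, label, roi) in zip(spans, labels, rois):
        c = segment_center(span, contour)
        t, n = tangent_normal(span, contour, center=c)
        out.append(Segment(label=label, endo_span=tuple(span), center=c,
                           tangent=t, normal=n, roi_mask=roi))
    return out


def split_six(contour: WallContour) -> list[Segment]:
    """Six equal-arc-length segments, three per side, ordered clockwise.

    Side 1 runs base-left -> apex, side 2 apex -> base-right; each is cut
    into three spans of equal endocardial arc length.
    """
    a = contour.apex_index
    n = len(contour.endo_points) - 1
    if a < 3 or n - a < 3:
        raise InvalidContourError("apex too close to a base endpoint")
    arc = contour.arc_lengths()
    b1 = _span_boundaries(arc, 0, a, 3)
    b2 = _span_boundaries(arc, a, n, 3)
    spans = [(b1[0], b1[1]), (b1[1], b1[2]), (b1[2], b1[3]),
             (b2[0], b2[1]), (b2[1], b2[2]), (b2[2], b2[3])]
    labels = [str(i + 1) for i in range(6)]
    return _build_segments(contour, spans, labels)


def subdivide(segments: list[Segment], contour: WallContour) -> list[Segment]:
    """Halve each of the six segments by arc length -> twelve segments.

    The child nearer the base keeps the parent label with suffix
    ``"upper"``; the child nearer the apex gets ``"lower"``.
    """
    arc = contour.arc_lengths()
    wall = contour.wall_mask()
    spans = []
    labels = []
    for seg in segments:
        i0, i1 = seg.endo_span
        b = _span_boundaries(arc, i0, i1, 2)
        # clockwise order: on the left side the basal half comes first,
        # on the right side it comes last
        left_side = i1 <= contour.apex_index
        halves = [(b[0], b[1]), (b[1], b[2])]
        names = (["upper", "lower"] if left_side else ["lower", "upper"])
        for (sp, nm) in zip(halves, names):
            spans.append(sp)
            labels.append(f"{seg.label}-{nm}")
    return _build_segments(contour, spans, labels, wall_mask=wall)


def decompose(flow: FlowField, segment: Segment):
    """Project flow onto the segment's radial/circumferential basis.

    Returns ``(radial, circumferential)`` per-pixel scalar fields (px):
    radial = flow . normal (positive toward the cavity), circumferential
    = flow . tangent.  Defined at every pixel; restrict to
    ``segment.roi_mask`` for segment statistics.
    """
    # flow vector in (row, col) is (v, u)
    radial = flow.v * segment.normal[0] + flow.u * segment.normal[1]
    circ = flow.v * segment.tangent[0] + flow.u * segment.tangent[1]
    return radial, circ
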