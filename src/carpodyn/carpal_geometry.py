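"""Joint-space and wrist-angle geometry from label masks.

From a per-frame segmentation of the wrist this module extracts smoothed
subpixel bone outlines, connects the proximal-row centroids with a
centreline, and measures the scapholunate (SL) and lunotriquetral (LT)
joint widths as the distances between the centreline's intersections with
the facing bone cortices.  The wrist angle is taken from minimal-area
rotated bounding boxes: one around the distal carpal row (hamate,
capitate, trapezium, trapezoid), one around the forearm (distal radius
and ulna); the signed angle between the box-centre connection line and
the forearm box's long axis is the wrist angle, positive toward ulnar
abduction (the ulnar direction is read off the ulna-vs-radius centroid
offset, so left and right wrists mirror automatically).

All geometry lives in continuous mm coordinates (x = column * spacing,
y = row * spacing); measurements are therefore invariant under rigid
transforms of the mask up to re-rasterization and scale covariant in the
pixel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .imaging import CLASS_MAP, LabelMask

SCAPHOID, LUNATE, TRIQUETRUM = 3, 4, 5
DISTAL_ROW_IDS = (6, 7, 8, 9)
FOREARM_IDS = (1, 2)

SMOOTH_WINDOW = 5        # vertices, periodic moving average variant
SMOOTH_SPAN_PX = 14.0    # arclength span of the Savitzky-Golay smoother, px
RESAMPLE_STEP_PX = 0.5   # uniform arclength resampling step, px
MIN_COMPONENT_PX = 8


class InvalidOutlineError(ValueError):
    """A requested bone is absent or too small to yield a valid outline."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class BoneOutline:
    """Closed, smoothed outline of one bone in mm coordinates."""

    bone_id: int
    points: np.ndarray            # (N, 2) open ring, mm
    centroid: np.ndarray = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or len(self.points) < 8:
            raise InvalidOutlineError(
                f"outline of {CLASS_MAP.get(self.bone_id, self.bone_id)} has "
                f"fewer than 8 points")
        poly = Polygon(self.points)
        if poly.area <= 0:
            raise InvalidOutlineError("outline encloses no area")
        self.centroid = np.array(poly.centroid.coords[0])

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        return Polygon(self.points).area


@dataclass
class Centreline:
    """Proximal-row centreline: scaphoid -> lunate -> triquetrum centroids."""

    anchors: np.ndarray           # (3, 2) centroids in bone-id order

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.anchors.shape != (3, 2):
            raise ValueError("centreline needs exactly three anchor points")
        d = np.linalg.norm(np.diff(self.anchors, axis=0), axis=1)
        if np.any(d < 1e-9) or np.linalg.norm(self.anchors[0] - self.anchors[2]) < 1e-9:
            raise ValueError("centreline anchors must be pairwise distinct")

    @property
    def segments(self):
        return ((self.anchors[0], self.anchors[1]),
                (self.anchors[1], self.anchors[2]))


@dataclass
class MinBoundingBox:
    """Minimal-area rotated rectangle around a point set."""

    center: np.ndarray
    long_axis: np.ndarray         # unit vector along the longer side
    extent: tuple[float, float]   # (length, width), length >= width

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        length, width = self.extent
        if not (length >= width > 0):
            raise ValueError("bounding box needs length >= width > 0")

    @property
    def area(self) -> float:
        return float(self.extent[0] * self.extent[1])


@dataclass
class JointMeasurement:
    """Per-frame wrist angle and SL/LT joint widths."""

    frame_index: int
    wrist_angle_deg: float
    sl_width_mm: float
    lt_width_mm: float
    valid: bool
    t_s: float = np.nan


# --------------------------------------------------------------------------
# Outline extraction
# --------------------------------------------------------------------------

def _mask_array(mask, spacing_mm):
    if isinstance(mask, LabelMask):
        return mask.labels, mask.spacing_mm
    if spacing_mm is None:
        spacing_mm = (1.0, 1.0)
    if np.isscalar(spacing_mm):
        spacing_mm = (float(spacing_mm), float(spacing_mm))
    return np.asarray(mask), spacing_mm


def smooth_ring(points: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Periodic moving average over the vertices of a closed ring."""
    if window <= 1:
        return points
    n = len(points)
    k = window // 2
    idx = (np.arange(n)[:, None] + np.arange(-k, k + 1)[None, :]) % n
    return points[idx].mean(axis=1)


def resample_ring(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a closed ring to uniform arclength spacing ``step``."""
    closed = np.vstack([points, points[:1]])
    d = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    t = np.arange(0.0, s[-1], step)
    return np.column_stack([np.interp(t, s, closed[:, 0]),
                            np.interp(t, s, closed[:, 1])])


def smooth_outline(points_mm: np.ndarray, span_mm: float,
                   step_mm: float) -> np.ndarray:
    """Curvature-preserving periodic smoothing of a closed outline.

    The ring is resampled to uniform arclength and smoothed with a
    periodic second-order Savitzky-Golay filter spanning ``span_mm`` of
    arclength.  Order 2 reproduces locally quadratic boundaries exactly,
    so — unlike a plain moving average — convex outlines are not shrunk
    while the half-pixel contour quantization zigzag is averaged out.
    """
    from scipy.signal import savgol_filter

    pts = resample_ring(np.asarray(points_mm, dtype=float), step_mm)
    window = int(round(span_mm / step_mm)) | 1
    if window > 2 and len(pts) > window:
        pts = savgol_filter(pts, window, polyorder=2, axis=0, mode="wrap")
    return pts


def extract_outline(mask, bone_id: int, spacing_mm=None,
                    smooth_span_px: float = SMOOTH_SPAN_PX) -> BoneOutline:
    """Subpixel outline of the largest connected component of one bone.

    The contour is traced at iso-level 0.5 on the binary bone image,
    converted to mm via the pixel spacing and smoothed with the periodic
    curvature-preserving filter of :func:`smooth_outline` (area change
    stays within a few percent).  The smoothing span is defined in pixels
    — the scale of the rasterization noise it suppresses — so geometry is
    exactly scale covariant in the pixel spacing.  Raises
    :class:`InvalidOutlineError` when the bone is absent or smaller than
    ``MIN_COMPONENT_PX`` pixels.
    """
    from skimage.measure import find_contours

    labels, spacing = _mask_array(mask, spacing_mm)
    binary = labels == bone_id
    if not binary.any():
        raise InvalidOutlineError(f"bone {CLASS_MAP.get(bone_id, bone_id)} absent from mask")

    comp, ncomp = ndimage.label(binary)
    if ncomp > 1:
        sizes = np.bincount(comp.ravel())[1:]
        binary = comp == (int(np.argmax(sizes)) + 1)
    if binary.sum() < MIN_COMPONENT_PX:
        raise InvalidOutlineError(
            f"bone {CLASS_MAP.get(bone_id, bone_id)} component below "
            f"{MIN_COMPONENT_PX} px")

    # crop with a 2 px pad for speed; contour coordinates stay global
    rows = np.any(binary, axis=1).nonzero()[0]
    cols = np.any(binary, axis=0).nonzero()[0]
    r0, r1 = max(rows[0] - 2, 0), min(rows[-1] + 3, binary.shape[0])
    c0, c1 = max(cols[0] - 2, 0), min(cols[-1] + 3, binary.shape[1])
    crop = binary[r0:r1, c0:c1].astype(np.float32)
    contours = find_contours(crop, 0.5)
    if not contours:
        raise InvalidOutlineError("no iso-contour found")
    ring = max(contours, key=len)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    if len(ring) < 8:
        raise InvalidOutlineError("contour too short")
    ring = ring + np.array([r0, c0], dtype=float)
    pts_mm = np.column_stack([ring[:, 1] * spacing[1], ring[:, 0] * spacing[0]])
    px = 0.5 * (spacing[0] + spacing[1])
    return BoneOutline(bone_id=bone_id,
                       points=smooth_outline(pts_mm, smooth_span_px * px,
                                             RESAMPLE_STEP_PX * px))


# --------------------------------------------------------------------------
# Centreline and cortex intersections
# --------------------------------------------------------------------------

def proximal_centreline(scaphoid: BoneOutline, lunate: BoneOutline,
                        triquetrum: BoneOutline) -> Centreline:
    """Straight centroid-to-centroid centreline through the proximal row.

    Input order is normalized by bone id, so permuting the arguments does
    not change the geometry.
    """
    by_id = {o.bone_id: o for o in (scaphoid, lunate, triquetrum)}
    if set(by_id) != {SCAPHOID, LUNATE, TRIQUETRUM}:
        raise ValueError("centreline needs the scaphoid, lunate and triquetrum outlines")
    return Centreline(anchors=np.array([by_id[SCAPHOID].centroid,
                                        by_id[LUNATE].centroid,
                                        by_id[TRIQUETRUM].centroid]))


def _as_polygon(outline) -> Polygon:
    if isinstance(outline, Polygon):
        return outline
    if isinstance(outline, BoneOutline):
        return outline.polygon
    return Polygon(np.asarray(outline, dtype=float))


def _boundary_hits(segment: LineString, poly: Polygon) -> np.ndarray:
    hit = segment.intersection(poly.boundary)
    if hit.is_empty:
        return np.empty((0, 2))
    if isinstance(hit, Point):
        return np.array([hit.coords[0]])
    pts = []
    for g in getattr(hit, "geoms", [hit]):
        pts.extend(g.coords)
    return np.asarray(pts, dtype=float)


def cortex_intersections(centroid_a, centroid_b, outline_a, outline_b):
    """Intersections of the centroid-to-centroid segment with the two
    facing cortices.

    Returns ``(point_a, point_b)``: the crossing of outline_a's boundary
    nearest to outline_b's centroid and vice versa; both lie on the
    segment between the centroids.  Raises ValueError when a boundary is
    not crossed (degenerate outline).
    """
    ca = np.asarray(centroid_a, dtype=float)
    cb = np.asarray(centroid_b, dtype=float)
    seg = LineString([ca, cb])
    poly_a, poly_b = _as_polygon(outline_a), _as_polygon(outline_b)
    hits_a = _boundary_hits(seg, poly_a)
    hits_b = _boundary_hits(seg, poly_b)
    if len(hits_a) == 0 or len(hits_b) == 0:
        raise ValueError("centreline segment does not cross a bone cortex")
    pa = hits_a[np.argmin(np.linalg.norm(hits_a - cb, axis=1))]
    pb = hits_b[np.argmin(np.linalg.norm(hits_b - ca, axis=1))]
    return pa, pb


def joint_width(outline_a: BoneOutline, outline_b: BoneOutline):
    """Joint width between two bones along their centroid axis.

    Returns ``(width_mm, ok)``; overlapping outlines give ``(0.0, False)``
    (clamped and flagged rather than negative).
    """
    poly_a, poly_b = outline_a.polygon, outline_b.polygon
    inter = poly_a.intersection(poly_b)
    if not inter.is_empty and inter.area > 1e-9:
        return 0.0, False
    pa, pb = cortex_intersections(outline_a.centroid, outline_b.centroid,
                                  poly_a, poly_b)
    # guard against grazing contact: the two cortex points must be ordered
    # outline_a-side first along the axis
    axis = outline_b.centroid - outline_a.centroid
    t_a = float(np.dot(pa - outline_a.centroid, axis))
    t_b = float(np.dot(pb - outline_a.centroid, axis))
    if t_b < t_a:
        return 0.0, False
    return float(np.linalg.norm(pa - pb)), True


def sl_joint_width(mask, spacing_mm=None) -> float:
    """Scapholunate joint width (mm) from a label mask."""
    s = extract_outline(mask, SCAPHOID, spacing_mm)
    l = extract_outline(mask, LUNATE, spacing_mm)
    w, _ = joint_width(s, l)
    return w


def lt_joint_width(mask, spacing_mm=None) -> float:
    """Lunotriquetral joint width (mm) from a label mask."""
    l = extract_outline(mask, LUNATE, spacing_mm)
    t = extract_outline(mask, TRIQUETRUM, spacing_mm)
    w, _ = joint_width(l, t)
    return w


# --------------------------------------------------------------------------
# Minimal bounding box and wrist angle
# --------------------------------------------------------------------------

def min_bounding_box(points) -> MinBoundingBox:
    """Minimal-area rotated rectangle enclosing a point set.

    Computed from the convex hull (rotating-calipers construction: the
    optimal rectangle is aligned with a hull edge).  Raises ValueError on
    degenerate (collinear or < 3 point) input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("min_bounding_box needs at least 3 points")
    rect = MultiPoint(pts).minimum_rotated_rectangle
    if not isinstance(rect, Polygon):
        raise ValueError("degenerate point set (collinear points)")
    corners = np.asarray(rect.exterior.coords[:4], dtype=float)
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if l2 > l1:
        e1, l1, l2 = e2, l2, l1
    return MinBoundingBox(center=corners.mean(axis=0), long_axis=e1 / l1,
                          extent=(float(l1), float(l2)))


def wrist_angle_from_points(distal_points, forearm_points, ulnar_vector) -> float:
    """Signed wrist angle (deg) from raw point sets in mm.

    Angle between the forearm-box-centre -> distal-box-centre vector and
    the forearm box long axis, positive toward the ulnar side given by
    ``ulnar_vector``.
    """
    fbox = min_bounding_box(forearm_points)
    dbox = min_bounding_box(distal_points)
    u = fbox.long_axis.copy()
    v = dbox.center - fbox.center
    if np.dot(v, u) < 0:
        u = -u
    w = np.asarray(ulnar_vector, dtype=float)
    n = w - np.dot(w, u) * u
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("ulnar direction parallel to the forearm axis")
    n /= norm
    return float(np.degrees(np.arctan2(np.dot(v, n), np.dot(v, u))))


def wrist_angle(mask, spacing_mm=None) -> float:
    """Wrist angle (deg, ulnar abduction positive) from a label mask.

    Requires the four distal carpal bones and both forearm bones; the
    ulnar direction is inferred from the ulna-vs-radius centroid offset.
    """
    distal = [extract_outline(mask, b, spacing_mm) for b in DISTAL_ROW_IDS]
    radius = extract_outline(mask, FOREARM_IDS[0], spacing_mm)
    ulna = extract_outline(mask, FOREARM_IDS[1], spacing_mm)
    distal_pts = np.vstack([o.points for o in distal])
    forearm_pts = np.vstack([radius.points, ulna.points])
    return wrist_angle_from_points(distal_pts, forearm_pts,
                                   ulna.centroid - radius.centroid)


# --------------------------------------------------------------------------
# Series measurement
# --------------------------------------------------------------------------

def measure_frame(mask, spacing_mm=None, frame_index: int = 0,
                  t_s: float = np.nan) -> JointMeasurement:
    """All three quantities for one frame; failures yield an invalid row."""
    try:
        s = extract_outline(mask, SCAPHOID, spacing_mm)
        l = extract_outline(mask, LUNATE, spacing_mm)
        t = extract_outline(mask, TRIQUETRUM, spacing_mm)
        proximal_centreline(s, l, t)  # validates distinct anchors
        sl, ok_sl = joint_width(s, l)
        lt, ok_lt = joint_width(l, t)
        theta = wrist_angle(mask, spacing_mm)
    except (InvalidOutlineError, ValueError):
        return JointMeasurement(frame_index=frame_index, wrist_angle_deg=np.nan,
                                sl_width_mm=np.nan, lt_width_mm=np.nan,
                                valid=False, t_s=t_s)
    return JointMeasurement(frame_index=frame_index, wrist_angle_deg=theta,
                            sl_width_mm=sl, lt_width_mm=lt,
                            valid=bool(ok_sl and ok_lt), t_s=t_s)


def measure_series(masks, spacing_mm=None, frame_interval_s: float = np.nan):
    """Measure every frame of a mask stack; invalid frames are flagged,
    never dropped.  Returns a list of :class:`JointMeasurement`."""
    out = []
    for i, mask in enumerate(masks):
        t_s = i * frame_interval_s if np.isfinite(frame_interval_s) else np.nan
        out.append(measure_frame(mask, spacing_mm, frame_index=i, t_s=t_s))
    return out


def measurements_to_frame(measurements):
    """Tabulate measurements with a per-frame sweep-direction tag.

    Columns: frame, t_s, angle_deg, sl_mm, lt_mm, valid, sweep_direction
    (sign of the smoothed angle increment: radial->ulnar when increasing).
    """
    import pandas as pd

    df = pd.DataFrame({
        "frame": [m.frame_index for m in measurements],
        "t_s": [m.t_s for m in measurements],
        "angle_deg": [m.wrist_angle_deg for m in measurements],
        "sl_mm": [m.sl_width_mm for m in measurements],
        "lt_mm": [m.lt_width_mm for m in measurements],
        "valid": [m.valid for m in measurements],
    })
    if len(df) >= 2:
        theta = df["angle_deg"].to_numpy()
        dth = np.gradient(np.nan_to_num(theta, nan=0.0))
        k = min(5, len(dth))
        dth = np.convolve(dth, np.ones(k) / k, mode="same")
        sweep = np.where(dth >= 0, "radial_to_ulnar", "ulnar_to_radial")
    else:
        sweep = ["radial_to_ulnar"] * len(df)
    df["sweep_direction"] = sweep
    return df
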