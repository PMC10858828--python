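"""Synthetic dynamic wrist phantom generator.

Generates paired (injured, contralateral-control) coronal wrist "movies":
per-frame grayscale images, ground-truth label masks, the true wrist angle
and the true scapholunate (SL) and lunotriquetral (LT) joint gaps.

The phantom is a 2D cartoon of the carpus: nine convex bone polygons
(distal radius, distal ulna; proximal row scaphoid/lunate/triquetrum;
distal row hamate/capitate/trapezium/trapezoid) laid out with correct
neighbour adjacencies on a 168 mm field of view at 1.0 mm/px.  During a
simulated radioulnar abduction cycle the distal carpal row rotates by the
full wrist angle about the pivot and the proximal row by a fixed fraction
of it, while the SL and LT gaps are enforced *exactly* in continuous
coordinates: for every frame the scaphoid (resp. triquetrum) is translated
along the centroid axis so that the distance between the facing cortices
on that axis equals the preset gap function evaluated at the current
angle.  Anatomical realism is not attempted; the geometry pipeline under
test is shape-agnostic and only the topology (adjacencies and gap axes)
matters.

Presets encode three ligament conditions as angle-dependent SL gap
profiles: a healthy wrist (flat, just under 2 mm), a partial tear
(≈3.1 mm on average, widest in the neutral position) and a complete tear
(≈3.4 mm on average, peaking at 7.5° ulnar abduction); complete tears
additionally make the LT gap increase monotonically from radial to ulnar
abduction.  Per-subject variability is a seeded jitter on shape scale and
gap amplitudes.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

from .imaging import CLASS_MAP, BONE_IDS, LabelMask, MotionFrame
from . import carpal_geometry as geom

# --------------------------------------------------------------------------
# Constants: acquisition geometry of the simulated real-time series
# --------------------------------------------------------------------------

IMAGE_SHAPE = (168, 168)          # px
PIXEL_SIZE_MM = 1.0               # acquired resolution, mm/px
FRAME_INTERVAL_S = 0.095          # temporal resolution, s/frame
CYCLE_S = 15.0                    # one full radial->ulnar->radial cycle, s
N_FRAMES = 300                    # 300 frames ~ 28.5 s ~ 1.9 cycles
ANGLE_EXTENT_DEG = (-20.0, 20.0)  # trajectory extent (device allows +-60)

PRESETS = ("healthy", "partial_tear", "complete_tear")

# SL gap presets: (mean over -10..+20 deg, peak location deg, peak value mm)
_SL_PRESET_PARAMS = {
    "healthy": (1.9, 0.0, 1.9),          # flat, "around 2 mm"
    "partial_tear": (3.12, 0.0, 3.35),   # widest in neutral position
    "complete_tear": (3.39, 7.5, 3.91),  # maximum at 5-10 deg ulnar
}
_SL_MEAN_WINDOW = (-10.0, 20.0)  # window over which preset means are defined
_LT_BASE_MM = 1.3
_LT_COMPLETE_SLOPE = 0.02        # mm/deg, monotone widening toward ulnar

JITTER_REL_SD = 0.15             # per-subject gap jitter, fraction of mean
_SHAPE_JITTER_SD = 0.03          # per-subject bone scale jitter

# grayscale intensities per class (arbitrary units, background first)
_INTENSITIES = {
    0: 0.05, 1: 0.45, 2: 0.50, 3: 0.60, 4: 0.70, 5: 0.80,
    6: 0.55, 7: 0.65, 8: 0.75, 9: 0.85,
}
NOISE_SIGMA = 0.03               # ~5% of mean bone intensity
BLUR_SIGMA_MM = 0.7

PROXIMAL_ROW = (3, 4, 5)         # scaphoid, lunate, triquetrum
DISTAL_ROW = (6, 7, 8, 9)        # hamate, capitate, trapezium, trapezoid
FOREARM = (1, 2)                 # radius, ulna
PROXIMAL_ROTATION_FRACTION = 0.5


# --------------------------------------------------------------------------
# Gap functions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GapCurve:
    """Angle-dependent joint gap in mm.

    kind 'bump': base + amp * 0.5*(1 + cos(pi*(theta-center)/halfwidth))
    inside |theta - center| < halfwidth, else base (a smooth cosine bump).
    kind 'linear': base + slope * theta.
    """

    kind: str                     # 'bump' | 'linear'
    base: float
    amp: float = 0.0
    center_deg: float = 0.0
    halfwidth_deg: float = 25.0
    slope: float = 0.0

    def __call__(self, theta_deg):
        th = np.asarray(theta_deg, dtype=float)
        if self.kind == "linear":
            out = self.base + self.slope * th
        elif self.kind == "bump":
            u = (th - self.center_deg) / self.halfwidth_deg
            bump = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
            out = self.base + self.amp * bump
        else:  # pragma: no cover - constructor controls kinds
            raise ValueError(f"unknown gap curve kind {self.kind!r}")
        return float(out) if np.isscalar(theta_deg) else out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GapCurve":
        return cls(**d)


def _bump_curve_from_mean(mean_mm: float, peak_deg: float, peak_mm: float,
                          halfwidth_deg: float = 25.0,
                          window=_SL_MEAN_WINDOW) -> GapCurve:
    """Cosine-bump gap curve with a prescribed mean over `window` and a
    prescribed peak value at `peak_deg`."""
    th = np.linspace(window[0], window[1], 2001)
    u = (th - peak_deg) / halfwidth_deg
    bump = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
    bbar = float(bump.mean())
    if peak_mm <= mean_mm:  # flat curve
        return GapCurve(kind="bump", base=mean_mm, amp=0.0,
                        center_deg=peak_deg, halfwidth_deg=halfwidth_deg)
    amp = (peak_mm - mean_mm) / (1.0 - bbar)
    base = mean_mm - amp * bbar
    if base <= 0:
        raise ValueError("gap curve parameters give non-positive base gap")
    return GapCurve(kind="bump", base=base, amp=amp,
                    center_deg=peak_deg, halfwidth_deg=halfwidth_deg)


# --------------------------------------------------------------------------
# Bone templates
# --------------------------------------------------------------------------

def _blob(cx, cy, rx, ry, n=18, wobble=0.05, phase=0.0):
    """Convex, slightly irregular ellipse-like polygon (vertices in mm)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    m = 1.0 + wobble * np.cos(2.0 * t + phase)
    pts = np.column_stack([cx + rx * m * np.cos(t), cy + ry * m * np.sin(t)])
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _base_templates() -> dict[int, np.ndarray]:
    """Neutral-pose bone polygons for a right wrist.

    Coordinates in mm with x = column (radial -> ulnar for a right wrist)
    and y = row (distal at the top of the image, forearm at the bottom).
    """
    return {
        # forearm bones deliberately long and narrow: the wrist angle is
        # referenced to their combined minimal bounding box, whose
        # orientation is only stable for a clearly elongated hull
        1: _blob(74.0, 128.0, 8.5, 30.0, n=26, wobble=0.03, phase=0.7),   # radius
        2: _blob(95.0, 129.0, 6.5, 28.0, n=26, wobble=0.03, phase=1.9),   # ulna
        3: _blob(59.0, 77.0, 10.0, 8.5, wobble=0.07, phase=0.3),          # scaphoid
        4: _blob(84.0, 79.0, 8.0, 8.0, wobble=0.06, phase=2.1),           # lunate
        5: _blob(106.0, 78.0, 8.0, 7.0, wobble=0.06, phase=4.0),          # triquetrum
        6: _blob(103.0, 54.0, 8.5, 7.5, wobble=0.06, phase=1.2),          # hamate
        7: _blob(83.0, 52.0, 8.0, 9.5, wobble=0.05, phase=5.1),           # capitate
        8: _blob(52.0, 57.0, 7.0, 6.5, wobble=0.07, phase=2.8),           # trapezium
        9: _blob(67.0, 53.0, 6.0, 5.5, wobble=0.07, phase=0.9),           # trapezoid
    }


def _rotate(points: np.ndarray, pivot: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return (points - pivot) @ rot.T + pivot


# --------------------------------------------------------------------------
# PhantomSpec / GroundTruth
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Full parametric description of one synthetic wrist and its motion."""

    bone_shapes: dict[int, np.ndarray]      # bone id -> (N, 2) polygon, mm
    pivot: np.ndarray                       # rotation centre, mm
    gap_sl_fn: GapCurve
    gap_lt_fn: GapCurve
    angle_extent_deg: tuple[float, float] = ANGLE_EXTENT_DEG
    cycle_s: float = CYCLE_S
    frame_interval_s: float = FRAME_INTERVAL_S
    n_frames: int = N_FRAMES
    noise_sigma: float = NOISE_SIGMA
    blur_sigma_mm: float = BLUR_SIGMA_MM
    seed: int = 0
    side: str = "right"
    preset: str = "healthy"
    image_shape: tuple[int, int] = IMAGE_SHAPE
    spacing_mm: float = PIXEL_SIZE_MM
    proximal_fraction: float = PROXIMAL_ROTATION_FRACTION
    ulnar_x_sign: float = 1.0               # +1: ulna on +x side (right wrist)

    def __post_init__(self):
        lo, hi = self.angle_extent_deg
        if not (-60.0 <= lo <= hi <= 60.0):
            raise ValueError("angle_extent_deg must lie within [-60, 60] "
                             "(the motion device allows 60 deg to each side)")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        th = np.linspace(lo, hi, 41)
        for name, fn in (("gap_sl_fn", self.gap_sl_fn), ("gap_lt_fn", self.gap_lt_fn)):
            if np.any(np.asarray(fn(th)) <= 0):
                raise ValueError(f"{name} must be positive over the trajectory")

    def to_json(self) -> str:
        d = {
            "bone_shapes": {str(k): v.tolist() for k, v in self.bone_shapes.items()},
            "pivot": self.pivot.tolist(),
            "gap_sl_fn": self.gap_sl_fn.to_dict(),
            "gap_lt_fn": self.gap_lt_fn.to_dict(),
            "angle_extent_deg": list(self.angle_extent_deg),
            "cycle_s": self.cycle_s,
            "frame_interval_s": self.frame_interval_s,
            "n_frames": self.n_frames,
            "noise_sigma": self.noise_sigma,
            "blur_sigma_mm": self.blur_sigma_mm,
            "seed": self.seed,
            "side": self.side,
            "preset": self.preset,
            "image_shape": list(self.image_shape),
            "spacing_mm": self.spacing_mm,
            "proximal_fraction": self.proximal_fraction,
            "ulnar_x_sign": self.ulnar_x_sign,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["bone_shapes"] = {int(k): np.asarray(v, dtype=float)
                            for k, v in d["bone_shapes"].items()}
        d["pivot"] = np.asarray(d["pivot"], dtype=float)
        d["gap_sl_fn"] = GapCurve.from_dict(d["gap_sl_fn"])
        d["gap_lt_fn"] = GapCurve.from_dict(d["gap_lt_fn"])
        d["angle_extent_deg"] = tuple(d["angle_extent_deg"])
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-frame oracle values: the simulated angle and joint gaps."""

    true_angle_deg: np.ndarray
    true_gap_sl_mm: np.ndarray
    true_gap_lt_mm: np.ndarray

    def __post_init__(self):
        n = len(self.true_angle_deg)
        if not (len(self.true_gap_sl_mm) == len(self.true_gap_lt_mm) == n):
            raise ValueError("ground-truth arrays must have equal length")
        if np.any(self.true_gap_sl_mm <= 0) or np.any(self.true_gap_lt_mm <= 0):
            raise ValueError("true gaps must be positive")

    def __len__(self) -> int:
        return len(self.true_angle_deg)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "frame": np.arange(len(self)),
            "true_angle_deg": self.true_angle_deg,
            "true_gap_sl_mm": self.true_gap_sl_mm,
            "true_gap_lt_mm": self.true_gap_lt_mm,
        })


# --------------------------------------------------------------------------
# Spec construction
# --------------------------------------------------------------------------

def make_phantom_spec(preset: str, side: str = "right", seed: int = 0,
                      **overrides) -> PhantomSpec:
    """Build a seeded per-subject phantom for a ligament-condition preset.

    `preset` is one of 'healthy', 'partial_tear', 'complete_tear'; `seed`
    controls the per-subject jitter on bone scale and gap amplitudes.
    Keyword overrides are applied to the resulting :class:`PhantomSpec`
    (e.g. ``n_frames=60`` for a short series).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    rng = np.random.default_rng(seed)
    # fixed draw count so matched seeds give matched jitter across presets
    shape_factors = np.clip(rng.normal(1.0, _SHAPE_JITTER_SD, size=9), 0.9, 1.1)
    f_mean, f_peak, f_lt = np.clip(rng.normal(1.0, JITTER_REL_SD, size=3), 0.6, 1.4)

    shapes = _base_templates()
    for i, bone_id in enumerate(sorted(shapes)):
        pts = shapes[bone_id]
        c = pts.mean(axis=0)
        shapes[bone_id] = (pts - c) * shape_factors[i] + c

    # pivot := centre of the forearm minimal bounding box, so that the
    # bounding-box wrist-angle construction recovers the device angle exactly
    forearm_pts = np.vstack([shapes[b] for b in FOREARM])
    fbox = geom.min_bounding_box(forearm_pts)
    pivot = np.asarray(fbox.center, dtype=float)
    axis = np.asarray(fbox.long_axis, dtype=float)

    # orient the forearm axis distally (toward the carpus, smaller y)
    carpal_centre = np.vstack([shapes[b] for b in DISTAL_ROW]).mean(axis=0)
    if np.dot(carpal_centre - pivot, axis) < 0:
        axis = -axis

    # align the distal-row box centre with the forearm axis (neutral pose
    # then measures exactly 0 deg)
    distal_pts = np.vstack([shapes[b] for b in DISTAL_ROW])
    dbox = geom.min_bounding_box(distal_pts)
    offset = np.asarray(dbox.center) - pivot
    perp = offset - np.dot(offset, axis) * axis
    for b in DISTAL_ROW:
        shapes[b] = shapes[b] - perp

    mean_sl, peak_deg, peak_mm = _SL_PRESET_PARAMS[preset]
    mean_sl_j = mean_sl * f_mean
    peak_mm_j = mean_sl_j + (peak_mm - mean_sl) * f_peak
    gap_sl = _bump_curve_from_mean(mean_sl_j, peak_deg, peak_mm_j)

    if preset == "complete_tear":
        # monotone widening toward ulnar abduction
        gap_lt = GapCurve(kind="linear", base=_LT_BASE_MM * f_lt,
                          slope=_LT_COMPLETE_SLOPE * f_lt)
    else:
        gap_lt = GapCurve(kind="linear", base=_LT_BASE_MM * f_lt, slope=0.0)

    if side == "left":
        # mirror about the image mid-column: ulna ends up on the -x side
        w = (IMAGE_SHAPE[1] - 1) * PIXEL_SIZE_MM
        for b in shapes:
            m = shapes[b].copy()
            m[:, 0] = w - m[:, 0]
            shapes[b] = m[::-1]  # keep vertex orientation
        pivot = np.array([w - pivot[0], pivot[1]])
        ulnar_x_sign = -1.0
    else:
        ulnar_x_sign = 1.0

    spec = PhantomSpec(bone_shapes=shapes, pivot=pivot, gap_sl_fn=gap_sl,
                       gap_lt_fn=gap_lt, seed=seed, side=side, preset=preset,
                       ulnar_x_sign=ulnar_x_sign)
    if overrides:
        spec = dataclasses.replace(spec, **overrides)
    return spec


# --------------------------------------------------------------------------
# Trajectory
# --------------------------------------------------------------------------

def angle_trajectory(spec: PhantomSpec) -> np.ndarray:
    """Sinusoidal wrist-angle trajectory theta(t), degrees.

    Starts at maximum radial abduction (the trajectory minimum), reaches
    maximum ulnar abduction after half a cycle and returns; sampled every
    ``frame_interval_s`` for ``n_frames`` frames.
    """
    lo, hi = spec.angle_extent_deg
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    t = np.arange(spec.n_frames) * spec.frame_interval_s
    return mid - half * np.cos(2.0 * np.pi * t / spec.cycle_s)


# --------------------------------------------------------------------------
# Frame geometry and rendering
# --------------------------------------------------------------------------

def _axis_gap(poly_a: Polygon, poly_b: Polygon) -> float:
    """Gap between two polygons along their centroid-to-centroid axis."""
    ca = np.array(poly_a.centroid.coords[0])
    cb = np.array(poly_b.centroid.coords[0])
    pa, pb = geom.cortex_intersections(ca, cb, poly_a, poly_b)
    return float(np.hypot(*(pa - pb)))


def pose_polygons(spec: PhantomSpec, angle_deg: float) -> dict[int, np.ndarray]:
    """Continuous-coordinate bone polygons at a given wrist angle.

    The distal row rotates by the full (signed, ulnar-positive) angle about
    the pivot, the proximal row by ``proximal_fraction`` of it; the forearm
    is fixed.  The SL and LT gaps along the centroid axes are enforced
    exactly before the row rotation (translation of the scaphoid and the
    triquetrum along the axis), so rigid rotation preserves them.
    """
    lo, hi = spec.angle_extent_deg
    if not (lo - 1e-9 <= angle_deg <= hi + 1e-9):
        raise ValueError(f"angle {angle_deg} outside trajectory extent {spec.angle_extent_deg}")

    shapes = {b: spec.bone_shapes[b].copy() for b in spec.bone_shapes}

    # enforce gaps in the neutral row frame
    lun = Polygon(shapes[4])
    for bone_id, target in ((3, float(spec.gap_sl_fn(angle_deg))),
                            (5, float(spec.gap_lt_fn(angle_deg)))):
        poly = Polygon(shapes[bone_id])
        current = _axis_gap(poly, lun)
        c_self = np.array(poly.centroid.coords[0])
        c_lun = np.array(lun.centroid.coords[0])
        u = c_self - c_lun
        u = u / np.linalg.norm(u)
        shapes[bone_id] = shapes[bone_id] + (target - current) * u

    # ulnar-positive rotation: for a right wrist (+x ulnar) a positive
    # angle swings the carpus toward +x, i.e. clockwise in (x, y=row)
    rot_sign = spec.ulnar_x_sign
    for b in PROXIMAL_ROW:
        shapes[b] = _rotate(shapes[b], spec.pivot,
                            rot_sign * spec.proximal_fraction * angle_deg)
    for b in DISTAL_ROW:
        shapes[b] = _rotate(shapes[b], spec.pivot, rot_sign * angle_deg)
    return shapes


def _check_disjoint(shapes: dict[int, np.ndarray], angle_deg: float) -> None:
    polys = {b: Polygon(p) for b, p in shapes.items()}
    ids = sorted(polys)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if polys[a].intersects(polys[b]) and polys[a].intersection(polys[b]).area > 1e-9:
                raise ValueError(
                    f"phantom invalid at {angle_deg:.1f} deg: bones "
                    f"{CLASS_MAP[a]} and {CLASS_MAP[b]} overlap after gap enforcement")


def rasterize(shapes: dict[int, np.ndarray], image_shape=IMAGE_SHAPE,
              spacing_mm: float = PIXEL_SIZE_MM) -> np.ndarray:
    """Rasterize bone polygons to an integer label image.

    Pixel centres sit at (row*spacing, col*spacing) mm, matching the
    coordinate convention used by subpixel contour extraction downstream.
    """
    from skimage.draw import polygon as draw_polygon

    labels = np.zeros(image_shape, dtype=np.uint8)
    for bone_id, pts in shapes.items():
        rr, cc = draw_polygon(pts[:, 1] / spacing_mm, pts[:, 0] / spacing_mm,
                              shape=image_shape)
        labels[rr, cc] = bone_id
    return labels


def render_frame(spec: PhantomSpec, angle_deg: float,
                 rng: np.random.Generator | None = None):
    """Render one frame: (grayscale image, label mask, ground-truth row).

    The grayscale image is a class-intensity map blurred by the point
    spread (``blur_sigma_mm``) with additive Gaussian noise; each bone is
    given a distinct tissue intensity so that the optional segmentation
    task is well posed in a single coronal slice.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shapes = pose_polygons(spec, angle_deg)
    _check_disjoint(shapes, angle_deg)
    labels = rasterize(shapes, spec.image_shape, spec.spacing_mm)

    lut = np.array([_INTENSITIES[c] for c in range(10)], dtype=np.float32)
    image = lut[labels]
    if spec.blur_sigma_mm > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma_mm / spec.spacing_mm)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape).astype(np.float32)
    truth = (float(angle_deg), float(spec.gap_sl_fn(angle_deg)),
             float(spec.gap_lt_fn(angle_deg)))
    return image.astype(np.float32), labels, truth


def generate_series(spec: PhantomSpec, render_grayscale: bool = True):
    """Render the full motion series for one wrist.

    Returns ``(frames, masks, truth)`` where ``frames`` is a float32 stack
    (or ``None`` when ``render_grayscale`` is false), ``masks`` a uint8
    label stack and ``truth`` a :class:`GroundTruth`.  Deterministic for a
    fixed spec (the noise stream is seeded by ``spec.seed``).
    """
    angles = angle_trajectory(spec)
    rng = np.random.default_rng(spec.seed)
    masks = np.empty((spec.n_frames, *spec.image_shape), dtype=np.uint8)
    frames = (np.empty((spec.n_frames, *spec.image_shape), dtype=np.float32)
              if render_grayscale else None)
    lut = np.array([_INTENSITIES[c] for c in range(10)], dtype=np.float32)
    for i, th in enumerate(angles):
        shapes = pose_polygons(spec, th)
        _check_disjoint(shapes, th)
        labels = rasterize(shapes, spec.image_shape, spec.spacing_mm)
        masks[i] = labels
        if render_grayscale:
            img = lut[labels]
            if spec.blur_sigma_mm > 0:
                img = ndimage.gaussian_filter(img, spec.blur_sigma_mm / spec.spacing_mm)
            if spec.noise_sigma > 0:
                img = img + rng.normal(0.0, spec.noise_sigma,
                                       size=img.shape).astype(np.float32)
            frames[i] = img
    truth = GroundTruth(true_angle_deg=angles,
                        true_gap_sl_mm=np.asarray(spec.gap_sl_fn(angles), dtype=float),
                        true_gap_lt_mm=np.asarray(spec.gap_lt_fn(angles), dtype=float))
    return frames, masks, truth


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class WristSeries:
    """One wrist's rendered series plus its provenance."""

    patient_id: int
    group: str                    # e.g. 'injured_partial', 'control_complete'
    side: str
    spec: PhantomSpec
    frames: np.ndarray | None
    masks: np.ndarray
    truth: GroundTruth


def generate_cohort(n_patients: int, tear_presets: Sequence[str], seed: int = 0,
                    render_grayscale: bool = True,
                    spec_overrides: dict | None = None) -> list[WristSeries]:
    """Generate a paired cohort: per patient one injured wrist drawn from
    its tear preset and one healthy contralateral control wrist.

    The two wrists of a patient share a seed lineage (spawned from the
    cohort seed) so subject-level jitter is correlated the way a real
    contralateral design is paired.  Group labels follow the
    injured_/control_ x partial/complete naming.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if len(tear_presets) != n_patients:
        raise ValueError(f"tear_presets has {len(tear_presets)} entries "
                         f"for {n_patients} patients")
    for p in tear_presets:
        if p not in PRESETS:
            raise ValueError(f"unknown preset {p!r}")

    overrides = spec_overrides or {}
    root = np.random.SeedSequence(seed)
    series: list[WristSeries] = []
    for pid, preset in enumerate(tear_presets):
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(pid,))
        s_inj, s_ctl = [int(s.generate_state(1)[0] % (2 ** 31)) for s in child.spawn(2)]
        injured_side = "right" if pid % 2 == 0 else "left"
        control_side = "left" if injured_side == "right" else "right"
        suffix = {"healthy": "healthy", "partial_tear": "partial",
                  "complete_tear": "complete"}[preset]
        for role, side, sd, pre in (("injured", injured_side, s_inj, preset),
                                    ("control", control_side, s_ctl, "healthy")):
            spec = make_phantom_spec(pre, side=side, seed=sd, **overrides)
            frames, masks, truth = generate_series(spec, render_grayscale)
            series.append(WristSeries(patient_id=pid, group=f"{role}_{suffix}",
                                      side=side, spec=spec, frames=frames,
                                      masks=masks, truth=truth))
    return series
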