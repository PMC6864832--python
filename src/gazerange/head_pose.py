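"""Head-angle estimation from windshield fiducial markers.

The driver wears a forward-looking view camera; four printed markers
(upward triangle, circle, downward triangle, star) sit on the windshield in a
fixed left-to-right order.  When the head rotates, the markers translate in
the image; the displacement of a marker from its forward-facing reference
position, scaled by the camera's degrees-per-pixel ratio, gives the head yaw
and pitch.  Head roll tilts the whole marker constellation in the image
plane and would corrupt the axis readout, so roll is estimated first from a
pair of markers and the detected coordinates are rotated back to a
zero-roll frame before yaw/pitch are read off.

Markers are located by normalized cross-correlation template matching.
Three search-space reductions keep per-frame cost low without losing hits:

1. ordering constraints — markers are searched in id order and each later
   marker's region is clipped to the right of earlier ones; the outermost
   marker (4) is never searched in a frame where markers 1 or 2 were just
   seen, because the camera field of view cannot contain both ends of the
   constellation at once;
2. three-section division — each region is split into three horizontal
   bands, each padded vertically by (template height − 1) px so a marker
   straddling a band boundary is still wholly contained in one band, and the
   bands are searched center → upper → bottom, stopping at the first band
   whose best score clears the similarity threshold;
3. motion extension — a region tracked from the previous frame is enlarged
   along the inter-frame displacement vector, so fast head turns do not
   outrun the search window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from skimage.feature import match_template

from .io_session import CameraModel, MarkerLayout, SessionConfig

__all__ = [
    "MarkerDetection",
    "SearchRegion",
    "CalibrationResult",
    "HeadPose",
    "match_template_region",
    "plan_search_regions",
    "split_into_sections",
    "calibrate",
    "extrapolate_reference",
    "estimate_roll",
    "derotate",
    "pixels_to_angle",
    "estimate_head_pose",
    "MarkerTracker",
    "track_frames",
    "CalibrationError",
]

MARKER_ORDER = (1, 2, 3, 4)


class CalibrationError(RuntimeError):
    """A marker required for calibration was never detected."""


@dataclass(frozen=True)
class MarkerDetection:
    """One accepted template-match hit (pixel anchor = template top-left)."""

    marker_id: int
    x: int
    y: int
    score: float
    frame: int = 0

    @property
    def pos(self) -> tuple[int, int]:
        return (self.x, self.y)


@dataclass(frozen=True)
class SearchRegion:
    """Half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x0 >= self.x1 or self.y0 >= self.y1:
            raise ValueError(f"degenerate search region {self!r}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def clip(self, width: int, height: int) -> "SearchRegion | None":
        x0, y0 = max(self.x0, 0), max(self.y0, 0)
        x1, y1 = min(self.x1, width), min(self.y1, height)
        if x0 >= x1 or y0 >= y1:
            return None
        return SearchRegion(x0, y0, x1, y1)

    @staticmethod
    def full(width: int, height: int) -> "SearchRegion":
        return SearchRegion(0, 0, width, height)


@dataclass(frozen=True)
class CalibrationResult:
    """Forward-facing reference pixel position for every marker.

    Markers 1–3 are observed directly during the forward-facing window;
    marker 4 lies outside the field of view while facing forward, so its
    reference x is extrapolated from the marker 2/3 spacing via the
    configured alpha:beta ratio.
    """

    ref: Mapping[int, tuple[float, float]]
    n_frames: int
    marker4_extrapolated: bool = True

    def __post_init__(self) -> None:
        missing = [m for m in MARKER_ORDER if m not in self.ref]
        if missing:
            raise ValueError(f"calibration missing marker(s) {missing}")


@dataclass(frozen=True)
class HeadPose:
    """Yaw/pitch/roll of the head for one frame, in degrees.

    Sign convention: yaw positive = head turned to the subject's right,
    pitch positive = head tilted up, roll = in-image tilt angle of the
    marker pair (counterclockwise positive in standard x-right/y-up terms).
    """

    frame: int
    yaw: float = math.nan
    pitch: float = math.nan
    roll: float = math.nan
    valid: bool = False
    yaw_marker: int | None = None
    pitch_marker: int | None = None

    def __post_init__(self) -> None:
        if self.valid:
            if not all(map(math.isfinite, (self.yaw, self.pitch, self.roll))):
                raise ValueError("valid pose requires finite angles")
            if abs(self.roll) >= 90.0:
                raise ValueError("|roll| must be < 90 deg")


# ---------------------------------------------------------------------------
# Template matching


def _ncc_peak(window: np.ndarray, template: np.ndarray) -> tuple[int, int, float]:
    """Peak of normalized cross-correlation of ``template`` over ``window``.

    Returns (dx, dy, score) with the anchor offset of the best placement
    inside the window and the NCC score mapped from [-1, 1] to [0, 1] by
    clipping negative correlations to zero (an anti-correlated patch is as
    useless as an uncorrelated one for marker acceptance).
    """
    resp = match_template(window, template, pad_input=False)
    iy, ix = np.unravel_index(int(np.argmax(resp)), resp.shape)
    score = float(np.clip(resp[iy, ix], 0.0, 1.0))
    return int(ix), int(iy), score


def match_template_region(
    frame: np.ndarray,
    template: np.ndarray,
    region: SearchRegion,
    threshold: float,
    marker_id: int = 0,
    frame_index: int = 0,
) -> MarkerDetection | None:
    """Best template placement inside ``region``, or None below ``threshold``.

    The returned (x, y) is the template's top-left anchor in full-frame
    coordinates.  Raises ValueError when the template does not fit in the
    region.
    """
    h, w = frame.shape[:2]
    if not (0 <= region.x0 < region.x1 <= w and 0 <= region.y0 < region.y1 <= h):
        raise ValueError(f"region {region} exceeds frame {(w, h)}")
    th, tw = template.shape[:2]
    if th > region.height or tw > region.width:
        raise ValueError(
            f"template {(tw, th)} larger than region {(region.width, region.height)}"
        )
    window = frame[region.y0 : region.y1, region.x0 : region.x1]
    dx, dy, score = _ncc_peak(window, template)
    if score < threshold:
        return None
    return MarkerDetection(
        marker_id=marker_id,
        x=region.x0 + dx,
        y=region.y0 + dy,
        score=score,
        frame=frame_index,
    )


# ---------------------------------------------------------------------------
# Search planning


def split_into_sections(
    region: SearchRegion, template_height: int
) -> list[SearchRegion]:
    """Divide a region into three horizontal bands, searched center-first.

    Each band is grown vertically by (template_height − 1) px on both sides
    and clipped back to the region, so a marker straddling a band boundary
    is fully contained in at least one band.
    """
    if region.height < 3:
        return [region]
    pad = max(int(template_height) - 1, 0)
    h3 = region.height // 3
    cuts = [region.y0, region.y0 + h3, region.y0 + 2 * h3, region.y1]
    bands = []
    for i in range(3):
        y0 = max(cuts[i] - pad, region.y0)
        y1 = min(cuts[i + 1] + pad, region.y1)
        bands.append(SearchRegion(region.x0, y0, region.x1, y1))
    upper, center, bottom = bands
    return [center, upper, bottom]


def _window_around(
    pos: tuple[int, int], tpl_shape: tuple[int, int], margin: float
) -> SearchRegion:
    th, tw = tpl_shape
    half_w = int(math.ceil(margin * tw))
    half_h = int(math.ceil(margin * th))
    x, y = pos
    return SearchRegion(x - half_w, y - half_h, x + tw + half_w, y + th + half_h)


def plan_search_regions(
    prev: Mapping[int, MarkerDetection] | None,
    prev2: Mapping[int, MarkerDetection] | None,
    frame_shape: tuple[int, int],
    templates: Mapping[int, np.ndarray],
    extension_gain: float = 1.5,
    search_margin: float = 2.0,
) -> dict[int, list[SearchRegion]]:
    """Per-marker search regions for the next frame.

    ``prev``/``prev2`` hold the detections of frames t−1 and t−2 keyed by
    marker id (either may be empty or None).  The emitted regions honor the
    marker ordering constraints (each later-searched marker lies to the
    right of the earlier ones; marker 4 is skipped entirely when marker 1
    or 2 was just seen), track the previous position with a window enlarged
    along the t−2→t−1 displacement by ``extension_gain`` x |displacement|,
    and degrade to the constrained frame portion when a marker was unseen.
    """
    prev = dict(prev or {})
    prev2 = dict(prev2 or {})
    h, w = frame_shape[:2]
    out: dict[int, list[SearchRegion]] = {}

    for mid in MARKER_ORDER:
        tpl = templates[mid]
        # marker 4 shares no frame with markers 1 or 2
        if mid == 4 and (1 in prev or 2 in prev):
            out[4] = []
            continue

        # left bound from the ordering constraints, based on frame t-1
        x_floor = 0
        left_ids = {2: (1,), 3: (1, 2), 4: (3,)}.get(mid, ())
        for lid in left_ids:
            if lid in prev:
                x_floor = max(x_floor, prev[lid].x + 1)

        if mid in prev:
            region = _window_around(prev[mid].pos, tpl.shape[:2], search_margin)
            if mid in prev2:
                dx = prev[mid].x - prev2[mid].x
                dy = prev[mid].y - prev2[mid].y
                ex = int(math.ceil(extension_gain * abs(dx)))
                ey = int(math.ceil(extension_gain * abs(dy)))
                region = SearchRegion(
                    region.x0 - (ex if dx < 0 else 0),
                    region.y0 - (ey if dy < 0 else 0),
                    region.x1 + (ex if dx > 0 else 0),
                    region.y1 + (ey if dy > 0 else 0),
                )
        else:
            region = SearchRegion.full(w, h)

        region = SearchRegion(max(region.x0, x_floor), region.y0, region.x1, region.y1) \
            if region.x1 > x_floor else None  # entirely left of the floor -> empty
        region = region.clip(w, h) if region is not None else None

        # drop regions too small for the template
        if region is not None and (
            region.width < tpl.shape[1] or region.height < tpl.shape[0]
        ):
            region = None
        out[mid] = [region] if region is not None else []
    return out


def detect_markers(
    frame: np.ndarray,
    templates: Mapping[int, np.ndarray],
    regions: Mapping[int, Sequence[SearchRegion]],
    threshold: float,
    frame_index: int = 0,
    sectioned: bool = True,
) -> dict[int, MarkerDetection]:
    """Run the sectioned, ordered marker search over one frame.

    For each marker (in id order) and each of its candidate regions the
    three vertical sections are tried center/upper/bottom; the first section
    whose best score clears ``threshold`` wins.  Because the expanded bands
    jointly cover every template placement in the region, a marker missed by
    all three bands would also be missed by a whole-region search, so no
    fallback pass is needed.
    """
    found: dict[int, MarkerDetection] = {}
    for mid in MARKER_ORDER:
        tpl = templates[mid]
        det: MarkerDetection | None = None
        for region in regions.get(mid, ()):
            bands = (
                split_into_sections(region, tpl.shape[0]) if sectioned else [region]
            )
            for band in bands:
                if band.height < tpl.shape[0] or band.width < tpl.shape[1]:
                    continue
                det = match_template_region(
                    frame, tpl, band, threshold, mid, frame_index
                )
                if det is not None:
                    break
            if det is not None:
                break
        if det is not None:
            found[mid] = det
    return found


# ---------------------------------------------------------------------------
# Calibration


def extrapolate_reference(ax: float, bx: float, alpha: float, beta: float) -> float:
    """Reference x of the off-screen marker from the two inner references.

    With A, B, C the reference x positions of markers 2, 3, 4 and the
    physical spacing ratio (A−B) : (B−C) = alpha : beta, B is the ratio
    point  B = (beta*A + alpha*C) / (alpha + beta); solving for C:

        C = −(1/alpha) * ( beta*(A − B) − alpha*B )

    The formula is orientation-agnostic: for A > B it extrapolates leftward
    (C < B < A), for A < B rightward.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    return -(beta * (ax - bx) - alpha * bx) / alpha


def calibrate(
    forward_frames: Sequence[np.ndarray],
    templates: Mapping[int, np.ndarray],
    layout: MarkerLayout,
    threshold: float = 0.70,
) -> CalibrationResult:
    """Record per-marker reference positions from a forward-facing window.

    Markers 1–3 must each be detected in at least one frame; their reference
    is the per-axis median of the accepted positions (robust to isolated
    mismatches).  Marker 4 never appears while facing forward: its x
    reference is extrapolated from markers 2 and 3 via the alpha:beta
    spacing ratio and its y reference copies marker 3.
    """
    if not forward_frames:
        raise CalibrationError("no calibration frames supplied")
    hits: dict[int, list[tuple[int, int]]] = {1: [], 2: [], 3: []}
    for idx, frame in enumerate(forward_frames):
        h, w = frame.shape[:2]
        full = SearchRegion.full(w, h)
        for mid in (1, 2, 3):
            det = match_template_region(frame, templates[mid], full, threshold, mid, idx)
            if det is not None:
                hits[mid].append(det.pos)
    for mid in (1, 2, 3):
        if not hits[mid]:
            raise CalibrationError(
                f"marker {mid} was never detected in the calibration window"
            )
    ref: dict[int, tuple[float, float]] = {}
    for mid in (1, 2, 3):
        arr = np.asarray(hits[mid], dtype=float)
        ref[mid] = (float(np.median(arr[:, 0])), float(np.median(arr[:, 1])))
    cx = extrapolate_reference(ref[2][0], ref[3][0], layout.alpha, layout.beta)
    ref[4] = (cx, ref[3][1])
    return CalibrationResult(ref=ref, n_frames=len(forward_frames))


# ---------------------------------------------------------------------------
# Geometry


def estimate_roll(d1: MarkerDetection, d2: MarkerDetection) -> float:
    """Roll angle (deg) from two marker detections: atan of the pair's slope.

    The pair is ordered so x2 > x1; equal x is degenerate (the markers sit
    on a horizontal line in the zero-roll frame, so a vertical pair cannot
    arise from |roll| < 90).
    """
    (x1, y1), (x2, y2) = d1.pos, d2.pos
    if x2 < x1:
        (x1, y1), (x2, y2) = (x2, y2), (x1, y1)
    if x2 == x1:
        raise ValueError("degenerate geometry: markers share the same x")
    return math.degrees(math.atan((y2 - y1) / (x2 - x1)))


def derotate(x: float, y: float, theta_deg: float) -> tuple[float, float]:
    """Rotate (x, y) by ``theta_deg``: x' = x cosθ − y sinθ, y' = x sinθ + y cosθ."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return (x * c - y * s, x * s + y * c)


def pixels_to_angle(displacement_px: float, axis_resolution: int, axis_fov: float) -> float:
    """Linear pixel→degree conversion: angle = displacement x fov / resolution.

    A displacement spanning the full image maps to the full viewing angle.
    """
    if axis_resolution <= 0:
        raise ValueError("axis resolution must be positive")
    if not (0.0 < axis_fov < 180.0):
        raise ValueError("axis fov must lie in (0, 180) deg")
    return displacement_px * axis_fov / axis_resolution


def _marker_center(
    det_xy: tuple[float, float], tpl_shape: tuple[int, int]
) -> tuple[float, float]:
    th, tw = tpl_shape
    return (det_xy[0] + (tw - 1) / 2.0, det_xy[1] + (th - 1) / 2.0)


def estimate_head_pose(
    detections: Mapping[int, MarkerDetection],
    calib: CalibrationResult,
    camera: CameraModel,
    templates: Mapping[int, np.ndarray],
    frame_index: int = 0,
    prev_roll: float = 0.0,
) -> HeadPose:
    """Convert one frame's marker detections into a roll-corrected head pose.

    With two or more detections the roll is taken from the two
    highest-scoring markers; with one it is carried over from the last
    valid frame.  Detected marker centers are rotated by −roll about the
    image center to a zero-roll frame and compared against the (roll-free)
    calibration references.  Yaw is read from the marker whose corrected x
    lies nearest the image x-center, pitch from the one nearest the
    y-center (displacement grows less linear away from the optical axis, so
    the central marker is the most faithful); ties break toward the lower
    marker id.  Signs: markers shift left when the head turns right and
    shift down (image y grows downward) when the head tilts up.
    """
    if not detections:
        return HeadPose(frame=frame_index)

    dets = sorted(detections.values(), key=lambda d: d.marker_id)
    if len(dets) >= 2:
        best = sorted(dets, key=lambda d: (-d.score, d.marker_id))[:2]
        try:
            roll = estimate_roll(best[0], best[1])
        except ValueError:
            roll = prev_roll
    else:
        roll = prev_roll

    cx, cy = camera.center
    corrected: dict[int, tuple[float, float]] = {}
    for d in dets:
        mx, my = _marker_center(d.pos, templates[d.marker_id].shape[:2])
        rx, ry = derotate(mx - cx, my - cy, -roll)
        corrected[d.marker_id] = (rx + cx, ry + cy)

    def ref_center(mid: int) -> tuple[float, float]:
        th, tw = templates[mid].shape[:2]
        rx, ry = calib.ref[mid]
        return (rx + (tw - 1) / 2.0, ry + (th - 1) / 2.0)

    yaw_id = min(corrected, key=lambda m: (abs(corrected[m][0] - cx), m))
    pitch_id = min(corrected, key=lambda m: (abs(corrected[m][1] - cy), m))

    ref_yaw = ref_center(yaw_id)
    ref_pitch = ref_center(pitch_id)
    yaw = pixels_to_angle(ref_yaw[0] - corrected[yaw_id][0], camera.width, camera.fov_x)
    pitch = pixels_to_angle(
        corrected[pitch_id][1] - ref_pitch[1], camera.height, camera.fov_y
    )
    return HeadPose(
        frame=frame_index,
        yaw=yaw,
        pitch=pitch,
        roll=roll,
        valid=True,
        yaw_marker=yaw_id,
        pitch_marker=pitch_id,
    )


# ---------------------------------------------------------------------------
# Frame-sequence tracking


class MarkerTracker:
    """Stateful per-frame tracker: plans regions, detects, estimates pose."""

    def __init__(
        self,
        templates: Mapping[int, np.ndarray],
        calib: CalibrationResult,
        config: SessionConfig,
    ) -> None:
        self.templates = dict(templates)
        self.calib = calib
        self.config = config
        self._prev: dict[int, MarkerDetection] = {}
        self._prev2: dict[int, MarkerDetection] = {}
        self._last_roll = 0.0

    def step(self, frame: np.ndarray, frame_index: int) -> tuple[HeadPose, dict[int, MarkerDetection]]:
        regions = plan_search_regions(
            self._prev,
            self._prev2,
            frame.shape[:2],
            self.templates,
            extension_gain=self.config.extension_gain,
            search_margin=self.config.search_margin,
        )
        dets = detect_markers(
            frame,
            self.templates,
            regions,
            self.config.similarity_threshold,
            frame_index=frame_index,
        )
        pose = estimate_head_pose(
            dets,
            self.calib,
            self.config.camera,
            self.templates,
            frame_index=frame_index,
            prev_roll=self._last_roll,
        )
        if pose.valid:
            self._last_roll = pose.roll
        self._prev2, self._prev = self._prev, dets
        return pose, dets


def track_frames(
    frames: Sequence[np.ndarray],
    templates: Mapping[int, np.ndarray],
    calib: CalibrationResult,
    config: SessionConfig,
    times: Sequence[float] | None = None,
) -> "pd.DataFrame":
    """Track every frame and return a tidy head-pose table.

    Columns: frame, t, yaw, pitch, roll, valid plus per-marker x/y/score
    (NaN where the marker was not accepted).
    """
    import pandas as pd

    tracker = MarkerTracker(templates, calib, config)
    rows = []
    for i, frame in enumerate(frames):
        pose, dets = tracker.step(frame, i)
        row: dict[str, float] = {
            "frame": i,
            "t": times[i] if times is not None else float(i),
            "yaw": pose.yaw,
            "pitch": pose.pitch,
            "roll": pose.roll,
            "valid": pose.valid,
        }
        for mid in MARKER_ORDER:
            d = dets.get(mid)
            row[f"m{mid}_x"] = d.x if d else math.nan
            row[f"m{mid}_y"] = d.y if d else math.nan
            row[f"m{mid}_score"] = d.score if d else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
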