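"""Ground-truthed synthetic sessions: rendered marker frames + eye streams.

The forward model mirrors the estimator's own geometry, deliberately: a
marker anchored at pixel ``a`` while facing forward is drawn, for a head
pose (yaw, pitch, roll), at

    p = R(roll) @ (a + [-yaw/dpx, +pitch/dpy] - c) + c

where ``c`` is the image center, ``dpx``/``dpy`` the camera's
degrees-per-pixel ratios and R an in-plane rotation — head turning right
pans the camera right, so markers translate left in the image; tilting up
translates them down (image y grows downward); rolling tilts the whole
constellation about the optical axis.  Markers leaving the frame are
clipped, which reproduces the real layout's key property: the outermost
marker is invisible while facing forward and only enters the view on large
head turns.

Rendering is linear (no perspective, no lens distortion) and the glyphs are
pasted at integer pixel positions, so template matching is near-exact and
the rendered frames function as a known-truth oracle for the whole
head-pose → fusion → range pipeline.

Everything is driven by a single integer seed; identical seeds produce
bit-identical frames and CSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io_session import (
    CameraModel,
    EyeSample,
    MarkerLayout,
    SessionConfig,
    save_config,
    write_eye_csv,
)

__all__ = [
    "PoseTrajectory",
    "SceneSpec",
    "default_scene",
    "make_templates",
    "render_frame",
    "simulate_gaze_stream",
    "simulate_session",
    "SimulatedSession",
]

BG_LEVEL = 170.0  # dashboard-gray background
INK_LEVEL = 20.0  # printed marker ink
PATCH_LEVEL = 250.0  # white marker card behind the glyph


@dataclass(frozen=True)
class PoseTrajectory:
    """Per-frame ground-truth head angles (deg) at a fixed frame rate."""

    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        n = len(self.yaw)
        if not (len(self.pitch) == len(self.roll) == n):
            raise ValueError("trajectory components differ in length")
        for name in ("yaw", "pitch", "roll"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} trajectory contains non-finite values")
        if np.any(np.abs(self.roll) >= 45.0):
            raise ValueError("|roll| must stay below 45 deg by construction")

    def __len__(self) -> int:
        return len(self.yaw)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate

    @staticmethod
    def sweep(
        n_frames: int,
        yaw_amp: float = 30.0,
        pitch_amp: float = 6.0,
        roll_amp: float = 5.0,
        frame_rate: float = 30.0,
    ) -> "PoseTrajectory":
        """Smooth sinusoidal scan: a slow wide yaw sweep with mild pitch/roll."""
        t = np.arange(n_frames) / frame_rate
        return PoseTrajectory(
            yaw=yaw_amp * np.sin(2 * math.pi * 0.05 * t),
            pitch=pitch_amp * np.sin(2 * math.pi * 0.08 * t + 1.0),
            roll=roll_amp * np.sin(2 * math.pi * 0.06 * t + 2.0),
            frame_rate=frame_rate,
        )


def _glyph_mask(kind: str, size: int) -> np.ndarray:
    """Boolean mask of a filled marker glyph on a size x size patch."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = size * 0.38
    if kind == "circle":
        return (xx - c) ** 2 + (yy - c) ** 2 <= r**2
    if kind in ("triangle_up", "triangle_down"):
        # barycentric test against an equilateral-ish triangle
        if kind == "triangle_up":
            verts = [(c, c - r), (c - r, c + r * 0.8), (c + r, c + r * 0.8)]
        else:
            verts = [(c, c + r), (c - r, c - r * 0.8), (c + r, c - r * 0.8)]
        gx = sum(v[0] for v in verts) / 3.0
        gy = sum(v[1] for v in verts) / 3.0
        mask = np.ones((size, size), dtype=bool)
        for i in range(3):
            (x1, y1), (x2, y2) = verts[i], verts[(i + 1) % 3]
            cross = (x2 - x1) * (yy - y1) - (y2 - y1) * (xx - x1)
            inside_sign = (x2 - x1) * (gy - y1) - (y2 - y1) * (gx - x1)
            mask &= cross * inside_sign >= 0
        return mask
    if kind == "star":
        ang = np.arctan2(yy - c, xx - c)
        rad = np.hypot(yy - c, xx - c)
        # five-pointed star: radius modulated between inner and outer radius
        k = 5
        outer, inner = r, r * 0.45
        phase = (ang + math.pi / 2) * k / (2 * math.pi)
        frac = np.abs((phase % 1.0) - 0.5) * 2.0  # 0 at point tips, 1 between
        bound = outer + (inner - outer) * frac
        return rad <= bound
    raise ValueError(f"unknown glyph kind {kind!r}")


GLYPHS = {1: "triangle_up", 2: "circle", 3: "triangle_down", 4: "star"}


def make_templates(size: int = 21) -> dict[int, np.ndarray]:
    """The four marker patches: dark glyph on a white card, float grayscale."""
    out = {}
    for mid, kind in GLYPHS.items():
        patch = np.full((size, size), PATCH_LEVEL, dtype=np.float64)
        patch[_glyph_mask(kind, size)] = INK_LEVEL
        out[mid] = patch
    return out


@dataclass(frozen=True)
class SceneSpec:
    """Camera, forward-facing marker anchors and background model.

    Anchors are template top-left positions at pose (0, 0, 0), ordered
    left→right by marker id; the outermost marker's anchor lies beyond the
    right frame edge so it is invisible while facing forward.  The anchor
    spacing implies the alpha:beta layout ratio
    (x2 − x3) : (x3 − x4) = alpha : beta used for reference extrapolation.
    """

    camera: CameraModel
    anchors: Mapping[int, tuple[float, float]]
    template_size: int = 21
    background: str = "uniform"  # "uniform" | "noise"
    noise_sigma: float = 12.0

    def __post_init__(self) -> None:
        xs = [self.anchors[m][0] for m in (1, 2, 3, 4)]
        increasing = all(a < b for a, b in zip(xs, xs[1:]))
        decreasing = all(a > b for a, b in zip(xs, xs[1:]))
        if not (increasing or decreasing):
            raise ValueError("marker anchors must be ordered monotonically in x")

    @property
    def alpha_beta(self) -> tuple[float, float]:
        x2, x3, x4 = (self.anchors[m][0] for m in (2, 3, 4))
        return (abs(x2 - x3), abs(x3 - x4))


def default_scene(
    width: int = 640,
    height: int = 480,
    fov_x: float = 60.0,
    fov_y: float = 45.0,
    background: str = "uniform",
) -> SceneSpec:
    """Default windshield layout.

    Markers 1–3 are visible facing forward; marker 4 sits 740 px from the
    left edge, past the 640 px frame, and only enters the view when the
    head turns right by more than ~10 deg — while markers 1 and 2 have by
    then left the frame on the other side (the two ends of the
    constellation are farther apart than one field of view).
    """
    camera = CameraModel(width=width, height=height, fov_x=fov_x, fov_y=fov_y)
    y = (height - 1) / 2.0 - 10  # template top-left => glyph centers near mid-height
    anchors = {1: (80.0, y), 2: (300.0, y), 3: (520.0, y), 4: (740.0, y)}
    return SceneSpec(camera=camera, anchors=anchors, background=background)


def _paste(frame: np.ndarray, patch: np.ndarray, x: int, y: int) -> None:
    h, w = frame.shape
    ph, pw = patch.shape
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + pw, w), min(y + ph, h)
    if x0 >= x1 or y0 >= y1:
        return
    frame[y0:y1, x0:x1] = patch[y0 - y : y1 - y, x0 - x : x1 - x]


def render_frame(
    pose: tuple[float, float, float],
    spec: SceneSpec,
    templates: Mapping[int, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one view-camera frame for a (yaw, pitch, roll) head pose.

    Marker patches are rotated by the roll angle (as the camera would see
    them) and pasted at the nearest integer pixel; positions off the frame
    are clipped away.
    """
    yaw, pitch, roll = pose
    if not all(map(math.isfinite, (yaw, pitch, roll))):
        raise ValueError("pose angles must be finite")
    cam = spec.camera
    if templates is None:
        templates = make_templates(spec.template_size)
    if spec.background == "noise":
        if rng is None:
            rng = np.random.default_rng(0)
        frame = rng.normal(BG_LEVEL, spec.noise_sigma, (cam.height, cam.width))
        frame = np.clip(frame, 0, 255)
    else:
        frame = np.full((cam.height, cam.width), BG_LEVEL, dtype=np.float64)

    cx, cy = cam.center
    th = math.radians(roll)
    cth, sth = math.cos(th), math.sin(th)
    for mid, (ax, ay) in spec.anchors.items():
        patch = templates[mid]
        ph, pw = patch.shape
        # glyph center, displaced by the head pose then rolled about the image center
        gx = ax + (pw - 1) / 2.0 - yaw / cam.deg_per_px_x
        gy = ay + (ph - 1) / 2.0 + pitch / cam.deg_per_px_y
        rx = cth * (gx - cx) - sth * (gy - cy) + cx
        ry = sth * (gx - cx) + cth * (gy - cy) + cy
        if abs(roll) > 1e-9:
            drawn = ndimage.rotate(
                patch, -math.degrees(th), reshape=True, order=1,
                mode="constant", cval=BG_LEVEL,
            )
        else:
            drawn = patch
        dh, dw = drawn.shape
        _paste(frame, drawn, int(round(rx - (dw - 1) / 2.0)), int(round(ry - (dh - 1) / 2.0)))
    return frame


def marker_positions(
    pose: tuple[float, float, float], spec: SceneSpec
) -> dict[int, tuple[float, float]]:
    """Ground-truth template top-left anchors for a pose (before clipping)."""
    yaw, pitch, roll = pose
    cam = spec.camera
    cx, cy = cam.center
    th = math.radians(roll)
    cth, sth = math.cos(th), math.sin(th)
    size = spec.template_size
    out = {}
    for mid, (ax, ay) in spec.anchors.items():
        gx = ax + (size - 1) / 2.0 - yaw / cam.deg_per_px_x
        gy = ay + (size - 1) / 2.0 + pitch / cam.deg_per_px_y
        rx = cth * (gx - cx) - sth * (gy - cy) + cx
        ry = sth * (gx - cx) + cth * (gy - cy) + cy
        out[mid] = (rx - (size - 1) / 2.0, ry - (size - 1) / 2.0)
    return out


# ---------------------------------------------------------------------------
# Gaze / session simulation


def simulate_gaze_stream(
    trajectory: PoseTrajectory,
    mu: tuple[float, float] = (0.0, 0.0),
    sigma: tuple[float, float] = (15.0, 8.0),
    saccade_rate: float = 2.0,
    seed: int = 0,
) -> tuple[list[EyeSample], np.ndarray]:
    """Eye-angle samples consistent with a target gaze distribution.

    World-referenced gaze targets are drawn from a 2-D Gaussian
    N(mu, diag(sigma^2)); targets are re-drawn at Poisson saccade times
    (``saccade_rate`` per second) and held between saccades, emulating a
    fixate-and-jump scan pattern.  The eye angle is then the target minus
    the ground-truth head angle, so fusing the simulated eye stream with
    the true head trajectory reproduces the sampled gaze exactly.

    Returns (eye_samples, gaze_targets) with one row per frame.
    """
    sx, sy = sigma
    if sx < 0 or sy < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(trajectory)
    times = trajectory.times
    gaze = np.empty((n, 2))
    current = np.array([rng.normal(mu[0], sx), rng.normal(mu[1], sy)])
    p_saccade = min(saccade_rate / trajectory.frame_rate, 1.0)
    for i in range(n):
        if i > 0 and rng.random() < p_saccade:
            current = np.array([rng.normal(mu[0], sx), rng.normal(mu[1], sy)])
        gaze[i] = current
    eye = [
        EyeSample(
            t=float(times[i]),
            x_eye=float(np.clip(gaze[i, 0] - trajectory.yaw[i], -180, 180)),
            y_eye=float(np.clip(gaze[i, 1] - trajectory.pitch[i], -180, 180)),
        )
        for i in range(n)
    ]
    return eye, gaze


@dataclass(frozen=True)
class SimulatedSession:
    """In-memory bundle of a fully ground-truthed session."""

    spec: SceneSpec
    config: SessionConfig
    templates: dict[int, np.ndarray]
    calibration_frames: list[np.ndarray]
    frames: list[np.ndarray]
    trajectory: PoseTrajectory
    eye_samples: list[EyeSample]
    gaze_truth: np.ndarray


def session_config_for(spec: SceneSpec, template_dir: str = "templates", **overrides) -> SessionConfig:
    """SessionConfig matching a scene spec (templates under ``template_dir``)."""
    alpha, beta = spec.alpha_beta
    layout = MarkerLayout(
        template_paths={m: f"{template_dir}/marker{m}.png" for m in (1, 2, 3, 4)},
        alpha=alpha,
        beta=beta,
    )
    return SessionConfig(camera=spec.camera, layout=layout, **overrides)


def simulate_session(
    trajectory: PoseTrajectory,
    spec: SceneSpec | None = None,
    mu: tuple[float, float] = (0.0, 0.0),
    sigma: tuple[float, float] = (15.0, 8.0),
    saccade_rate: float = 2.0,
    n_calibration_frames: int = 5,
    seed: int = 0,
    render: bool = True,
) -> SimulatedSession:
    """Simulate a complete recording: calibration frames, driving frames,
    eye CSV stream and ground truth, all reproducible from ``seed``.

    ``render=False`` skips frame rendering (for statistics-only studies the
    ground-truth trajectory stands in for the tracked head pose).
    """
    if spec is None:
        spec = default_scene()
    templates = make_templates(spec.template_size)
    rng = np.random.default_rng(seed + 1)
    calib = (
        [render_frame((0.0, 0.0, 0.0), spec, templates, rng) for _ in range(n_calibration_frames)]
        if render
        else []
    )
    frames = (
        [
            render_frame(
                (trajectory.yaw[i], trajectory.pitch[i], trajectory.roll[i]),
                spec,
                templates,
                rng,
            )
            for i in range(len(trajectory))
        ]
        if render
        else []
    )
    eye, gaze = simulate_gaze_stream(trajectory, mu, sigma, saccade_rate, seed)
    return SimulatedSession(
        spec=spec,
        config=session_config_for(spec),
        templates=templates,
        calibration_frames=calib,
        frames=frames,
        trajectory=trajectory,
        eye_samples=eye,
        gaze_truth=gaze,
    )


def write_session(session: SimulatedSession, out_dir: str | Path) -> dict[str, object]:
    """Write a simulated session to disk in the formats the pipeline reads.

    Layout: ``templates/marker{1..4}.png``, ``calib/frame_%04d.png``,
    ``frames/frame_%04d.png``, ``eye.csv``, ``truth.csv``, ``config.yaml``.
    Returns a manifest-style dict of what was written.
    """
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    (out / "templates").mkdir(parents=True, exist_ok=True)
    (out / "calib").mkdir(exist_ok=True)
    (out / "frames").mkdir(exist_ok=True)
    for mid, patch in session.templates.items():
        iio.imwrite(out / "templates" / f"marker{mid}.png", patch.astype(np.uint8))
    for i, f in enumerate(session.calibration_frames):
        iio.imwrite(out / "calib" / f"frame_{i:04d}.png", f.astype(np.uint8))
    for i, f in enumerate(session.frames):
        iio.imwrite(out / "frames" / f"frame_{i:04d}.png", f.astype(np.uint8))
    write_eye_csv(out / "eye.csv", session.eye_samples)
    pd.DataFrame(
        {
            "frame": np.arange(len(session.trajectory)),
            "t": session.trajectory.times,
            "yaw": session.trajectory.yaw,
            "pitch": session.trajectory.pitch,
            "roll": session.trajectory.roll,
            "x_gaze_true": session.gaze_truth[:, 0],
            "y_gaze_true": session.gaze_truth[:, 1],
        }
    ).to_csv(out / "truth.csv", index=False)
    save_config(out / "config.yaml", session.config)
    return {
        "n_frames": len(session.frames),
        "n_calibration_frames": len(session.calibration_frames),
        "n_eye_samples": len(session.eye_samples),
        "config": str(out / "config.yaml"),
    }
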