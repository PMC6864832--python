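"""Session I/O: eye/head/gaze time series, marker templates, and configuration.

All other modules consume the in-memory containers defined here (plain
dataclasses plus pandas DataFrames) and never touch files directly, so the
on-disk formats — CSV for time series, PNG/JPEG for images, YAML or JSON for
configuration — are confined to this module.

Conventions fixed project-wide:

* angles in degrees; horizontal positive = subject's right, vertical
  positive = up;
* pixel coordinates are 0-based with the origin at the image top-left,
  x rightward, y downward; rectangles are half-open;
* CSV files are comma-separated UTF-8 with one header row, time in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EyeSample",
    "CameraModel",
    "MarkerLayout",
    "ZoneRule",
    "SessionConfig",
    "SchemaError",
    "read_eye_csv",
    "write_eye_csv",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_head_csv",
    "write_head_csv",
    "load_templates",
    "load_config",
    "save_config",
    "read_frame",
    "read_frames",
    "DEFAULT_ZONE_RULES",
]

#: the nine gaze-area labels used for zone classification
ZONE_LABELS = (
    "front",
    "rearview mirror",
    "meter",
    "right mirror",
    "right",
    "right back",
    "left mirror",
    "left",
    "left back",
)

MARKER_IDS = (1, 2, 3, 4)


class SchemaError(ValueError):
    """A file or mapping does not conform to the expected schema."""


@dataclass(frozen=True)
class EyeSample:
    """One eye-in-head angle sample from the pupil tracker.

    The tracker reports eye rotation relative to the head; both components
    are bounded by the device range of +/-180 degrees.
    """

    t: float
    x_eye: float
    y_eye: float

    def __post_init__(self) -> None:
        for name in ("x_eye", "y_eye"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if abs(v) > 180.0:
                raise ValueError(f"|{name}| must be <= 180 deg, got {v!r}")


@dataclass(frozen=True)
class CameraModel:
    """Pinhole-free linear view-camera model: resolution plus viewing angle.

    The head-angle conversion is linear: one pixel of marker displacement
    corresponds to ``fov/resolution`` degrees along each axis.
    """

    width: int
    height: int
    fov_x: float
    fov_y: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("camera resolution must be positive")
        if not (0.0 < self.fov_x < 180.0 and 0.0 < self.fov_y < 180.0):
            raise ValueError("viewing angles must lie in (0, 180) deg")

    @property
    def deg_per_px_x(self) -> float:
        return self.fov_x / self.width

    @property
    def deg_per_px_y(self) -> float:
        return self.fov_y / self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)


@dataclass(frozen=True)
class MarkerLayout:
    """The four windshield markers: template paths and the alpha:beta spacing ratio.

    ``alpha``/``beta`` encode the inter-marker distance ratio used to
    extrapolate the reference position of the outermost marker, which never
    appears in the view frame while the driver faces forward:
    ``(A - B) / (B - C) = alpha / beta`` where A, B, C are the x positions
    of markers 2, 3 and 4.
    """

    template_paths: Mapping[int, str]
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        ids = tuple(sorted(int(k) for k in self.template_paths))
        if ids != MARKER_IDS:
            raise SchemaError(
                f"marker layout must define exactly markers 1..4, got {ids}"
            )
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass(frozen=True)
class ZoneRule:
    """One gaze-area rule: a (possibly unbounded) closed rectangle in gaze angles."""

    label: str
    x_min: float = -math.inf
    x_max: float = math.inf
    y_min: float = -math.inf
    y_max: float = math.inf

    def __post_init__(self) -> None:
        if self.label not in ZONE_LABELS:
            raise SchemaError(
                f"zone label {self.label!r} not in the nine-area vocabulary"
            )
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("zone rule interval is empty")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


#: Default gaze-area partition (degrees).  The nine labels are fixed by the
#: judgment vocabulary; the angular boundaries are a configurable convention:
#: "front" is the central +/-20 deg box, side zones start beyond +/-20 deg in
#: x, "back" zones beyond +/-90 deg, the meter cluster is below the front box
#: and the mirrors are rectangles at typical glance positions.  Rules are
#: evaluated in order and the first match wins, so boundary points resolve to
#: the more central zone.
DEFAULT_ZONE_RULES: tuple[ZoneRule, ...] = (
    ZoneRule("front", -20, 20, -20, 20),
    ZoneRule("meter", -20, 20, -math.inf, -20),
    ZoneRule("rearview mirror", -20, 20, 20, math.inf),
    ZoneRule("left mirror", -55, -25, -30, -10),
    ZoneRule("right mirror", 25, 55, -30, -10),
    ZoneRule("left back", -math.inf, -90),
    ZoneRule("right back", 90, math.inf),
    ZoneRule("left", -math.inf, -20),
    ZoneRule("right", 20, math.inf),
)


@dataclass(frozen=True)
class SessionConfig:
    """Everything a processing run needs besides the data streams themselves."""

    camera: CameraModel
    layout: MarkerLayout
    zone_rules: tuple[ZoneRule, ...] = DEFAULT_ZONE_RULES
    frame_rate: float = 30.0
    similarity_threshold: float = 0.70
    bin_width: float = 5.0
    range_threshold: float = 0.05
    extension_gain: float = 1.5
    search_margin: float = 2.0  # search window half-size, in template diagonals

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold must lie in [0, 1]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not (0.0 < self.range_threshold < 1.0):
            raise ValueError("range_threshold must lie in (0, 1)")
        if self.extension_gain < 0:
            raise ValueError("extension_gain must be nonnegative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


# ---------------------------------------------------------------------------
# CSV time series


def _read_csv_strict(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {df[col][row]!r} in column "
                f"{col!r} at data row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SchemaError(f"{path}: empty cell in column {col!r} at data row {row}")
        df[col] = coerced.astype(float)
    return df


def read_eye_csv(path: str | Path) -> list[EyeSample]:
    """Read an eye-angle time series (columns ``t, x_eye, y_eye``).

    Rows are returned in file order; time must be nondecreasing.
    """
    df = _read_csv_strict(path, ("t", "x_eye", "y_eye"))
    t = df["t"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise SchemaError(f"{path}: time column is not nondecreasing")
    return [
        EyeSample(t=row.t, x_eye=row.x_eye, y_eye=row.y_eye)
        for row in df.itertuples(index=False)
    ]


def write_eye_csv(path: str | Path, samples: Sequence[EyeSample]) -> None:
    df = pd.DataFrame(
        {
            "t": [s.t for s in samples],
            "x_eye": [s.x_eye for s in samples],
            "y_eye": [s.y_eye for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_gaze_csv(path: str | Path) -> pd.DataFrame:
    """Read a fused-gaze series (``t, x_gaze, y_gaze, zone, valid``)."""
    df = _read_csv_strict(path, ("t", "x_gaze", "y_gaze"))
    if "zone" not in df.columns or "valid" not in df.columns:
        raise SchemaError(f"{path}: missing required column(s) ['zone', 'valid']")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_gaze_csv(path: str | Path, gaze: pd.DataFrame) -> None:
    cols = ["t", "x_gaze", "y_gaze", "zone", "valid"]
    missing = [c for c in cols if c not in gaze.columns]
    if missing:
        raise SchemaError(f"gaze frame missing column(s) {missing}")
    gaze[cols].to_csv(path, index=False)


HEAD_COLUMNS = ("frame", "t", "yaw", "pitch", "roll")


def read_head_csv(path: str | Path) -> pd.DataFrame:
    """Read a head-pose series (``frame, t, yaw, pitch, roll, valid`` + detections)."""
    df = _read_csv_strict(path, HEAD_COLUMNS)
    if "valid" not in df.columns:
        raise SchemaError(f"{path}: missing required column(s) ['valid']")
    df["frame"] = df["frame"].astype(int)
    df["valid"] = df["valid"].astype(bool)
    return df


def write_head_csv(path: str | Path, head: pd.DataFrame) -> None:
    missing = [c for c in (*HEAD_COLUMNS, "valid") if c not in head.columns]
    if missing:
        raise SchemaError(f"head-pose frame missing column(s) {missing}")
    head.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Images


def _to_gray(img: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, C]) uint8/float image to float64 grayscale in [0, 255]."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    arr = arr.astype(np.float64)
    if arr.size and arr.max() <= 1.0:
        arr = arr * 255.0
    return arr


def read_frame(path: str | Path) -> np.ndarray:
    """Read one view-camera frame as float64 grayscale."""
    return _to_gray(iio.imread(path))


def read_frames(paths: Sequence[str | Path]) -> list[np.ndarray]:
    return [read_frame(p) for p in paths]


def load_templates(
    config: SessionConfig, base_dir: str | Path | None = None
) -> dict[int, np.ndarray]:
    """Load the four marker template patches as grayscale arrays keyed 1..4.

    Every patch must be strictly smaller than the camera frame along both
    axes, otherwise matching is impossible.
    """
    base = Path(base_dir) if base_dir is not None else None
    out: dict[int, np.ndarray] = {}
    for mid in MARKER_IDS:
        p = Path(config.layout.template_paths[mid])
        if base is not None and not p.is_absolute():
            p = base / p
        if not p.exists():
            raise SchemaError(f"template for marker {mid} not found: {p}")
        patch = _to_gray(iio.imread(p))
        if patch.size == 0:
            raise SchemaError(f"template for marker {mid} is empty: {p}")
        if patch.shape[0] >= config.camera.height or patch.shape[1] >= config.camera.width:
            raise SchemaError(
                f"template for marker {mid} ({patch.shape}) is not smaller "
                f"than the frame ({config.camera.height}, {config.camera.width})"
            )
        out[mid] = patch
    return out


# ---------------------------------------------------------------------------
# Configuration (YAML, with JSON accepted — JSON is a YAML subset)


def _require(mapping: Mapping, key: str, ctx: str):
    if key not in mapping:
        raise SchemaError(f"config: missing required field {ctx}.{key}")
    return mapping[key]


def config_from_dict(d: Mapping) -> SessionConfig:
    cam = _require(d, "camera", "")
    camera = CameraModel(
        width=int(_require(cam, "width", "camera")),
        height=int(_require(cam, "height", "camera")),
        fov_x=float(_require(cam, "fov_x", "camera")),
        fov_y=float(_require(cam, "fov_y", "camera")),
    )
    lay = _require(d, "markers", "")
    layout = MarkerLayout(
        template_paths={int(k): str(v) for k, v in _require(lay, "templates", "markers").items()},
        alpha=float(lay.get("alpha", 1.0)),
        beta=float(lay.get("beta", 1.0)),
    )
    if "zones" in d:
        rules = tuple(
            ZoneRule(
                label=_require(z, "label", "zones[]"),
                x_min=float(z.get("x_min", -math.inf)),
                x_max=float(z.get("x_max", math.inf)),
                y_min=float(z.get("y_min", -math.inf)),
                y_max=float(z.get("y_max", math.inf)),
            )
            for z in d["zones"]
        )
    else:
        rules = DEFAULT_ZONE_RULES
    kwargs = {}
    for key in ("frame_rate", "similarity_threshold", "bin_width", "range_threshold", "extension_gain", "search_margin"):
        if key in d:
            kwargs[key] = float(d[key])
    return SessionConfig(camera=camera, layout=layout, zone_rules=rules, **kwargs)


def config_to_dict(cfg: SessionConfig) -> dict:
    def _num(v: float):
        return v if math.isfinite(v) else (".inf" if v > 0 else "-.inf")

    return {
        "camera": {
            "width": cfg.camera.width,
            "height": cfg.camera.height,
            "fov_x": cfg.camera.fov_x,
            "fov_y": cfg.camera.fov_y,
        },
        "markers": {
            "templates": {k: v for k, v in cfg.layout.template_paths.items()},
            "alpha": cfg.layout.alpha,
            "beta": cfg.layout.beta,
        },
        "zones": [
            {
                "label": z.label,
                "x_min": _num(z.x_min),
                "x_max": _num(z.x_max),
                "y_min": _num(z.y_min),
                "y_max": _num(z.y_max),
            }
            for z in cfg.zone_rules
        ],
        "frame_rate": cfg.frame_rate,
        "similarity_threshold": cfg.similarity_threshold,
        "bin_width": cfg.bin_width,
        "range_threshold": cfg.range_threshold,
        "extension_gain": cfg.extension_gain,
        "search_margin": cfg.search_margin,
    }


def _parse_inf(v):
    if isinstance(v, str):
        if v in (".inf", "inf"):
            return math.inf
        if v in ("-.inf", "-inf"):
            return -math.inf
    return v


def load_config(path: str | Path) -> SessionConfig:
    """Load a session config from YAML or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path}: config root must be a mapping")

    def walk(obj):
        if isinstance(obj, dict):
            return {k: walk(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [walk(v) for v in obj]
        return _parse_inf(obj)

    return config_from_dict(walk(raw))


def save_config(path: str | Path, cfg: SessionConfig) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
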