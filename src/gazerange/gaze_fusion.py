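"""Eye + head fusion into the gaze signal, and gaze-area classification.

Eye and head rotations combine additively when a person redirects their
gaze (eye–head coordinated movement), so the gaze direction in vehicle
coordinates is simply

    E(t) = f1(t) + f2(t)

componentwise, where f1 is the eye-in-head angle reported by the pupil
tracker and f2 the head angle recovered from the marker system.  Each fused
sample is then assigned to one of nine gaze areas (front, rearview mirror,
meter, right mirror, right, right back, left mirror, left, left back) by a
configurable rectangle partition of the gaze plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_session import DEFAULT_ZONE_RULES, EyeSample, ZoneRule
from .head_pose import HeadPose

__all__ = [
    "GazeSample",
    "AlignmentError",
    "fuse",
    "fuse_series",
    "classify_zone",
    "zone_family",
    "agreement_rate",
]


class AlignmentError(ValueError):
    """Eye and head streams could not be aligned in time."""


@dataclass(frozen=True)
class GazeSample:
    """One fused gaze sample; invalid when the head pose was invalid."""

    t: float
    x_gaze: float
    y_gaze: float
    zone: str = "unknown"
    valid: bool = True


def fuse(eye: EyeSample, head: HeadPose, time_tolerance: float | None = None) -> GazeSample:
    """Fuse one eye sample with one head pose: componentwise addition.

    An invalid head pose yields an invalid gaze sample (NaN angles).  When
    ``time_tolerance`` is given, the head pose's frame index is interpreted
    as its timestamp and must lie within the tolerance of the eye sample's
    time.
    """
    if time_tolerance is not None and abs(eye.t - head.frame) > time_tolerance:
        raise AlignmentError(
            f"eye sample at t={eye.t} vs head frame {head.frame}: "
            f"misaligned beyond {time_tolerance}"
        )
    if not head.valid:
        return GazeSample(t=eye.t, x_gaze=math.nan, y_gaze=math.nan, valid=False)
    return GazeSample(
        t=eye.t,
        x_gaze=eye.x_eye + head.yaw,
        y_gaze=eye.y_eye + head.pitch,
        valid=True,
    )


def classify_zone(
    x_gaze: float,
    y_gaze: float,
    zone_rules: Sequence[ZoneRule] = DEFAULT_ZONE_RULES,
    valid: bool = True,
) -> str:
    """Deterministic gaze-area label for one gaze direction.

    Rules are evaluated in order and the first containing rectangle wins,
    which resolves boundary points to the more central zone.  Invalid or
    non-finite samples are labeled ``"unknown"``.
    """
    if not valid or not (math.isfinite(x_gaze) and math.isfinite(y_gaze)):
        return "unknown"
    for rule in zone_rules:
        if rule.contains(x_gaze, y_gaze):
            return rule.label
    return "unknown"


def fuse_series(
    eye_samples: Sequence[EyeSample],
    head: pd.DataFrame,
    zone_rules: Sequence[ZoneRule] = DEFAULT_ZONE_RULES,
    max_dt: float | None = None,
) -> pd.DataFrame:
    """Align an eye time series with a head-pose table and fuse sample-wise.

    Each eye sample is matched to the head row with the nearest time; by
    default the match must fall within half the median head-frame interval
    (nearest-neighbor alignment), otherwise the sample is dropped from the
    fused output.  Raises :class:`AlignmentError` when no samples overlap.

    Returns a DataFrame with columns t, x_gaze, y_gaze, zone, valid.
    """
    if not len(eye_samples) or head.empty:
        raise AlignmentError("empty eye or head stream")
    ht = head["t"].to_numpy(dtype=float)
    if max_dt is None:
        max_dt = (float(np.median(np.diff(ht))) / 2.0) if len(ht) > 1 else math.inf

    et = np.asarray([s.t for s in eye_samples], dtype=float)
    idx = np.searchsorted(ht, et)
    idx = np.clip(idx, 0, len(ht) - 1)
    left = np.clip(idx - 1, 0, len(ht) - 1)
    use_left = np.abs(ht[left] - et) <= np.abs(ht[idx] - et)
    nearest = np.where(use_left, left, idx)
    dt = np.abs(ht[nearest] - et)
    keep = dt <= max_dt
    if not keep.any():
        raise AlignmentError("eye and head streams do not overlap in time")

    yaw = head["yaw"].to_numpy(dtype=float)[nearest]
    pitch = head["pitch"].to_numpy(dtype=float)[nearest]
    hvalid = head["valid"].to_numpy(dtype=bool)[nearest]

    rows = []
    for i, s in enumerate(eye_samples):
        if not keep[i]:
            continue
        if hvalid[i]:
            xg, yg = s.x_eye + yaw[i], s.y_eye + pitch[i]
            zone = classify_zone(xg, yg, zone_rules)
            rows.append((s.t, xg, yg, zone, True))
        else:
            rows.append((s.t, math.nan, math.nan, "unknown", False))
    return pd.DataFrame(rows, columns=["t", "x_gaze", "y_gaze", "zone", "valid"])


# ---------------------------------------------------------------------------
# Judgment-agreement reporting

#: maps each fine zone label onto the coarse judgment family used when a
#: human reviewer logs only left/right/front
_FAMILY = {
    "front": "front",
    "meter": "front",
    "rearview mirror": "front",
    "left": "left",
    "left mirror": "left",
    "left back": "left",
    "right": "right",
    "right mirror": "right",
    "right back": "right",
    "unknown": "unknown",
}

#: situation words treated as equivalent when scoring agreement
_EQUIVALENT = {"straight": "front"}


def zone_family(label: str) -> str:
    """Coarse left/right/front family of a zone label."""
    return _FAMILY.get(label.strip().lower(), "unknown")


def agreement_rate(situations: Sequence[str], flags: Sequence[str]) -> tuple[int, int, float]:
    """Fraction of judged samples whose flag matches the logged situation.

    ``situations`` are the ground-truth words logged by a reviewer (e.g.
    Left / Right / Straight / Front; "straight" counts as "front");
    ``flags`` are the system's judgment labels, compared family-wise.
    Returns (n_matches, n_total, rate_percent).
    """
    if len(situations) != len(flags):
        raise ValueError("situations and flags must have equal length")
    n = len(situations)
    matches = 0
    for s, f in zip(situations, flags):
        s_norm = s.strip().lower()
        s_norm = _EQUIVALENT.get(s_norm, s_norm)
        if zone_family(s_norm) == zone_family(f) and zone_family(f) != "unknown":
            matches += 1
        elif s_norm == f.strip().lower():
            matches += 1
    return matches, n, 100.0 * matches / n if n else math.nan
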