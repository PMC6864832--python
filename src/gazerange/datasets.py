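"""Bundled reference data from the original field evaluation of the method.

Three small tables ship with the package:

* the 30-point outdoor judgment sample — eye, head and fused gaze angles
  (one decimal, degrees) logged around turns and straight stretches of a
  driving-school course, with the reviewer's situation word and the
  system's judgment flag; two points are marked as judgment errors (one
  template-matching failure, one eye-measurement failure) and their printed
  gaze values are NOT consistent with eye + head addition, so they are
  excluded from exact-sum checks;
* the indoor head-angle accuracy run — per-target absolute error of the
  estimated head angle for gaze targets placed every 10 deg from 10 to
  60 deg;
* the per-marker template-matching recognition rates from the same run.

These serve as fixed ground truth for regression tests and for the summary
helpers that aggregate them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_outdoor_eval",
    "indoor_angle_errors",
    "marker_recognition_rates",
    "indoor_error_summary",
    "recognition_summary",
]

#: indoor accuracy run: target angle (deg) -> absolute head-angle error (deg)
INDOOR_ANGLE_ERRORS = {
    10: 1.9,
    20: 4.3,
    30: 6.1,
    40: 7.3,
    50: 4.1,
    60: 0.9,
}

#: per-marker template-matching recognition rate (percent), indoor run
MARKER_RECOGNITION_RATES = {
    "marker1_triangle_up": 93.9,
    "marker2_circle": 87.5,
    "marker3_triangle_down": 91.4,
    "marker4_star": 88.2,
}


def load_outdoor_eval() -> pd.DataFrame:
    """The 30-point outdoor judgment table.

    Columns: number, situation, time, x_eye, y_eye, x_head, y_head,
    x_gaze, y_gaze, flag, judgment_error (1 for the two logged failures).
    """
    with resources.files("gazerange.data").joinpath("outdoor_eval.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    df["judgment_error"] = df["judgment_error"].astype(bool)
    return df


def indoor_angle_errors() -> pd.Series:
    """Per-target absolute head-angle errors (deg), indexed by target angle."""
    s = pd.Series(INDOOR_ANGLE_ERRORS, name="error_deg")
    s.index.name = "target_deg"
    return s.astype(float)


def marker_recognition_rates() -> pd.Series:
    """Per-marker recognition rates (percent)."""
    return pd.Series(MARKER_RECOGNITION_RATES, name="recognition_pct").astype(float)


def indoor_error_summary() -> dict[str, float]:
    """Aggregate of the indoor accuracy run: mean/max per-target error (deg)."""
    s = indoor_angle_errors()
    return {"mean_error_deg": float(s.mean()), "max_error_deg": float(s.max()), "n_targets": int(s.size)}


def recognition_summary() -> dict[str, float]:
    """Aggregate of the per-marker recognition rates (percent)."""
    s = marker_recognition_rates()
    return {"mean_recognition_pct": float(s.mean()), "min_recognition_pct": float(s.min()), "n_markers": int(s.size)}
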