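"""Torque–angle curve analysis for non-destructive torsion tests.

Extracts the five biomechanical outcome variables from a torsion test of
an operated (or contralateral) tibia: apparent stiffness (Nm/degree) in
the linear region of the loading curve, yield torque (Nm), ultimate
torque (Nm), rotation to failure (degree) and energy to failure
(Nm*degree).  Failure is the machine's stop criterion — the first drop
of 3 Nm below the running torque maximum.  Operated-limb metrics can be
normalized to the contralateral limb (percent of contralateral).

The linear region is located with a sliding-window maximum-slope search
(window: a fixed fraction of the pre-ultimate angle range); the yield
point uses a linear-fit offset criterion with a configurable offset
angle.  Both are deterministic, parameter-logged surrogates for the
visually chosen regions of a manual evaluation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

DEFAULT_FAILURE_DROP = 3.0  # Nm
DEFAULT_WINDOW_FRACTION = 0.2
DEFAULT_OFFSET_ANGLE = 0.5  # degree


@dataclass
class TorsionCurve:
    """A recorded torque–angle curve.

    ``angle`` in degrees (monotone non-decreasing as recorded; duplicate
    angles are averaged away on construction so the stored channel is
    strictly increasing), ``torque`` in Nm.
    """

    angle: np.ndarray
    torque: np.ndarray
    sampling_rate: float = 20.0  # Hz
    angular_rate: float = 5.0  # degree/min

    def __post_init__(self) -> None:
        angle = np.asarray(self.angle, dtype=np.float64)
        torque = np.asarray(self.torque, dtype=np.float64)
        if angle.shape != torque.shape or angle.ndim != 1:
            raise ValueError("angle and torque must be equal-length 1-D channels")
        if np.any(np.diff(angle) < 0):
            raise ValueError("angle channel must be monotone non-decreasing")
        # deduplicate repeated angles (hold phases) by averaging torque
        uniq, inverse = np.unique(angle, return_inverse=True)
        if uniq.size != angle.size:
            sums = np.bincount(inverse, weights=torque)
            counts = np.bincount(inverse)
            angle, torque = uniq, sums / counts
        if angle.size < 10:
            raise ValueError("curve needs at least 10 samples")
        self.angle, self.torque = angle, torque

    @property
    def n_samples(self) -> int:
        return self.angle.size

    @property
    def angle_step(self) -> float:
        return float(np.median(np.diff(self.angle)))


def read_curve_csv(path: str | Path, **meta) -> TorsionCurve:
    """Read a two-column CSV (angle_deg, torque_Nm), optional header."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError:
                continue  # header line
    arr = np.asarray(rows)
    return TorsionCurve(angle=arr[:, 0], torque=arr[:, 1], **meta)


def write_curve_csv(curve: TorsionCurve, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["angle_deg", "torque_Nm"])
        w.writerows(zip(curve.angle, curve.torque))


@dataclass
class TorsionMetrics:
    stiffness: float  # Nm/degree
    yield_torque: float  # Nm
    ultimate_torque: float  # Nm
    rotation_to_failure: float  # degree
    energy_to_failure: float  # Nm*degree
    yield_flagged: bool = False  # curve never deviated from linearity
    failure_detected: bool = True
    normalized: dict[str, float] | None = None  # variable -> % of contralateral

    def as_dict(self) -> dict[str, float]:
        return {
            "stiffness": self.stiffness,
            "yield_torque": self.yield_torque,
            "ultimate_torque": self.ultimate_torque,
            "rotation_to_failure": self.rotation_to_failure,
            "energy_to_failure": self.energy_to_failure,
        }


def detect_failure(curve: TorsionCurve, drop: float = DEFAULT_FAILURE_DROP) -> int | None:
    """First sample where the running torque maximum exceeds the current
    torque by at least ``drop`` Nm; ``None`` if the criterion never fires."""
    if drop <= 0:
        raise ValueError("drop must be > 0")
    running_max = np.maximum.accumulate(curve.torque)
    hits = np.flatnonzero(running_max - curve.torque >= drop)
    return int(hits[0]) if hits.size else None


def _pre_failure(curve: TorsionCurve) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Angle/torque channels truncated at the failure peak."""
    fail = detect_failure(curve)
    if fail is None:
        return curve.angle, curve.torque, None
    # last attainment of the running max before the detected drop
    peak = int(np.argmax(curve.torque[:fail]))
    return curve.angle[: peak + 1], curve.torque[: peak + 1], fail


def _max_slope_window(
    angle: np.ndarray, torque: np.ndarray, window_fraction: float
) -> tuple[float, float, int, int]:
    """Sliding-window max least-squares slope.

    Returns (slope, intercept, start, end) of the best window, spanning
    ``window_fraction`` of the pre-ultimate angle range.
    """
    i_ult = int(np.argmax(torque))
    if i_ult < 1:
        raise ValueError("no rising region before the ultimate torque")
    x = angle[: i_ult + 1]
    y = torque[: i_ult + 1]
    span = x[-1] - x[0]
    step = float(np.median(np.diff(x)))
    w = max(5, int(round(window_fraction * span / step)))
    if x.size < w:
        w = x.size
    if w < 5:
        raise ValueError("fewer than 5 samples in the stiffness window")
    n = x.size - w + 1
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    sx = cx[w:] - cx[:-w] if n > 0 else np.array([])
    sy = cy[w:] - cy[:-w]
    sxx = cxx[w:] - cxx[:-w]
    sxy = cxy[w:] - cxy[:-w]
    denom = w * sxx - sx**2
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = (w * sxy - sx * sy) / denom
    slopes = np.where(denom > 0, slopes, -np.inf)
    best = int(np.argmax(slopes))
    slope = float(slopes[best])
    intercept = float((sy[best] - slope * sx[best]) / w)
    return slope, intercept, best, best + w


def apparent_stiffness(
    curve: TorsionCurve, window_fraction: float = DEFAULT_WINDOW_FRACTION
) -> float:
    """Maximum least-squares slope (Nm/degree) over a sliding window
    covering ``window_fraction`` of the pre-ultimate angle range."""
    angle, torque, _ = _pre_failure(curve)
    slope, _, _, _ = _max_slope_window(angle, torque, window_fraction)
    return slope


def yield_point(
    curve: TorsionCurve,
    offset_angle: float = DEFAULT_OFFSET_ANGLE,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
) -> tuple[float, bool]:
    """Offset-criterion yield torque.

    The linear fit of the stiffness window is shifted right by
    ``offset_angle`` degrees; the yield torque is the recorded torque at
    the first sample past the window start where the curve falls to or
    below the shifted line.  If the curve never deviates, the ultimate
    torque is returned with the flag set.
    """
    angle, torque, _ = _pre_failure(curve)
    slope, intercept, w_start, _ = _max_slope_window(angle, torque, window_fraction)
    offset_line = intercept + slope * (angle - offset_angle)
    below = (torque <= offset_line) & (np.arange(angle.size) > w_start)
    hits = np.flatnonzero(below)
    i_ult = int(np.argmax(torque))
    if hits.size == 0 or hits[0] > i_ult:
        return float(torque[i_ult]), True
    return float(torque[hits[0]]), False


def energy_to_failure(curve: TorsionCurve) -> float:
    """Trapezoidal integral of torque over angle up to failure (or the
    end of the curve if no failure is detected), Nm*degree."""
    angle, torque, _ = _pre_failure(curve)
    return float(np.trapezoid(torque, angle))


def analyze_curve(
    curve: TorsionCurve,
    drop: float = DEFAULT_FAILURE_DROP,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    offset_angle: float = DEFAULT_OFFSET_ANGLE,
) -> TorsionMetrics:
    """Extract all five outcome variables from one curve."""
    angle, torque, fail = _pre_failure(curve)
    stiffness = apparent_stiffness(curve, window_fraction)
    yld, flagged = yield_point(curve, offset_angle, window_fraction)
    ultimate = float(torque.max())
    rotation = float(angle[int(np.argmax(torque))])
    energy = float(np.trapezoid(torque, angle))
    return TorsionMetrics(
        stiffness=stiffness,
        yield_torque=yld,
        ultimate_torque=ultimate,
        rotation_to_failure=rotation,
        energy_to_failure=energy,
        yield_flagged=flagged,
        failure_detected=fail is not None,
    )


def normalize_to_contralateral(
    operated: TorsionMetrics, contralateral: TorsionMetrics
) -> TorsionMetrics:
    """Report each variable as 100 x operated / contralateral (%)."""
    norm = {}
    for key, op_val in operated.as_dict().items():
        ref = contralateral.as_dict()[key]
        if ref <= 0:
            raise ValueError(f"non-positive contralateral {key}: {ref}")
        norm[key] = 100.0 * op_val / ref
    return replace(operated, normalized=norm)
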