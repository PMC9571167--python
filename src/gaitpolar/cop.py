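"""Signed medial-lateral centre of pressure (COPx) from pooled insole forces.

COPx is the force-weighted mean of the signed sensor coordinates over *both*
feet, expressed as a percentage of the fifth-metatarsal coordinate:

    COPx = (sum_i F_i * x_i / sum_i F_i) * 100 / x_5th_meta

Because right-foot coordinates are positive and left-foot coordinates are
negative, the sign of COPx encodes the stance side (+ right, - left) and a
single signed waveform describes the alternating gait: during level walking
it looks like a (distorted) sine of the gait cycle.

Samples where the pooled force drops below a floor (flight, idle, sensor
drop-out) carry no pressure information: they are flagged invalid and the
last valid COPx is held, which keeps the downstream oscillator input finite
without inventing sign changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SignalError, ValidationError
from .grf_io import GRFTrial, SensorLayout


@dataclass
class COPxSeries:
    """Signed normalized COPx per sample, with validity flags."""

    t: np.ndarray
    copx: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.copx = np.asarray(self.copx, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (self.t.shape == self.copx.shape == self.valid_mask.shape):
            raise ValidationError("COPxSeries arrays must share one shape")


def compute_copx(trial: GRFTrial, layout: SensorLayout, force_floor: float | None = None) -> COPxSeries:
    """Pooled 10-sensor COPx in percent of the fifth-metatarsal coordinate.

    ``force_floor`` defaults to 2% of the 95th percentile of the pooled total
    force; samples at or below it are invalid and hold the last valid value
    (leading invalid samples take the first valid value).
    """
    if force_floor is not None and force_floor < 0:
        raise ValidationError("force_floor must be >= 0")
    F = np.hstack([trial.F_right, trial.F_left])  # (n, 10)
    x = np.asarray(layout.positions_right + layout.positions_left, dtype=float)
    total = F.sum(axis=1)
    if force_floor is None:
        force_floor = 0.02 * float(np.percentile(total, 95))
    valid = total > force_floor
    if not valid.any():
        raise SignalError("no stance detected: pooled force never exceeds the floor")
    copx = np.zeros_like(total)
    copx[valid] = (F[valid] @ x) / total[valid] * (100.0 / layout.x5th_meta)
    # hold-last-valid fill for invalid samples
    idx = np.where(valid, np.arange(total.size), -1)
    np.maximum.accumulate(idx, out=idx)
    first_valid = int(np.argmax(valid))
    idx[idx < 0] = first_valid
    copx = copx[idx]
    return COPxSeries(trial.t, copx, valid)


def _signs_with_zero_forward(copx: np.ndarray) -> np.ndarray:
    """Sign of COPx with zero samples attached to the *following* run."""
    s = np.sign(copx).astype(int)
    for i in range(s.size - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    return s


def stance_sign_segments(cop: COPxSeries) -> list[tuple[str, int, int]]:
    """Maximal constant-sign runs as ``(side, start, end)`` inclusive indices.

    ``side`` is ``"R"`` for positive COPx and ``"L"`` for negative; zero
    samples attach to the following run (trailing all-zero samples are
    dropped).  May return an empty list for an all-zero series.
    """
    s = _signs_with_zero_forward(cop.copx)
    segments: list[tuple[str, int, int]] = []
    start = None
    side = 0
    for i, si in enumerate(s):
        if si == 0:
            continue
        if start is None or si != side:
            if start is not None:
                segments.append(("R" if side > 0 else "L", start, i - 1))
            start, side = i, si
    if start is not None:
        segments.append(("R" if side > 0 else "L", start, len(s) - 1))
    return segments
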