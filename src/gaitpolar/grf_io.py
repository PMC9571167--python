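"""Reading, writing and validation of insole GRF trials and sensor layouts.

A trial is a synchronized pair of 5-channel force recordings (one channel per
insole pressure sensor, one insole per foot) sampled on a uniform time grid.
The sensor layout gives each sensor's signed medial-lateral coordinate in the
subject frame: lateral-right is positive, so all right-foot sensors sit at
positive coordinates and the left foot mirrors them at negative coordinates.
The fifth-metatarsal sensor is the outermost one and its coordinate magnitude
normalizes the centre-of-pressure ratio downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import FormatError, TimingError, ValidationError

logger = logging.getLogger("gaitpolar")

#: Canonical anatomical sensor order used throughout the package.
SENSOR_LABELS = ("big_toe", "first_metatarsal", "fifth_metatarsal", "cuboid", "heel")

#: Column layout of a trial CSV.
TRIAL_COLUMNS = ("time", "R1", "R2", "R3", "R4", "R5", "L1", "L2", "L3", "L4", "L5")

GROUPS = ("healthy", "stroke", "unknown")


@dataclass(frozen=True)
class SensorLayout:
    """Medial-lateral sensor coordinates (mm) for both insoles.

    ``positions_right[i]`` is the signed coordinate of sensor ``labels[i]`` on
    the right foot; the left foot must be its sign mirror.  ``x5th_meta`` is
    the magnitude of the fifth-metatarsal coordinate and must be positive.
    """

    positions_right: tuple[float, ...]
    positions_left: tuple[float, ...]
    x5th_meta: float
    labels: tuple[str, ...] = SENSOR_LABELS

    def __post_init__(self):
        object.__setattr__(self, "positions_right", tuple(float(x) for x in self.positions_right))
        object.__setattr__(self, "positions_left", tuple(float(x) for x in self.positions_left))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.positions_right) != 5 or len(self.positions_left) != 5:
            raise ValidationError("layout requires exactly 5 sensor positions per foot")
        if len(self.labels) != 5:
            raise ValidationError("layout requires exactly 5 sensor labels")
        if not self.x5th_meta > 0:
            raise ValidationError("x5th_meta must be positive")
        if "heel" not in self.labels:
            raise ValidationError("layout must label a 'heel' sensor (heel-strike detection needs it)")
        if not np.allclose(self.positions_left, [-x for x in self.positions_right], rtol=1e-9, atol=1e-9):
            raise ValidationError("positions_left must mirror positions_right with opposite sign")

    @property
    def heel_index(self) -> int:
        return self.labels.index("heel")

    def to_dict(self) -> dict:
        return {
            "positions_right": list(self.positions_right),
            "positions_left": list(self.positions_left),
            "x5th_meta": self.x5th_meta,
            "labels": list(self.labels),
        }


def default_layout() -> SensorLayout:
    """Synthetic reference layout (mm from the body midline, right foot).

    The fifth-metatarsal sensor is the outermost; coordinate magnitudes are
    deliberately symmetric along the heel-to-toe roll-over (heel and big toe
    equal, cuboid and first metatarsal equal) so that the pooled COPx of an
    even stance traces a sinusoid-like arc that peaks at mid-stance - the
    waveform shape the medial-lateral COP of level walking exhibits.
    """
    right = (55.0, 75.0, 90.0, 75.0, 55.0)  # big_toe, 1st met, 5th met, cuboid, heel
    return SensorLayout(right, tuple(-x for x in right), x5th_meta=90.0)


def read_layout(path) -> SensorLayout:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        return SensorLayout(
            tuple(raw["positions_right"]),
            tuple(raw["positions_left"]),
            float(raw["x5th_meta"]),
            tuple(raw.get("labels", SENSOR_LABELS)),
        )
    except KeyError as exc:
        raise FormatError(f"layout JSON missing key {exc}") from exc


def write_layout(layout: SensorLayout, path) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(layout.to_dict(), fh, indent=2)
    return str(path)


@dataclass
class GRFTrial:
    """Synchronized per-sensor force time series for both feet.

    Forces are non-negative (FSR output cannot pull); the time vector must be
    uniform at ``1/fs`` within 1%.
    """

    t: np.ndarray
    F_right: np.ndarray  # shape (n, 5)
    F_left: np.ndarray   # shape (n, 5)
    fs: float = 100.0
    subject_id: str = "unknown"
    group: str = "unknown"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.F_right = np.asarray(self.F_right, dtype=float)
        self.F_left = np.asarray(self.F_left, dtype=float)
        n = self.t.shape[0]
        if n == 0:
            raise ValidationError("empty trial (0 samples) rejected")
        if self.F_right.shape != (n, 5) or self.F_left.shape != (n, 5):
            raise ValidationError(
                f"force arrays must have shape ({n}, 5); got {self.F_right.shape} / {self.F_left.shape}"
            )
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        if np.min(self.F_right) < 0 or np.min(self.F_left) < 0:
            raise ValidationError("forces must be non-negative (clamp upstream if needed)")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if n > 1:
            dt = np.diff(self.t)
            nominal = 1.0 / self.fs
            if np.min(dt) <= 0:
                raise TimingError("time vector must be strictly increasing")
            if np.max(np.abs(dt - nominal)) > 0.01 * nominal:
                raise TimingError(
                    "non-uniform timestamps: spacing deviates from 1/fs by more than 1%"
                )

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return self.t[-1] - self.t[0] + 1.0 / self.fs

    def with_meta(self, subject_id=None, group=None) -> "GRFTrial":
        return replace(
            self,
            subject_id=self.subject_id if subject_id is None else subject_id,
            group=self.group if group is None else group,
        )


def read_trial(path, layout: SensorLayout | None = None, subject_id: str | None = None,
               group: str = "unknown") -> GRFTrial:
    """Read a trial CSV (``time,R1..R5,L1..L5``) and validate it.

    Negative readings (FSR noise) are clamped to zero and counted in a logged
    warning; every other invariant violation raises.
    """
    if layout is not None and len(layout.positions_right) != 5:
        raise ValidationError("layout sensor count must be 5 per foot")
    df = pd.read_csv(path, float_precision="round_trip")
    if tuple(df.columns) != TRIAL_COLUMNS:
        raise FormatError(
            f"expected columns {','.join(TRIAL_COLUMNS)}; got {','.join(map(str, df.columns))}"
        )
    t = df["time"].to_numpy(dtype=float)
    if t.shape[0] == 0:
        raise ValidationError("empty trial (0 samples) rejected")
    FR = df[["R1", "R2", "R3", "R4", "R5"]].to_numpy(dtype=float)
    FL = df[["L1", "L2", "L3", "L4", "L5"]].to_numpy(dtype=float)
    n_neg = int(np.sum(FR < 0) + np.sum(FL < 0))
    if n_neg:
        logger.warning("read_trial(%s): clamped %d negative force samples to 0", path, n_neg)
        FR = np.clip(FR, 0.0, None)
        FL = np.clip(FL, 0.0, None)
    if t.shape[0] > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 100.0
    return GRFTrial(t, FR, FL, fs=fs,
                    subject_id=subject_id if subject_id is not None else str(path),
                    group=group)


def write_trial(trial: GRFTrial, path) -> str:
    """Write a trial to CSV at full float precision (round-trip safe)."""
    df = pd.DataFrame({"time": trial.t})
    for j in range(5):
        df[f"R{j + 1}"] = trial.F_right[:, j]
    for j in range(5):
        df[f"L{j + 1}"] = trial.F_left[:, j]
    df.to_csv(path, index=False, float_format="%.17g")  # round-trip exact
    return str(path)
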