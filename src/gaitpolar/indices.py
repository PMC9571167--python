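"""Reference gait-asymmetry indices: PPD and PCI, with heel-strike detection.

These two indices predate the gaitogram and serve as comparison baselines.

PPD (percentage of plantar pressure difference) compares the total load borne
by each foot over the trial:

    PPD = 2 |GRF_R - GRF_L| / (GRF_R + GRF_L) * 100

where ``GRF_X`` is the sum of all five sensor channels of foot X over every
sample.  It is 0% for equal loading and scale-invariant in the force units.

PCI (phase coordination index) measures the regularity and symmetry of the
left-right stepping rhythm from heel-strike times.  For each right-left-right
heel-strike triplet the stepping phase is

    phi_i = 2*pi * (tL_i - tR_i) / (tR_{i+1} - tR_i)

which is pi for ideally anti-phased stepping.  With ``phi_ABS`` the mean
absolute deviation of phi_i from pi, ``P_phi_ABS = 100 * phi_ABS / pi`` is the
percentage phase offset, and ``phi_CV`` is the coefficient of variation of
phi_i in percent.  ``PCI = phi_CV + P_phi_ABS``.

Heel strikes are detected from the heel sensor channel: an event is an upward
crossing of a fraction of the channel's robust maximum, backtracked to the
local force onset, with a refractory window suppressing re-triggers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DetectionError, PairingError, UndefinedIndexError, ValidationError
from .grf_io import GRFTrial, SensorLayout

logger = logging.getLogger("gaitpolar")


@dataclass
class HeelStrikeEvents:
    """Heel-strike times per foot (s), strictly increasing within each foot."""

    t_R: np.ndarray
    t_L: np.ndarray

    def __post_init__(self):
        self.t_R = np.asarray(self.t_R, dtype=float)
        self.t_L = np.asarray(self.t_L, dtype=float)
        for name, arr in (("t_R", self.t_R), ("t_L", self.t_L)):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValidationError(f"{name} must be strictly increasing")


def _smooth(f: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or f.size < width:
        return f
    kernel = np.ones(width) / width
    return np.convolve(f, kernel, mode="same")


def _detect_channel(t: np.ndarray, f: np.ndarray, threshold_frac: float,
                    refractory: float, fs: float) -> np.ndarray:
    # crossings are detected on a lightly smoothed copy so sensor noise does
    # not re-trigger; onsets are then refined by backtracking the raw channel
    fsm = _smooth(f, max(int(round(0.05 * fs)), 1))
    thr = threshold_frac * float(np.percentile(fsm, 95))
    if thr <= 0:
        return np.asarray([])
    hold = max(int(round(0.05 * fs)), 1)       # crossing must be sustained
    peak_win = max(int(round(0.15 * fs)), 1)   # ... and reach a loading peak
    # raw-signal onset floor: the heel channel idles near zero outside stance,
    # so its median is a robust noise level (exactly 0 on clean recordings)
    noise_level = float(np.percentile(f, 50))
    onset_floor = max(0.02 * thr, 3.0 * noise_level)
    max_back = max(int(round(refractory * fs)), 1)
    events = []
    last = -np.inf
    for i in range(f.size):
        below_before = fsm[i - 1] <= thr if i else True
        if not (fsm[i] > thr and below_before):
            continue
        if not np.all(fsm[i:i + hold] > thr):
            continue
        if np.max(fsm[i:i + peak_win]) < 2.5 * thr:
            continue
        j = i
        while j > 0 and f[j - 1] > onset_floor and (i - j) < max_back:
            j -= 1
        # smoothing can place the crossing before the raw onset: advance to
        # the first raw sample actually above the floor
        while j < min(i + peak_win, f.size - 1) and f[j] <= onset_floor:
            j += 1
        if t[j] - last >= refractory:
            events.append(t[j])
            last = t[j]
    return np.asarray(events)


def detect_heel_strikes(trial: GRFTrial, layout: SensorLayout,
                        threshold_frac: float = 0.1,
                        refractory: float = 0.3) -> HeelStrikeEvents:
    """Heel-strike times from the heel channels of both feet.

    A strike is an upward crossing of ``threshold_frac`` times the channel's
    95th-percentile force, walked back to the force onset (first sample above
    20% of the threshold) so that the reported time is the initial contact
    rather than the threshold crossing.  Crossings within ``refractory``
    seconds of the previous strike are suppressed.  Raises if either foot
    yields no strikes.  Non-alternating event sequences are kept but logged.
    """
    if not 0 < threshold_frac < 1:
        raise ValidationError("threshold_frac must be in (0, 1)")
    hi = layout.heel_index
    t_R = _detect_channel(trial.t, trial.F_right[:, hi], threshold_frac, refractory, trial.fs)
    t_L = _detect_channel(trial.t, trial.F_left[:, hi], threshold_frac, refractory, trial.fs)
    if t_R.size == 0 or t_L.size == 0:
        raise DetectionError("no heel strikes detected on at least one foot")
    merged = sorted([(tt, "R") for tt in t_R] + [(tt, "L") for tt in t_L])
    swaps = sum(1 for a, b in zip(merged[:-1], merged[1:]) if a[1] == b[1])
    if swaps:
        logger.warning("heel strikes do not strictly alternate (%d repeats)", swaps)
    return HeelStrikeEvents(t_R=t_R, t_L=t_L)


@dataclass
class PCIResult:
    """Per-stride stepping phases and the phase coordination index."""

    phi: np.ndarray       # per-stride phases (rad)
    phi_abs: float        # mean |phi_i - pi| (rad)
    p_phi_abs: float      # 100 * phi_abs / pi (%)
    phi_mean: float       # mean phi_i (rad)
    delta: float          # mean squared deviation of phi_i (rad^2)
    phi_cv: float         # coefficient of variation of phi_i (%)
    pci: float            # phi_cv + p_phi_abs (%)
    n_strides: int
    dropped: int = 0


def compute_pci(events: HeelStrikeEvents, cv_mode: str = "sqrt") -> PCIResult:
    """PCI from heel-strike times.

    Each right-stride interval ``[tR_i, tR_{i+1})`` must contain exactly one
    left strike; intervals with none are dropped (and counted), intervals
    with several use the first and log a warning.  ``cv_mode="sqrt"`` (the
    default) uses the standard coefficient of variation
    ``100 * sqrt(delta) / phi_mean`` with ``delta`` the population mean
    squared deviation; ``cv_mode="literal"`` reports the unrooted, unscaled
    ratio ``delta / phi_mean`` instead (kept for comparison with the
    square-deviation formulation; its units are rad, not percent).
    """
    tR, tL = events.t_R, events.t_L
    if tR.size < 2:
        raise PairingError("PCI needs at least 2 right heel strikes")
    phis = []
    dropped = 0
    for i in range(tR.size - 1):
        inside = tL[(tL > tR[i]) & (tL < tR[i + 1])]
        if inside.size == 0:
            dropped += 1
            continue
        if inside.size > 1:
            logger.warning("stride %d contains %d left strikes; using the first", i, inside.size)
        phis.append(2.0 * math.pi * (inside[0] - tR[i]) / (tR[i + 1] - tR[i]))
    if not phis:
        raise PairingError(f"no pairable right-left-right triplets ({dropped} strides dropped)")
    phi = np.asarray(phis)
    phi_abs = float(np.mean(np.abs(phi - math.pi)))
    p_phi_abs = 100.0 * phi_abs / math.pi
    phi_mean = float(np.mean(phi))
    delta = float(np.mean((phi - phi_mean) ** 2))
    if cv_mode == "sqrt":
        phi_cv = 100.0 * math.sqrt(delta) / phi_mean
    elif cv_mode == "literal":
        phi_cv = delta / phi_mean
    else:
        raise ValidationError(f"unknown cv_mode {cv_mode!r}")
    return PCIResult(
        phi=phi,
        phi_abs=phi_abs,
        p_phi_abs=p_phi_abs,
        phi_mean=phi_mean,
        delta=delta,
        phi_cv=phi_cv,
        pci=phi_cv + p_phi_abs,
        n_strides=phi.size,
        dropped=dropped,
    )


@dataclass
class PPDResult:
    grf_sum_R: float
    grf_sum_L: float
    ppd: float


def compute_ppd(trial: GRFTrial) -> PPDResult:
    """Percentage of plantar pressure difference over the whole trial."""
    sR = float(np.sum(trial.F_right))
    sL = float(np.sum(trial.F_left))
    if sR + sL <= 0:
        raise UndefinedIndexError("total force is zero: PPD undefined")
    return PPDResult(grf_sum_R=sR, grf_sum_L=sL,
                     ppd=200.0 * abs(sR - sL) / (sR + sL))
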