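"""Synthetic insole GRF trials with known ground truth.

The generator emulates level walking as seen by a 5-sensor-per-foot insole at
100 Hz, with every gait feature the downstream pipeline estimates available
as ground truth: heel-strike times, per-foot stance intervals, stride time,
and the weight-bearing share of each foot.

Model
-----
Right heel strikes occur at ``k * T`` (stride time ``T``), left strikes at
``(k + q) * T`` with ``q`` the left-offset fraction (0.5 for anti-phased
stepping).  Each template's ``duty_R : duty_L`` sets the relative
weight-bearing time of the two feet; the shares are normalized internally
(``share_R = duty_R / (duty_R + duty_L)``) and each foot's stance occupies
its share of the cycle plus the double-support fraction, so consecutive
stances overlap and body weight is handed over smoothly.

During a stance, the total foot load is an M-shaped profile (two bumps for
loading response and push-off over a plateau) scaled by the foot's amplitude,
and it is distributed across the five sensors by triangular activation
windows that progress heel -> cuboid -> fifth metatarsal -> first metatarsal
-> big toe over normalized stance time, which makes the pooled medial-lateral
centre of pressure swing smoothly between the feet - a sinusoid-like signed
waveform.  At each weight transfer the outgoing and incoming feet follow
complementary cosine ramps over the overlap window, so the transfer midpoint
(the COPx zero crossing) sits at the window centre and the positive/negative
COPx time shares reproduce the duty shares by construction.

Optional degradations: additive Gaussian sensor noise, and low-force "heel
tap" artifacts before true contact (shuffling, as seen in hemiplegic gait).
All randomness flows from the template seed through one generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .grf_io import GRFTrial, SensorLayout, default_layout

logger = logging.getLogger("gaitpolar")

#: Activation centre (fraction of stance) per sensor, in SENSOR_LABELS order:
#: big_toe, first_metatarsal, fifth_metatarsal, cuboid, heel.
_ACTIVATION_CENTERS = np.array([0.88, 0.70, 0.50, 0.30, 0.12])
_ACTIVATION_HALFWIDTH = 0.30


@dataclass(frozen=True)
class GaitTemplate:
    """Parameters of one synthetic walking trial.

    ``duty_R``/``duty_L`` are relative weight-bearing times (only their ratio
    matters); ``left_offset_frac`` is the left heel strike as a fraction of
    the stride; amplitudes are peak total loads in body-weight units;
    ``noise_sd`` is the per-channel Gaussian noise SD in the same units.
    """

    stride_time: float = 1.1
    duty_R: float = 0.6
    duty_L: float = 0.6
    left_offset_frac: float = 0.5
    amplitude_R: float = 1.0
    amplitude_L: float = 1.0
    double_support_frac: float = 0.1
    noise_sd: float = 0.02
    shuffle_prob: float = 0.0
    shuffle_magnitude: float = 0.1
    n_strides: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.duty_R < 1 and 0 < self.duty_L < 1):
            raise ValidationError("duty fractions must be in (0, 1)")
        if not 0 < self.left_offset_frac < 1:
            raise ValidationError("left_offset_frac must be in (0, 1)")
        if not (self.amplitude_R > 0 and self.amplitude_L > 0):
            raise ValidationError("amplitudes must be positive")
        if self.n_strides < 2:
            raise ValidationError("n_strides must be >= 2")
        if not 0 <= self.double_support_frac < 0.4:
            raise ValidationError("double_support_frac must be in [0, 0.4)")
        if not self.stride_time > 0:
            raise ValidationError("stride_time must be positive")
        if self.noise_sd < 0 or self.shuffle_prob < 0 or self.shuffle_prob > 1:
            raise ValidationError("noise_sd >= 0 and shuffle_prob in [0, 1] required")

    @property
    def share_R(self) -> float:
        return self.duty_R / (self.duty_R + self.duty_L)


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery tests."""

    heel_strikes_R: np.ndarray   # s
    heel_strikes_L: np.ndarray   # s
    stance_R: list[tuple[float, float]]  # (start, end) s
    stance_L: list[tuple[float, float]]
    stride_time: float
    share_R: float               # weight-bearing share of the right foot
    left_offset_frac: float
    template: GaitTemplate


def _total_load_shape(s: np.ndarray) -> np.ndarray:
    """M-shaped stance load: two bumps over a plateau, in [0.85, ~1.15]."""
    return (0.85
            + 0.30 * np.exp(-(((s - 0.28) / 0.12) ** 2))
            + 0.30 * np.exp(-(((s - 0.72) / 0.12) ** 2)))


def _sensor_weights(s: np.ndarray) -> np.ndarray:
    """(n, 5) normalized triangular sensor activations over stance time."""
    d = np.abs(s[:, None] - _ACTIVATION_CENTERS[None, :])
    w = np.clip(1.0 - d / _ACTIVATION_HALFWIDTH, 0.0, None)
    total = w.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return w / total


def _add_stance(F: np.ndarray, t: np.ndarray, start: float, dur: float,
                amplitude: float, ramp_up: float, ramp_down: float) -> None:
    """Accumulate one stance's 5-channel force into ``F`` (in place)."""
    i0 = np.searchsorted(t, start)
    i1 = np.searchsorted(t, start + dur, side="right")
    if i1 - i0 < 2:
        return
    tt = t[i0:i1]
    s = (tt - start) / dur
    env = np.ones_like(tt)
    rising = tt < start + ramp_up
    env[rising] = 0.5 - 0.5 * np.cos(np.pi * (tt[rising] - start) / ramp_up)
    falling = tt > start + dur - ramp_down
    env[falling] = 0.5 + 0.5 * np.cos(np.pi * (tt[falling] - (start + dur - ramp_down)) / ramp_down)
    load = amplitude * env * _total_load_shape(s)
    F[i0:i1] += load[:, None] * _sensor_weights(s)


def generate_trial(template: GaitTemplate, layout: SensorLayout | None = None,
                   fs: float = 100.0) -> tuple[GRFTrial, GroundTruth]:
    """Generate one synthetic trial and its ground truth.

    The sampling rate must resolve the double-support handover (>= 20 Hz).
    Reproducible: the same template (including seed) yields a bit-identical
    trial.
    """
    if layout is None:
        layout = default_layout()
    if fs < 20:
        raise ValidationError("fs < 20 Hz cannot resolve double support")
    T = template.stride_time
    q = template.left_offset_frac
    ds = template.double_support_frac
    share_R = template.share_R
    S_R = (share_R + ds) * T        # right stance duration
    S_L = (1.0 - share_R + ds) * T  # left stance duration
    n_str = template.n_strides
    strikes_R = np.arange(n_str) * T
    strikes_L = (np.arange(n_str) + q) * T
    t_end = max(strikes_R[-1] + S_R, strikes_L[-1] + S_L) + 0.1
    n = int(np.ceil(t_end * fs)) + 1
    t = np.arange(n) / fs

    min_ramp = max(0.02, 2.0 / fs)

    def ramps(starts, dur, other_starts, other_dur):
        """Per-stance (ramp_up, ramp_down) = overlap with neighbouring
        opposite-foot stances, floored at a minimal ramp."""
        out = []
        for s0 in starts:
            prev_end = [os + other_dur for os in other_starts if os < s0]
            up = max(prev_end) - s0 if prev_end else min_ramp
            nxt = [os for os in other_starts if os > s0]
            down = (s0 + dur) - min(nxt) if nxt else min_ramp
            out.append((float(np.clip(up, min_ramp, dur / 2)),
                        float(np.clip(down, min_ramp, dur / 2))))
        return out

    FR = np.zeros((n, 5))
    FL = np.zeros((n, 5))
    for s0, (up, down) in zip(strikes_R, ramps(strikes_R, S_R, strikes_L, S_L)):
        _add_stance(FR, t, s0, S_R, template.amplitude_R, up, down)
    for s0, (up, down) in zip(strikes_L, ramps(strikes_L, S_L, strikes_R, S_R)):
        _add_stance(FL, t, s0, S_L, template.amplitude_L, up, down)

    rng = np.random.default_rng(template.seed)
    heel = 4  # SENSOR_LABELS order: heel is the last channel
    if template.shuffle_prob > 0:
        for F, strikes, amp in ((FR, strikes_R, template.amplitude_R),
                                (FL, strikes_L, template.amplitude_L)):
            for s0 in strikes:
                if rng.uniform() < template.shuffle_prob:
                    t0 = s0 - rng.uniform(0.08, 0.2)
                    width = 0.08
                    mask = (t >= t0) & (t < t0 + width)
                    F[mask, heel] += (template.shuffle_magnitude * amp * 0.5
                                      * (1 - np.cos(2 * np.pi * (t[mask] - t0) / width)))
    if template.noise_sd > 0:
        FR += rng.normal(0.0, template.noise_sd * template.amplitude_R, FR.shape)
        FL += rng.normal(0.0, template.noise_sd * template.amplitude_L, FL.shape)
        np.clip(FR, 0.0, None, out=FR)
        np.clip(FL, 0.0, None, out=FL)

    trial = GRFTrial(t=t, F_right=FR, F_left=FL, fs=fs)
    truth = GroundTruth(
        heel_strikes_R=strikes_R,
        heel_strikes_L=strikes_L,
        stance_R=[(float(s0), float(s0 + S_R)) for s0 in strikes_R],
        stance_L=[(float(s0), float(s0 + S_L)) for s0 in strikes_L],
        stride_time=T,
        share_R=share_R,
        left_offset_frac=q,
        template=template,
    )
    return trial, truth


#: Default stroke-like template: weight-bearing duty 1.4x on the unaffected
#: (right) side, 1.3x load asymmetry, delayed left stepping, noisier signal.
STROKE_TEMPLATE = GaitTemplate(
    duty_R=0.7, duty_L=0.5,
    amplitude_R=1.3, amplitude_L=1.0,
    left_offset_frac=0.58,
    noise_sd=0.03,
)

HEALTHY_TEMPLATE = GaitTemplate()


@dataclass
class CohortMember:
    trial: GRFTrial
    truth: GroundTruth


def generate_cohort(healthy_template: GaitTemplate | None = None,
                    stroke_template: GaitTemplate | None = None,
                    n_healthy: int = 8, n_stroke: int = 4,
                    seed: int = 0,
                    layout: SensorLayout | None = None,
                    fs: float = 100.0) -> list[CohortMember]:
    """A cohort of per-subject jittered trials with group labels.

    Each subject perturbs the group template (stride time 4%, duties 1.5%,
    amplitudes 5% multiplicative jitter; stepping offset +/- 0.01) and draws a
    fresh noise seed, all from one cohort-level generator.
    """
    if n_healthy < 2 or n_stroke < 2:
        raise ValidationError("need at least 2 subjects per group")
    healthy_template = healthy_template or HEALTHY_TEMPLATE
    stroke_template = stroke_template or STROKE_TEMPLATE
    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    plan = [("healthy", healthy_template, i + 1) for i in range(n_healthy)]
    plan += [("stroke", stroke_template, i + 1) for i in range(n_stroke)]
    for group, base, idx in plan:
        jit = replace(
            base,
            stride_time=base.stride_time * rng.normal(1.0, 0.04),
            duty_R=base.duty_R * rng.normal(1.0, 0.015),
            duty_L=base.duty_L * rng.normal(1.0, 0.015),
            amplitude_R=base.amplitude_R * rng.normal(1.0, 0.05),
            amplitude_L=base.amplitude_L * rng.normal(1.0, 0.05),
            left_offset_frac=float(np.clip(base.left_offset_frac + rng.normal(0.0, 0.01), 0.3, 0.7)),
            seed=int(rng.integers(2**31 - 1)),
        )
        trial, truth = generate_trial(jit, layout=layout, fs=fs)
        sid = f"{'h' if group == 'healthy' else 's'}{idx:02d}"
        members.append(CohortMember(trial=trial.with_meta(subject_id=sid, group=group), truth=truth))
    return members
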