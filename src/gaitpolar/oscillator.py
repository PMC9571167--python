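"""Adaptive frequency oscillator (AO) for continuous gait-phase estimation.

The AO entrains a bank of harmonically locked oscillators to a quasi-periodic
input ``u(t)``.  With ``i = 1..order`` harmonics, phases ``phi_i``, amplitudes
``alpha_i``, offset ``alpha_0`` and fundamental frequency ``omega``, the
continuous-time dynamics are

    dphi_i/dt   = i*omega + k_phi   * e * cos(phi_i)
    domega/dt   =           k_omega * e * cos(phi_1)
    dalpha_i/dt =           k_alpha * e * sin(phi_i)
    dalpha_0/dt =           k_0     * e

with reconstruction ``uhat = alpha_0 + sum_i alpha_i sin(phi_i)`` and tracking
error ``e = u - uhat``.  When the reconstruction is exact (``e = 0``) the
frequency, amplitudes and offset are exact fixed points and each phase
advances at ``i*omega``: the fundamental phase ``phi_1`` is then a continuous
gait phase on ``[0, 2*pi)`` with one wrap per gait cycle.

Integration is explicit forward Euler at the sampling period (``dt = 1/fs``),
mirroring the real-time embedded setting the estimator targets.  The
adaptation gains are amplitude-sensitive, so ``estimate_phase`` rescales its
input to unit amplitude by default (see ``AOParams.input_scale``).

Two gain presets are shipped: a responsive one for healthy gait and a stiffer
one for strongly asymmetric (e.g. post-stroke hemiplegic) gait whose COPx
waveform is less regular:

    healthy: k_phi=0.8, k_alpha=1.2, k_omega=0.6, k_0=1.0
    stroke:  k_phi=0.2, k_alpha=0.2, k_omega=0.4, k_0=0.8

Both are starting points; the gains interact with insole mechanics and should
be tuned to the recording conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .cop import COPxSeries
from .errors import InsufficientCyclesError, NumericError, ValidationError

logger = logging.getLogger("gaitpolar")

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class AOParams:
    """Adaptation gains and integration settings for the oscillator bank.

    Parameters
    ----------
    k_phi, k_alpha, k_omega, k_0
        Positive adaptation gains for phase, amplitude, frequency and offset.
    order
        Number of harmonics (>= 1); 5 resolves the COPx waveform well.
    omega_init
        Initial fundamental frequency (rad/s).  Default ``2*pi*0.9`` matches a
        typical self-selected cadence of ~0.9 strides/s.
    dt
        Euler step (s); use the sampling period.
    omega_floor
        Lower clip for omega (rad/s): the frequency update can transiently
        drive omega negative, which would flip the rotation sense.
    input_scale
        Divisor applied to the input before adaptation.  ``None`` (default)
        estimates a robust amplitude from the signal so that the preset gains
        see a ~unit-amplitude input regardless of the units of COPx.
    """

    k_phi: float = 0.8
    k_alpha: float = 1.2
    k_omega: float = 0.6
    k_0: float = 1.0
    order: int = 5
    omega_init: float = TWO_PI * 0.9
    dt: float = 0.01
    omega_floor: float = 0.1
    input_scale: float | None = None

    def __post_init__(self):
        for name in ("k_phi", "k_alpha", "k_omega", "k_0"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"gain {name} must be positive")
        if self.order < 1:
            raise ValidationError("order must be >= 1")
        if not self.dt > 0:
            raise ValidationError("dt must be positive")


PROFILES = {
    "healthy": AOParams(k_phi=0.8, k_alpha=1.2, k_omega=0.6, k_0=1.0),
    "stroke": AOParams(k_phi=0.2, k_alpha=0.2, k_omega=0.4, k_0=0.8),
}


def ao_profile(name: str, **overrides) -> AOParams:
    """Return a gain preset (``"healthy"`` or ``"stroke"``), with overrides."""
    try:
        base = PROFILES[name]
    except KeyError:
        raise ValidationError(f"unknown AO profile {name!r}; choose from {sorted(PROFILES)}")
    return replace(base, **overrides) if overrides else base


@dataclass
class AOState:
    """Oscillator bank state: phases, amplitudes, offset and frequency."""

    phi: np.ndarray
    alpha: np.ndarray
    alpha0: float
    omega: float

    @classmethod
    def initial(cls, params: AOParams) -> "AOState":
        return cls(
            phi=np.zeros(params.order),
            alpha=np.zeros(params.order),
            alpha0=0.0,
            omega=float(params.omega_init),
        )

    def reconstruct(self) -> float:
        return float(self.alpha0 + np.sum(self.alpha * np.sin(self.phi)))


def ao_step(state: AOState, u_sample: float, params: AOParams) -> AOState:
    """One forward-Euler update of all ``2*order + 2`` state variables.

    The update is simultaneous: every right-hand side is evaluated at the old
    state.  Phases are left unwrapped internally.
    """
    if not np.isfinite(u_sample):
        raise NumericError("non-finite input sample")
    dt = params.dt
    harmonics = np.arange(1, params.order + 1, dtype=float)
    uhat = state.reconstruct()
    e = float(u_sample) - uhat
    cos_phi = np.cos(state.phi)
    phi = state.phi + dt * (harmonics * state.omega + params.k_phi * e * cos_phi)
    omega = state.omega + dt * params.k_omega * e * cos_phi[0]
    alpha = state.alpha + dt * params.k_alpha * e * np.sin(state.phi)
    alpha0 = state.alpha0 + dt * params.k_0 * e
    omega = max(omega, params.omega_floor)
    new = AOState(phi=phi, alpha=alpha, alpha0=alpha0, omega=omega)
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(alpha)) and np.isfinite(alpha0)):
        raise NumericError("oscillator state became non-finite")
    return new


@dataclass
class GaitPhaseSeries:
    """Per-sample phase estimate and oscillator diagnostics."""

    t: np.ndarray
    phase: np.ndarray         # phi_1 wrapped to [0, 2*pi)
    omega_series: np.ndarray  # rad/s
    uhat: np.ndarray          # reconstruction, input units
    error: np.ndarray         # tracking error, input units
    converged: bool = True


def run_oscillator(u: np.ndarray, params: AOParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drive the AO over a raw signal; returns (phi1_unwrapped, omega, uhat).

    Low-level loop shared by :func:`estimate_phase` and the tests; the input
    is used as-is (no rescaling).
    """
    n = u.shape[0]
    state = AOState.initial(params)
    phi1 = np.empty(n)
    omega = np.empty(n)
    uhat = np.empty(n)
    for k in range(n):
        # record the reconstruction *before* the update so uhat[k] is the
        # oscillator's prediction of u[k]
        uhat[k] = state.reconstruct()
        phi1[k] = state.phi[0]
        omega[k] = state.omega
        state = ao_step(state, u[k], params)
    return phi1, omega, uhat


def estimate_phase(cop: COPxSeries, params: AOParams) -> GaitPhaseSeries:
    """Continuous gait phase from a COPx series.

    Requires at least 2 s of signal.  The input is divided by
    ``params.input_scale`` (robust amplitude when ``None``) before adaptation
    and the reconstruction/error are reported back in input units.  With
    well-matched gains the oscillator synchronizes within a few steps of gait;
    if the tracking error grows over the last quarter of the trial a
    convergence warning is logged and the series is flagged.
    """
    u = np.asarray(cop.copx, dtype=float)
    n = u.shape[0]
    if n * params.dt < 2.0:
        raise ValidationError("estimate_phase requires at least 2 s of signal")
    if not np.all(np.isfinite(u)):
        raise NumericError("COPx contains non-finite samples")
    scale = params.input_scale
    if scale is None:
        scale = float(np.percentile(np.abs(u - np.median(u)), 95))
    scale = max(scale, 1e-9)
    phi1, omega, uhat = run_oscillator(u / scale, params)
    uhat = uhat * scale
    err = u - uhat
    # divergence heuristic: error power growing over the final quarter
    q = max(n // 4, 2)
    tail = float(np.sqrt(np.mean(err[-q:] ** 2)))
    mid = float(np.sqrt(np.mean(err[n // 4:n // 2] ** 2))) if n >= 8 else tail
    sig = float(np.sqrt(np.mean(u ** 2))) + 1e-12
    converged = not (tail > 3.0 * mid and tail > 0.5 * sig)
    if not converged:
        logger.warning("adaptive oscillator may be diverging (tail error %.3g vs %.3g)", tail, mid)
    return GaitPhaseSeries(
        t=np.asarray(cop.t, dtype=float),
        phase=np.mod(phi1, TWO_PI),
        omega_series=omega,
        uhat=uhat,
        error=err,
        converged=converged,
    )


@dataclass
class CyclePhaseStats:
    """Per-cycle phase spans and their summary."""

    spans: np.ndarray
    mean: float
    sd: float
    deficit: float  # 2*pi - mean
    n_cycles: int


def wrap_indices(phase: np.ndarray) -> np.ndarray:
    """Sample indices k where the wrapped phase drops (end of a cycle at k)."""
    return np.where(np.diff(phase) < -math.pi)[0]


def cycle_phase_stats(series: GaitPhaseSeries, skip_initial: int = 2) -> CyclePhaseStats:
    """Span of each gait cycle: the last pre-wrap value of the wrapped phase.

    A cycle ends at each downward wrap of phi_1; an ideal cycle spans just
    under ``2*pi`` (short by at most ``omega*dt`` of discretization).  The
    first ``skip_initial`` cycles are dropped by default because they cover
    the oscillator's entrainment transient; at least two spans are always
    retained.  Reports the mean span, sample SD and the deficit ``2*pi -
    mean``.
    """
    wraps = wrap_indices(series.phase)
    if wraps.size < 2:
        raise InsufficientCyclesError("need at least 2 phase wraps for cycle statistics")
    spans = series.phase[wraps]
    skip = min(max(skip_initial, 0), spans.size - 2)
    spans = spans[skip:]
    mean = float(np.mean(spans))
    sd = float(np.std(spans, ddof=1)) if spans.size > 1 else 0.0
    return CyclePhaseStats(spans=spans, mean=mean, sd=sd, deficit=TWO_PI - mean, n_cycles=spans.size)
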