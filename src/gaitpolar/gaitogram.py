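"""Polar gaitogram construction and the gait-asymmetry indices built on it.

A polar gaitogram plots the gait against itself: each sample's radius is the
magnitude of the medial-lateral centre of pressure, ``r = |COPx|``, and its
angle is the continuous gait phase, ``theta = phi_1``.  Over one gait cycle
the right-foot stance (COPx > 0) traces an upper closed lobe and the left
stance (COPx < 0) a lower lobe.  For a perfectly symmetric gait the two lobes
are congruent; an asymmetric, e.g. hemiplegic, gait shrinks the lobe of the
affected foot.

Three quantities are read off the gaitogram:

* ``AreaClosed.R/L``     -- polar area of each lobe, ``integral 1/2 r^2 dtheta``;
* ``Arearatio.R/L``      -- each lobe's percentage of the total lobe area, and
  ``ARI = |Arearatio.R - Arearatio.L|``, the area ratio index.  ARI is 0% for
  identical weight-bearing and grows with the weight-bearing-time asymmetry;
* ``Angtangent``         -- the absolute slope angle of the line joining the
  two weight-transfer points (where COPx changes sign), i.e. the common
  tangent of the two lobes near the origin.

The disorder rule: with a chosen ARI threshold ``T`` (percent), a subject is
classified as having a gait disorder when ``ARI > T``; equivalently either
area ratio falls outside ``50 +/- T/2``.  The foot whose ratio exceeds
``50 + T/2`` bears weight longest and is the *unaffected* foot; the opposite
foot is the affected one.

Aggregation: lobe areas are computed per cycle and averaged across cycles
before forming ratios, which makes subject-level indices insensitive to the
number of strides recorded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cop import COPxSeries, _signs_with_zero_forward
from .errors import (
    GeometryError,
    InsufficientCyclesError,
    UndefinedIndexError,
    UndefinedSlopeError,
    ValidationError,
)
from .oscillator import TWO_PI, GaitPhaseSeries, wrap_indices

logger = logging.getLogger("gaitpolar")


@dataclass
class GaitogramCycle:
    """Samples of one complete gait cycle in polar form."""

    theta: np.ndarray  # rad, non-decreasing within the cycle
    r: np.ndarray      # |COPx|, percent
    side: np.ndarray   # +1 right stance, -1 left stance


@dataclass
class PolarGaitogram:
    """Per-cycle polar samples plus an across-cycle mean curve for rendering."""

    cycles: list[GaitogramCycle]
    theta_grid: np.ndarray
    r_mean: np.ndarray
    r_sd: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass
class CrossingPoint:
    """A weight-transfer point: polar location where COPx changes sign."""

    r: float
    theta: float

    @property
    def xy(self) -> tuple[float, float]:
        return (self.r * math.cos(self.theta), self.r * math.sin(self.theta))


@dataclass
class GaitogramIndices:
    """Subject-level gaitogram indices (areas averaged over cycles)."""

    area_R: float
    area_L: float
    arearatio_R: float
    arearatio_L: float
    ari: float
    ang_tangent_printed: float
    ang_tangent_cartesian: float
    crossing_R: CrossingPoint
    crossing_L: CrossingPoint
    n_cycles: int


def anchor_phase_to_transfer(phase: GaitPhaseSeries, cop: COPxSeries) -> GaitPhaseSeries:
    """Rotate the phase so theta = 0 sits at the left-to-right weight transfer.

    The oscillator's phase origin depends on its initial conditions and on the
    harmonic content of COPx, so the raw gaitogram is rotated by an arbitrary
    constant.  The published geometry puts the upward COPx zero crossing
    (weight moving onto the right foot, i.e. the start of a gait cycle) at
    angle 0, which splits the lobes into the upper (0, pi) right-stance and
    lower (pi, 2*pi) left-stance halves.  This helper estimates the mean
    phase of the upward crossings (circular mean) and subtracts it.
    """
    c = cop.copx
    th = phase.phase
    s = _signs_with_zero_forward(c)
    vx = vy = 0.0
    for i in range(len(c) - 1):
        if s[i] < 0 and s[i + 1] > 0:
            frac = _zero_cross_frac(c[i], c[i + 1])
            dth = th[i + 1] - th[i]
            if dth < -math.pi:
                dth += TWO_PI
            theta_c = th[i] + frac * dth
            vx += math.cos(theta_c)
            vy += math.sin(theta_c)
    if vx == 0.0 and vy == 0.0:
        raise UndefinedSlopeError("no upward COPx crossings: cannot anchor phase")
    theta0 = math.atan2(vy, vx)
    out = GaitPhaseSeries(
        t=phase.t,
        phase=np.mod(phase.phase - theta0, TWO_PI),
        omega_series=phase.omega_series,
        uhat=phase.uhat,
        error=phase.error,
        converged=phase.converged,
    )
    return out


def build_gaitogram(phase: GaitPhaseSeries, cop: COPxSeries, grid_points: int = 181) -> PolarGaitogram:
    """Pair each sample's wrapped phase with |COPx| and a stance-side label.

    The series must share one time grid.  Cycles are delimited by downward
    phase wraps; the incomplete boundary segments before the first wrap and
    after the last are dropped.  Samples where the phase transiently steps
    backwards (possible during oscillator transients) are discarded so that
    theta is non-decreasing within each cycle.
    """
    if phase.t.shape != cop.t.shape or not np.allclose(phase.t, cop.t):
        raise ValidationError("phase and COPx series must share the same time grid")
    wraps = wrap_indices(phase.phase)
    if wraps.size < 2:
        raise InsufficientCyclesError("no complete gait cycle between phase wraps")
    signs = _signs_with_zero_forward(cop.copx)
    r_all = np.abs(cop.copx)
    cycles: list[GaitogramCycle] = []
    for a, b in zip(wraps[:-1], wraps[1:]):
        sl = slice(a + 1, b + 1)  # first sample after a wrap .. last before next
        theta = phase.phase[sl]
        keep = theta >= np.maximum.accumulate(theta) - 1e-12
        theta = np.maximum.accumulate(theta[keep])
        cycles.append(GaitogramCycle(theta=theta, r=r_all[sl][keep], side=signs[sl][keep]))
    grid = np.linspace(0.0, TWO_PI, grid_points)
    stack = np.full((len(cycles), grid_points), np.nan)
    for i, c in enumerate(cycles):
        if c.theta.size >= 2:
            stack[i] = np.interp(grid, c.theta, c.r, left=c.r[0], right=c.r[-1])
    r_mean = np.nanmean(stack, axis=0)
    r_sd = np.nanstd(stack, axis=0, ddof=1) if len(cycles) > 1 else np.zeros(grid_points)
    return PolarGaitogram(cycles=cycles, theta_grid=grid, r_mean=r_mean, r_sd=r_sd)


def closed_area(theta: np.ndarray, r: np.ndarray, literal: bool = False) -> float:
    """Polar area of one lobe: trapezoidal ``integral 1/2 r^2 dtheta``.

    ``literal=True`` evaluates ``integral 1/2 r^2 theta dtheta`` instead (an
    alternative weighting of the same samples, kept for comparison; the
    unweighted form is the geometric lobe area and the package default).
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    if theta.size < 3:
        raise GeometryError("closed_area needs at least 3 samples")
    if np.any(np.diff(theta) < 0):
        raise GeometryError("theta must be non-decreasing within a lobe")
    integrand = 0.5 * r ** 2
    if literal:
        integrand = integrand * theta
    return float(np.trapezoid(integrand, theta))


def _side_runs(side: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (sign, start, stop-exclusive) runs of a +/-1 label array."""
    runs = []
    start = 0
    for i in range(1, side.size + 1):
        if i == side.size or side[i] != side[start]:
            runs.append((int(side[start]), start, i))
            start = i
    return runs


def cycle_side_areas(cycle: GaitogramCycle, literal: bool = False) -> tuple[float, float]:
    """Lobe areas (right, left) of one cycle.

    Each same-side run is integrated over its own theta span; at a sign change
    the lobe is closed by extending it to the interpolated zero crossing of
    the signed radius, so adjacent lobes meet at r = 0 rather than double
    counting the transition interval.
    """
    area = {1: 0.0, -1: 0.0}
    signed = cycle.r * cycle.side
    for sgn, a, b in _side_runs(cycle.side):
        if sgn == 0:
            continue
        theta = list(cycle.theta[a:b])
        r = list(cycle.r[a:b])
        # close toward the preceding run
        if a > 0 and cycle.side[a - 1] != sgn:
            fr = _zero_cross_frac(signed[a - 1], signed[a])
            theta.insert(0, cycle.theta[a - 1] + fr * (cycle.theta[a] - cycle.theta[a - 1]))
            r.insert(0, 0.0)
        # close toward the following run
        if b < cycle.side.size and cycle.side[b] != sgn:
            fr = _zero_cross_frac(signed[b - 1], signed[b])
            theta.append(cycle.theta[b - 1] + fr * (cycle.theta[b] - cycle.theta[b - 1]))
            r.append(0.0)
        if len(theta) >= 3:
            area[sgn] += closed_area(np.asarray(theta), np.asarray(r), literal=literal)
    return area[1], area[-1]


def _zero_cross_frac(v0: float, v1: float) -> float:
    d = v0 - v1
    return 0.5 if d == 0 else float(np.clip(v0 / d, 0.0, 1.0))


def area_ratio_index(area_R: float, area_L: float) -> tuple[float, float, float]:
    """Percentage share of each lobe and their absolute difference (ARI).

    Both ratios are normalized by ``area_R + area_L`` so they sum to 100
    exactly; ``ARI = |ratio_R - ratio_L|``.
    """
    total = area_R + area_L
    if total <= 0:
        raise UndefinedIndexError("both lobe areas are zero: area ratios undefined")
    ratio_R = 100.0 * area_R / total
    ratio_L = 100.0 * area_L / total
    return ratio_R, ratio_L, abs(ratio_R - ratio_L)


@dataclass
class Classification:
    verdict: str    # "normal" | "disorder"
    affected: str   # "none" | "left" | "right"
    unaffected: str  # "none" | "left" | "right"


def disorder_cutoffs(ari_threshold: float = 10.0) -> tuple[float, float]:
    """Area-ratio band ``50 +/- ari_threshold/2`` separating normal from disorder.

    With the default 10% ARI threshold the band is (45%, 55%): a foot whose
    area ratio exceeds 55% marks a gait disorder (and is the unaffected foot);
    the opposite foot, below 45%, is the affected one.
    """
    if not ari_threshold > 0:
        raise ValidationError("ari_threshold must be positive")
    half = ari_threshold / 2.0
    return 50.0 - half, 50.0 + half


def classify_disorder(arearatio_R: float, arearatio_L: float,
                      ari_threshold: float = 10.0) -> Classification:
    """Threshold rule: disorder iff ARI exceeds the threshold.

    The foot with the larger weight-bearing share (area ratio above the upper
    cutoff) is reported as unaffected and the opposite foot as affected.
    """
    lower, upper = disorder_cutoffs(ari_threshold)
    ari = abs(arearatio_R - arearatio_L)
    if ari <= ari_threshold:
        return Classification("normal", "none", "none")
    if arearatio_R > upper:
        return Classification("disorder", affected="left", unaffected="right")
    return Classification("disorder", affected="right", unaffected="left")


def crossing_points(phase: GaitPhaseSeries, cop: COPxSeries) -> tuple[CrossingPoint, CrossingPoint]:
    """Mean weight-transfer points of the gaitogram.

    The right point is where COPx changes from positive to negative (weight
    leaves the right foot), the left point where it changes from negative to
    positive.  Each sign change contributes one polar sample: the phase is
    interpolated to the zero crossing between the bracketing samples, and the
    radius is the mean |COPx| of those two samples (the interpolated radius
    itself is ~0 by construction and would carry no direction information).
    Per-side points are averaged in Cartesian coordinates across all strides.
    """
    c = cop.copx
    th = phase.phase
    pts: dict[str, list[tuple[float, float]]] = {"R": [], "L": []}
    s = _signs_with_zero_forward(c)
    for i in range(len(c) - 1):
        if s[i] == 0 or s[i + 1] == 0 or s[i] == s[i + 1]:
            continue
        frac = _zero_cross_frac(c[i], c[i + 1])
        dth = th[i + 1] - th[i]
        if dth < -math.pi:  # wrap between the two samples
            dth += TWO_PI
        theta_c = math.fmod(th[i] + frac * dth, TWO_PI)
        r_c = 0.5 * (abs(c[i]) + abs(c[i + 1]))
        key = "R" if s[i] > 0 else "L"
        pts[key].append((r_c * math.cos(theta_c), r_c * math.sin(theta_c)))
    if not pts["R"] or not pts["L"]:
        raise UndefinedSlopeError("no weight-transfer points on one side")
    out = []
    for key in ("R", "L"):
        xy = np.mean(np.asarray(pts[key]), axis=0)
        out.append(CrossingPoint(r=float(np.hypot(*xy)), theta=float(np.arctan2(xy[1], xy[0]) % TWO_PI)))
    return out[0], out[1]


def tangent_angle(crossing_R: CrossingPoint, crossing_L: CrossingPoint,
                  mode: str = "as_printed") -> float:
    """Absolute slope angle of the tangent line through the transfer points.

    ``mode="as_printed"`` forms the angle directly from polar differences,
    ``|atan2(theta_R - theta_L, r_R - r_L)|`` -- a dimensionally mixed but
    simple expression.  ``mode="cartesian"`` converts both points to Cartesian
    coordinates first and reports the acute angle between the connecting
    segment and the horizontal axis, which is the geometric slope one reads
    off a rendered gaitogram (0 for a symmetric gait).  Neither mode is
    canonical; reports always record which one was used.
    """
    dr = crossing_R.r - crossing_L.r
    dth = crossing_R.theta - crossing_L.theta
    xR, yR = crossing_R.xy
    xL, yL = crossing_L.xy
    if abs(xR - xL) < 1e-12 and abs(yR - yL) < 1e-12:
        raise UndefinedSlopeError("coincident crossing points: slope undefined")
    if mode == "as_printed":
        if abs(dr) < 1e-12 and abs(dth) < 1e-12:
            raise UndefinedSlopeError("coincident polar crossing points")
        return abs(math.atan2(dth, dr))
    if mode == "cartesian":
        return math.atan2(abs(yR - yL), abs(xR - xL))
    raise ValidationError(f"unknown tangent mode {mode!r}")


def gaitogram_indices(phase: GaitPhaseSeries, cop: COPxSeries,
                      literal_area: bool = False,
                      anchor: bool = True) -> GaitogramIndices:
    """Full gaitogram index set for one trial (areas averaged per cycle).

    By default the phase is first anchored so that theta = 0 coincides with
    the left-to-right weight transfer (see :func:`anchor_phase_to_transfer`),
    which removes the oscillator's arbitrary phase origin from the tangent
    angle and splits the lobes into upper/lower halves.
    """
    if anchor:
        phase = anchor_phase_to_transfer(phase, cop)
    gg = build_gaitogram(phase, cop)
    per_cycle = np.asarray([cycle_side_areas(c, literal=literal_area) for c in gg.cycles])
    area_R = float(np.mean(per_cycle[:, 0]))
    area_L = float(np.mean(per_cycle[:, 1]))
    ratio_R, ratio_L, ari = area_ratio_index(area_R, area_L)
    pR, pL = crossing_points(phase, cop)
    return GaitogramIndices(
        area_R=area_R,
        area_L=area_L,
        arearatio_R=ratio_R,
        arearatio_L=ratio_L,
        ari=ari,
        ang_tangent_printed=tangent_angle(pR, pL, "as_printed"),
        ang_tangent_cartesian=tangent_angle(pR, pL, "cartesian"),
        crossing_R=pR,
        crossing_L=pL,
        n_cycles=gg.n_cycles,
    )


def plot_gaitogram(gg: PolarGaitogram, path, indices: GaitogramIndices | None = None,
                   title: str | None = None) -> str:
    """Render the gaitogram to an image file (headless-safe).

    Upper (right-stance) samples blue, lower (left-stance) red, across-cycle
    SD band gray, tangent line dashed black.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    band_lo = np.clip(gg.r_mean - gg.r_sd, 0, None)
    band_hi = gg.r_mean + gg.r_sd
    grid_x = np.cos(gg.theta_grid)
    grid_y = np.sin(gg.theta_grid)
    ax.fill(np.concatenate([band_hi * grid_x, band_lo[::-1] * grid_x[::-1]]),
            np.concatenate([band_hi * grid_y, band_lo[::-1] * grid_y[::-1]]),
            color="0.8", lw=0, label="mean ± SD")
    for c in gg.cycles:
        x = c.r * np.cos(c.theta)
        y = c.r * np.sin(c.theta)
        up = c.side > 0
        ax.plot(np.where(up, x, np.nan), np.where(up, y, np.nan), color="tab:blue", lw=0.8)
        ax.plot(np.where(~up, x, np.nan), np.where(~up, y, np.nan), color="tab:red", lw=0.8)
    if indices is not None:
        (xR, yR), (xL, yL) = indices.crossing_R.xy, indices.crossing_L.xy
        ax.plot([xR, xL], [yR, yL], "k--", lw=1.2, label="tangent line")
    ax.axhline(0, color="0.6", lw=0.5)
    ax.axvline(0, color="0.6", lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("|COPx| cos θ (%)")
    ax.set_ylabel("|COPx| sin θ (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
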