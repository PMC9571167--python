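"""End-to-end analysis pipeline, configuration and report assembly.

``analyze_trial`` chains the stages on one trial:

    forces -> COPx -> adaptive-oscillator phase -> polar gaitogram ->
    area-ratio / tangent-angle indices -> classification, plus the PPD and
    PCI reference indices and per-cycle phase statistics,

and returns an :class:`IndexReport` whose JSON form is deterministic for
fixed inputs and configuration.  Display values follow the conventional
rounding (1 decimal for area ratios and ARI, 2 for the tangent angle, PPD
and PCI, 3 for phase spans); unrounded values are kept alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import gaitogram as gg
from .cop import compute_copx
from .errors import GaitError, ValidationError
from .grf_io import GRFTrial, SensorLayout, read_layout, read_trial
from .indices import compute_pci, compute_ppd, detect_heel_strikes
from .oscillator import CyclePhaseStats, ao_profile, cycle_phase_stats, estimate_phase
from .stats import SubjectIndexRecord, round_half_away

logger = logging.getLogger("gaitpolar")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the pipeline, echoed verbatim into every report.

    ``ao_profile="auto"`` picks the oscillator gain preset from the trial's
    group tag (falling back to "healthy"); gains can be overridden
    individually through ``ao_overrides``.
    """

    ao_profile: str = "auto"
    ao_overrides: dict = field(default_factory=dict)
    force_floor: float | None = None
    ari_threshold: float = 10.0
    ppd_threshold: float = 10.0
    angtangent_cutoff: float = 0.155
    ang_mode: str = "as_printed"   # which tangent mode is the headline value
    heel_threshold_frac: float = 0.1
    refractory: float = 0.3
    cv_mode: str = "sqrt"
    skip_initial_cycles: int = 2
    literal_area: bool = False

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class IndexReport:
    """All per-subject results of one analysis run."""

    subject_id: str
    group: str
    cycle_stats: CyclePhaseStats
    gaitogram: gg.GaitogramIndices
    classification: gg.Classification
    ppd: float
    pci: float
    p_phi_abs: float
    phi_cv: float
    n_strides: int
    heel_strikes_R: list[float]
    heel_strikes_L: list[float]
    config: AnalysisConfig

    @property
    def ang_tangent(self) -> float:
        if self.config.ang_mode == "cartesian":
            return self.gaitogram.ang_tangent_cartesian
        return self.gaitogram.ang_tangent_printed

    def to_record(self) -> SubjectIndexRecord:
        return SubjectIndexRecord(
            subject_id=self.subject_id, group=self.group,
            arearatio_R=self.gaitogram.arearatio_R,
            arearatio_L=self.gaitogram.arearatio_L,
            ari=self.gaitogram.ari,
            ang_tangent=self.ang_tangent,
            ppd=self.ppd, pci=self.pci,
        )

    def to_dict(self) -> dict:
        g = self.gaitogram
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "cycle_stats": {
                "mean_span_rad": round_half_away(self.cycle_stats.mean, 3),
                "sd_span_rad": round_half_away(self.cycle_stats.sd, 3),
                "deficit_vs_2pi_rad": round_half_away(self.cycle_stats.deficit, 3),
                "n_cycles": self.cycle_stats.n_cycles,
            },
            "indices": {
                "arearatio_R": round_half_away(g.arearatio_R, 1),
                "arearatio_L": round_half_away(g.arearatio_L, 1),
                "ari": round_half_away(g.ari, 1),
                "ang_tangent": round_half_away(self.ang_tangent, 2),
                "ang_tangent_mode": self.config.ang_mode,
                "ang_tangent_printed": round_half_away(g.ang_tangent_printed, 2),
                "ang_tangent_cartesian": round_half_away(g.ang_tangent_cartesian, 2),
                "ppd": round_half_away(self.ppd, 2),
                "pci": round_half_away(self.pci, 2),
                "p_phi_abs": round_half_away(self.p_phi_abs, 2),
                "phi_cv": round_half_away(self.phi_cv, 2),
            },
            "raw": {
                "area_R": g.area_R,
                "area_L": g.area_L,
                "arearatio_R": g.arearatio_R,
                "arearatio_L": g.arearatio_L,
                "ari": g.ari,
                "ang_tangent_printed": g.ang_tangent_printed,
                "ang_tangent_cartesian": g.ang_tangent_cartesian,
                "ppd": self.ppd,
                "pci": self.pci,
                "mean_span_rad": self.cycle_stats.mean,
            },
            "classification": {
                "verdict": self.classification.verdict,
                "affected": self.classification.affected,
                "unaffected": self.classification.unaffected,
            },
            "n_strides": self.n_strides,
            "heel_strikes_R": list(map(float, self.heel_strikes_R)),
            "heel_strikes_L": list(map(float, self.heel_strikes_L)),
            "n_gaitogram_cycles": g.n_cycles,
            "config": self.config.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _resolve_params(config: AnalysisConfig, group: str):
    name = config.ao_profile
    if name == "auto":
        name = group if group in ("healthy", "stroke") else "healthy"
    return ao_profile(name, **config.ao_overrides)


def analyze_trial(trial: GRFTrial, layout: SensorLayout,
                  config: AnalysisConfig | None = None) -> IndexReport:
    """Run the full pipeline on an in-memory trial."""
    config = config or AnalysisConfig()
    stages: list[tuple[str, float]] = []

    def timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except GaitError as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc
        stages.append((name, time.perf_counter() - t0))
        return out

    cop = timed("cop", compute_copx, trial, layout, config.force_floor)
    params = _resolve_params(config, trial.group)
    phase = timed("oscillator", estimate_phase, cop, params)
    cycles = timed("cycle_stats", cycle_phase_stats, phase, config.skip_initial_cycles)
    indices = timed("gaitogram", gg.gaitogram_indices, phase, cop, config.literal_area)
    verdict = gg.classify_disorder(indices.arearatio_R, indices.arearatio_L,
                                   config.ari_threshold)
    ppd = timed("ppd", compute_ppd, trial)
    strikes = timed("heel_strikes", detect_heel_strikes, trial, layout,
                    config.heel_threshold_frac, config.refractory)
    pci = timed("pci", compute_pci, strikes, config.cv_mode)
    for name, dt in stages:
        logger.info("stage %-12s %.1f ms", name, 1e3 * dt)
    return IndexReport(
        subject_id=trial.subject_id,
        group=trial.group,
        cycle_stats=cycles,
        gaitogram=indices,
        classification=verdict,
        ppd=ppd.ppd,
        pci=pci.pci,
        p_phi_abs=pci.p_phi_abs,
        phi_cv=pci.phi_cv,
        n_strides=pci.n_strides,
        heel_strikes_R=list(strikes.t_R),
        heel_strikes_L=list(strikes.t_L),
        config=config,
    )


def analyze(trial_path, layout_path, config: AnalysisConfig | None = None,
            subject_id: str | None = None, group: str = "unknown") -> IndexReport:
    """File-based wrapper around :func:`analyze_trial`."""
    layout = read_layout(layout_path)
    trial = read_trial(trial_path, layout, subject_id=subject_id, group=group)
    return analyze_trial(trial, layout, config)
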