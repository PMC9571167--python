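"""Group-level aggregation, threshold separation and exact Mann-Whitney tests.

Per-subject index records (computed by the pipeline or entered from a
published reference table) are summarized per group as mean / sample SD /
min / max, checked for threshold separation (are the two groups' ranges
disjoint around the clinical threshold?), and compared index-by-index with
the Mann-Whitney U test.  Sample sizes in this setting are small (a handful
of subjects per group), so the test is computed exactly: the full null
distribution of U over all C(n1+n2, n1) rank assignments, with the two-sided
p defined as ``min(1, 2 * min(P(U <= u), P(U >= u)))``.  Tied data fall back
to the midrank normal approximation with tie correction.

A bundled reference cohort (8 healthy adults and 4 post-stroke hemiplegic
patients, with published per-subject values of the area-ratio, tangent-angle,
plantar-pressure and phase-coordination indices plus their estimated gait
cycle phase spans) ships with the package for validation and demonstration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

INDEX_COLUMNS = ("arearatio_R", "arearatio_L", "ari", "ang_tangent", "ppd", "pci")


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero at the printed precision (display rule).

    A binary double cannot hold a decimal half-way point exactly (e.g. the
    mean of four 3-decimal values can land at ...49999999999999), so the value
    is first snapped to 6 guard digits before the final quantization.
    """
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-(ndigits + 6)), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SubjectIndexRecord:
    """One subject's index values with a group label."""

    subject_id: str
    group: str
    arearatio_R: float
    arearatio_L: float
    ari: float
    ang_tangent: float
    ppd: float
    pci: float

    def __post_init__(self):
        for col in INDEX_COLUMNS:
            if not np.isfinite(getattr(self, col)):
                raise ValidationError(f"{self.subject_id}: non-finite {col}")
        if not self.group:
            raise ValidationError("group label required")


def load_reference_cohort() -> list[SubjectIndexRecord]:
    """Bundled per-subject reference index table (8 healthy + 4 stroke)."""
    with resources.files("gaitpolar.data").joinpath("reference_cohort.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        SubjectIndexRecord(
            subject_id=row.subject_id, group=row.group,
            arearatio_R=row.arearatio_R, arearatio_L=row.arearatio_L,
            ari=row.ari, ang_tangent=row.ang_tangent, ppd=row.ppd, pci=row.pci,
        )
        for row in df.itertuples(index=False)
    ]


def load_reference_gait_phase() -> pd.DataFrame:
    """Bundled per-subject mean (SD) gait-cycle phase spans in rad."""
    with resources.files("gaitpolar.data").joinpath("reference_gait_phase.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class GroupSummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int

    def rounded(self, ndigits: int) -> tuple[float, float]:
        return round_half_away(self.mean, ndigits), round_half_away(self.sd, ndigits)


def summarize_group(records: list[SubjectIndexRecord], group: str) -> dict[str, GroupSummary]:
    """Mean, sample (n-1) SD, min and max of every index within one group."""
    rows = [r for r in records if r.group == group]
    if len(rows) < 2:
        raise ValidationError(f"group {group!r} needs at least 2 records")
    out = {}
    for col in INDEX_COLUMNS:
        v = np.asarray([getattr(r, col) for r in rows], dtype=float)
        out[col] = GroupSummary(
            mean=float(np.mean(v)), sd=float(np.std(v, ddof=1)),
            min=float(np.min(v)), max=float(np.max(v)), n=v.size,
        )
    return out


@dataclass
class MannWhitneyResult:
    U: float       # U statistic of the first sample
    p: float       # two-sided p
    method: str    # "exact" | "asymptotic"


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of U over all C(n1+n2, n1) rank assignments.

    ``counts[u]`` is the number of assignments with statistic u, built from
    the recurrence N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1).
    """
    U = n1 * n2
    cur = np.zeros((n1 + 1, U + 1))
    cur[:, 0] = 1.0  # n = 0: only u = 0
    for n in range(1, n2 + 1):
        nxt = np.zeros_like(cur)
        nxt[0, 0] = 1.0
        for m in range(1, n1 + 1):
            nxt[m] = cur[m]
            nxt[m, n:] += nxt[m - 1, : U + 1 - n]
        cur = nxt
    return cur[n1]


def mann_whitney_exact(x, y, max_arrangements: int = 1_000_000) -> MannWhitneyResult:
    """Mann-Whitney U test, exact by enumeration whenever feasible.

    Exact when the pooled data are tie-free and the number of rank
    assignments C(n1+n2, n1) does not exceed ``max_arrangements``; otherwise
    the midrank normal approximation with tie correction (via scipy) is used.
    The exact two-sided p is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    U1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and comb(n1 + n2, n1) <= max_arrangements:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u = int(round(U1))
        cdf = counts[: u + 1].sum() / total
        sf = counts[u:].sum() / total
        return MannWhitneyResult(U=U1, p=min(1.0, 2.0 * min(cdf, sf)), method="exact")
    # midrank normal approximation with tie correction
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(U=U1, p=1.0, method="asymptotic")
    z = (U1 - mu - 0.5 * np.sign(U1 - mu)) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(U=U1, p=float(p), method="asymptotic")


@dataclass
class IndexComparison:
    healthy: GroupSummary
    stroke: GroupSummary
    threshold: float | None
    separated: bool
    test: MannWhitneyResult


@dataclass
class GroupComparison:
    """Per-index group summaries, separation flags and exact tests."""

    indices: dict[str, IndexComparison]
    ari_mean_ratio: float
    alpha: float = 0.05


def compare_groups(records: list[SubjectIndexRecord],
                   ari_threshold: float = 10.0,
                   ppd_threshold: float = 10.0,
                   angtangent_cutoff: float = 0.155) -> GroupComparison:
    """Compare the healthy and stroke groups index by index.

    Separation means the two group ranges are disjoint; for indices with a
    clinical threshold (ARI, PPD, tangent angle) the threshold must also fall
    between the healthy maximum and the stroke minimum.  Also reports the
    stroke-to-healthy ratio of group-mean ARI.
    """
    groups = {r.group for r in records}
    if not {"healthy", "stroke"} <= groups:
        raise ValidationError("records must contain both 'healthy' and 'stroke' groups")
    healthy = summarize_group(records, "healthy")
    stroke = summarize_group(records, "stroke")
    thresholds = {"ari": ari_threshold, "ppd": ppd_threshold, "ang_tangent": angtangent_cutoff}
    out = {}
    for col in INDEX_COLUMNS:
        h, s = healthy[col], stroke[col]
        thr = thresholds.get(col)
        disjoint = h.max < s.min or s.max < h.min
        if thr is not None:
            lo, hi = (h, s) if h.max < s.min else (s, h)
            separated = disjoint and lo.max < thr <= hi.min
        else:
            separated = disjoint
        test = mann_whitney_exact(
            [getattr(r, col) for r in records if r.group == "healthy"],
            [getattr(r, col) for r in records if r.group == "stroke"],
        )
        out[col] = IndexComparison(healthy=h, stroke=s, threshold=thr,
                                   separated=separated, test=test)
    ratio = stroke["ari"].mean / healthy["ari"].mean if healthy["ari"].mean else math.inf
    return GroupComparison(indices=out, ari_mean_ratio=float(ratio))
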