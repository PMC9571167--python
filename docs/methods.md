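# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `gaitpolar`, in the order the pipeline runs.

## Data model

A trial is a pair of synchronized 5-channel force recordings (one channel per
insole pressure sensor) on a uniform grid, nominally 100 Hz. Forces are
non-negative; negative readings (FSR noise) are clamped to zero at read time
and counted in a logged warning — the only silent repair the I/O layer
performs. Timestamps must be uniform within 1 % of the sampling period.

The sensor layout carries signed medial–lateral coordinates in millimetres in
the subject frame (lateral-right positive); the left foot must mirror the
right with opposite sign, and the fifth-metatarsal magnitude `x_5th` is the
normalization of COPx. Published insole studies derive coordinates from the
wearer's shoe size or height but do not print them, so layouts are
user-supplied JSON; the package's default layout is a synthetic reference
with magnitudes (big toe 55, first metatarsal 75, fifth metatarsal 90,
cuboid 75, heel 55 mm). The magnitudes are deliberately symmetric along the
heel-to-toe roll-over so that the pooled COPx of an even stance traces a
sinusoid-like arc peaking at mid-stance — the waveform shape this method
assumes of level walking. A strongly fore-aft-asymmetric layout skews the
lobe radii sampled on either side of a weight transfer and biases the area
ratio relative to the weight-bearing-time share (a few percentage points at
duty ratio 1.5 in our experiments).

## COPx

COPx is computed over all 10 sensors pooled, so its sign is the stance side
and double support interpolates smoothly between feet. Samples whose pooled
force falls at or below a floor carry no pressure information; the floor
defaults to 2 % of the 95th-percentile pooled force (scale-invariant, robust
to spikes). Such samples are flagged invalid and hold the last valid COPx —
holding, rather than zeroing, avoids inventing sign changes during flight or
idle periods. Leading invalid samples take the first valid value. In
stance-side segmentation, zero-valued samples attach to the *following* run,
a deterministic tie-break.

## Adaptive frequency oscillator

Integration is explicit forward Euler at the sampling period (`dt = 1/fs`),
matching the real-time microcontroller setting this estimator targets; no
higher-order integrator is used because the published gains were evidently
tuned in that regime. State initialization: phases and amplitudes zero,
offset zero, `ω(0) = 2π·0.9 rad/s` (a typical self-selected cadence of
~0.9 strides/s; no initial condition is published). The frequency is clipped
below at 0.1 rad/s because the frequency update can transiently drive ω
negative and flip the rotation sense.

The adaptation gains multiply the tracking error, so they are
amplitude-sensitive: presets published for COPx inputs assume a particular
signal scale. `estimate_phase` therefore rescales its input to roughly unit
amplitude (robust 95th-percentile of |u − median|) before adaptation and
reports the reconstruction in input units; `input_scale` can be pinned
explicitly. Entrainment behaviour worth knowing: with the healthy preset the
oscillator locks within a few gait cycles when `ω(0)` is within ~15 % of the
true cadence, but capture from a distant start is slow — a pure 0.5 or
1.5 Hz sinusoid takes on the order of 100–200 s to pull in from the default
initialization. The property tests use 200 s sinusoids and 60-stride trials
for the extreme stride times for this reason.

Per-cycle phase statistics: a cycle ends at each downward wrap of `φ_1`, and
its span is the last pre-wrap phase value, so an ideal cycle is short of 2π
by at most `ω·dt` (~0.03 rad at 100 Hz and ~0.9 Hz cadence). This
discretization convention reproduces the form of published per-subject cycle
statistics (means slightly below 2π with a small "deficit"). The first two
cycles are skipped by default as entrainment transient.

## Polar gaitogram

`r = |COPx|`, `θ = φ_1`. The oscillator's phase origin is arbitrary (it
depends on initialization and on the harmonic content of COPx), so before
indices are computed the phase is anchored: the circular-mean phase of the
upward COPx zero crossings (weight moving onto the right foot) is rotated to
θ = 0. This reproduces the published geometry — upper lobe = right stance on
(0, π) — and removes the arbitrary rotation from the tangent angle. Without
anchoring, a perfectly symmetric gait would show a spurious tangent tilt
equal to the phase lag between the oscillator fundamental and the weight
transfer.

Lobe areas use the standard polar area `∫ ½ r² dθ` by trapezoid. One
published rendering of the integrand carries an extra θ factor (making the
"area" depend on where the cycle starts, and breaking the interpretation of
the ratios as weight-bearing-time shares); we treat that as a typesetting
slip and implement the standard form, keeping the literal variant behind
`literal_area=True` for comparison. Likewise the ratio denominators are
`Area_R + Area_L` for both feet — the only reading under which the two
ratios sum to 100 %.

Within each cycle, same-side runs are integrated separately and closed to
the interpolated zero crossing of the signed radius at each sign change, so
adjacent lobes meet at r = 0 without double-counting. Samples where the
phase transiently steps backwards (oscillator transients) are dropped to
keep θ non-decreasing per cycle. Incomplete boundary cycles are dropped.
Areas are computed per cycle and averaged across cycles before forming
ratios — how published subject-level values aggregate strides is unstated,
and the per-cycle mean is robust to stride-count differences.

**Weight-transfer (crossing) points.** At a COPx sign change the
interpolated radius is ~0 by construction and carries no information, so
each crossing contributes the interpolated θ with the mean |COPx| of the two
bracketing samples as r; per-side points are averaged in Cartesian
coordinates across strides. **Tangent angle modes.** The published formula
mixes polar differences (`|atan2(θ_R−θ_L, r_R−r_L)|`, dimensionally odd but
simple); the geometric reading is the slope of the chord between the two
transfer points on the rendered gaitogram. Both are computed:
`as_printed` (the default headline value, faithful to the formula) and
`cartesian` (acute angle between the chord and the horizontal axis, 0 for a
symmetric gait). Every report names the mode; the cartesian value is the one
comparable to published per-subject tangent angles.

**Classification.** Disorder iff `ARI > T` (default T = 10 %); the area
ratio band is `50 ± T/2`, i.e. (45 %, 55 %) at the default. Since the ratios
sum to 100, `ARI > T` is equivalent to one ratio exceeding the upper cut-off;
that foot (longest weight-bearing) is reported unaffected, the opposite foot
affected.

## PPD and PCI

PPD sums all sensor forces per foot over the whole trial (aggregation window
unspecified in the literature; whole-trial sums are scale-invariant and
stride-count robust). PCI pairs each right-stride interval with the single
left strike it contains; strides without one are dropped and counted. The
published variability term is a mean *squared* deviation (units rad²) summed
with a percentage — not computable as printed — so the coefficient of
variation uses the standard `100·sqrt(δ)/φ′` (population variance under the
root, consistent with "coefficient of variation" and percent units); the
literal unrooted ratio remains available as `cv_mode="literal"`. `P_φABS`
uses the per-stride mean of `|φ_i − π|`.

**Heel-strike detection** (no published detector): an upward crossing of 10 %
of the heel channel's 95th-percentile force, detected on a 50 ms
moving-average copy so sensor noise cannot re-trigger, required to be
sustained for 50 ms and to reach 2.5× threshold within 150 ms (rejects brief
shuffling taps), then backtracked on the raw channel to the force onset
(first raw sample above a floor combining 2 % of threshold with 3× the
channel's median, which is its quiescent noise level). A 0.3 s refractory
window suppresses re-triggers. On noise-free synthetic trials this recovers
ground-truth contact times within one sample.

## Group statistics

Summaries use the sample (n−1) SD. Display rounding is half-away-from-zero
at the conventional precision (1 decimal for area ratios and ARI, 2 for
tangent angle / PPD / PCI, 3 for phase spans), implemented over a 6-guard-
digit decimal snap because binary doubles cannot represent decimal half-way
points exactly. The Mann–Whitney test is exact (full null-distribution
enumeration via the standard counting recurrence) whenever the pooled data
are tie-free and the number of arrangements is at most 10⁶; otherwise the
midrank normal approximation with tie correction is used. Two-sided
`p = min(1, 2·min(P(U≤u), P(U≥u)))`. Separation flags: group ranges disjoint,
and for indices with a clinical threshold (ARI 10 %, PPD 10 %, tangent-angle
cut-off 0.155 rad — the midpoint of the published 0.15–0.16 band) the
threshold must fall between the healthy maximum and the stroke minimum.

The bundled reference cohort TSVs carry published per-subject index values
(8 healthy adults, 4 stroke patients) and per-subject gait-phase spans; they
are validation fixtures and demo inputs, not measurement data shipped by
this package. One footnote: the published PPD p-value (0.008) is larger than
what the tie-free exact test yields for completely separated groups of size
8 and 4 (0.004, as for ARI); the original computation is not reconstructible,
so PPD's p-value is not used as a check anywhere.

## Synthetic gait generator

The generator is the package's test bed: it emulates what a 5-sensor insole
sees during level walking, not musculoskeletal physiology. Per stride of
period `T` (default 1.1 s), right heel strikes at `kT` and left at
`(k+q)T` (`q` = 0.5 for anti-phased stepping). The duty parameters set
relative weight-bearing times; they are normalized to shares internally and
each foot's stance occupies its share plus the double-support fraction
(default 0.1), so consecutive stances overlap. During each overlap the
outgoing and incoming feet follow complementary cosine ramps, which puts the
COPx zero crossing at the transfer-window centre; together with the
symmetric default layout this makes the positive/negative COPx shares — and
hence the area ratios — reproduce the duty shares by construction (the
recovery tests validate exactly this chain through the full pipeline).
Stance load is an M-shaped two-bump profile over a plateau, distributed
across sensors by triangular activations progressing heel → cuboid → fifth
metatarsal → first metatarsal → big toe. Degradations: per-channel Gaussian
noise (default SD 2 % of body weight) and optional low-force pre-contact
heel taps emulating shuffling. All randomness flows from one seed.

Default study conditions: the healthy template is symmetric; the stroke
template uses duty asymmetry 1.4 (unaffected right side), load asymmetry
1.3, left-offset 0.58 and noise 3 %. Cohorts jitter templates per subject
(stride time 4 %, duties 1.5 %, amplitudes 5 %, offset ±0.01). The default
8 + 4 cohort separates cleanly on ARI with all stroke-template subjects
classified disorder/left-affected.

What the generator does *not* emulate — and hence what passing tests do not
establish about real recordings: anterior–posterior COP dynamics, sensor
saturation and hysteresis, cross-talk, gait initiation/termination
transients, turning, or the foot-placement variability of real pathology.
The recovery tolerances (area ratio ±2 points, stepping-phase offset
±1 point on clean trials) characterize pipeline fidelity under the model,
not clinical accuracy.

## Problem sizes in the shipped tests

Unit and property tests run on trials of 10–25 strides at 100 Hz; the
oscillator capture-range test uses 200 s sinusoids; the recovery sweeps use
10 seeds per condition; the end-to-end cohort is 8 + 4 subjects of 20
strides. The full suite completes in well under a minute on one CPU.

## Known limitations

- The tangent angle's published polar form and its geometric reading differ;
  both are reported, neither silently preferred. Cross-study comparability
  of the headline value depends on the mode.
- The exact aggregation of published subject-level gaitogram curves
  (mean curve vs per-cycle indices) is unknown; per-cycle averaging was
  chosen and documented.
- The oscillator assumes a quasi-periodic input; it will not track gait with
  frequent stops, and capture from a badly mismatched initial frequency is
  slow (see above).
- PCI requires detectable heel strikes; heavy shuffling degrades it — which
  is precisely the motivation for the gaitogram indices.
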