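# Methods

## Trajectory measurement

The anterior plate trajectory of a hemipelvis is modeled as three
circular arcs joined end to end: pubic (landmarks O–C–B), quadrilateral
(B–Q–Z) and iliac (Z–E–H).  For each region the circumcircle through
the landmark triple is computed in closed form, and the region length
is the chord between the outer landmarks converted by
`arc = d·arcsin(c/d)`.  This conversion is exact only for central
angles up to π.  When the mid landmark falls on the major arc of its
chord — detected by a side test against the circle center — the
formula value (the minor arc) is still returned, with an
`ArcAmbiguityWarning`, because the conversion formula is the defining
measurement convention of this pipeline; callers who need the true
path length on such geometry must re-landmark.  In anatomical data the
region arcs are well below a semicircle, so the case is not expected
outside synthetic abuse.

Derived landmarks are constructed from raw anatomical points the way a
surgeon digitizing a CT reconstruction would: the pelvic-ring circle is
fit through O, S and S1; B, Q and Z are radial 5 mm outward offsets of
the ring projections B_PR, Q_PR, Z_PR from the ring center; E is a
10 mm offset of the auricular-surface point E_AS.  "Upward" for Q and
"lateral" for E are not rigorous geometric directions; we resolve Q by
the same radial rule as B and Z (consistent, frame-free), and E by a
caller-supplied direction defaulting to the ring normal (oriented
toward the iliac crest) projected into the plane of Z_PR, E_AS and H —
i.e. away from the pelvic ring while staying in the iliac-arc plane.
Both offsets are configurable.

Numerical conventions: coordinates are mm in an arbitrary right-handed
frame; triangles with area < 1e−9 mm² are degenerate; arcsin ratios in
(1, 1+1e−9] are clamped to 1 (floating-point noise), larger ratios are
hard errors; plane/circle constructions are accurate to ~1e−9 mm and
all lengths are rigid-motion and reflection invariant to < 1e−6 mm.

## Synthetic trajectories

`gen_arc_trajectory` lays out each region's arc in a local plane
(radius rᵢ, central angle θᵢ ≤ π, mid landmark at the exact arc
midpoint) and chains the frames so consecutive regions share their
junction landmark; a per-junction hinge rotation about the local
radial axis tilts the next arc plane, values near π producing the
S-shaped curvature reversal seen anatomically.  Ground-truth region
lengths are rᵢθᵢ by construction, so the measurement code can be
checked against exact references; optional isotropic Gaussian noise
(SD in mm) emulates landmark-placement error.  Defaults (radii
55.4/62.8/79.2 mm, lengths 60.96/69.11/84.40 mm) mirror the published
cohort means.  The generator does not attempt realistic bone surfaces,
only landmark geometry: passing tests demonstrate correctness of the
measurement mathematics, not robustness to segmentation error.

## Synthetic populations

Published summary statistics for the 834-hemipelvis cohort are: region
means (60.96 ± 5.39), (69.11 ± 5.28), (84.40 ± 6.41) mm, total
(214.46 ± 10.15) mm, ratio correlation r = 0.622 and ratio regression
Y = 0.731·X + 0.559 (X = LQR/LPR, Y = LIR/LPR).  No joint distribution
is published, so the generator makes explicit modeling choices:

* **Ratio structure.**  X ~ N(μx, σx) with μx = 69.11/60.96 ≈ 1.134
  and σx = 0.08 by default; Y = 0.731·X + 0.559 + ε with ε Gaussian.
  The residual SD is set by the closed form
  σε = |slope|·σx·√(1/r² − 1) (`calibrate_residual_sd`) so the
  population correlation equals the target r.  When group effects add
  spread to X, the calibration uses the effective SD
  √(σx² + Var(shifts)) so the realized correlation still lands on
  target.
* **Length anchor.**  The default draws the total length from a
  truncated normal (214.46, 10.15; floor 1 mm) and splits it,
  LPR = total/(1 + X + Y).  This reproduces the published total
  distribution exactly and yields region SDs within ~20% of the
  published values.  The alternative `anchor="lpr"` draws LPR from
  (60.96, 5.39) and multiplies outward; it matches the pubic SD
  exactly but, because LPR and the ratios are then independent, it
  inflates the total SD to roughly twice the published cohort value
  (the published numbers imply a strong negative dependence between
  pubic length and the ratios, which a product model without it cannot
  reproduce).  The total anchor is therefore the default.
* **Group effects.**  Sex and geographic region enter as additive mean
  shifts on the anchor length and on X, with signs and magnitudes
  taken from the published group contrasts (men: shorter pubic region,
  longer total; totals increasing from southern to northeastern
  groups).  Shifts are de-meaned against the fixed cohort composition
  (490/344 male/female; 93/549/177/15 NE/central/south/NW) so overall
  means stay calibrated; within-group SDs are shared, since no
  group-specific dispersion or correlation structure is published.
* **Determinism.**  Composition is apportioned by largest remainder,
  assignment shuffled and all draws made from one `numpy` Generator, so
  a model plus seed reproduces a table bit-for-bit.  The documentation
  default seed is 20230121.

These choices mean recovery tests (sample mean total within 3 SE,
refit slope/correlation near targets) validate the calibration
machinery, not anatomy; real cohorts may differ in tails, skew and
covariance beyond the matched moments.

## Statistics

Summaries (n−1 SDs), Pearson correlation with its t test, simple
regression with the slope F test (satisfying F = r²(n−2)/(1−r²)),
paired t, independent t, and one-way ANOVA are computed from their
defining formulas, with p-values from scipy's t, F and
studentized-range distributions; scipy's own test functions serve as
independent cross-checks in the test suite, never as the
implementation.  The independent-samples test is pooled-variance by
default (the convention of the tabulated cohort comparisons this
mirrors), with Welch behind a flag.  Pairwise comparisons after ANOVA
use the Student–Newman–Keuls procedure: means ordered, range statistic
q = (m_hi − m_lo)/√(MSW/2·(1/n_hi + 1/n_lo)) (Tukey–Kramer SE for
unequal n), critical values from the studentized-range quantile at the
stretch of each range, quantiles computed numerically rather than from
tables, and the step-down rule that a range inside any non-significant
range is itself declared non-significant.  Degenerate cases follow the
usual conventions (zero-variance paired differences with zero mean
give t = 0, p = 1; with nonzero mean, |t| = ∞, p = 0).  A
Shapiro–Wilk check only switches summary formatting between mean ± SD
and median (IQR); it never changes which test runs.

## Catalog design and coverage

Totals: medium = cohort mean total rounded half-up to integer mm;
small/large = medium ∓ 20 mm, so the three ±10 mm bands tile
184–244 mm without gaps.  Ratio families: r1 ∈ {1.1, 1.3} fixed, r2 =
round₁(0.731·r1 + 0.559), giving 1/1.1/1.4 and 1/1.3/1.5.  Region
lengths use the remainder rule — base = total/(1 + r1 + r2), the
quadrilateral and iliac regions round half-up to integer mm, the pubic
region takes the remainder — the only single rounding rule consistent
with the published plate table's A1, A2, C1 and C2 rows.  That table's
B1 row (51, 67, 86; sum 204) and B2 row (56, 73, 84; sum 213)
contradict both the rule (which yields 61/67/86 and 57/73/84) and
their own stated 214 mm total; we treat them as misprints and generate
the rule-consistent values.

All rounding of reported values is decimal half-up (never banker's):
integer mm for plate regions, one decimal for ratios, two decimals for
percentages (787/834 → 94.36).

Acceptance intervals are closed, [value − 10, value + 10] mm per
region; the sources do not state whether bounds are inclusive, and
closed bounds are the symmetric choice.  Design-mode matching requires
all three regions inside their intervals; clinical mode instead
requires the plate to be no longer than the anatomy in each region and
within a configurable slack below it (default: the tolerance), since
the clinical criterion is stated only as "plate ≤ anatomy" without
granularity.  Coverage tallies per-model counts, per-size-class unions
and subtype intersections (inclusion–exclusion holds by construction),
cross-size-class overlaps — size tiers are *not* assumed disjoint,
and with ±10 mm bands on 20 mm-spaced tiers adjacent classes do
overlap — and the overall union, with percentages over the population
size.  The vectorized counter is tested for exact parity with a
brute-force per-record double loop.

## Problem sizes and limitations

The test suite and the acceptance script run entirely on synthetic
data: populations of n = 834 (the cohort size), 100-replicate recovery
studies, 10⁶-draw Monte-Carlo checks of the residual calibration, and
10⁶-segment polyline oracles for arc length — all chosen to keep a
full run in well under a minute while leaving Monte-Carlo error far
below the tolerances tested.  Known limitations: region SDs under the
total anchor sit somewhat below the published per-region SDs; the
generator models no age structure, no measurement-method bias, and no
left/right asymmetry; and the published per-group statistics
(specimen-validation table, geographic/sex tables) cannot be
reproduced exactly because the underlying specimen and CT data are not
deposited — the property suite covers the statistical machinery
instead.
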