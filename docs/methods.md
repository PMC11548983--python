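# Methods

## Pipeline

`fuzzyhaem` implements a type-1 (Mamdani) fuzzy inference pipeline over CBC
panels: crisp inputs → fuzzifier → rule base → inference engine →
defuzzifier → per-disease scores. The design decisions below are the
package's own; each is configurable where noted.

### Fuzzification

Every (lab parameter, demographic group) pair resolves to a partition of the
parameter's axis into ordered linguistic categories, LOW / NORMAL / HIGH by
default (the config schema accepts any ordered label set with at least two
entries). Membership functions are trapezoids with *complementary linear
transitions*: adjacent categories share the band $[c, d]$, one falling while
the other rises, crossing at 0.5. Consequences:

- degrees sum to 1 at every point (partition of unity), so at most two
  categories are ever simultaneously supported;
- as band widths shrink to zero the fuzzifier degenerates to the crisp
  categoriser (verified by the crisp-limit tests);
- a single anchor point (x, degree) fully determines a band given either its
  start or its width — the calibration primitive
  `calibrate_transition` exploits this.

Out-of-universe values are clamped to the universe edge with a warning
rather than rejected: extreme pathology values are real data. Exact-tie
crisp categorisation resolves to the lower-indexed category — arbitrary but
deterministic.

### Default reference partitions

The shipped `default_config.json` encodes standard sex/age-stratified
hematology reference intervals (universes: MCV 40–160 fL, RDW 5–35 %,
Hb 2–25 g/dL, PCV 10–75 %). Three bands are calibrated rather than taken
from textbook tables:

- adult RDW LOW→NORMAL band **[10.0, 12.5]** — solved from the published
  anchor μ_LOW(10.5) = 0.8 with the LOW plateau end fixed at 10.0;
- adult MCV LOW→NORMAL band **[76.5, 81.5]** — solved from the anchor
  μ_LOW(80.0) = 0.3 with the band width fixed at 5.0 fL;
- adult-female Hb LOW→NORMAL band **[10.5, 12.0113]** — the only *fitted*
  default: with the LOW plateau end fixed at 10.5 g/dL, the band end is
  solved (one-parameter root find on the defuzzified score) so that the
  reference normal female panel (MCV 89.6, RDW 13.6, Hb 12.0, PCV 39.5)
  scores 0.83 for D0. The resulting NORMAL plateau begins at ≈12.0 g/dL,
  the conventional female anemia cutoff.

All other breakpoints are plain reference intervals (e.g. adult male Hb
normal 13.0–16.5 g/dL with transition bands of 1–1.5 g/dL; pediatric MCV/Hb/
PCV ranges per age band; pregnancy-adjusted Hb/PCV for the G3 stratum).
Pregnant-female partitions are not age-stratified; G3 entries for pediatric
age groups mirror the G3 adult ranges purely for totality of the lookup.
RDW units are stored as % (it is a coefficient of variation); some sources
mislabel the column fL.

### Rule base

The shipped rule base is the classical MCV/RDW anemia-classification matrix
(cell size × size heterogeneity), with Hb attached to the uniform-RDW
branches, plus Hb/PCV rules for polycythemia vera (Hb HIGH ∧ PCV HIGH),
dehydration (PCV HIGH), generic anemia (Hb LOW) and the all-normal case.
Grammar: conjunction-only antecedents, one clause per parameter, optional
multiplicative weight in (0, 1]; disjunction is written as multiple rules.
ABSENT activations default to the complement of the aggregated PRESENT
activation, so negative rules need not be enumerated; explicit ABSENT rules
override the complement when they fire harder.

`validate_rulebase` classifies a missing PRESENT rule or an unknown category
label as a *defect* and an input-category combination that activates no
disease as a *warning*: the classical matrix deliberately has no rules on
RDW LOW (isolated low RDW is clinically insignificant), so such combinations
are inert by design.

### Inference and defuzzification

Min for AND, clipping for implication, max for aggregation. Each disease's
output space is [0, 1] with ABSENT = triangle(0, 0.16, 0.32) and PRESENT =
triangle(0.68, 0.84, 1.0); both are configurable. The centroid of the
clipped union is computed by trapezoidal quadrature on a fixed 8001-point
grid — the contract requires ≥ 2001 points; the default is denser so the
quadrature agrees with a 10×-resolution Riemann oracle to 1e-6, far below
the two-decimal reporting precision. Mean-of-maxima ships as an untuned
alternative (`defuzzifier="mom"`). Degenerate all-zero activations (possible
only with hand-built activations, not via the complement convention) fall
back to score 0 with a warning.

Score geometry under the defaults: full PRESENT activation → 0.84 (the
PRESENT triangle's centroid), balanced 0.5/0.5 → 0.50, full ABSENT → 0.16.
The defuzzifier is strictly increasing in the present activation. Rankings
are capped at 8 entries at or above a report threshold of 0.25, with ties
broken by ascending disease index.

## Evaluation

The four classical metrics follow the standard confusion-matrix identities
(accuracy = (TP+TN)/S_T, precision = TP/(TP+FP), recall = TP/(TP+FN),
F = harmonic mean), with zero denominators guarded to 0 and flagged. The
multiclass top-N extension is one-vs-rest on nested top-N lists: TP requires
the truth label to equal the disease *and* the disease to appear in the
top-N prediction. Recall and recurrence proportions are therefore monotone
non-decreasing in N; precision need not be, since false positives also grow
with N. Ground truth is selectable: first professional diagnosis (default),
any professional diagnosis, the further-diagnosis outcome, or the
later-appearing disease. Macro averages are unweighted over diseases with at
least one actual positive. The recurrence estimator is the plain proportion
of horizon-labeled records whose top-N list contains the horizon label.

## Synthetic cohorts

Each disease has a signature assigning a target category per parameter
(anemias: Hb LOW and PCV LOW on top of their MCV/RDW cell; dehydration:
PCV HIGH at normal Hb; polycythemia: both HIGH). Generation samples each
value uniformly on the target category's plateau for the record's
demographic partition, then adds centred Gaussian noise with standard
deviation σ × (adjacent transition-band width), clamped to the universe;
σ = 0 yields categorically pure records. The shipped cohort composition
mirrors the published 311-record test set's per-disease, per-demographic
counts.

What the generator does *not* emulate: physiological covariance beyond
signature consistency (e.g. the tight Hb–PCV ≈ 1:3 ratio), within-category
value distributions (real MCVs are not uniform on a plateau), measurement
error structure, or longitudinal trajectories. Passing recovery tests
therefore certifies engine/rule/partition self-consistency, not clinical
accuracy on real panels.

Diseases sharing a crisp signature (D3/D4/D5; D6/D7; D8/D9; D1/D10/D11/D17;
D12/D13/D14) are indistinguishable by construction, so recovery is stated at
the level of *signature groups* — the argmax-score set of a disease's pure
signature record, computed per demographic. On a noise-free seeded
311-record cohort, top-1 signature-group recall is exactly 1.0; recall
degrades with σ and improves with N.

## Problem sizes

All computations are desk-scale by design: the worked-case suite covers the
22 packaged cases, property grids use a few hundred points per partition,
the metrics oracle checks 1,000 random confusion matrices, and the synthetic
self-consistency cohort has 311 records. The full test suite runs in well
under a minute on one CPU; `scripts/acceptance.py` in about a second.

## Known limitations

- The shipped reference intervals are reasonable textbook values, not a
  clinically validated set; they are meant to be replaced per laboratory.
- Published worked-case tables constrain only a handful of breakpoints; the
  remaining defaults reproduce the *qualitative* disease groupings of those
  tables but not every printed intermediate score (several printed rows are
  mutually inconsistent under any single partition-of-unity configuration —
  e.g. one row treats RDW 11.9 as fully normal while the published RDW
  anchor places it inside the LOW→NORMAL band; the generic-anemia column
  prints 0.50 alongside Hb values that fully activate Hb LOW).
- Type-2 fuzzy sets, Gaussian membership functions, rule learning and fuzzy
  hedges are out of scope; OR within a single antecedent is unsupported by
  the grammar.
- Scores are possibilities; they are not calibrated probabilities and must
  not be read as disease prevalence.
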