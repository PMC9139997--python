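# Methods

This note documents the models, parameter choices and numerical decisions
behind `partmorph`, and what the synthetic-observer experiments do and do
not show.

## Shape model

**Growth.**  A part's skeleton is a heading-space random walk: the first
segment deviates from the attachment direction by a uniform draw in
±`angle_range_deg`; each later segment deviates from its predecessor by a
draw from the same range, or — for "curved" limbs — by a magnitude drawn
uniformly in [50°, 100°] with random sign, which concentrates curvature
away from near-straight configurations.  Segment lengths are uniform in
`seg_length_range` (default 0.08–0.16 of body height).  Limb joint counts
are drawn from 3–5.

**Silhouette.**  The joint chain is interpolated with a natural cubic
spline parameterized by cumulative chord length (the simplest C² curve
through the joints), then inflated by offsetting each dense vertex
perpendicular to the local tangent by half the local width.  Width factors
are specified at stations spaced evenly along the path and interpolated
linearly; `taper` multiplies the terminal station, so `taper=0` yields a
pointed tip.  End caps are semicircular fans with an odd sample count so
the on-axis cap vertex is included exactly; this makes the main body's
boundary vertex set exactly mirror-symmetric, which in turn makes the
perimeter map `t → 1−t` an exact reflection — the property the mirroring
and displacement operations rely on.  When high curvature folds the offset
ribbon onto itself, the silhouette is rebuilt as the union of per-segment
quads plus the cap fans (connected by construction), hairline point
contacts are closed with a tiny dilate–erode pass, and self-loop
enclosures are filled.  A genuinely disconnected result raises an error.

**Main body.**  A deterministic, vertically elongated blob: a straight
3-joint vertical skeleton with width profile (0.78, 1.0, 0.78), tapered
0.9, width 0.32 of its height, rescaled to height exactly 1 and centred.
Its perimeter parameterization starts at the topmost vertex and runs
counterclockwise (down the left flank, around the bottom, up the right
flank).

**Composition.**  A shape is the boolean union of the body and all part
ribbons.  Sibling overlaps are allowed (the union resolves them); a union
that splits into components is an error.  Each part contributes one
skeleton intersection point — its root, which lies on both the part
skeleton and the parent's boundary or skeleton — for part segmentation.

**Coordinates and reproducibility.**  Continuous 2-D Cartesian, y-up,
body height 1.  All randomness flows from NumPy `SeedSequence` roots with
documented spawn order, so identical seeds give bit-identical joints.

## Part-structure manipulations

* *Mirroring* reflects a first-order limb's local path about the body
  axis and re-roots it at `1−t`; turning angles flip sign, segment lengths
  and widths are identical.
* *Displacement* slides one limb of a pair by a perimeter fraction
  (levels 0.025–0.125).  "Up or down" is resolved per flank; a shift that
  would cross the body's top or bottom cap (2 % margin) is clamped and
  logged rather than wrapped, since a limb sliding across a pole of the
  body has no biological reading.  Exactly one limb per pair is displaced,
  chosen at random.
* *Straightening* multiplies every **turning angle** (the deviation
  between successive skeletal segments; 0 = collinear) by the factor,
  preserving segment lengths by forward reconstruction.  The turning-angle
  reading of "angle between joints" is an interpretation: scaling it
  toward zero straightens the limb, and the 100° → 25° example under
  factor 0.25 holds exactly.  Straightening forms a one-parameter
  semigroup and commutes with mirroring.
* *Transplanting* detaches a donor pair from the body and re-roots each
  donor on the same-side host limb at a uniform skeletal fraction in
  [0.3, 0.8] (avoiding root and tip), preserving donor geometry in the new
  frame; part count is conserved and donors become second-order.
* *Sprouting* grows order-2 limbs at uniform fractions [0.15, 0.85] of a
  parent, starting orthogonal to the parent tangent (the same attachment
  rule as first-order limbs), with total length `size_scale` × parent
  length.  A zero-size sprout is kept as a degenerate part (no geometry,
  recorded in metadata) so part identity is conserved across morph steps.

## Morphing

All schedules are linear over the five steps — the simplest monotone
choice: displacement 0 → 0.125 (the largest Experiment 1 level),
straightening factor 1.0 → 0.05, sprout size 0 → 0.6 of parent length in
the growing condition and fixed at 0.6 in the symmetrical condition.  One
sprout per first-order limb.  Limb roots are placed in the perimeter zone
[0.16, 0.345] of each flank so the largest displacement never reaches a
cap — this keeps the asymmetry schedule strictly monotone, which is
verified over all 110 sequences.  The odd limb of odd counts is unpaired,
on a random side, offset so it mirrors no existing root.  Sprouts are
straightened along with their parents.

## Experiment designs

Counts follow the study design exactly: 400 pairs per Experiment 1
condition (20 × 4 × 5, read as pairs), 500 Experiment 2 pairs, and 110
sequences = 550 shapes for Experiment 3, allocated as a balanced factorial
(5 limb counts × 2 sprouting conditions × 11 replicates; the original
split is not recorded, so balance is the natural default).  Experiment 2
shapes have two symmetric pairs (four first-order limbs); its
"asymmetrical" types use a fixed 0.10 displacement and its "straight"
types factor 0.05 — mid-to-extreme levels chosen once so the four types
are clearly separated.  Trial tables are seeded permutations with
randomized left/right placement.

## Cue measurement and the synthetic observer

The cue definitions are operationalizations owned by this package (they
make the generator's manipulations measurable; they are not claimed to be
the quantities human observers compute):

* **asymmetry** — mean over nominal pairs of the attachment offset from
  perfect mirror position (`|t_i + t_j − 1|` wrapped), a perimeter
  fraction; NaN when there are no pairs, rather than 0, to keep "no pairs"
  distinct from "perfect pairs".
* **curvedness** — mean unsigned turning angle (degrees) over first-order
  limbs; scales exactly with the straightening factor.
* **sprout prominence** — summed order-2 ribbon area / total silhouette
  area.

The observer pools evidence additively over parts: each pair contributes
its offset normalised by 0.125, each limb its straightness
(1 − mean|θ|/100°), sprouts their normalised area fraction.  The decision
variable subtracts a per-limb reference (0.9) so mid-morph shapes are
ambiguous at any limb count, and adds a small plant bias (0.3).  Additive
pooling is the substantive modelling choice here: more limbs carry more
evidence, so categorical transitions sharpen with limb count — the
mechanism behind the slope-by-limb-count pattern.  Ratings are
`logistic(signal + Gaussian noise)` (noise on the logit keeps ratings in
[0, 1] with a tractable likelihood); 2-AFC choices use the signal
difference between pair members with a lapse-adjusted logistic.  Defaults
(weights 1.0/1.0/1.5, noise 0.8, lapse 0.02) were set once to produce
psychophysically plausible performance levels — neither at ceiling nor at
chance.

**What the simulations show.**  With a plant-positive observer, the full
pipeline reproduces the qualitative pattern of the study: the displaced
member is preferred as "plant" in Experiment 1, the transplanted member in
Experiment 2, mean ratings rise monotonically across morph steps with an
overall plant-side bias (most steps carry asymmetry and sprouts), and
fitted slopes grow with limb count, with odd counts shallower than even.
These are pattern checks of the generator–observer loop, not fits to the
human data, which are unpublished; the synthetic observer shares only the
response *structure* (trial counts, response types) with the human
experiments, not human variability, individual differences, attention
lapses in time, or any image-level processing.

## Statistics

Standard steps are delegated to SciPy/statsmodels (exact binomial test,
`f_oneway`, `tukey_hsd`, `ttest_1samp`, logistic regression for weight
recovery); all are verified against brute-force oracles in the tests.  The
JZS Bayes factor is computed in-package by adaptive quadrature of the
Zellner-g mixture with a Cauchy scale of 0.707, and cross-checked against
an independent fixed-grid quadrature and against `pingouin`.  Psychometric
functions are four-parameter logistics (location, slope, guess, lapse,
the latter two bounded in [0, 0.5)) fitted by bounded maximum likelihood —
Gaussian for ratings, Bernoulli for choices — from three slope starts; a
deterministic MLE fit is used instead of a Bayesian psychometric package
deliberately: it is dependency-light and sufficient for slope/threshold
summaries.  Flat data return a zero-slope fit with a warning flag.
Degenerate inputs (zero variance) raise errors in the ANOVA and t-test
rather than returning 0/NaN silently.

## Problem sizes

The test suite regenerates the full designs (400 + 400 + 500 pairs, 110
sequences) once per session and runs 20 observer replicates for weight
recovery (5200 trials each; a 400-pair battery mixing the three pair types
so all three weights are identifiable) and 20 for the slope pattern —
small enough to run in well under a minute each on one CPU, at the study's
actual trial counts.

## Known limitations

* The silhouette is a polygonal approximation; closed-form checks
  (stadium area/perimeter) hold to ~1 % at default sampling.
* Sibling limbs may overlap; the original stimuli's collision policy is
  unknown, and no avoidance is attempted.
* The cheap-ring/quad-union fallback can very slightly change vertex
  counts for extremely curled limbs; areas are stable.
* Perimeter parameterization is piecewise linear on the body polygon;
  arc-length claims hold to the polygon, not to an idealised smooth curve.
* The observer has no spatial vision: it reads cue values off the
  geometry.  Nothing here bears on image-computable models of part
  segmentation.
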