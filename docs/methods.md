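# Methods

This note documents the models, conventions and numerical choices behind
`embryomorph`, in the spirit of the methods documentation of mature
morphometrics and simulation packages. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The landmark scheme

The catalogue holds 36 ectodermal surface landmarks for E10.5–E12.5 mouse
embryos: 6 midline points and 15 bilateral pairs, with integer ids 1–38 in
which 19 and 36 are unused. The gap is preserved without interpretation;
ids are opaque labels throughout and never array indices. The first-listed
member of each pair is designated *left*, its mate *right* — which
physical side is which is a convention, and every statistic treats the
sides symmetrically. Each landmark carries an anatomical subset (Nasal,
Maxillary/Mandibular, Non-Facial) and a *trouble* flag marking landmarks
with high placement error (labels 2, 7/24, 10/27, 13/30, 17/34, 18/35,
21/38). A second named constant records the stricter removal
recommendation (2, 7/24, 17/34, 18/35, 21/38); the remaining two trouble
labels are considered fixable by clarifying their definitions.

File formats: CSV with the fixed header
`specimen,age,observer,trial,landmark,x,y,z`, and 3D TPS (`LM3=` blocks,
`ID=specimen|age|observer|trial`), both with coordinates printed to 12
significant digits so round-trips are exact to well below 1e-9 mm.
Embryonic ages are categorical labels; no fractional-day arithmetic is
performed.

## The synthetic-data generator

No public embryo landmark coordinates accompany this design, so the
generator stands in for them. It emulates the *statistical* structure of
the study — not the anatomy. For observer o, trial t, specimen i of age a:

```
observed = true_i + bias(o, landmark) + N(0, sigma_trial(o)^2 I_3)
true_i   = CS_i * base + slope * (CS_i − mean CS) * V + N(0, sigma_specimen^2 I_3)
```

where `base` is a hand-placed, bilaterally symmetric 36-point head shape
scaled to unit centroid size (+x rostral, +y left, +z dorsal; midline at
y = 0). The geometry is stylized: only its topology (midline vs bilateral,
facial vs non-facial placement) and millimetre scale are meaningful. Its
scale is loosely anchored to the ~0.13 mm nasal-ridge dimensions of real
embryos of this age; no anatomical fidelity is claimed.

Parameter defaults and rationale (all in mm unless noted):

| parameter | default | rationale |
|---|---|---|
| specimens per age | 10 / 9 / 10 | the study design |
| observers, trials | 4 (3 experienced + 1 novice), 2 | the study design |
| growth targets (CS) | 5.0 / 6.5 / 8.5 | head spanning ~2–4 mm across these ages |
| `sigma_trial` | 0.02 experienced, 0.05 novice | median trial distance is `sqrt(2)·sigma·chi(3) median ≈ 2.18 sigma`, i.e. ~0.044 mm for experienced (well under the 0.1 mm reference, near 0.05) and ~0.11 mm for the novice (above it) |
| `observer_bias_scale` | 0.03 | stable per-(observer, landmark) interpretation offsets; gives interobserver centroid sizes of ~0.08 mm for three observers. May be a per-observer tuple: heterogeneous magnitudes are what create a true observer main effect in the placement ANOVA (a common scale produces none, because deviations from the across-observer mean are centred) |
| `trouble_inflation` | 2.5 | multiplies bias and noise s.d. at trouble landmarks, pushing their medians past the 0.1 mm reference while the rest stay clearly under it |
| `size_cv` | 0.03 | within-age centroid-size variation |
| `sigma_specimen` | 0.05 | per-coordinate biological shape variation between specimens |
| `allometry_slope` | calibrated | see below |

The allometric direction `V` (a unit vector over all 3k coordinates)
emulates the qualitative ontogenetic trend: facial landmarks move
rostrally and toward the midline (midline facial points also ventrally),
non-facial landmarks caudally and dorsally. It is mirror-symmetric,
zero-mean per axis and orthogonalized against the seven similarity
directions (translations, scaling, rotations) of the base shape, so the
injected signal survives Procrustes superimposition essentially intact.

The default slope is calibrated by a closed form so that the allometric
signal accounts for 80% of the total shape variance of the analyzed
per-specimen mean shapes: the non-allometric variance counts
`sigma_specimen^2` plus the measurement error surviving the averaging over
the experienced observers' trial means (`bias^2/m + trial var/(m t)`,
inflation-weighted), and the signal variance is `slope^2 · Var(CS)` at the
nominal design sizes. Because the injected displacement is in mm while
Procrustes shapes are unit-size, the realized shape offset scales as
`(CS − mean CS)/CS`, so the score–size relation is close to, but not
exactly, linear — mirroring the "roughly linear" association seen in real
data.

All randomness flows from one integer seed through NumPy's PCG64
(`numpy.random.default_rng`); a fixed (parameters, seed) pair reproduces a
dataset bit for bit, and the ground truth (templates, true shapes, biases,
direction, slope) is recorded exactly.

What the generator does **not** emulate: spatially correlated placement
error, age- or surface-dependent error anisotropy, nonlinear growth,
fixation artefacts, or real anatomical covariance between landmarks.
Passing tests therefore demonstrate that the *pipeline* recovers what was
injected under the design's sample sizes and noise levels — not that real
embryos behave this way.

## Error analysis

Intraobserver error requires exactly two trials and is the per-landmark
Euclidean distance between them; left/right values of a bilateral pair are
pooled under the pair label (values kept, label merged). Interobserver
error averages each included observer's trials and takes the centroid size
of those observer-mean points, sides separate; it is invariant to observer
relabelling and global translation.

The placement ANOVA deliberately includes **all four observers** and
averages each observer's two trials into a single observation per
(specimen, landmark, observer) cell — the only reading consistent with
residual degrees of freedom 1392/1249/1392 for 10/9/10 specimens, 36
landmark instances and 4 observers. Bilateral landmarks enter as separate
instances (landmark df 35). The response is the deviation *distance* (not
the coordinates; no multivariate Procrustes ANOVA is attempted), the model
is additive main effects with sequential sums of squares (identical under
every factor ordering because the design is balanced; asserted on every
run together with the SS decomposition and df-sum identities), and
p-values are raw — no multiple-testing correction. The fit is delegated to
statsmodels OLS/anova_lm; tests verify it against an independent
projection-matrix oracle. Degenerate (zero-variance) responses report
`None` p-values. Unbalanced tables are rejected rather than approximated.

Trouble flagging: a landmark is flagged when its median intraobserver
error exceeds 0.1 mm at any age for any included observer, or when its
median interobserver centroid size at some age exceeds both the 0.9
quantile of per-landmark medians and an absolute 0.1 mm floor. The floor
prevents a uniformly-low-error dataset from flagging its top decile; the
quantile keeps the criterion adaptive. Both thresholds are configurable.

## Procrustes machinery

Full GPA with scaling to unit centroid size; raw centroid sizes are kept
separately as the downstream regressor. Rotations are always proper
(determinant +1, smallest singular-vector pair sign-flipped if needed)
because embryo heads are chiral — a mirror-image target leaves a positive
residual by design. Convergence: consensus RMS change < 1e-10, at most 100
iterations, first consensus = first shape after centering/scaling (order
dependence is limited to a global rotation and covered by an invariance
test). Tangent-space projection at the consensus is available as an option
but off by default: at the shape dispersions produced here its effect is
negligible.

The baseline superimposition registers a shape to the frame of three
anchor landmarks (first anchor at the origin, second on +x, third in the
xy-plane with +y), giving subsets that share the anchors parallel axes.
The default anchors are (1, 8, 22) — the three non-trouble Non-Facial
landmarks. They are present in every canonical subset except the one that
removes the Non-Facial group (only two midline landmarks survive both the
trouble and nasal removals, so a purely midline anchor triple does not
exist).

## Allometry and the subset experiment

Specimen shapes entering the regression are per-specimen means over the
experienced observers' trial means (configurable); all ages are pooled
into a single superimposition, and the regressor is raw centroid size in
mm (not log). Percent variance explained is `100·SS_pred/SS_tot` over all
shape coordinates; regression scores are projections onto the
unit-normalized coefficient vector.

The subset experiment refits after removing each landmark group (the
7-label trouble column — not the 5-label removal list — plus the three
anatomical subsets). Subsets containing the anchors are registered by the
baseline superimposition (scaled by the subset configuration's centroid
size, regressed on the same); the anchor-less Non-Facial-removed subset
falls back to GPA (configurable to an error instead).

Comparing slope fields across superimpositions is frame-sensitive: an
anchored frame suppresses displacement near the anchors, and a subset GPA
absorbs the similarity component of the restricted signal. The angle
metric therefore registers each fit's *predicted configurations* at its
smallest and largest centroid size onto the all-landmark fit's predictions
(ordinary Procrustes over the shared landmarks) and compares the
registered per-landmark displacement vectors. Angles are reported as NaN
where the reference displacement is shorter than 10% of the median — a
direction is not meaningful for a near-zero vector (this also covers
anchor landmarks, whose displacement is identically zero in their own
frame). The angle threshold used in tests (15 degrees) is this package's
operationalization of "does not grossly change"; no significance test of
vector angles is attempted.

## Pipeline

A run is fully determined by (config, seed): outputs are written under a
directory named by the config hash, contain no timestamps, and reproduce
byte for byte. Stages execute in the study's order (errors → ANOVA →
flagging → subset allometry); a stage failure aborts with the stage name,
leaving completed outputs on disk. Exit codes of the CLI: 0 success, 2
config error, 3 data/design error, 4 numerical failure.

## Problem sizes

Replicate studies (observer-effect power, null calibration) simulate a
single-age design (10 specimens × 36 landmarks × 4 observers × 2 trials)
per replicate — 100 replicates for power, 200 for the null — and the
allometry recovery uses 20 replicates of the full 29-specimen design;
these sizes give stable rates while keeping any run to seconds or a few
tens of seconds.

## Known limitations

- The template geometry is stylized; conclusions about particular
  anatomical landmarks do not transfer to real embryos.
- The angle metric and the 10% displacement floor are this package's own
  operationalizations; other choices (e.g. comparing raw slope fields in a
  shared GPA) give systematically different numbers.
- Observer bias is modelled as fixed per-(observer, landmark) offsets;
  real interobserver differences may drift over time or depend on the
  specimen.
- No missing-landmark estimation, sliding semilandmarks, or
  object-symmetry decomposition; datasets must be complete and balanced.
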