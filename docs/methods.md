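# Methods

This note documents the models, numerical choices and open design decisions
behind `jawprobe`, and what the synthetic experiments do and do not show.

## Kinematic measures

All measures are ratios of inter-landmark distances and are therefore
invariant under translation, rotation and uniform scaling of the image
coordinates (verified property-based in the test suite). Coordinates are 2-D
image pixels, x rightward and y downward; only the *sign* of lateral
deviation depends on this convention, and the analysis uses its absolute
value.

**Mouth-opening ratio.** Implemented exactly as the clinical description has
it — mouth width (between the cheilion landmarks) divided by mouth height
(between stomion superius and inferius). This orientation *decreases* as the
mouth opens and diverges at full closure; the height denominator is floored
at `1e-3 ×` facial width so a closed mouth yields a large finite value
rather than an infinity. Whether the original analysis guarded this
singularity is unknown; a `height_over_width` convention is available as a
configuration switch, and because downstream features are z-scores of
within-interval ranges, either convention carries the same information.

**Pogonion lateral deviation.** The facial midline is fixed from the *rest*
posture as the perpendicular bisector of the exocanthion pair; per frame the
signed distance of the pogonion from that line is taken in absolute value
and divided by facial width — the mean of the three bilateral rest distances
(zygion, tragion, exocanthion). The landmark set is dictated by the
clinical protocol; the combination rule (perpendicular bisector, mean of
three widths) is this package's choice, as no combination is specified
anywhere.

**Rest posture.** How "rest" was captured clinically is not documented. In
the file format, rows with `frame = -1` designate the rest posture; when
absent, the loader falls back to the first frame of that participant's "Um"
production (a near-closed posture) and logs the fallback.

**Time normalization and velocity.** Raw 60 frames/s series are linearly
interpolated onto 1000 equally spaced points of normalized time [0, 1]
(`np.interp`; endpoints preserved exactly; idempotent). Velocity is the
first derivative of the *normalized* series — central differences inside,
one-sided at the endpoints (`np.gradient`), per unit normalized time.
Computing velocity before or after normalization is an undocumented detail
of the original workflow; this package normalizes first, because features
are z-scored across participants so absolute time units cancel, and
resampling after differentiation would alias frame-rate noise. No smoothing
is applied by default (none is documented); an optional moving-average
window is exposed.

**Sub-periods and range of motion.** Each (word, criterion) pair has
expert-defined sub-period intervals in percent of word duration (packaged as
`data/subperiods.yaml`, overridable). On the 1000-point grid, an interval
[a, b] selects the closed index range `ceil(a/100·999) … floor(b/100·999)`.
"Range of motion" is `max − min` within the interval — the standard
kinematic usage and the only definition requiring no extra parameters, as
none is given in the source protocol. *Papa* carries two gestures and two
intervals; all other words one.

## Feature construction

The classification feature for (participant, word, criterion, measurement)
is the mean over the word's intervals of |z|, where each interval's range of
motion is z-scored against the mean and sample SD (n−1) of the same
quantity over all *other* participants scored appropriate (1) on that
criterion and word. Decisions worth recording:

* the averaging in "average absolute z" runs over sub-period intervals —
  the only plural quantity in scope (it matters only for *Papa*);
* reference statistics are computed per interval, not pooled, so Papa's two
  gestures are compared like-for-like;
* participants scored inappropriate still receive features (they are the
  classification targets); only the *reference pool* is score-filtered;
* the reference pool always excludes the participant being featurised, so a
  participant's feature never depends on their own range of motion or score
  (asserted as a property test);
* a reference pool smaller than 2, or with zero spread, is an error
  (`DegenerateReferenceError`), not an imputed value.

The published word-level confusion matrices total 540 = 54 × 10
observations although the accompanying text describes building features
from the 41 TD participants only; the package computes features for
whichever cohort subset it is given and leaves this discrepancy to the
caller — both subsets are supported.

## Classification schemes

Both schemes use scikit-learn logistic regression with an elastic-net
penalty; mixing ratio 0 is ridge, 1 is lasso; "strength" is the penalty
weight λ (scikit-learn's `C = 1/λ`). Solvers: liblinear for the pure-lasso
and pure-ridge ends, saga for intermediate mixes; tolerance 1e-8, max
10 000 iterations; fits are deterministic given the data and seed. liblinear
penalises the intercept, so `intercept_scaling = 100` is set and, when a
penalty shrinks every slope to zero, the intercept is replaced by its
closed-form unpenalised MLE — this restores the λ → ∞ limit (intercept-only
model predicting the majority class, or a 0.5 tie under balanced weighting).
The decision threshold is a predicted probability of 0.5, ties resolved to
the positive (inappropriate / SSD) class. A LOOCV training fold that loses
the only member of a class predicts the remaining class.

**Default grid.** Mixing ratios {0, 0.25, 0.5, 0.75, 1}; strengths 10⁻²…10²
in 9 logarithmic steps; class weighting {none, balanced}. No grid is
documented for the original analysis; this one spans the usual elastic-net
working range.

**Hyperparameter placement.** Following the original design, hyperparameters
are selected *once* by maximizing the LOOCV balanced accuracy on the full
dataset and then frozen for the reported LOOCV predictions. This is
optimistic — the selected score is a maximum over grid entries of a
cross-validated statistic, and the original authors themselves read their
atypical precision–recall profile as a lack of generalisability. A stricter
nested mode (`StackedDiagnosisModel.fit(nested=True)`) re-tunes inside every
outer fold.

**Stacked tuning order.** Tuning "at both levels" jointly is combinatorial
(|grid|² scheme evaluations), so the package tunes sequentially: each
criterion model by its own LOOCV balanced accuracy, then the meta level by
full-scheme LOOCV with the criterion level frozen. Level-one models do not
depend on the meta entry, so their LOOCV folds are computed once and shared
across the meta search. The meta-classifier consumes criterion-model
predicted *probabilities* (preserving ranking information for
precision–recall curves); hard labels are a configuration switch.

## Evaluation

Balanced accuracy = (sensitivity + specificity)/2; balanced precision =
(PPV + NPV)/2; undefined quantities (an empty true or predicted class)
raise rather than impute. Precision–recall curves enumerate every distinct
probability as a threshold (prediction positive at probability ≥ threshold),
ties grouped. Report-parity rounding is 2 decimal places, half-up.

**Significance thresholds.** The null model behind the published thresholds
is not specified. The default here is a *fixed-margin permutation*: the
observed number of predicted positives m is assigned to a uniformly random
subset of the N cases, making the true-positive overlap hypergeometric; the
sampler draws that overlap count directly, and a separate exact enumeration
(pmf-weighted quantile over achievable statistic values) provides the
closed-form cross-check. The threshold is the empirical (1−α) quantile
(order statistic at ⌈(1−α)·n_runs⌉), default 10⁶ runs, α = 0.01;
"significant" requires strictly exceeding the threshold. At the published
margins (N = 54, K = 13, m = 22) the enumeration gives 0.688 (balanced
accuracy) and 0.642 (balanced precision); the published 0.729 / 0.661 fall
within one discrete step of the achievable statistic grid — bracketed, not
matched, and not matchable without knowing the original null. A
`bernoulli_rate` null (independent predictions at a fixed rate) is provided
as an alternative; its undefined runs (empty predicted class) are discarded.

## Group statistics

Cohen's d uses the (n−1)-weighted pooled SD; this reproduces the published
table values 0.96 (jaw range), 0.94 (voicing transitions), 0.80 (percent
total), 1.10 (PVC) and 1.27 (PPC) at 2 dp, and the jaw-range CI
(0.31–1.61) via `d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`. Two printed
values are *not* reproducible from the printed summaries and are treated as
source inconsistencies, not targets: the PCC d (printed 0.83; the formula
gives 0.87) and the prose effect sizes for jaw control/phase/syllable
structure (0.47/0.37/0.35, vs 0.54/0.41/0.41 from the table summaries).
The normality gate is Shapiro–Wilk p > 0.05 *and* standardized skewness and
kurtosis within ±1.96, using the standard large-sample SE formulas (the SPSS
convention; the exact convention used originally is unstated). Mann–Whitney
U is reported as min(U₁, U₂) with midrank ties and a continuity-corrected
normal p (scipy). Alpha is 0.05 with no multiplicity adjustment, matching
the deliberately type-II-protective design.

## Synthetic cohort generator

**Score sheets.** Each of the 50 entries is an independent Bernoulli draw
with a per-criterion, per-group probability; the defaults are the published
group mean criterion totals divided by 10 (TD: .829/.695/.654/.907/.976;
SSD: .646/.538/.523/.792/.954), with 41 TD and 13 SSD participants.
Independence across words and criteria is a simplification — real sheets
have word-difficulty structure and within-child correlation — so synthetic
cohorts are somewhat *easier* to classify than real ones at matched
marginals; recovery results bound what the pipeline can do under its own
assumptions, not clinical performance.

**Trajectories.** Mouth height follows one raised-cosine bump per syllable
(smooth, band-limited, zero-velocity endpoints; *Papa* has two), on a static
face whose bilateral distances average exactly the configured facial width.
Flags modulate generation deterministically: an inappropriate jaw-range flag
multiplies the opening amplitude by `range_scale_inappropriate` (default
0.5); an inappropriate jaw-control flag adds per-frame Gaussian amplitude
noise (modulated by the gesture envelope so the mouth still closes cleanly)
and widens the pogonion lateral noise SD. A between-production amplitude SD
(`amplitude_between_sd`) gives appropriate productions realistic
participant-to-participant variation — without it all appropriate
trajectories would be identical and every reference pool degenerate. The
generator does not simulate voicing, phase or syllable-structure kinematics
(perceptual flags only), head motion, tracking error, or amplitude–duration
covariation.

**Coupling.** `generate_cohort(..., coupling=p)` copies each kinematic flag
from the participant's perceptual score with probability p (else flips it):
coupling 1 gives perfectly agreeing kinematics, coupling 0.5 makes them
independent, putting downstream word-level classification at chance.

## Simulation study conditions

Chosen once at desk scale and then fixed:

* *Word-level recovery* runs on 41/13 cohorts with the strong-effect
  parameter set (`strong_effect_params`: range scale 0.3, between-production
  amplitude SD 0.01, lateral SDs 0.003/0.03, amplitude jitter 0.05) and a
  fixed single-entry grid (ridge, strength 1, balanced) in both the
  coupled and uncoupled arms. Fixing the hyperparameters isolates the
  properties under test — near-ceiling recovery with coupling 1, chance with
  coupling 0.5 — from grid-search selection optimism, which at chance biases
  the maximized LOOCV balanced accuracy upward by a few points and is a
  property of the tuning procedure, not of the features.
* *Stacked-diagnosis replicates* (50 seeds in the test suite, 25 in the
  acceptance script) use `replicate_grids()`: criterion level mix {0, 1} ×
  strength 1 × balanced; meta level mix {0, 1} × strengths
  {0.1, 1, 3.16, 10} × {balanced, none}. The full default grid behaves
  similarly but costs two orders of magnitude more per replicate (its
  interior-mix entries require the slower saga solver at tolerance 1e-8);
  each replicate's significance is judged against the exact fixed-margin
  threshold at that run's own predicted-positive margin, α = 0.01.
* Monte-Carlo thresholds use 10⁵ runs in tests and 10⁶ in the acceptance
  script; the hypergeometric enumeration is exact and run-count-free.

## Known limitations

* The mouth-opening ratio's closure singularity is floored, not modelled;
  analyses of words with long closed phases should prefer the
  `height_over_width` convention.
* Landmark-tracking quality is out of scope: coordinates are consumed as
  given, with no gap-filling or outlier handling beyond validation errors.
* The stacked scheme's meta-classifier is trained on in-sample criterion
  probabilities within each outer fold (classic stacking leakage at level
  one); with n = 53 training cases and heavily regularised level-one models
  the effect is small, and the nested mode does not remove it (only a
  further internal split would).
* Synthetic cohorts draw score-sheet entries independently; replicate-level
  results quantify pipeline behaviour under that assumption, not expected
  performance on real clinical cohorts.
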