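# Methods

## The stimulus space

A sequence of `n` pulses is summarized by five temporal features: total
event duration (TED, the summed pulse time), mean event duration (MED =
TED/n; for regular trains this equals the individual event duration),
total stimulus duration (TSD, first onset to last offset), mean event
period (MEP = TSD/n) and coverage (Cov = TED/TSD).  Because these features
covary with numerosity, the package parameterizes stimuli instead by two
composite axes that are orthogonal to numerosity in log space:

    Dur  = TED × MED        (intrinsic: how much pulse time per event)
    TmSp = TSD × MEP        (extrinsic: how spread out the train is)

Inverting gives the square-root feature map (TED = √(Dur·n), MED =
√(Dur/n), TSD = √(TmSp·n), MEP = √(TmSp/n), Cov = √(Dur/TmSp)).  In log₂
coordinates every feature is a half-weight linear combination of
(log n, log Dur, log TmSp), and feature *ratios* between two stimuli obey
the same half-weight relations.  All logarithms in the package are base 2;
the base only rescales GLM coefficients and is documented wherever
coefficients are reported.  `Dur` and `TmSp` carry frames² at a
configurable frame rate (default 60 Hz); millisecond values are computed
views, never stored.

For irregular sequences we take Dur = TED × MED throughout (MED and the
individual event duration coincide only for regular trains, so no separate
IED type exists).

## Sequence realization

A stimulus is a 0-based integer-frame timestamp train.  Targets TED and
TSD−TED are rounded to whole frames, then split into `n` event durations
in [2, 16] frames and `n−1` gaps in [3, 30] frames (33–267 ms and
50–500 ms at 60 Hz, above visual and auditory temporal-resolution
thresholds).  The bounded composition samples each part uniformly on the
interval that keeps the remainder feasible and then shuffles; the induced
distribution over compositions is *not* uniform — only the bounds and sum
are guaranteed, which is all the design requires.  Frame rounding bounds
the log₂ discrepancy between achieved and target features at ≈0.02 for the
default grid.  A feasibility verdict (`n·dmin ≤ round(TED) ≤ n·dmax` and
`(n−1)·gmin ≤ round(TSD−TED) ≤ (n−1)·gmax`) gates every realization;
infeasible grid combinations are rejected and resampled during dataset
construction.

## Grids, pairs and the balanced subsample

Each cardinal dimension takes 13 levels evenly spaced on a log scale over
a 1:4 range.  Numerosity runs 7–28 and is rounded to distinct integers
(7, 8, 9, 10, 11, 12, 14, 16, 18, 20, 22, 25, 28).  The Dur and TmSp
anchors are free parameters of the design; the defaults, Dur ∈ [252,
1008] frames² and TmSp ∈ [1487, 5948] frames², were calibrated once so
that (a) MED spans 3–12 frames, safely inside the 2–16 event bound, and
(b) realized total stimulus durations at 60 Hz span 1.70–6.80 s, the
intended presentation window.  A comparison pair draws, independently per
dimension, an index distance of 1–6 grid steps (ideal ratio 4^(1/12) ≈
1.12 up to exactly 2) with random sign and placement.  Ratio constraints
are enforced on the ideal (continuous) grid values; integer-rounded
numerosity pairs can deviate marginally (12:11 = 1.09, 25:12 = 2.08).

The per-participant subsample must balance the 12 signed index-distance
bins of *all three* dimensions simultaneously (ten pairs per bin at
m = 120) while covering each dimension's extreme levels.  This coupled
balance is solved by a randomized best-swap local search on the bin-count
deviation objective (milliseconds per draw; used for the thousands of
fresh subsamples in power simulations), with an exact binary-integer
program (HiGHS via `scipy.optimize.milp`) as a fallback and as an
independently testable reference method.  Extreme-level coverage is then
restored, if needed, by swaps between pairs with identical bin profiles,
which cannot disturb balance; if a particular draw admits no such repair,
the selection is redrawn (small subsamples may legitimately fail, in which
case the error names the deficient bins).

## Simulated observers

An observer chooses the second interval with probability
`λ/2 + (1−λ)·Φ(β₀ + β_Num·x_n + β_Dur·x_d + β_TmSp·x_t)` on the trial's
log₂ ratios — the exact generative inverse of the analysis GLM, plus a
symmetric lapse λ (default 0, since the analysis model carries no lapse
term; recovery tests are therefore generative-model-faithful).  Cohorts
draw each coefficient from an independent normal; defaults are the
visual-modality group means and SDs, β = (1.89, −0.16, 0.24), SD = (0.53,
0.32, 0.40).  Response times are cosmetic — lognormal with a 900 ms median
(within the 878–1010 ms range of observed means) — and exist only to
exercise the screening rules.  Simulated sessions shuffle trial order and
carry a practice block when a practice pool is supplied.

What the generator deliberately does not emulate: sequential effects,
learning or fatigue drifts, RT–difficulty coupling, and cross-modal
transfer.  Passing recovery tests therefore shows the estimator is
faithful to the stated generative model, not that human data are free of
those ingredients.

## Response model

Per participant, a binomial GLM with probit link is fit by IRLS
(statsmodels; deviance tolerance 1e-8) to the test trials, with an
intercept capturing interval-order bias plus the three cardinal log-ratio
slopes.  One-sided response vectors and diverged estimates (|β| > 50) are
reported as separation errors rather than numbers.  Fit quality uses a
deviance-based adjusted pseudo-R²,
`1 − (D_res/(n−4)) / (D_null/(n−1))`, and a 3-df likelihood-ratio test
against the constant model.  Note the adjusted form is slightly negative
(−3/(n−4)) when the model explains nothing, and 1 for perfect prediction.

The slope triple is the discrimination vector.  Its angle from the
numerosity axis is `arccos(β_Num/‖β‖)` (nondirectional in the sense of
ignoring the orientation of the bias components; a negative β_Num yields
angles beyond 90°).  Feature lines are the unit-normalized half-weight
directions (numerosity (1,0,0); TED (1,1,0)/√2; MED (−1,1,0)/√2; TSD
(1,0,1)/√2; MEP (−1,0,1)/√2; Cov (0,1,−1)/√2) and projections are plain
dot products, so a pure-TED reader with gain c projects to c√2 on the TED
line — strictly above its own β_Num = c, the diagnostic signature used in
the projection contrasts.

### A note on finite-sample bias

The probit MLE is consistent but biased away from zero in finite samples:
at 120 trials with |β| ≈ 1.9 the mean recovered β_Num runs ≈6% high,
shrinking to <1% by 2000 trials.  This is a property of maximum likelihood
in binary regression, not of the implementation (the estimates match an
independent brute-force likelihood search to 1e-3); analyses comparing
coefficient *magnitudes* across groups are unaffected at matched trial
counts, but absolute coefficient values at 120 trials should be read with
this bias in mind.

## Screening

Rules follow the printed exclusion ladder with "below"/"more than"
semantics (boundary values are kept): refresh rate ≠ 60 Hz; practice
accuracy < 50%; accuracy < 75% on catch trials (pairs at the maximal 2:1
numerosity ratio — on the default grid exactly the distance-6 pairs);
responses < 200 ms or > 4 s discarded, with participants excluded when
> 20% of test trials are lost (practice trials are excluded from the
denominator, configurable); adjusted pseudo-R² < 0.2.  A missing practice
block raises a flag rather than passing silently, and screening is
idempotent.

## Group statistics and power

Group tests are gated by Shapiro–Wilk at α = .05: Student t with Cohen's d
when normality is not rejected, otherwise Wilcoxon signed-rank (one-sample
and paired contrasts) or Mann–Whitney U (two-sample) with rank-biserial
correlation.  The five projection-vs-β_Num contrasts are Bonferroni
corrected (×5).  Tests are two-sided throughout.  Bayes factors for
t statistics use the JZS default Cauchy prior (scale 0.707) via adaptive
quadrature of the Zellner–Siow mixture (relative accuracy 1e-6, checked in
tests against dense-grid integration and against pingouin).

The power engine reports Monte Carlo rejection rates with Wilson 95%
intervals over a grid of cohort sizes.  Two engines are provided because
the generative assumptions of a power analysis are configuration, not
fact: `"draws"` samples per-subject coefficients directly from the
population normal (and so matches the noncentral-t closed form — e.g.
power 0.721 at d = 0.6, n = 20, α = .05), while `"pipeline"` runs the full
simulate → fit → test chain, whose type-I rate at β_Dur = β_TmSp = 0 and
n = 40 calibrates to ≈5%.

## Reproducibility and problem sizes

Every random consumer takes an explicit NumPy generator or a seed; the
pipeline spawns named child streams (dataset generation, practice pool,
simulation) from one master seed, so stages are independently
reproducible and two runs of a config produce byte-identical artifacts.
The shipped analyses use the study-scale sizes throughout: 500-pair
datasets, 120-trial balanced sessions, 200 replicate sessions for
parameter recovery, and 150–3000 Monte Carlo replicates for calibration
checks, chosen to hold Monte Carlo standard errors near or below the
tolerances being asserted.

## Known limitations

- Axes are physical, not perceptual: no just-noticeable-difference
  rescaling of the three dimensions is attempted.
- The composition sampler is not uniform over bounded compositions.
- No mixed-effects group model; group inference is two-stage
  (per-participant ML, then group tests on the estimates).
- Stimulus rendering (discs, tones) and presentation timing belong to
  presentation software; the package stops at frame timestamps.
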