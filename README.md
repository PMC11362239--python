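# seqnum

Tools for building **sequential numerosity comparison** experiments with
orthogonal control of temporal magnitudes, and for modeling the responses
they elicit.

When people judge which of two pulse trains (flashing discs, tone pips)
contains more events, their judgments can be biased by temporal quantities
that covary with numerosity: how long the pulses last, how widely they are
spread in time.  `seqnum` constructs stimuli in a three-dimensional log
space whose cardinal axes — numerosity *n*, duration *Dur* and temporal
spacing *TmSp* — are mutually orthogonal, while the familiar temporal
features are fixed linear combinations of them:

    TED = √(Dur·n)    total event duration     MED = √(Dur/n)   mean event duration
    TSD = √(TmSp·n)   total stimulus duration  MEP = √(TmSp/n)  mean event period
    Cov = √(Dur/TmSp) coverage (TED/TSD)

so that in log₂ coordinates every feature ratio between two stimuli is a
half-weight combination of the three cardinal ratios (e.g.
log r_TED = ½log r_Dur + ½log r_n).  Responses are then modeled per
participant with a **binomial GLM with probit link** on the second/first
log₂ ratios of the cardinal axes; the fitted slopes (β_Num, β_Dur, β_TmSp)
form a *discrimination vector* whose angle from the numerosity axis
measures non-numerical bias and whose projections onto the feature lines
identify single-feature strategies (a pure TED reader, for instance, shows
β_Num ≈ β_Dur and a TED projection exceeding β_Num).

The package covers the full workflow:

- `seqnum.feature_space` — exact algebra of the cardinal axes and derived features;
- `seqnum.sequence_gen` — integer-frame pulse trains under per-event (2–16
  frames) and per-gap (3–30 frames) bounds at 60 Hz;
- `seqnum.dataset_builder` — 13-level log grids (numerosity 7–28, 1:4
  ranges), ratio-constrained pairs (1.12–2 per dimension), the 500-pair
  dataset, balanced 120-pair subsamples, JSON/CSV serialization;
- `seqnum.observer_sim` — simulated probit observers with lapses, sessions
  and cohorts;
- `seqnum.response_model` — per-participant probit GLM, adjusted pseudo-R²,
  LR test, discrimination-vector geometry;
- `seqnum.screening` — the trial/participant exclusion ladder (refresh
  rate, practice and catch accuracy, response-time filtering, model fit);
- `seqnum.group_stats` — normality-gated group tests, Bonferroni
  correction, JZS Bayes factors, Monte Carlo power;
- `seqnum.cli_io` — YAML run configs, the end-to-end pipeline and the
  `seqnum` command line.

## Worked example

```python
import numpy as np
from seqnum import (build_dataset, subsample_balanced, ObserverParams,
                    simulate_session, fit_probit_glm)
from seqnum.response_model import discrimination_vector

dataset = build_dataset(500, seed=7)                      # 500 stimulus pairs
rng = np.random.default_rng(11)
session_set = subsample_balanced(dataset, 120, rng)       # one balanced session
observer = ObserverParams(beta_num=1.89, beta_dur=-0.16, beta_tmsp=0.24)
session = simulate_session(session_set, observer, rng)

fit = fit_probit_glm(session)
dv = discrimination_vector(fit)
print(f"betas  = {np.round(fit.betas, 3)}")
print(f"r2_adj = {fit.r2_adj:.3f}")
print(f"angle  = {dv.angle_deg:.1f} deg")
```

prints (with these seeds):

```
betas  = [ 1.954 -0.525  0.09 ]
r2_adj = 0.452
angle  = 15.3 deg
```

The observer was simulated with a strong numerosity coefficient and small
temporal biases; the single-session fit recovers slopes of that shape
(within one session's sampling noise), the adjusted pseudo-R² clears the
0.2 screening floor, and the discrimination vector sits ~15° off the
numerosity axis — a mildly temporally biased but number-driven strategy.  A full simulated study (cohort, screening, group
tests) runs from one config:

```sh
seqnum run --seed 1 --out out/demo
```

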