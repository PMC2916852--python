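# avloc

Bayesian causal inference for audiovisual spatial localization: forward
simulation, Monte-Carlo maximum-likelihood fitting, and per-observer
classification of perceptual decision strategies.

## The scientific problem

When a brief sound and a brief flash occur in close succession, an observer
implicitly infers whether they came from one object or two before deciding
where each was.  The causal-inference model formalizes this: on each trial
noisy sensations `x_A ~ N(s_A, σ_A²)` and `x_V ~ N(s_V, σ_V²)` are combined
with a central spatial prior `s ~ N(0°, σ_P²)` and a prior probability
`p_common = p(C=1)` of a common cause.  Bayes' rule gives the posterior over
causal structure,

    p(C=1 | x_A, x_V) = p(x_A, x_V | C=1) p_common /
                        [ p(x_A, x_V | C=1) p_common + p(x_A, x_V | C=2)(1 − p_common) ]

with closed-form Gaussian likelihoods for both structures, and closed-form
conditional location estimates: reliability-weighted fusion under C=1 and
single-cue shrinkage toward straight ahead under C=2.

The interesting question is what the observer *does* with the structure
posterior.  Three strategies are implemented:

- **model averaging** — report the posterior-weighted mixture of the two
  conditional estimates (minimizes expected squared error);
- **model selection** — commit to the more probable structure
  (posterior compared with a fixed 0.5 criterion, or a free criterion in
  the biased variant);
- **probability matching** — commit to the common-cause structure with
  probability equal to its posterior, via a fresh uniform draw per trial.

The strategies leave distinct fingerprints in the response distributions
(averaging is unimodal, selection/matching bimodal at moderate cue
conflicts), and each observer can be classified by fitting all three to
their trial-level data and comparing log-likelihoods.  This package is
aimed at psychophysicists who want to simulate such observers, fit the
model to localization data (real or synthetic), and run the strategy
classification with principled inclusion criteria.

Because the model attached to a decision strategy has no closed-form
response density, fitting uses simulation-based likelihoods: per condition,
the predicted response distribution is built from thousands of simulated
trials with common random numbers, binned at 1°, floored, and renormalized;
bounded multi-start Nelder-Mead maximizes the resulting deterministic
surface.  Goodness of fit is the Nagelkerke generalized R² against a
location-blind null model, and per-subject classifications are filtered by
the log-likelihood margin between the best and second-best strategy.

## Worked example

```python
from avloc import (MEAN_SUBJECT_PARAMS, classify_subject, fit_all_strategies)
from avloc.fitting import FitConfig
from avloc.synth import SyntheticSubjectSpec, build_design, generate_subject

# a synthetic probability-matching observer on the standard 525-trial design
spec = SyntheticSubjectSpec("demo", "matching", MEAN_SUBJECT_PARAMS, seed=42)
subject = generate_subject(spec, build_design(repetitions=15, seed=7))

fits = fit_all_strategies(subject, FitConfig(mc_samples=2000, restarts=4, max_evals=500, seed=3))
for name, fit in fits.items():
    print(f"{name:10s} loglik={fit.loglik:8.1f}  R2={fit.r2:.2f}")
result = classify_subject(fits, subject="demo")
print(f"winner: {result.winner}  margin: {result.margin:.1f}")
```

This prints (numbers from an actual run):

```
averaging  loglik= -2619.5  R2=0.83
selection  loglik= -2593.3  R2=0.84
matching   loglik= -2561.6  R2=0.85
winner: matching  margin: 31.7
```

The matching fit wins by ~32 natural-log units — far beyond the margin-3
inclusion cut — so the generating strategy is recovered decisively, and the
winning model explains ~85% of the response variance in the Nagelkerke
sense.

The same pipeline is scriptable from the shell:

```bash
avloc generate --n-per-strategy 5 --seed 1 --out cohort.csv
avloc fit cohort.csv --mc-samples 2000 --out fits.json
avloc classify fits.json --margin 3 --margin 10 --out-prefix cohort
avloc simulate --strategy matching --seed 0 --out-dir sims   # Fig-style panels
avloc recover --n-per-strategy 5 --seed 2 --out-dir recovery # end-to-end check
```

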