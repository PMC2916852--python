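# Methods

## Generative model

A trial presents a sound at azimuth `s_A`, a flash at `s_V`, or both.  The
observer receives noisy sensations `x_A ~ N(s_A, σ_A²)`, `x_V ~ N(s_V, σ_V²)`
(independent across trials and channels) and holds a central spatial prior
`s ~ N(0°, σ_P²)` plus a prior probability `p_common` that the two signals
share one cause.  Marginalizing the source location(s) gives closed-form
structure likelihoods

- `p(x_A, x_V | C=1) = exp(−½ [(x_A−x_V)² σ_P² + x_A² σ_V² + x_V² σ_A²]/D) / (2π√D)`
  with `D = σ_A²σ_V² + σ_A²σ_P² + σ_V²σ_P²`,
- `p(x_A, x_V | C=2) = N(x_A; 0, σ_A²+σ_P²) · N(x_V; 0, σ_V²+σ_P²)`,

combined by Bayes' rule into the structure posterior.  Conditional location
estimates are the Gaussian posterior means: reliability-weighted fusion of
both cues and the prior under C=1, single-cue shrinkage
`x · σ_P²/(σ_P² + σ²)` under C=2.  All likelihood arithmetic runs in log
space; the posterior is a logistic transform of the log-likelihood ratio,
so it stays in [0,1] at arbitrarily large cue conflicts.

The decision strategies map these to the trial's report: averaging takes the
posterior-weighted mixture; selection commits to C=1 iff the posterior
exceeds a criterion (0.5 unless the biased variant frees it); matching
commits to C=1 iff the posterior exceeds a fresh Uniform(0,1) draw ξ.  Two
conventions are fixed deliberately:

- **Tie-break.** At posterior exactly equal to the threshold, C=2 is chosen
  (strict inequality for C=1).  The event has measure zero; the convention
  only pins down reproducibility.
- **One structure per trial.** Selection and matching make a single
  structure choice that governs both the auditory and the visual report of
  a bisensory trial.  The inequality direction for matching (C=1 iff
  posterior > ξ) is likewise a convention; with ξ uniform, either direction
  yields matching behavior.
- **Unisensory trials** bypass causal inference and use the C=2 shrinkage
  rule with the stimulated modality's σ.

## Parameters

| parameter  | meaning                          | units | default | bounds in fitting |
|------------|----------------------------------|-------|---------|-------------------|
| `σ_A`      | auditory likelihood SD           | deg   | 10.1    | [0.1, 45]         |
| `σ_V`      | visual likelihood SD             | deg   | 2.5     | [0.1, 45]         |
| `σ_P`      | central-prior SD (mean fixed 0°) | deg   | 33.0    | [1, 200]          |
| `p_common` | prior probability of one cause   | —     | 0.57    | [0, 1]            |
| `criterion`| selection threshold              | —     | 0.5     | [0, 1] (biased variant only) |

The defaults are typical human-observer values for this task and double as
the generating parameters of the synthetic cohorts.  The bounds cover the
plausible psychophysical range with generous headroom.

## Synthetic data

The standard session is 5 auditory-only, 5 visual-only and 25 bisensory
conditions over azimuths {−13°, −6.5°, 0°, 6.5°, 13°}, 15 repetitions each,
pseudorandomly interleaved — 525 trials, 900 reports (bisensory trials give
two).  Reports are quantized at the 0.1° cursor resolution and clipped at
±67° (the screen's half-width).  No motor noise is added: response
variability comes entirely from sensory noise plus, for matching, the
stochastic criterion.  Between-subject heterogeneity, when requested, is
log-normal jitter on the σ's (geometric SD 1.25, ≈25% spread) and
logistic-normal jitter on `p_common` (logit-scale SD 0.5) around the typical
observer; the distribution of parameters across real observers is not well
characterized, so this sampler is a modeling choice.  Synthetic cohorts
therefore emulate the design, resolution, and trial counts of a real
session but not response-order effects, practice, lapses, attention drift,
or eccentricity-dependent noise — passing recovery tests shows the pipeline
is consistent, not that real observers satisfy the model's assumptions.

## Simulation-based likelihood

With a strategy attached, the model's response density has no closed form
(selection and matching are sensation-dependent mixtures), so the subject
log-likelihood is built by Monte Carlo:

1. per condition, simulate `mc_samples` trials (default 10,000, the same
   count used for the reference response-pattern figures; 2,000 in the
   reduced-scale recovery runs) using a **fixed** set of standard-normal and
   uniform draws per fit ("common random numbers"), so the likelihood is a
   deterministic function of the parameters;
2. bin the simulated reports at 1° over ±67°, add a floor of 1e−6 per bin,
   renormalize;
3. sum the log predicted probability of every observed report.  Observed
   reports outside the grid are clipped into the edge bins with a warning
   and counted in the fit diagnostics.

Bin width, floor, grid, and sample count are all exposed on `FitConfig`.
At the defaults, doubling `mc_samples` moves the log-likelihood at the
generating parameters by well under one unit.  The hot loop (sensations →
posterior → strategy rule → reports) is jit-compiled; a unit test pins the
compiled path to the readable reference implementation.

Optimization is bounded multi-start Powell search: the first start is the
typical-observer point, the rest are drawn log-uniformly (σ's) / uniformly
(probabilities) over the bounds; the best restart is polished by a second
search.  Powell's bracketing line searches matter here — the hard
threshold in the selection and matching rules carves staircase-like
plateaus into the common-random-numbers likelihood surface, on which
simplex methods stall tens of log-units short of the optimum.  Defaults
are 20 restarts × 400 evaluations; the recovery runs in the test suite use
4 × 500, which is enough for this likelihood at 525 trials.

## Goodness of fit and classification

Nagelkerke's generalized R² compares the fitted log-likelihood `L1` with a
null `L0` over the same `n` reports:
`R² = [1 − exp(−(2/n)(L1−L0))] / [1 − exp((2/n) L0)]`.  The null model is
deliberately weak and strategy-free: one Gaussian per condition type and
modality fitted to the pooled reports, ignoring stimulus locations, then
discretized on the same grid.  Negative R² (model worse than null) is
allowed and flags a failed fit.

A subject's winner is the strategy with the highest log-likelihood; the
margin is its lead over the runner-up in natural-log units.  The headline
tabulation includes a subject iff margin > 3 (substantial evidence), with
margin > 10 as a sensitivity regime and no-exclusion totals alongside.  The
margin is kept in natural logs; the threshold is configurable for anyone
preferring a log10 convention.  The biased-selection variant (free
criterion, 5 parameters) competes only in a dedicated analysis mode and is
penalized by BIC = k·ln(n) − 2·loglik.

## Mode diagnostic

"Unimodal vs bimodal" is operationalized by smoothing the binned response
distribution with a Gaussian kernel (bandwidth 1.5°, the visual stimulus
envelope scale) and counting local maxima whose prominence exceeds 20% of
the global maximum.  The prominence floor is what makes the taxonomy match
the strategies' qualitative descriptions: model averaging develops a
shallow (<10% deep) dimple at the extreme 26° conflict which is a shoulder,
not a second response mode, while the selection/matching modes stand clear
of their valley by 90%+.  Both diagnostic parameters are recorded in the
returned object.  With these settings, at the typical-observer parameters:
averaging is unimodal at every conflict, selection turns bimodal from 13°
conflicts, matching from ~20°, and selection's modes separate more cleanly
than matching's — matching can even show a segregated tail at zero conflict
because the stochastic criterion occasionally follows the independent
structure.

## Problem sizes and numerical notes

Recovery checks in the test suite use 20 subjects per strategy, 525 trials
each, fits at 2,000 Monte-Carlo samples per condition with 4 restarts —
sizes at which classification is already decisive (median margins in the
tens of log units) while the full suite stays comfortably runnable on a
laptop core.  Degenerate inputs are handled explicitly: `p_common` of 0 or
1 short-circuits the posterior, empty distributions and empty datasets
raise, and a report in a bin never visited by the simulation contributes
`log` of the floored probability rather than −∞.

## Known limitations

- The likelihood is fairly flat in σ_P at 525 trials (the prior SD trades
  off against p_common over a broad ridge); σ_V and p_common recover
  tightly, σ_A and σ_P with more spread.
- The null model's pooled-Gaussian choice is one of several defensible
  nulls; R² magnitudes should be compared only within a fixed null.
- The fitter assumes the response grid covers the data; reports beyond ±67°
  are clipped, which slightly flattens extreme-eccentricity likelihoods.
- No lapse/guessing process is modeled; real data with lapses will deflate
  R² and can blur strategy margins.
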