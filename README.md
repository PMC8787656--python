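# bsmaskit

Tools for studying how *classification schemes* for problematic social media
use behave against a *data-driven benchmark*.

The Bergen Social Media Addiction Scale (BSMAS) asks six questions — one per
core addiction symptom: salience, tolerance, mood modification, loss of
control, withdrawal, conflict — each rated 1 ("very rarely") to 5 ("very
often"). To turn the six ratings into a yes/no screen, applied studies cross
two choices:

* **criterion cutoff** — an item counts as "symptom present" at ≥ 3 (the
  scale midpoint) or, stricter, at ≥ 4;
* **counting rule** — **monothetic** (all six criteria required) or
  **polythetic** (more than half, i.e. ≥ 4 of 6).

That yields four schemes (strict monothetic, strict polythetic, monothetic,
polythetic) whose prevalence estimates differ by an order of magnitude on
the *same* respondents. `bsmaskit` implements the full evaluation workflow
a prevalence-methods study needs:

1. **Synthetic cohorts** (`bsmaskit.simulate`) — respondent tables drawn
   from a three-tier latent mixture (low / at / high risk) with realistic
   demographic margins and class-linked depression (CES-D) and anxiety
   (STAI) totals, so every stage is testable without survey data.
2. **Schemes** (`bsmaskit.schemes`) — dichotomization, counting rules,
   prevalence, overall and per stratum.
3. **Latent profile analysis** (`bsmaskit.lpa`) — diagonal Gaussian
   mixtures fit by multi-start EM; BIC / sample-size-adjusted BIC / AIC;
   relative entropy; an approximate adjusted likelihood-ratio test; a
   parametric **bootstrap likelihood ratio test** whose replicates pass
   through the same 1–5 rating observation filter as the data; a
   rule-based class-count selection with an audit trail; risk-tier
   labeling.
4. **Benchmarking** (`bsmaskit.benchmark`) — sensitivity, specificity,
   positive/negative predictive value and overall consistency of each
   scheme against the latent high-risk tier.
5. **Comorbidity** (`bsmaskit.comorbidity`) — probable-case screening
   (CES-D ≥ 16, STAI ≥ 40), risk ratios at scheme / demographic / single
   criterion level, one-tailed Welch group contrasts, Cronbach's α.
6. **Pipeline + CLI** (`bsmaskit.pipeline`, `bsmaskit.cli`) — one seeded,
   bit-reproducible run from cohort to report bundle.

## The model at the core

Latent profile analysis treats the six ratings of respondent *i* as
continuous indicators that are independent given a latent class
*c<sub>i</sub>* ∈ {1…K}:

    x_i | c_i = k  ~  ∏_j N(μ_kj, σ_j²)        (class-invariant variances)

fit by EM over K = 2…5. Model choice follows the applied-LPA protocol:
candidates with relative entropy < 0.80 are dropped; among the survivors
the chosen K must improve on K−1 by a significant likelihood-ratio test
while K+1 brings no further significant gain; ties resolve to the smaller K.
Because Likert ratings are coarse, a naive bootstrap LRT rejects for every
K (an extra class can always model the discreteness); the bootstrap here
therefore simulates replicates from the null model *composed with the
observation filter* (round to integers, clip to 1–5), with latent moments
recovered by inverting that filter. The chosen class solution, coded
high-risk vs rest, is the benchmark each scheme is scored against.

## Worked example

```bash
python examples/03_latent_profiles.py
```

prints (seeded UK-like cohort, n = 573):

```
             loglik       bic    ssabic       aic  entropy  lmr_p  blrt_p
n_classes
2         -4152.932  8426.531  8366.214  8343.864    0.935    0.0   0.048
3         -3793.909  7752.941  7670.402  7639.818    0.956    0.0   0.048
4         -3747.980  7705.540  7600.779  7561.961    0.939    0.0   0.810
5         -3712.738  7679.511  7552.528  7505.476    0.919    0.0   0.143

chosen K = 3
class weights (low -> high): [0.577 0.32  0.103]
class mean profiles (low -> high):
[[1.32 1.36 1.31 1.33 1.29 1.29]
 [2.88 2.83 2.97 1.93 1.94 1.79]
 [3.55 3.62 3.74 3.57 3.57 3.68]]
```

Reading it: information criteria keep falling with K (they always do on
discretized ratings), but the observation-filtered bootstrap LRT goes
non-significant at the 4-class model, so three tiers are retained — a
majority low-risk floor profile, an at-risk tier elevated only on the
first three symptoms, and a ~10% high-risk tier above the midpoint on
every symptom. `examples/04_scheme_benchmark.py` then scores the four
schemes against that benchmark, and `examples/02_classification_schemes.py`
shows the prevalence spread (0.3% → 15.9% across schemes on one seeded
cohort). The other examples cover simulation, comorbidity risk ratios, and
the end-to-end pipeline.

The same workflow is available from the shell:

```bash
bsmaskit simulate --preset uk --n 573 --seed 42 --out cohort.csv
bsmaskit analyze --input cohort.csv --seed 7 --outdir out/run1
```

`out/run1/` then holds the fit report, prevalence / concordance /
descriptives / risk-ratio tables, per-respondent assignments, the
selection audit trail and a manifest that reproduces the run byte for
byte.

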