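# Methods

This note documents the statistical model, the synthetic-data design, the
numerical choices, and the limitations of `bsmaskit`, in the order a reader
would meet them in the pipeline.

## 1. Data model

One row per respondent: six BSMAS item ratings (integers 1–5; salience,
tolerance, mood modification, loss of control, withdrawal, conflict), sex,
age band (18–34 / 35–49 / 50–65), a CES-D depression total (0–60) and a
STAI state-anxiety total (20–80). Input validation rejects rows outside
these domains with row-level reasons; nothing is imputed.

## 2. Synthetic cohorts

The generator emulates the structure such survey samples repeatedly show:
a finite mixture of risk tiers with distinct mean symptom profiles.

* **Latent class** drawn from mixture weights. The UK-like preset uses
  weights (0.55, 0.331, 0.119), the US-like preset (0.622, 0.287, 0.091).
* **Ratings**: for class k, item j, a normal deviate N(μ_kj, s_kj²)
  rounded to the nearest integer and clipped to [1, 5]. Round-and-clip was
  chosen over an ordinal-threshold (graded response) model for simplicity;
  it preserves the ordering of class means, which is the property the
  pipeline relies on. Latent item SDs are 0.5 in the low-risk tier (whose
  observed distribution is floor-compressed) and 0.8 elsewhere — values in
  the usual range for 5-point Likert items; the class mean profiles place
  the low tier near the response floor, the at-risk tier near the midpoint
  on the first three symptoms only, and the high tier above the midpoint
  (on all six items in the UK-like preset; on four of six in the US-like
  preset, whose high tier is defined by salience, tolerance, mood
  modification and withdrawal).
* **Comorbidity scores**: class-conditional normals, rounded and clipped
  to the instrument range. The low and at-risk means are chosen so their
  mixture average reproduces the pooled "low-to-at-risk" moments that
  such studies report (e.g. UK CES-D: 14.0 and 18.5 pooling to ≈15.75).
* **Demographics**: sex and age band are drawn independently of class
  from the preset margins; an optional per-class age distribution
  (`age_splits_by_class`) exists because prevalence is age-graded in real
  samples, but independence is the default since no published
  parameterization of that dependence is available.
* The generating class index is stored in `true_class` but stripped by
  `analysis_view()` before any analysis stage; only parameter-recovery
  tests may read it.

**What passing tests on these cohorts do and do not show.** The generator
is class-conditionally independent (no response-style correlation inside a
tier), its comorbidity scores are symmetric normals (real CES-D/STAI
distributions are right-skewed), and its tiers are cleanly separated.
Results on it validate the *machinery* — estimator correctness, selection
behavior, index algebra, reproducibility — not the empirical sizes of
real-data quantities. Two consequences are worth naming: (a) comorbidity
risk ratios on default cohorts are modest (~1.5) because a normal
reference group with mean near the screening cutoff already has a ~50%
case rate; skewed real scores produce much larger ratios from the same
means and SDs. (b) Scheme-vs-benchmark predictive values follow the
nesting logic exactly (see §6).

## 3. Latent profile model and EM

K-class mixture of diagonal Gaussians over the six ratings; variances are
class-invariant by default (σ_j² shared across classes, p = (K−1) + 6K + 6
parameters), optionally class-varying (p = (K−1) + 12K). Class-invariant
is the convention of the software used for LPA in the applied literature,
and on rounded ratings it is also the *stable* choice: with class-varying
variances the likelihood is maximized by spike components sitting on
discrete cells at the variance floor, which is statistically meaningless.
The floor is 1e-3 on the rating scale; fits that touch it are flagged.

EM regime: `n_starts` initializations (the first refines k-means++
centroids via `scipy.cluster.vq.kmeans2`, the rest are jittered random
data rows), each run 20 short iterations; the best 5 by log-likelihood run
to convergence, declared when the relative LL change drops below `tol`
(default 1e-6). The LL path is asserted non-decreasing at every iteration.
A component whose expected count falls below one respondent aborts that
start; if every start aborts, the fit errors carrying the best partial
model. K=1 is closed form (sample means, ML variances, exact Gaussian
log-density sum).

## 4. Fit indices and tests

* BIC = −2LL + p·ln n; AIC = −2LL + 2p; sample-size-adjusted BIC =
  −2LL + p·ln((n+2)/24). Lower is better.
* Relative entropy E = 1 − Σ_i Σ_k (−p_ik ln p_ik) / (n ln K) ∈ [0, 1];
  E ≥ 0.80 is the conventional bar for crisp assignment. At K=1 the
  classification is trivially certain and E is defined as 1 (and excluded
  from the entropy filter).
* **Adjusted LRT (approximate).** 2ΔLL shrunk by a Bartlett-style factor
  1 + 1/(Δp·ln n) and referred to χ²(Δp). This is an analytic
  *approximation* in the spirit of the Lo–Mendell–Rubin test, explicitly
  labeled as such in the API; it is liberal on discretized data, and the
  bootstrap test is authoritative whenever the two disagree.
* **Bootstrap LRT.** Parametric bootstrap of 2(LL_K − LL_{K−1}) with
  p = (1 + #{replicate ≥ observed}) / (n_boot + 1). Two refinements make
  the null distribution faithful for rating data:
  1. *Observation filter.* When the observed indicators are integer
     ratings in 1–5 (auto-detected, overridable), replicates drawn from
     the fitted null mixture are rounded and clipped the same way. A
     Gaussian mixture is only an approximation to coarse ratings, and an
     extra class harvests a large likelihood gain from the discreteness
     itself; simulating continuous replicates would put none of that gain
     into the null distribution and the test would reject at every K.
  2. *Moment-matched generator.* Each null class's per-item latent mean
     and variance are re-estimated from its modal members by numerically
     inverting the round-and-clip observation model, so replicate rating
     distributions match the observed class-conditional ones instead of
     a doubly-smoothed version (rounded variances already contain the
     ~1/12 rounding variance). For continuous data both refinements are
     exact no-ops at a one-class null and consistent estimates otherwise,
     preserving the test's nominal calibration (verified: 13/200
     rejections at the 5% level under a one-class truth, inside the exact
     binomial 95% band).
  All fits inside the test — observed and replicate alike — use the same
  reduced multi-start regime, so the comparison is symmetric. Replicates
  that fail to converge are redrawn up to three times, then excluded with
  a warning.
* **Selection rule**: drop K with entropy < 0.80; among survivors require
  the LRT for K vs K−1 significant (p < .05) with the successor's LRT
  non-significant, taking the largest such K; otherwise fall back to the
  smallest surviving K. BLRT p-values are used when present, else the
  adjusted LRT. Every elimination lands in an audit trail that is written
  out even when selection fails. Information criteria are reported but do
  not enter the rule: on discretized ratings they decrease through every
  K and cannot locate the generating class count.

## 5. Assignment and labels

Modal assignment (argmax posterior; ties to the lowest class index).
Classes are ordered by the mean of their six item means; the lowest is
"low-risk", the highest "high-risk", all intermediates "at-risk". The
binary benchmark codes high-risk as positive and low + at-risk as
negative. Per-item pairwise group contrasts use two-sided Welch t tests
with Bonferroni adjustment within each item's family of pairs; pairs
involving a group of fewer than two members are flagged not computable.

## 6. Scheme benchmarking

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN), overall consistency (TP+TN)/n; any zero denominator yields a
"not computable" NaN, rendered "N/A" in formatted reports (which round to
integer percent; machine-readable output keeps full precision).

A structural note on expectations: under class-conditional independence
with itemwise endorsement probabilities increasing in tier, the criterion
count has a monotone likelihood ratio in the latent tier, so a stricter
(nested) scheme always has weakly *higher* PPV and lower sensitivity. On
default cohorts the polythetic scheme therefore shows the highest
sensitivity (~0.99) and the lowest PPV (~0.7), with the monothetic-style
schemes near PPV 1.0 at very low sensitivity. Real survey data can break
this ordering only through within-class dependence (e.g. response styles),
which the generator deliberately omits.

## 7. Comorbidity

Probable depression: CES-D ≥ 16; probable anxiety: STAI ≥ 40 (inclusive —
the threshold score is a case, matching standard screening practice).
Risk ratios are ratios of case proportions, with "not computable" for a
zero reference risk or empty stratum; an optional log-normal (Katz)
confidence interval is available but not part of the core report.
Demographic risk ratios use female sex and the 50–65 band as reference
levels. Group descriptives use n−1 SDs and a one-tailed Welch t test
(alternative: high-risk mean greater); Welch was chosen over the pooled
test because group sizes and variances are markedly unequal in this
setting, and the two agree in decision on balanced equal-variance data.
Cronbach's α = (k/(k−1))(1 − Σ item variances / total variance).

## 8. Pipeline and reproducibility

A master seed fans out to fixed-tag child seeds (simulate / lpa / blrt)
via `numpy.random.SeedSequence([master, tag])`, so toggling one stage
never perturbs another's randomness. All report CSVs are written with a
fixed float format; identical config + seed reproduce the bundle byte for
byte. Defaults: K ∈ {2…5}, all four schemes, 50 EM starts, 20 bootstrap
replicates (p-value floor 1/21 ≈ 0.048, just below the .05 rule), tol
1e-6. Stage failures after model selection mark the bundle partial rather
than discarding completed reports.

## 9. Problem sizes used in the test suite

Property and recovery tests run at the sizes where their guarantees are
sharp but affordable: exhaustive enumeration over all 2⁶ criterion
patterns; prevalence/margin checks at n = 5000–20000; class-count
recovery on 20 cohorts of n = 2000 with 20 bootstrap replicates per
comparison; bootstrap-LRT null calibration with 200 outer replicates of
n = 500 and 99 bootstrap draws each; concordance patterns on 20 cohorts
of n = 2000. The acceptance script analyzes one UK-like (n = 573) and one
US-like (n = 474) cohort, the sizes the study design targets.

## 10. Known limitations

* Items are class-conditionally independent; no copula or response-style
  dependence (out of scope by design).
* Comorbidity totals are normals, not item-level CES-D/STAI simulations;
  risk-ratio magnitudes on synthetic data are accordingly compressed.
* The adjusted LRT is an acknowledged approximation; it does not
  reproduce the conservative behavior of the original test's weighted
  reference distribution on misspecified (discretized) data.
* Ratings are modeled as continuous indicators inside the mixture, the
  standard practice for LPA on Likert items; an ordinal mixture model
  would be the principled alternative and is not implemented.
* The selection rule's behavior is validated on well-separated synthetic
  tiers; weakly separated real data may legitimately fail the entropy
  filter or the LRT chain, in which case the audit trail documents why.
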