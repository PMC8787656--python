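"""Evaluate each classification scheme against the latent benchmark.

The latent high-risk tier (vs low + at-risk) is the reference grouping;
each scheme's binary labels are cross-tabulated against it and summarized
by sensitivity, specificity, positive and negative predictive value, and
overall consistency.
"""

import bsmaskit as bk
from bsmaskit import benchmark, lpa
from bsmaskit.schemes import SCHEME_ORDER
from bsmaskit.simulate import ITEM_COLUMNS

cohort = bk.generate_cohort(bk.uk_like_spec(n=573, seed=42))
X = cohort[list(ITEM_COLUMNS)].to_numpy(dtype=float)

model, post = lpa.fit_lpa(X, 3, n_starts=20, seed=7)
_, _, high = lpa.assign_and_label(model, post)

report = benchmark.scheme_benchmark_report(cohort, SCHEME_ORDER, high)
print(report[["tp", "fp", "fn", "tn"]])
print()
print(benchmark.format_report_percent(report))
print()
print(
    "Monothetic-style schemes are so strict that nearly every respondent "
    "they flag is genuinely high-risk (PPV ~100%) but they miss most of "
    "the latent high-risk tier (low sensitivity); the polythetic scheme "
    "captures nearly the whole tier at the cost of some false positives "
    "from the at-risk tier."
)
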