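"""Kendall W effect sizes from reported repeated-measures statistics.

The Friedman chi-square from a subject x condition rank test converts to
the Kendall W concordance effect size as W = chi2 / (N (k-1)), where N is
the cohort size and k the number of conditions; W = 1 means perfectly
concordant rankings. This reproduces published worked examples.
"""

from micropursuit import kendall_w

cases = [
    ("inertia w.r.t. stimulus, N=23, k=3", 23.565, 23, 3),
    ("inertia w.r.t. fixation, N=23, k=3", 37.130, 23, 3),
    ("MPC contrast,            N=23, k=2", 23.0, 23, 2),
    ("inertia w.r.t. fixation, N=9,  k=3", 8.667, 9, 3),
    ("MPC contrast,            N=9,  k=2", 9.0, 9, 2),
    ("inertia w.r.t. fixation, N=10, k=3", 8.6, 10, 3),
    ("inertia w.r.t. stimulus, N=10, k=3", 2.4, 10, 3),
    ("MPC contrast,            N=10, k=2", 1.6, 10, 2),
]

for label, chi2, n, k in cases:
    print(f"{label}: chi2 = {chi2:7.3f}  ->  W = {kendall_w(chi2, n, k):.3f}")

# A chi-square equal to N(k-1) is the maximum the Friedman statistic can
# reach, so those contrasts print W = 1.000 (every subject ranked the
# conditions identically).
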