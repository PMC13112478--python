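"""Independent reference decompositions used as oracles by the test suite.

These accumulate sums of squares with explicit Python loops and share no code
with the package implementation.
"""

import numpy as np


def icc21_sums_oracle(table):
    """ICC(2,1) from explicitly accumulated two-way sums of squares."""
    table = np.asarray(table, float)
    n, k = table.shape
    grand = sum(sum(row) for row in table) / (n * k)
    ss_rows = sum((sum(row) / k - grand) ** 2 for row in table) * k
    ss_cols = sum((sum(table[:, j]) / n - grand) ** 2 for j in range(k)) * n
    ss_tot = sum((x - grand) ** 2 for row in table for x in row)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def rm_anova_f_sums_oracle(table):
    """Within-subject one-way RM-ANOVA F from explicit sums of squares."""
    table = np.asarray(table, float)
    n, m = table.shape
    grand = table.sum() / (n * m)
    ss_meth = n * sum((table[:, j].sum() / n - grand) ** 2 for j in range(m))
    ss_subj = m * sum((table[i].sum() / m - grand) ** 2 for i in range(n))
    ss_tot = sum((x - grand) ** 2 for row in table for x in row)
    ss_err = ss_tot - ss_meth - ss_subj
    return (ss_meth / (m - 1)) / (ss_err / ((n - 1) * (m - 1)))
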