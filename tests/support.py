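"""Shared helpers for the test suite: the desk-scale toy dataset and an
independent Wilcoxon signed-rank oracle."""

import math

import numpy as np
from scipy.stats import norm

from paleobridge.occurrences import CladeDataset


def toy_extinct_dataset() -> CladeDataset:
    """Three fossil bins (1, 2, 1 species at 10-12 Ma), extinct clade."""
    counts = np.zeros(13, dtype=int)
    counts[10:13] = [1, 2, 1]
    return CladeDataset("toy_extinct", "family", 0, counts)


#: fixed model parameters for the toy oracle comparison (the quadrature
#: marginalizes only (t0, te, trajectory), so the comparison is exact in
#: the same low-dimensional posterior the MCMC samples)
TOY_FIXED = dict(sigma2=0.05, q0=0.5, beta=0.0)
TOY_MAX_AGE = 50.0


def wilcoxon_oracle(x, y):
    """Hand-rolled two-sided Wilcoxon signed-rank test (normal
    approximation, zeros dropped, average ranks); independent of scipy."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(n)
    absd = np.abs(d)[order]
    r = np.arange(1, n + 1, dtype=float)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[j + 1] == absd[i]:
            j += 1
        r[i:j + 1] = r[i:j + 1].mean()
        i = j + 1
    ranks[order] = r
    w_plus = ranks[d > 0].sum()
    mean = n * (n + 1) / 4
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    return 2 * norm.sf(abs((w_plus - mean) / sd))
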