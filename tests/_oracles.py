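"""Independent oracles shared by unit and acceptance tests.

Each oracle recomputes a statistic by direct enumeration, independently of
the package's implementation path.
"""

import numpy as np
from scipy.stats import hypergeom, nbinom


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration.

    Sums P(X = x) over the support for every x whose point probability does
    not exceed the observed one (with a 1 + 1e-7 relative tolerance, the
    standard convention).
    """
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (n - row1))
    hi = min(col1, row1)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def chi2_textbook_oracle(table) -> float:
    """Pearson chi-squared by the Sum (O - E)^2 / E formula."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def nb_exact_test_oracle(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Conditional NB exact test by direct pmf enumeration over splits.

    Builds the conditional law of the first group sum given the total from
    scipy's nbinom pmf (converting mean/dispersion to (n, p) parameters)
    and doubles the smaller tail.
    """
    total = s1 + s2
    mu = total / (n1 + n2)

    def pmf(k, n_samples):
        mean = n_samples * mu
        disp = phi / n_samples
        r = 1.0 / disp
        p = r / (r + mean)
        return nbinom.pmf(k, r, p)

    ks = np.arange(total + 1)
    joint = pmf(ks, n1) * pmf(total - ks, n2)
    joint = joint / joint.sum()
    left = joint[: s1 + 1].sum()
    right = joint[s1:].sum()
    return float(min(1.0, 2.0 * min(left, right)))
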