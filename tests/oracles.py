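"""Independent brute-force oracles used by the test suite."""

from scipy.stats import hypergeom


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    With margins fixed, the table is determined by its top-left cell k;
    the two-sided p-value sums the probabilities of every k whose
    probability does not exceed that of the observed table (with the
    standard tiny relative slack for floating-point ties).
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    k_min, k_max = max(0, row1 + col1 - n), min(row1, col1)
    support = range(k_min, k_max + 1)
    pmf = hypergeom.pmf(list(support), n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
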