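"""Independent brute-force oracles shared by the test suite."""

from itertools import product

import numpy as np
from scipy.stats import rankdata


def wilcoxon_exact_oracle(diffs) -> float:
    """Two-sided signed-rank p by enumerating all sign assignments.

    Valid for untied, nonzero differences; independent of any library
    implementation of the test.
    """
    d = np.asarray(diffs, dtype=float)
    ranks = rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    n = len(d)
    t_all = np.array(
        [np.dot(signs, ranks) for signs in product([0, 1], repeat=n)]
    )
    cdf = np.mean(t_all <= t_obs)
    sf = np.mean(t_all >= t_obs)
    return min(1.0, 2 * min(cdf, sf))
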