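"""Independent oracles for distance computations.

Both solve the optimal-transport problem defining the first Wasserstein
distance without quantile integration, so they check the production code by a
different route: exhaustive assignment for equal-size samples, and a linear
program over the full transport polytope for unequal sizes.
"""

import itertools

import numpy as np
from scipy.optimize import linprog


def emd_permutation_oracle(a, b):
    """Minimum-cost perfect matching between equal-size samples (brute force).

    W1 between two n-point empirical distributions equals the minimum over
    permutations sigma of mean |a_i - b_sigma(i)|.  Exponential; n <= 8 only.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    assert a.size == b.size <= 8
    perms = np.array(list(itertools.permutations(range(b.size))))
    costs = np.abs(a[None, :] - b[perms]).mean(axis=1)
    return float(costs.min())


def emd_lp_oracle(a, b):
    """Exact transport linear program with uniform marginal weights."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    # row marginals: sum_j x_ij = 1/n; column marginals: sum_i x_ij = 1/m
    A_eq = np.zeros((n + m, n * m))
    for i in range(n):
        A_eq[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        A_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)
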