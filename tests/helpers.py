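"""Independent oracles used by the test suite.

These deliberately avoid the package's own recursions: the HMM likelihood is
an exhaustive sum over donor paths, and the Hardy-Weinberg probabilities use
exact integer combinatorics.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def enumerate_copying_loglik(recipient, donors, intervals, region_ids,
                             rho_eff, mu) -> float:
    """Total log-likelihood by brute-force enumeration of donor paths."""
    donors = np.asarray(donors)
    recipient = np.asarray(recipient)
    region_ids = np.asarray(region_ids)
    k, S = donors.shape
    total = 0.0
    start = 0
    for j in range(1, S + 1):
        if j == S or region_ids[j] != region_ids[j - 1]:
            n = j - start
            g = np.asarray(intervals[start + 1:j], dtype=float)
            prob = 0.0
            for path in itertools.product(range(k), repeat=n):
                p = 1.0 / k
                for t in range(n):
                    site = start + t
                    p *= (1 - mu) if donors[path[t], site] == recipient[site] \
                        else mu
                    if t < n - 1:
                        stay = math.exp(-rho_eff * g[t])
                        if path[t + 1] == path[t]:
                            p *= stay + (1 - stay) / k
                        else:
                            p *= (1 - stay) / k
                prob += p
            total += math.log(prob)
            start = j
    return total


def hwe_exact_pvalue_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value via exact rational enumeration."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, 2 * n - n_A)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        naa = (rare - h) // 2
        nAA = n - h - naa
        weights[h] = (
            Fraction(math.factorial(n),
                     math.factorial(nAA) * math.factorial(h)
                     * math.factorial(naa))
            * Fraction(2) ** h
        )
    total = sum(weights.values())
    p_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)
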