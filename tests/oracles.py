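"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's log-gamma code path: probabilities are
obtained by integrating binomial likelihoods against Beta densities on a dense
grid and by enumerating read-origin configurations directly.
"""

import numpy as np
from scipy.integrate import simpson
from scipy.stats import beta as beta_dist
from scipy.stats import binom

GRID = np.linspace(0.0, 1.0, 4001)


def quadrature_beta_binomial(k: int, m: int, a: float, b: float) -> float:
    """P(k | m) with rate integrated over a Beta(a, b) density on a dense grid."""
    pdf = beta_dist.pdf(GRID, a, b)
    like = binom.pmf(k, m, GRID)
    return simpson(like * pdf, x=GRID) / simpson(pdf, x=GRID)


def brute_force_posterior(N, n, a_loc, b_loc, a_dist=None, b_dist=None):
    """Posterior over N2 by enumerating error configurations per origin split.

    For each candidate N2, the N - N2 local reads produce j errors (observed
    distal) at rate theta1 ~ Beta(a_loc, b_loc); the N2 genuinely distal reads
    are each observed distal with probability 1 - theta2 (theta2 ~
    Beta(a_dist, b_dist)), or with certainty if no distal rates are given.
    Rates are integrated on a dense grid; a uniform prior over N2 applies.
    """
    like = np.zeros(N + 1)
    for n2 in range(N + 1):
        m1 = N - n2
        total = 0.0
        for j in range(0, n + 1):
            if j > m1:
                continue
            k2 = n - j  # mobile reads observed as distal
            if k2 > n2:
                continue
            p_local = quadrature_beta_binomial(j, m1, a_loc, b_loc)
            if a_dist is None:
                p_mobile = 1.0 if k2 == n2 else 0.0
            else:
                # observed-distal count among mobile reads: Binomial(n2, 1 - theta2)
                pdf = beta_dist.pdf(GRID, a_dist, b_dist)
                p_mobile = simpson(binom.pmf(k2, n2, 1.0 - GRID) * pdf, x=GRID) / simpson(
                    pdf, x=GRID
                )
            total += p_local * p_mobile
        like[n2] = total
    return like / like.sum()
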