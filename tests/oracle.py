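"""Independent brute-force evaluation of the decoding posterior.

Evaluates the generative equations literally, keeping the P(C_i) factors
explicitly (uniform over a finite column pool) instead of cancelling them,
and works in plain probability space. Kept deliberately independent of the
library's log-space implementation.
"""

import numpy as np

from decodon.codons import AA_ORDER, N_MODELS


def brute_force_posterior(
    emissions: np.ndarray, bg: np.ndarray, pool_size: int
) -> np.ndarray:
    """Posterior over the 21 decoding models for columns with the given
    emission vectors (rows), background bg, and P(C_i) = 1/pool_size."""
    emissions = np.atleast_2d(np.asarray(emissions, dtype=float))
    n = emissions.shape[0]
    p_c = 1.0 / pool_size
    lik = np.empty(N_MODELS)
    for a in range(len(AA_ORDER)):
        prod = 1.0
        for i in range(n):
            prod *= emissions[i, a] * p_c / bg[a]
        lik[a] = prod
    lik[-1] = p_c**n  # nonspecific model draws columns at random
    prior = 1.0 / N_MODELS
    joint = prior * lik
    return joint / joint.sum()
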