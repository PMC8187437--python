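"""Shared independent oracles for the test suite."""

import itertools

import numpy as np


def brute_force_best_path(log_emis, log_trans, log_init):
    """Score every one of the k^m state paths by direct enumeration and
    return the best (lexicographically first on ties, matching the
    lower-state tie-break of the decoder under test)."""
    k, m = log_emis.shape
    paths = np.array(list(itertools.product(range(k), repeat=m)),
                     dtype=np.int64)
    scores = log_init[paths[:, 0]] + log_emis[paths[:, 0], 0]
    for t in range(1, m):
        scores = (scores + log_trans[t - 1][paths[:, t - 1], paths[:, t]]
                  + log_emis[paths[:, t], t])
    best = int(np.argmax(scores))
    return paths[best], float(scores[best])
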