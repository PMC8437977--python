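"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def pair_counting_auc(scores, labels):
    """AUC by exhaustive comparison of all (event, non-event) pairs.

    A concordant pair counts 1, a tied pair 1/2 — the defining
    probabilistic interpretation of the ROC area, O(n^2) and independent of
    the rank-based implementation it checks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum(float(p > q) + 0.5 * float(p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
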