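import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20140511)


def brute_force_auroc(labels, scores):
    """Exhaustive pair-counting AUROC: (wins + 0.5*ties) / (n_pos * n_neg).

    Independent oracle for the rank-based implementation; O(n^2) on purpose.
    """
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    wins = sum(1 for p in pos for q in neg if p > q)
    ties = sum(1 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
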