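import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_signed_network(rng, m):
    """Dense random symmetric signed matrix, zero diagonal, weights in (-1, 1)."""
    A = rng.uniform(-1, 1, size=(m, m))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


def partitions_into_k(m, K):
    """All set partitions of range(m) into exactly K non-empty blocks,
    yielded as label vectors (restricted growth strings)."""

    def rec(i, labels, used):
        if i == m:
            if used == K:
                yield np.array(labels)
            return
        # pruning: remaining nodes must be able to open the missing blocks
        if used + (m - i) < K:
            return
        for lab in range(min(used + 1, K)):
            labels.append(lab)
            yield from rec(i + 1, labels, max(used, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)
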