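import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


# ---------------------------------------------------------------------
# Independent affine-gap alignment oracle: plain recursive enumeration of
# every global alignment path, scoring as it goes. Exponential — only for
# short sequences — and deliberately free of any alignment library.

def enumerate_global_score(a: str, b: str, score_fn, gap_open: float,
                           gap_extend: float) -> float:
    """Best global score over all alignments by exhaustive path enumeration.

    A gap of length L costs gap_open + (L-1)*gap_extend. ``score_fn(x, y)``
    scores an aligned residue pair.
    """
    best = [-float("inf")]

    def walk(i, j, acc, state):
        if i == len(a) and j == len(b):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, acc + score_fn(a[i], b[j]), 0)
        if i < len(a):  # gap in b row
            cost = gap_extend if state == 1 else gap_open
            walk(i + 1, j, acc - cost, 1)
        if j < len(b):  # gap in a row
            cost = gap_extend if state == 2 else gap_open
            walk(i, j + 1, acc - cost, 2)

    walk(0, 0, 0.0, 0)
    return best[0]
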