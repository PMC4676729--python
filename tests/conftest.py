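import numpy as np
import pytest

from lcrsim.sequences import DEFAULT_CHARGES, NupSequence
from lcrsim.synthetic import fixture_suite


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


def random_sequence(rng, max_len=200, charged_fraction=0.3):
    """Random amino-acid sequence with a controlled charged-residue load."""
    n = rng.integers(1, max_len + 1)
    frac = rng.random() * charged_fraction
    neutral = list("ASTNQGPFLYVMIWCH")
    charged = list(DEFAULT_CHARGES)
    seq = [
        str(rng.choice(charged)) if rng.random() < frac else str(rng.choice(neutral))
        for _ in range(n)
    ]
    return NupSequence("rand", "".join(seq))


def brute_force_lcr(seq, min_charges=2):
    """Independent O(L^2) oracle: enumerate every interval, keep those whose
    charged residues share one sign with at least ``min_charges`` of them,
    then filter to maximal intervals by direct boundary inspection."""
    q = [DEFAULT_CHARGES.get(aa, 0) for aa in seq.residues]
    L = len(q)
    out = []
    for i in range(L):
        for j in range(i, L):
            window = q[i : j + 1]
            npos = sum(1 for c in window if c > 0)
            nneg = sum(1 for c in window if c < 0)
            for sign, nsame, nopp in ((1, npos, nneg), (-1, nneg, npos)):
                if nopp or nsame < min_charges:
                    continue
                left_blocked = i == 0 or q[i - 1] == -sign
                right_blocked = j == L - 1 or q[j + 1] == -sign
                if left_blocked and right_blocked:
                    out.append((i + 1, j + 1, sign, nsame))
    out.sort(key=lambda r: (r[0], -r[2]))
    return out
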