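import numpy as np
import pytest

import panbalance as pb


@pytest.fixture(scope="session")
def basis():
    return pb.mango_basis()


@pytest.fixture(scope="session")
def sbp():
    return pb.mango_sbp()


@pytest.fixture(scope="session")
def norms():
    return pb.mango_norms()


def random_sbp_codes(n_parts: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a uniformly random valid SBP by recursive random bipartition."""
    rows = []
    stack = [list(range(n_parts))]
    while stack:
        group = stack.pop(rng.integers(len(stack)))
        while True:
            sides = rng.integers(0, 2, size=len(group))
            if sides.any() and not sides.all():
                break
        row = np.zeros(n_parts, dtype=int)
        plus = [g for g, s in zip(group, sides) if s]
        minus = [g for g, s in zip(group, sides) if not s]
        row[plus] = 1
        row[minus] = -1
        rows.append(row)
        for side in (plus, minus):
            if len(side) > 1:
                stack.append(side)
    return np.array(rows)
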