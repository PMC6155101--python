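import numpy as np
import pytest

from barreljoint import CAlphaTrace, ResidueId


@pytest.fixture
def linear_trace():
    """A 40-residue trace on a gentle helix (no collinear triples)."""
    n = 40
    t = np.arange(n)
    coords = np.stack(
        [3.0 * np.cos(0.3 * t), 3.0 * np.sin(0.3 * t), 1.5 * t], axis=1
    )
    residues = tuple((ResidueId(i + 1), "ALA") for i in range(n))
    return CAlphaTrace("A", residues, coords)


def rid(number, icode=""):
    return ResidueId(number, icode)
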