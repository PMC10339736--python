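import numpy as np
import pytest

from dhipea.fixtures import make_toy

# Fixture-suite toys use a wide gap (0.8 E_h) and narrow energy bands so that
# every 1h/1p root stays clear of the 2h1p/2p1h quasi-continuum -- the
# single-root-dominant regime the methods target.
GAP = 0.8


@pytest.fixture(scope="session")
def toy47():
    """The workhorse toy: 4 occupied, 6 virtual, 20 auxiliary, seed 7."""
    return make_toy(4, 6, 20, seed=7, gap_min=GAP)


@pytest.fixture(scope="session")
def toy_small():
    return make_toy(3, 4, 12, seed=11, gap_min=GAP)


@pytest.fixture(scope="session")
def toy_minimal():
    """One occupied, one virtual orbital: the hand-algebra base case."""
    return make_toy(1, 1, 6, seed=2, gap_min=GAP)


def seeded_toys(n, start_seed=0, sizes=((3, 4, 12), (4, 5, 14), (5, 7, 20),
                                        (2, 6, 12), (4, 6, 16))):
    """A ladder of deterministic small toys for oracle-equivalence sweeps."""
    out = []
    for t in range(n):
        o, v, q = sizes[t % len(sizes)]
        out.append(make_toy(o, v, q, seed=start_seed + t, gap_min=GAP))
    return out


@pytest.fixture
def water_xyz(tmp_path):
    p = tmp_path / "water.xyz"
    p.write_text(
        "3\nwater, equilibrium-ish geometry (angstrom)\n"
        "O   0.0000   0.0000   0.1173\n"
        "H   0.0000   0.7572  -0.4692\n"
        "H   0.0000  -0.7572  -0.4692\n"
    )
    return p
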